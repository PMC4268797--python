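"""Readers, writers and configuration shared by all pipeline stages.

All tabular formats are TSV with fixed column orders; nested summaries are
JSON; configuration is YAML.  Readers validate aggressively and name the
offending row/column/cell in their error messages, because silent schema
drift is the most common failure mode of hand-assembled expression tables.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classifier import ClassifierConfig
from .errors import ConfigurationError, InputError

__all__ = [
    "PipelineConfig",
    "read_expression",
    "write_expression",
    "read_annotation",
    "write_annotation",
    "read_qpcr",
    "write_qpcr",
    "read_interactions",
    "write_interactions",
    "read_gmt",
    "write_gmt",
    "validate_matrix_annotation",
]

_ANNOTATION_COLS = [
    "sample_id",
    "class_label",
    "icd10",
    "is_control",
    "include_pooled",
    "include_pairwise",
    "center",
]
_QPCR_COLS = ["sample_id", "class_label", "ct_target", "ct_reference"]
_INTERACTION_COLS = ["mirna_id", "gene_id", "evidence"]


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a feature x sample intensity matrix from TSV.

    Header row holds sample ids; first column holds feature ids.  Duplicate
    ids, missing cells and non-numeric cells are hard errors naming the
    offender.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dups = sorted({c for c in header if header.count(c) > 1})
    if dups:
        raise InputError(f"duplicated sample id(s): {dups[:5]}")
    # round_trip parsing: the default C parser can be 1 ulp off
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.columns = header  # undo pandas' duplicate-header mangling safeguard
    dup_f = df.index[df.index.duplicated()].tolist()
    if dup_f:
        raise InputError(f"duplicated feature id(s): {dup_f[:5]}")
    cols = {}
    for c in df.columns:
        col = df[c]
        if not np.issubdtype(col.dtype, np.number):
            num = pd.to_numeric(col, errors="coerce")
            bad = col.index[num.isna()]
            raise InputError(
                f"missing or non-numeric cell at feature {bad[0]!r}, sample {c!r}"
            )
        if col.isna().any():
            bad = col.index[col.isna()]
            raise InputError(
                f"missing or non-numeric cell at feature {bad[0]!r}, sample {c!r}"
            )
        cols[c] = col.astype(float)
    out = pd.DataFrame(cols, index=df.index)
    out.index.name = "feature_id"
    return out


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="feature_id")


# ---------------------------------------------------------------------------
# sample annotation
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _ANNOTATION_COLS[:-1] if c not in df.columns]
    if missing:
        raise InputError(f"annotation missing column(s): {missing}")
    if "center" not in df.columns:
        df["center"] = ""
    dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
    if dup:
        raise InputError(f"duplicated sample id(s) in annotation: {dup[:5]}")
    for c in ("is_control", "include_pooled", "include_pairwise"):
        df[c] = df[c].map({"True": True, "False": False, "1": True, "0": False})
        if df[c].isna().any():
            raise InputError(f"annotation column {c!r} must be boolean")
        df[c] = df[c].astype(bool)
    return df[_ANNOTATION_COLS]


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation[_ANNOTATION_COLS].to_csv(path, sep="\t", index=False)


def validate_matrix_annotation(matrix: pd.DataFrame, annotation: pd.DataFrame) -> None:
    """Require matrix columns and annotation sample ids to match exactly."""
    mcols = list(matrix.columns)
    aids = annotation["sample_id"].tolist()
    if mcols != aids:
        only_m = sorted(set(mcols) - set(aids))[:5]
        only_a = sorted(set(aids) - set(mcols))[:5]
        raise InputError(
            "matrix columns and annotation sample ids differ "
            f"(matrix-only: {only_m}, annotation-only: {only_a}, "
            f"order mismatch: {set(mcols) == set(aids)})"
        )


# ---------------------------------------------------------------------------
# qPCR / interactions / GMT
# ---------------------------------------------------------------------------

def read_qpcr(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _QPCR_COLS if c not in df.columns]
    if missing:
        raise InputError(f"qPCR table missing column(s): {missing}")
    dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
    if dup:
        raise InputError(f"duplicated sample id(s) in qPCR table: {dup[:5]}")
    for c in ("ct_target", "ct_reference"):
        vals = pd.to_numeric(df[c], errors="coerce")
        if vals.isna().any() or not np.isfinite(vals).all():
            bad = df.loc[vals.isna() | ~np.isfinite(vals), "sample_id"].iloc[0]
            raise InputError(f"non-finite {c} for sample {bad!r}")
        if (vals <= 0).any():
            bad = df.loc[vals <= 0, "sample_id"].iloc[0]
            raise InputError(f"non-positive {c} for sample {bad!r}")
        df[c] = vals.astype(float)
    return df[_QPCR_COLS]


def write_qpcr(table: pd.DataFrame, path: str | Path) -> None:
    table[_QPCR_COLS].to_csv(path, sep="\t", index=False)


def read_interactions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _INTERACTION_COLS if c not in df.columns]
    if missing:
        raise InputError(f"interaction table missing column(s): {missing}")
    return df[_INTERACTION_COLS].drop_duplicates(
        subset=["mirna_id", "gene_id"], ignore_index=True
    )


def write_interactions(table: pd.DataFrame, path: str | Path) -> None:
    table[_INTERACTION_COLS].to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT gene-set file: name TAB description TAB member...

    Lines with fewer than three fields are parse errors reported with their
    line number.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(f"GMT line {lineno}: expected >= 3 tab-separated fields")
            name = fields[0]
            if name in sets:
                raise InputError(f"GMT line {lineno}: duplicate set name {name!r}")
            sets[name] = set(fields[2:])
    return sets


def write_gmt(
    gene_sets: dict[str, set[str]],
    path: str | Path,
    descriptions: dict[str, str] | None = None,
) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and stage settings for the end-to-end pipeline."""

    alpha: float = 0.05
    n_boot: int = 2000
    ci_level: float = 0.95
    balloon_min_total: int = 8
    general_marker_min: int = 8
    equal_var: bool = False
    seed: int = 0
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must be in (0, 1)")
        if not 0.0 < self.ci_level < 1.0:
            raise ConfigurationError("ci_level must be in (0, 1)")
        if self.n_boot < 0:
            raise ConfigurationError("n_boot must be >= 0")
        if self.balloon_min_total < 0 or self.general_marker_min < 1:
            raise ConfigurationError("invalid balloon/general-marker thresholds")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["classifier"]["subset_sizes"] = list(self.classifier.subset_sizes)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        clf = d.pop("classifier", {})
        if "subset_sizes" in clf:
            clf["subset_sizes"] = tuple(clf["subset_sizes"])
        return cls(classifier=ClassifierConfig(**clf), **d)

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, seed=seed, classifier=replace(self.classifier, seed=seed))
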