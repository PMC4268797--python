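"""Cross-disease specificity machinery.

Given a multi-disease cohort, every disease is screened separately against the
control group, and each feature's profile — in how many diseases it is
significantly up- versus downregulated — drives three summaries:

* a balloon table counting features per (n_down, n_up) cell,
* "general disease marker" calls: features significant with one consistent
  direction in at least a threshold number of diseases and never in the
  opposite direction,
* "stable marker" calls: features whose cross-class one-way ANOVA stays
  non-significant after FDR adjustment (endogenous-control candidates).

Pairwise signatures (every unordered pair of eligible classes, controls
included as a class) and their uniqueness complete the picture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import benjamini_hochberg, resolve_selector, two_group_stats
from .errors import InputError

__all__ = [
    "ProfileSet",
    "PairwiseSignature",
    "per_disease_profiles",
    "balloon_table",
    "call_general_markers",
    "pairwise_signatures",
    "signature_uniqueness",
    "set_overlap",
    "auc_correlation",
    "anova_across_classes",
]


@dataclass
class ProfileSet:
    """Per-feature disease-specificity profiles.

    ``signif`` holds -1/0/+1 per (feature, disease): sign of a significant
    effect after per-disease BH adjustment, 0 if non-significant.  ``counts``
    aggregates to n_up / n_down per feature.
    """

    diseases: list[str]
    signif: pd.DataFrame
    p_adjusted: pd.DataFrame
    counts: pd.DataFrame
    alpha: float
    skipped: list[tuple[str, str]] = field(default_factory=list)


def per_disease_profiles(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    alpha: float = 0.05,
    equal_var: bool = False,
) -> ProfileSet:
    """Compare each eligible disease separately against controls.

    Each disease-vs-control comparison is BH-adjusted independently across
    features.  Direction comes from the sign of the t statistic.  Diseases
    with fewer than 2 samples are skipped with a warning and recorded.
    """
    ctrl_mask = resolve_selector(annotation, "controls")
    if ctrl_mask.sum() < 2:
        raise InputError("need at least 2 control samples")
    eligible = annotation.loc[
        annotation["include_pairwise"] & ~annotation["is_control"], "class_label"
    ]
    diseases = list(dict.fromkeys(eligible))
    if not diseases:
        raise InputError("no eligible disease classes")

    cols = annotation["sample_id"].to_numpy()
    xb = matrix[cols[ctrl_mask]].to_numpy(dtype=float)
    signif = {}
    padj = {}
    skipped: list[tuple[str, str]] = []
    kept = []
    for lab in diseases:
        mask = (annotation["class_label"] == lab).to_numpy()
        if mask.sum() < 2:
            warnings.warn(f"disease {lab!r} has < 2 samples; skipped")
            skipped.append((lab, "fewer than 2 samples"))
            continue
        xa = matrix[cols[mask]].to_numpy(dtype=float)
        ts = two_group_stats(xa, xb, equal_var=equal_var)
        adj = benjamini_hochberg(ts["p"])
        sig = np.where(adj < alpha, np.sign(ts["t"]).astype(int), 0)
        signif[lab] = sig
        padj[lab] = adj
        kept.append(lab)

    signif_df = pd.DataFrame(signif, index=matrix.index)
    padj_df = pd.DataFrame(padj, index=matrix.index)
    counts = pd.DataFrame(
        {
            "n_up": (signif_df > 0).sum(axis=1),
            "n_down": (signif_df < 0).sum(axis=1),
        },
        index=matrix.index,
    )
    return ProfileSet(
        diseases=kept,
        signif=signif_df,
        p_adjusted=padj_df,
        counts=counts,
        alpha=alpha,
        skipped=skipped,
    )


def balloon_table(profiles: ProfileSet | pd.DataFrame, min_total: int = 8) -> pd.DataFrame:
    """Count features per (n_down, n_up) cell, keeping n_down + n_up >= min_total.

    This is the tabular form of the balloon plot: each bubble's size is the
    number of features sharing that up/down pattern across diseases.
    """
    counts = profiles.counts if isinstance(profiles, ProfileSet) else profiles
    total = counts["n_up"] + counts["n_down"]
    kept = counts[total >= min_total]
    if kept.empty:
        return pd.DataFrame(columns=["n_down", "n_up", "count"]).astype(int)
    out = (
        kept.groupby(["n_down", "n_up"])
        .size()
        .rename("count")
        .reset_index()
        .sort_values(["n_down", "n_up"], ignore_index=True)
    )
    return out


def call_general_markers(
    profiles: ProfileSet | pd.DataFrame,
    min_diseases: int = 8,
    require_consistent: bool = True,
) -> pd.DataFrame:
    """Call features dysregulated one way in >= ``min_diseases`` diseases.

    With ``require_consistent`` (default) a feature is rejected if it is
    significant in the opposite direction in even one disease — the
    "upregulated in 10 diseases while not downregulated in any other" rule.
    Returns a DataFrame (feature_id, direction, n_up, n_down).
    """
    counts = profiles.counts if isinstance(profiles, ProfileSet) else profiles
    major = counts[["n_up", "n_down"]].max(axis=1)
    minor = counts[["n_up", "n_down"]].min(axis=1)
    called = major >= min_diseases
    if require_consistent:
        called &= minor == 0
    out = counts.loc[called].copy()
    out["direction"] = np.where(out["n_up"] >= out["n_down"], "up", "down")
    out.index.name = "feature_id"
    return out.reset_index()[["feature_id", "direction", "n_up", "n_down"]]


@dataclass(frozen=True)
class PairwiseSignature:
    class_a: str
    class_b: str
    significant_features: frozenset[str]

    @property
    def n_significant(self) -> int:
        return len(self.significant_features)


def pairwise_signatures(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    alpha: float = 0.05,
    equal_var: bool = False,
) -> list[PairwiseSignature]:
    """Significant-feature sets for every unordered pair of eligible classes.

    Controls count as one of the classes; classes flagged ``include_pairwise =
    False`` are omitted.  With k classes this yields C(k, 2) signatures, each
    BH-adjusted independently.  Pairs involving a class with < 2 samples are
    skipped with a warning.
    """
    eligible = annotation.loc[annotation["include_pairwise"], "class_label"]
    classes = list(dict.fromkeys(eligible))
    if len(classes) < 2:
        raise InputError("need at least 2 eligible classes")
    cols = annotation["sample_id"].to_numpy()
    blocks = {}
    for lab in classes:
        mask = (annotation["class_label"] == lab).to_numpy()
        blocks[lab] = matrix[cols[mask]].to_numpy(dtype=float)

    feats = matrix.index.to_numpy()
    out: list[PairwiseSignature] = []
    for a, b in combinations(classes, 2):
        if blocks[a].shape[1] < 2 or blocks[b].shape[1] < 2:
            warnings.warn(f"pair ({a!r}, {b!r}) skipped: a class has < 2 samples")
            continue
        ts = two_group_stats(blocks[a], blocks[b], equal_var=equal_var)
        adj = benjamini_hochberg(ts["p"])
        out.append(
            PairwiseSignature(
                class_a=a,
                class_b=b,
                significant_features=frozenset(feats[adj < alpha]),
            )
        )
    return out


def signature_uniqueness(
    signatures: Sequence[PairwiseSignature],
) -> dict[tuple[str, str], bool]:
    """Flag each pair whose significant set differs from every other pair's."""
    seen: dict[frozenset[str], int] = {}
    for sig in signatures:
        seen[sig.significant_features] = seen.get(sig.significant_features, 0) + 1
    return {
        (s.class_a, s.class_b): seen[s.significant_features] == 1 for s in signatures
    }


def comparison_counts(signatures: Sequence[PairwiseSignature]) -> pd.Series:
    """Per-feature count of pairwise comparisons in which it is significant."""
    counter: dict[str, int] = {}
    for sig in signatures:
        for f in sig.significant_features:
            counter[f] = counter.get(f, 0) + 1
    return pd.Series(counter, dtype=int).sort_index()


def set_overlap(set_a: Iterable, set_b: Iterable) -> tuple[int, int, int]:
    """Venn counts ``(|a only|, |shared|, |b only|)``."""
    a, b = set(set_a), set(set_b)
    return len(a - b), len(a & b), len(b - a)


def auc_correlation(records_a: pd.DataFrame, records_b: pd.DataFrame) -> float:
    """Pearson correlation of per-feature oriented AUCs between two screens."""
    a = records_a.set_index("feature_id")["auc_oriented"]
    b = records_b.set_index("feature_id")["auc_oriented"]
    if set(a.index) != set(b.index):
        raise InputError("comparisons cover different feature sets")
    b = b.reindex(a.index)
    return float(np.corrcoef(a.to_numpy(), b.to_numpy())[0, 1])


def anova_across_classes(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    alpha: float = 0.05,
    include_excluded: bool = False,
) -> pd.DataFrame:
    """One-way fixed-effects ANOVA per feature across all eligible classes.

    Features that stay non-significant after BH adjustment are flagged
    ``stable`` — candidates for endogenous normalization controls.  By default
    only ``include_pairwise`` classes enter (controls included); set
    ``include_excluded`` to use every class.  Features with zero variance in
    every class get F = 0, p = 1.
    """
    ann = annotation if include_excluded else annotation[annotation["include_pairwise"]]
    classes = list(dict.fromkeys(ann["class_label"]))
    groups = []
    for lab in classes:
        ids = ann.loc[ann["class_label"] == lab, "sample_id"].to_numpy()
        if ids.size < 2:
            warnings.warn(f"class {lab!r} has < 2 samples; excluded from ANOVA")
            continue
        groups.append(matrix[list(ids)].to_numpy(dtype=float))
    if len(groups) < 2:
        raise InputError("ANOVA needs at least 2 classes with >= 2 samples")
    with np.errstate(divide="ignore", invalid="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.f_oneway(*groups, axis=1)
    f = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    bad = ~np.isfinite(p)
    f[bad] = 0.0
    p[bad] = 1.0
    np.clip(p, np.finfo(float).tiny, 1.0, out=p)
    adj = benjamini_hochberg(p)
    return pd.DataFrame(
        {
            "feature_id": matrix.index,
            "f_statistic": f,
            "p_raw": p,
            "p_adjusted": adj,
            "stable": adj >= alpha,
        }
    ).reset_index(drop=True)
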