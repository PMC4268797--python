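"""Synthetic whole-blood miRNome cohorts with planted signal structure.

The generator emulates a multi-disease screening study: an intensity matrix of
miRNA features across samples drawn from a control cohort and many disease
cohorts, plus a qRT-PCR CT table for a validation subset.  Planted structure —
consistently dysregulated "general disease" markers, disease-specific markers,
low-variance "stable" markers, and near-background features whose patient mean
is inflated by sporadic high-expression spikes — gives every downstream
statistic a known ground truth.

The noise model is Gaussian on a fixed arbitrary intensity scale, clamped at
zero.  Gaussian noise keeps closed-form checks available: a marker shifted by
``delta`` against noise ``sigma`` has true AUC ``Phi(delta / (sigma * sqrt(2)))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .errors import ConfigurationError

__all__ = [
    "Cohort",
    "StudyDesign",
    "GeneralMarker",
    "SpecificMarker",
    "BackgroundFeature",
    "PlantedSignalSpec",
    "QpcrDesign",
    "default_study_design",
    "default_signal_spec",
    "default_qpcr_design",
    "generate_cohort",
    "generate_qpcr",
    "generate_interactions",
]


# ---------------------------------------------------------------------------
# study design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Cohort:
    label: str
    icd10: str
    n_samples: int


@dataclass(frozen=True)
class StudyDesign:
    """Class labels, cohort sizes and pooling rules for one screening study."""

    classes: tuple[Cohort, ...]
    control_label: str = "normal"
    excluded_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        labels = [c.label for c in self.classes]
        if len(set(labels)) != len(labels):
            raise ConfigurationError("class labels must be unique")
        if self.control_label not in labels:
            raise ConfigurationError(
                f"control label {self.control_label!r} not among classes"
            )
        for c in self.classes:
            if c.n_samples < 1:
                raise ConfigurationError(
                    f"cohort {c.label!r} has n_samples={c.n_samples}; need >= 1"
                )
        for lab in self.excluded_labels:
            if lab not in labels:
                raise ConfigurationError(f"excluded label {lab!r} not among classes")

    @property
    def n_total(self) -> int:
        return sum(c.n_samples for c in self.classes)

    @property
    def disease_labels(self) -> tuple[str, ...]:
        """Disease classes that enter pooled and per-disease comparisons."""
        return tuple(
            c.label
            for c in self.classes
            if c.label != self.control_label and c.label not in self.excluded_labels
        )


# The screening study's cohort table: 19 diseases (10 cancers, 9 non-cancer),
# healthy controls, long-lived individuals (excluded: age bias) and a mixed
# "others" group (excluded: unclear diagnoses), totalling 1,049 samples.
# Transcribed verbatim from the source cohort table.
_DEFAULT_COHORTS: tuple[tuple[str, str, int], ...] = (
    ("normal", "", 94),
    ("long-lived", "", 15),
    ("stomach tumor", "C16", 13),
    ("colon cancer", "C18", 29),
    ("lung cancer", "C24", 73),
    ("pancreatic ductal adenocarcinoma", "C25", 45),
    ("melanoma", "C43", 35),
    ("ovarian cancer", "C56", 24),
    ("prostate cancer", "C61", 65),
    ("wilms tumor", "C64", 124),
    ("renal cancer", "C65", 20),
    ("glioma", "C71", 20),
    ("sarcoidosis", "D86.0", 45),
    ("multiple sclerosis", "G35", 23),
    ("acute myocardial infarction", "I21.3", 62),
    ("non-ischemic systolic heart failure", "I42", 33),
    ("chronic obstructive pulmonary disease", "J40-47", 47),
    ("periodontitis", "K05.4", 18),
    ("pancreatitis", "K85", 37),
    ("psoriasis", "L40", 43),
    ("benign prostate hyperplasia", "N40", 35),
    ("others", "", 149),
)


def default_study_design() -> StudyDesign:
    """The 22-cohort screening design (1,049 samples, 20 eligible classes)."""
    return StudyDesign(
        classes=tuple(Cohort(*row) for row in _DEFAULT_COHORTS),
        control_label="normal",
        excluded_labels=("long-lived", "others"),
    )


# ---------------------------------------------------------------------------
# planted signal
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneralMarker:
    """A marker shifted with one direction in many diseases at once."""

    feature_id: str
    direction: str  # "up" | "down"
    shift: float
    diseases: tuple[str, ...] | str = "all"  # "all" = every eligible disease


@dataclass(frozen=True)
class SpecificMarker:
    feature_id: str
    disease: str
    direction: str
    shift: float


@dataclass(frozen=True)
class BackgroundFeature:
    """Near-background feature with sporadic high spikes in patients.

    With probability ``spike_prob`` a patient sample's value is multiplied by
    ``spike_scale``, producing a heavy right tail: the median stays near the
    background level while the patient mean rises well above it.
    """

    feature_id: str
    background_level: float = 5.4
    spike_prob: float = 0.2
    spike_scale: float = 8.0


@dataclass(frozen=True)
class PlantedSignalSpec:
    n_features: int
    general_markers: tuple[GeneralMarker, ...] = ()
    specific_markers: tuple[SpecificMarker, ...] = ()
    stable_markers: tuple[str, ...] = ()
    background_features: tuple[BackgroundFeature, ...] = ()
    noise_sd: float = 2.0
    baseline_mean: float = 10.0
    stable_sd_factor: float = 0.3  # stable markers: noise_sd scaled down by this

    def planted_ids(self) -> list[str]:
        ids = (
            [m.feature_id for m in self.general_markers]
            + [m.feature_id for m in self.specific_markers]
            + list(self.stable_markers)
            + [b.feature_id for b in self.background_features]
        )
        return ids

    def validate(self) -> None:
        ids = self.planted_ids()
        if len(set(ids)) != len(ids):
            raise ConfigurationError("planted marker lists must be disjoint")
        if len(ids) > self.n_features:
            raise ConfigurationError(
                f"{len(ids)} planted features exceed n_features={self.n_features}"
            )
        for m in list(self.general_markers) + list(self.specific_markers):
            if m.shift <= 0:
                raise ConfigurationError(f"shift must be > 0 for {m.feature_id}")
            if m.direction not in ("up", "down"):
                raise ConfigurationError(f"direction must be up/down for {m.feature_id}")
        for b in self.background_features:
            if not 0.0 <= b.spike_prob <= 1.0:
                raise ConfigurationError(f"spike_prob out of [0,1] for {b.feature_id}")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")


def default_signal_spec(design: StudyDesign | None = None) -> PlantedSignalSpec:
    """848-feature planted scenario mirroring the screening study's structure.

    34 general disease markers (22 down, 12 up) shifted by 1.5 noise SD in the
    first 14 eligible diseases, 10 disease-specific markers, 19 stable
    low-variance markers, and 5 near-background spike features.
    """
    design = design or default_study_design()
    diseases = design.disease_labels
    affected = tuple(diseases[:14])
    general = tuple(
        GeneralMarker(
            feature_id=f"miR-gen-{i:02d}",
            direction="down" if i < 22 else "up",
            shift=1.5 * 2.0,
            diseases=affected,
        )
        for i in range(34)
    )
    specific = tuple(
        SpecificMarker(
            feature_id=f"miR-spec-{i:02d}",
            disease=diseases[i],
            direction="up" if i % 2 == 0 else "down",
            shift=2.0 * 2.0,
        )
        for i in range(10)
    )
    stable = tuple(f"miR-stab-{i:02d}" for i in range(19))
    background = tuple(
        BackgroundFeature(feature_id=f"miR-bg-{i}", background_level=5.4)
        for i in range(5)
    )
    return PlantedSignalSpec(
        n_features=848,
        general_markers=general,
        specific_markers=specific,
        stable_markers=stable,
        background_features=background,
        noise_sd=2.0,
        baseline_mean=10.0,
    )


# ---------------------------------------------------------------------------
# expression cohort generation
# ---------------------------------------------------------------------------

def _feature_ids(signal: PlantedSignalSpec) -> list[str]:
    ids = signal.planted_ids()
    fill = signal.n_features - len(ids)
    taken = set(ids)
    out = list(ids)
    i = 0
    while len(out) < signal.n_features:
        cand = f"miR-sim-{i:04d}"
        if cand not in taken:
            out.append(cand)
        i += 1
        if i > signal.n_features + 10_000:  # pragma: no cover
            raise ConfigurationError("could not allocate filler feature ids")
    del fill
    return out


def build_annotation(design: StudyDesign) -> pd.DataFrame:
    """Sample annotation table implied by a study design."""
    rows = []
    i = 0
    for c in design.classes:
        for _ in range(c.n_samples):
            i += 1
            rows.append(
                {
                    "sample_id": f"S{i:04d}",
                    "class_label": c.label,
                    "icd10": c.icd10,
                    "is_control": c.label == design.control_label,
                    "include_pooled": c.label not in design.excluded_labels,
                    "include_pairwise": c.label not in design.excluded_labels,
                    "center": "simulated",
                }
            )
    return pd.DataFrame(rows)


def generate_cohort(
    design: StudyDesign, signal: PlantedSignalSpec, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate an (expression matrix, sample annotation) pair.

    The matrix is a features x samples DataFrame of nonnegative intensities.
    Identical ``(design, signal, seed)`` triples produce bit-identical output.
    """
    signal.validate()
    ann = build_annotation(design)
    feature_ids = _feature_ids(signal)
    n_feat, n_samp = signal.n_features, design.n_total
    rng = substream(seed, "cohort")

    row_of = {fid: i for i, fid in enumerate(feature_ids)}
    class_cols = {
        lab: np.flatnonzero((ann["class_label"] == lab).to_numpy())
        for lab in {c.label for c in design.classes}
    }
    eligible = design.disease_labels

    # per-row mean / sd, then one Gaussian draw for the whole matrix
    mean = np.full(n_feat, signal.baseline_mean)
    sd = np.full(n_feat, signal.noise_sd)
    for fid in signal.stable_markers:
        sd[row_of[fid]] = signal.noise_sd * signal.stable_sd_factor
    for bg in signal.background_features:
        mean[row_of[bg.feature_id]] = bg.background_level
    X = mean[:, None] + sd[:, None] * rng.standard_normal((n_feat, n_samp))

    for m in signal.general_markers:
        diseases = eligible if m.diseases == "all" else tuple(m.diseases)
        delta = m.shift if m.direction == "up" else -m.shift
        r = row_of[m.feature_id]
        for lab in diseases:
            X[r, class_cols[lab]] += delta
    for m in signal.specific_markers:
        delta = m.shift if m.direction == "up" else -m.shift
        X[row_of[m.feature_id], class_cols[m.disease]] += delta

    patient_cols = np.flatnonzero((~ann["is_control"]).to_numpy())
    for bg in signal.background_features:
        r = row_of[bg.feature_id]
        spikes = rng.random(patient_cols.size) < bg.spike_prob
        X[r, patient_cols[spikes]] *= bg.spike_scale

    np.maximum(X, 0.0, out=X)
    matrix = pd.DataFrame(X, index=feature_ids, columns=ann["sample_id"].tolist())
    matrix.index.name = "feature_id"
    return matrix, ann


# ---------------------------------------------------------------------------
# qRT-PCR generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QpcrDesign:
    """Groups and planted ΔΔCT effects for a qRT-PCR validation experiment.

    ``planted_ddct`` maps each class label to the ΔΔCT (cycles) of its mean
    ΔCT relative to the control group; the control maps to 0.  CT values for
    the endogenous reference gene fluctuate around ``ct_reference_mean`` and
    the target's control-group ΔCT sits at ``delta_ct_control``.
    """

    groups: tuple[tuple[str, int], ...]
    control_label: str
    planted_ddct: dict[str, float] = field(default_factory=dict)
    ct_reference_mean: float = 25.0
    delta_ct_control: float = 5.0
    ct_noise_sd: float = 0.5

    def validate(self) -> None:
        labels = [g[0] for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ConfigurationError("qPCR group labels must be unique")
        if self.control_label not in labels:
            raise ConfigurationError("qPCR control label missing from groups")
        for lab, n in self.groups:
            if n < 2:
                raise ConfigurationError(f"qPCR group {lab!r} needs >= 2 samples")
        for lab, d in self.planted_ddct.items():
            if not np.isfinite(d):
                raise ConfigurationError(f"non-finite planted ΔΔCT for {lab!r}")
        if self.ct_noise_sd < 0:
            raise ConfigurationError("ct_noise_sd must be >= 0")


def default_qpcr_design() -> QpcrDesign:
    """A 10-disease validation design with a planted general downregulation.

    Negative planted ΔΔCT follows the reporting convention used throughout the
    package: negative = target downregulated in the disease group.
    """
    diseases = [
        ("acute myocardial infarction", 30),
        ("non-ischemic systolic heart failure", 25),
        ("glioma", 20),
        ("pancreatitis", 20),
        ("breast cancer", 37),
        ("wilms tumor", 25),
        ("psoriasis", 20),
        ("renal cancer", 20),
        ("prostate cancer", 30),
        ("lung cancer", 25),
    ]
    return QpcrDesign(
        groups=(("normal", 60),) + tuple(diseases),
        control_label="normal",
        planted_ddct={lab: -1.9 for lab, _ in diseases},
    )


def generate_qpcr(design: QpcrDesign, seed: int) -> pd.DataFrame:
    """Generate a CT table (sample_id, class_label, ct_target, ct_reference)."""
    design.validate()
    rng = substream(seed, "qpcr")
    rows = []
    i = 0
    for lab, n in design.groups:
        ddct = design.planted_ddct.get(lab, 0.0)
        if lab == design.control_label:
            ddct = 0.0
        for _ in range(n):
            i += 1
            ct_ref = design.ct_reference_mean + design.ct_noise_sd * rng.standard_normal()
            ct_tgt = (
                ct_ref
                + design.delta_ct_control
                + ddct
                + design.ct_noise_sd * rng.standard_normal()
            )
            rows.append(
                {
                    "sample_id": f"Q{i:04d}",
                    "class_label": lab,
                    "ct_target": ct_tgt,
                    "ct_reference": ct_ref,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# toy interaction tables (network-stage plumbing)
# ---------------------------------------------------------------------------

def generate_interactions(
    mirna_ids: Sequence[str],
    seed: int,
    n_genes: int = 60,
    mean_targets: float = 6.0,
    hub_bias: float = 2.0,
) -> pd.DataFrame:
    """Synthetic miRNA-target edge table for exercising the network stage.

    Gene popularity is skewed (first genes are ``hub_bias`` times more likely
    to be drawn) so that shared hub targets arise, as in curated interaction
    databases.  Purely synthetic plumbing — not curated biology.
    """
    rng = substream(seed, "interactions")
    genes = [f"GENE{j:03d}" for j in range(n_genes)]
    w = hub_bias ** -(np.arange(n_genes) / max(n_genes - 1, 1) * 4)
    w /= w.sum()
    rows = []
    for mid in mirna_ids:
        k = max(1, rng.poisson(mean_targets))
        k = min(k, n_genes)
        for g in rng.choice(n_genes, size=k, replace=False, p=w):
            rows.append({"mirna_id": mid, "gene_id": genes[g], "evidence": "reporter_assay"})
    return pd.DataFrame(
        rows, columns=["mirna_id", "gene_id", "evidence"]
    ).drop_duplicates(ignore_index=True)


def with_null_signal(signal: PlantedSignalSpec) -> PlantedSignalSpec:
    """Copy of a signal spec with every planted effect removed (global null)."""
    return replace(
        signal,
        general_markers=(),
        specific_markers=(),
        stable_markers=(),
        background_features=(),
    )
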