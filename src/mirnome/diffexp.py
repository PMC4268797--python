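"""Per-miRNA two-group statistics.

Each feature is scored against a case/control split with a two-tailed unpaired
t-test (Welch by default, pooled-variance optional), Benjamini-Hochberg FDR
adjustment across the features of one comparison, median fold change, and the
rank-based (Mann-Whitney) AUC with a stratified percentile bootstrap
confidence interval.

Two AUC orientations are reported: ``auc_oriented`` is P(case > control) with
midrank tie handling — below 0.5 for downregulated features — and ``auc`` is
the discriminative value ``max(auc_oriented, 1 - auc_oriented)``, matching how
ROC tools auto-orient the curve (a strongly downregulated marker is still
reported with AUC > 0.5).
"""

from __future__ import annotations

import warnings
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._rng import substream
from .errors import DegenerateInputError, InputError

__all__ = [
    "ttest_two_tailed",
    "benjamini_hochberg",
    "auc_mann_whitney",
    "auc_bootstrap_ci",
    "roc_curve",
    "run_comparison",
    "resolve_selector",
]

_TINY_P = np.finfo(float).tiny


def _as_1d(v, name: str) -> np.ndarray:
    a = np.asarray(v, dtype=float).ravel()
    if a.size == 0:
        raise InputError(f"{name} is empty")
    if not np.all(np.isfinite(a)):
        raise InputError(f"{name} contains non-finite values")
    return a


def ttest_two_tailed(
    x: Sequence[float], y: Sequence[float], equal_var: bool = False
) -> tuple[float, float]:
    """Two-tailed unpaired t-test; returns ``(t, p)`` with sign(t) = sign(mean x - mean y).

    Welch's unequal-variance form by default; ``equal_var=True`` gives the
    pooled Student form.  Both groups need >= 2 observations.  If both groups
    have zero variance the test is undefined: equal means raise
    :class:`DegenerateInputError`, unequal means return ``(±inf, tiny)``.
    """
    xa, ya = _as_1d(x, "x"), _as_1d(y, "y")
    if xa.size < 2 or ya.size < 2:
        raise InputError("each group needs at least 2 observations")
    if np.ptp(xa) == 0.0 and np.ptp(ya) == 0.0:  # both groups constant
        d = float(xa[0] - ya[0])
        if d == 0.0:
            raise DegenerateInputError("zero variance in both groups with equal means")
        return (np.inf if d > 0 else -np.inf, _TINY_P)
    res = stats.ttest_ind(xa, ya, equal_var=equal_var)
    p = float(res.pvalue)
    return float(res.statistic), max(p, _TINY_P)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise InputError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def auc_mann_whitney(
    cases: Sequence[float], controls: Sequence[float]
) -> tuple[float, float, str]:
    """Rank AUC with midrank ties: ``(auc_oriented, auc, direction)``.

    ``auc_oriented = (#{case > control} + 0.5 * #{ties}) / (n1 * n2)`` is the
    normalized Mann-Whitney U; ``direction`` is ``"down"`` iff it is < 0.5.
    """
    c = _as_1d(cases, "cases")
    k = _as_1d(controls, "controls")
    ranks = stats.rankdata(np.concatenate([c, k]))
    u = ranks[: c.size].sum() - c.size * (c.size + 1) / 2.0
    oriented = float(u / (c.size * k.size))
    direction = "up" if oriented > 0.5 else ("down" if oriented < 0.5 else "none")
    return oriented, max(oriented, 1.0 - oriented), direction


def _bootstrap_auc_samples(
    cases: np.ndarray, controls: np.ndarray, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    """Oriented AUC for ``n_boot`` stratified (within-group) resamples."""
    n1, n2 = cases.size, controls.size
    bc = cases[rng.integers(0, n1, size=(n_boot, n1))]
    bk = controls[rng.integers(0, n2, size=(n_boot, n2))]
    ranks = stats.rankdata(np.concatenate([bc, bk], axis=1), axis=1)
    u = ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n2)


def auc_bootstrap_ci(
    cases: Sequence[float],
    controls: Sequence[float],
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Stratified percentile bootstrap CI for the oriented rank AUC.

    Samples are resampled with replacement within each group; the interval is
    the ``(1-level)/2`` and ``1-(1-level)/2`` percentiles of the bootstrap
    AUC distribution.  Deterministic for a fixed seed.
    """
    c = _as_1d(cases, "cases")
    k = _as_1d(controls, "controls")
    if c.size < 2 or k.size < 2:
        raise InputError("bootstrap needs >= 2 samples per group")
    if n_boot < 1:
        raise InputError("n_boot must be >= 1")
    if not 0.0 < level < 1.0:
        raise InputError("level must be in (0, 1)")
    rng = substream(seed, "auc-bootstrap")
    aucs = _bootstrap_auc_samples(c, k, n_boot, rng)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(aucs, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def roc_curve(
    cases: Sequence[float], controls: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """ROC points (fpr, tpr) for scoring cases above controls.

    The curve starts at (0,0), ends at (1,1), and its trapezoidal area equals
    the oriented rank AUC exactly (midrank ties appear as diagonal segments).
    """
    from sklearn.metrics import roc_curve as _sk_roc

    c = _as_1d(cases, "cases")
    k = _as_1d(controls, "controls")
    y = np.concatenate([np.ones(c.size), np.zeros(k.size)])
    fpr, tpr, _ = _sk_roc(y, np.concatenate([c, k]), drop_intermediate=False)
    return fpr, tpr


# ---------------------------------------------------------------------------
# whole-matrix comparisons
# ---------------------------------------------------------------------------

def resolve_selector(
    annotation: pd.DataFrame,
    selector: str | Sequence[str] | np.ndarray | Callable[[pd.DataFrame], np.ndarray],
) -> np.ndarray:
    """Boolean sample mask for a group selector.

    Accepts a class label, a list of labels, a boolean mask, a callable on the
    annotation table, or the keywords ``"all-disease"`` / ``"all-cancer"``
    (pool-eligible non-control samples; cancers identified by an ICD-10 "C"
    code) and ``"controls"``.
    """
    if callable(selector):
        mask = np.asarray(selector(annotation), dtype=bool)
    elif isinstance(selector, str):
        pooled = annotation["include_pooled"].to_numpy(dtype=bool)
        ctrl = annotation["is_control"].to_numpy(dtype=bool)
        if selector == "all-disease":
            mask = pooled & ~ctrl
        elif selector == "all-cancer":
            cancer = annotation["icd10"].fillna("").astype(str).str.startswith("C")
            mask = pooled & ~ctrl & cancer.to_numpy()
        elif selector == "controls":
            mask = ctrl
        else:
            mask = (annotation["class_label"] == selector).to_numpy()
    elif isinstance(selector, np.ndarray) and selector.dtype == bool:
        mask = selector
    else:
        mask = annotation["class_label"].isin(list(selector)).to_numpy()
    if mask.shape != (len(annotation),):
        raise InputError("selector mask length does not match annotation")
    return mask


def two_group_stats(
    xa: np.ndarray, xb: np.ndarray, equal_var: bool = False
) -> dict[str, np.ndarray]:
    """Vectorized per-row t statistics for two sample blocks (rows = features).

    Rows where both groups have zero variance are flagged degenerate: equal
    means give ``t=0, p=1``; unequal means give ``t=±inf`` and a tiny p.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(xa, xb, axis=1, equal_var=equal_var)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    var_a = xa.var(axis=1)
    var_b = xb.var(axis=1)
    diff = xa.mean(axis=1) - xb.mean(axis=1)
    degenerate = (var_a == 0) & (var_b == 0)
    flat = degenerate & (diff == 0)
    sep = degenerate & (diff != 0)
    t[flat] = 0.0
    p[flat] = 1.0
    t[sep] = np.where(diff[sep] > 0, np.inf, -np.inf)
    p[sep] = _TINY_P
    bad = ~np.isfinite(p)
    p[bad] = 1.0
    t[bad & ~np.isfinite(t)] = 0.0
    np.clip(p, _TINY_P, 1.0, out=p)
    return {"t": t, "p": p, "degenerate": degenerate}


def matrix_auc(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Oriented rank AUC per row: P(case > control) with midrank ties."""
    n1 = xa.shape[1]
    ranks = stats.rankdata(np.concatenate([xa, xb], axis=1), axis=1)
    u = ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2.0
    return u / (n1 * xb.shape[1])


def run_comparison(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    group_a,
    group_b,
    *,
    alpha: float = 0.05,
    equal_var: bool = False,
    n_boot: int = 0,
    ci_level: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Full two-group screen: one row of statistics per feature.

    ``group_a`` is the case side, ``group_b`` the control side (selectors as in
    :func:`resolve_selector`; the two sample sets must be disjoint and each
    have >= 2 members).  BH adjustment is applied across the features of this
    comparison only.  Bootstrap AUC confidence intervals are computed when
    ``n_boot > 0``; otherwise the ci columns are NaN.

    Fold change is the ratio of group medians (case / control); the mean
    columns are retained because near-background features can carry their
    signal in the mean, not the median.
    """
    mask_a = resolve_selector(annotation, group_a)
    mask_b = resolve_selector(annotation, group_b)
    if np.any(mask_a & mask_b):
        raise InputError("case and control selectors overlap")
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise InputError("each group needs at least 2 samples")
    cols = annotation["sample_id"].to_numpy()
    xa = matrix[cols[mask_a]].to_numpy(dtype=float)
    xb = matrix[cols[mask_b]].to_numpy(dtype=float)

    ts = two_group_stats(xa, xb, equal_var=equal_var)
    p_adj = benjamini_hochberg(ts["p"])
    oriented = matrix_auc(xa, xb)
    oriented[ts["degenerate"]] = 0.5

    med_a = np.median(xa, axis=1)
    med_b = np.median(xb, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = med_a / med_b
    direction = np.where(oriented > 0.5, "up", np.where(oriented < 0.5, "down", "none"))

    ci_low = np.full(matrix.shape[0], np.nan)
    ci_high = np.full(matrix.shape[0], np.nan)
    if n_boot > 0:
        rng = substream(seed, "comparison-bootstrap")
        alpha_tail = (1.0 - ci_level) / 2.0
        for i in range(matrix.shape[0]):
            aucs = _bootstrap_auc_samples(xa[i], xb[i], n_boot, rng)
            ci_low[i], ci_high[i] = np.quantile(aucs, [alpha_tail, 1.0 - alpha_tail])

    return pd.DataFrame(
        {
            "feature_id": matrix.index,
            "median_case": med_a,
            "median_control": med_b,
            "mean_case": xa.mean(axis=1),
            "mean_control": xb.mean(axis=1),
            "fold_change": fold,
            "direction": direction,
            "t_statistic": ts["t"],
            "p_raw": ts["p"],
            "p_adjusted": p_adj,
            "auc_oriented": oriented,
            "auc": np.maximum(oriented, 1.0 - oriented),
            "ci_low": ci_low,
            "ci_high": ci_high,
            "degenerate": ts["degenerate"],
            "significant": p_adj < alpha,
        }
    ).reset_index(drop=True)
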