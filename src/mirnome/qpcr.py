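"""Relative quantification of qRT-PCR data by the 2^-ΔΔCT method.

Each sample's target CT is normalized by an endogenous reference gene
(ΔCT = CT_target - CT_reference); group contrasts are formed on the mean ΔCT
(ΔΔCT = mean ΔCT case - mean ΔCT control).

Sign convention: because higher CT means later amplification (less template),
a *positive* ΔΔCT under the formula above corresponds to lower target
expression in cases.  Published tables, however, frequently print a negative
ΔΔCT next to "downregulated x-fold".  This module therefore reports the fold
change as a magnitude ``2**|ΔΔCT|`` together with an explicit ``direction``
field, interpreting negative ΔΔCT as downregulation — reproducing the printed
(ΔΔCT, fold) convention without asserting the ambiguous sign.  The group test
on ΔCT values is a two-tailed Welch t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexp import benjamini_hochberg, ttest_two_tailed
from .errors import DegenerateInputError, InputError

__all__ = ["DdctResult", "delta_ct", "ddct_fold_change", "per_disease_qpcr"]


def delta_ct(ct_target, ct_reference) -> np.ndarray | float:
    """ΔCT = CT_target - CT_reference (element-wise for vectors)."""
    t = np.asarray(ct_target, dtype=float)
    r = np.asarray(ct_reference, dtype=float)
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(r))):
        raise InputError("CT values must be finite")
    d = t - r
    return float(d) if d.ndim == 0 else d


@dataclass(frozen=True)
class DdctResult:
    case_label: str
    control_label: str
    n_case: int
    n_control: int
    delta_ct_case_mean: float
    delta_ct_control_mean: float
    delta_delta_ct: float
    fold_change_magnitude: float  # 2 ** |ΔΔCT|, always >= 1
    direction: str  # "down" iff ΔΔCT < 0 (printed convention), "none" iff 0
    p_raw: float
    p_adjusted: float = np.nan


def _group_delta_ct(table: pd.DataFrame, label: str) -> np.ndarray:
    grp = table[table["class_label"] == label]
    if len(grp) < 2:
        raise InputError(f"group {label!r} has {len(grp)} samples; need >= 2")
    return delta_ct(grp["ct_target"].to_numpy(), grp["ct_reference"].to_numpy())


def ddct_fold_change(
    table: pd.DataFrame, case_label: str, control_label: str
) -> DdctResult:
    """ΔΔCT contrast of one disease group against the control group.

    ``table`` needs columns sample_id, class_label, ct_target, ct_reference.
    Fold magnitude is reported at full precision (round to one decimal for
    display); the p-value comes from a Welch t-test on the per-sample ΔCTs.
    """
    dc_case = _group_delta_ct(table, case_label)
    dc_ctrl = _group_delta_ct(table, control_label)
    ddct = float(dc_case.mean() - dc_ctrl.mean())
    try:
        _, p = ttest_two_tailed(dc_case, dc_ctrl)
    except DegenerateInputError:  # identical noise-free groups: no evidence
        p = 1.0
    direction = "none" if ddct == 0 else ("down" if ddct < 0 else "up")
    return DdctResult(
        case_label=case_label,
        control_label=control_label,
        n_case=dc_case.size,
        n_control=dc_ctrl.size,
        delta_ct_case_mean=float(dc_case.mean()),
        delta_ct_control_mean=float(dc_ctrl.mean()),
        delta_delta_ct=ddct,
        fold_change_magnitude=float(2.0 ** abs(ddct)),
        direction=direction,
        p_raw=p,
    )


def per_disease_qpcr(
    table: pd.DataFrame, control_label: str, alpha: float = 0.05
) -> pd.DataFrame:
    """ΔΔCT contrast of every disease group vs control, BH-adjusted across diseases.

    Returns one row per disease with the :class:`DdctResult` fields plus a
    ``significant`` flag at ``alpha``.
    """
    labels = [
        lab for lab in dict.fromkeys(table["class_label"]) if lab != control_label
    ]
    if not labels:
        raise InputError("no disease groups in qPCR table")
    results = [ddct_fold_change(table, lab, control_label) for lab in labels]
    padj = benjamini_hochberg([r.p_raw for r in results])
    rows = []
    for r, pa in zip(results, padj):
        d = r.__dict__.copy()
        d["p_adjusted"] = float(pa)
        d["significant"] = pa < alpha
        rows.append(d)
    return pd.DataFrame(rows)
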