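"""Independent brute-force oracles used to cross-check the implementations.

Everything here is written from the textbook definition of each quantity and
stays independent of the code paths it validates.
"""

from itertools import combinations

import numpy as np
from scipy.special import stdtr


def bh_stepup(p_values) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up: adj_(i) = min_{j>=i} min(1, m p_(j)/j)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        adj_sorted[rank - 1] = min(1.0, running)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def auc_paircount(cases, controls) -> float:
    """P(case > control) by exhaustive pair enumeration, ties counted half."""
    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    wins = sum(1.0 for c in cases for k in controls if c > k)
    ties = sum(1.0 for c in cases for k in controls if c == k)
    return (wins + 0.5 * ties) / (cases.size * controls.size)


def ora_enumeration(universe: set, gene_set: set, query: set) -> float:
    """P(overlap >= observed) by enumerating all size-|query| draws."""
    uni = sorted(universe)
    inset = gene_set & universe
    k_obs = len(query & inset)
    n = len(query)
    hits = 0
    total = 0
    for draw in combinations(uni, n):
        total += 1
        if len(set(draw) & inset) >= k_obs:
            hits += 1
    return hits / total


def welch_t_p(x, y) -> tuple[float, float]:
    """Welch t and two-tailed p from first principles (Satterthwaite df, stdtr)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = x.size, y.size
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stdtr(df, -abs(t))
    return float(t), float(p)
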