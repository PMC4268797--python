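"""Multi-miRNA classification with filter feature selection and permutation nulls.

The procedure mirrors a common biomarker-panel evaluation: repeated stratified
10-fold cross-validation of an SVM, with a stepwise-forward *filter* subset
selection — features ranked by their per-feature t-test p-value, models
trained on growing prefixes of the ranking — and, as an overtraining control,
the identical evaluation repeated with randomly permuted class labels.

When cohorts are unbalanced, the larger class is subsampled without
replacement to the smaller class's size once per repetition ("equal cohort
sizes").  Decision values are pooled across held-out folds to form one ROC per
(subset size, repetition).

Feature ranking is recomputed inside each training split by default
(``ranking_mode="within_fold"``), which keeps the held-out folds untouched by
selection.  A ``"global"`` mode that ranks once on the full data set is kept
because published procedures are often ambiguous on this point; on pure-noise
data it exhibits the classic selection-bias optimism, which the test suite
documents explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from ._rng import substream
from .diffexp import auc_mann_whitney, resolve_selector, two_group_stats
from .errors import ConfigurationError, InputError

__all__ = ["ClassifierConfig", "ClassifierEvaluation", "filter_rank", "evaluate",
           "classification_report"]


@dataclass(frozen=True)
class ClassifierConfig:
    kernel: str = "rbf"  # "rbf" | "linear"
    n_folds: int = 10
    n_repetitions: int = 10
    n_permutations: int = 10  # permutation runs per (subset size, repetition)
    subset_sizes: tuple[int, ...] = (1, 2, 5, 10, 20)
    ranking_mode: str = "within_fold"  # "within_fold" | "global"
    equal_cohort: bool = True
    svm_cost: float = 1.0
    seed: int = 0

    def validate(self, n_features: int) -> None:
        if self.kernel not in ("rbf", "linear"):
            raise ConfigurationError(f"unknown kernel {self.kernel!r}")
        if self.n_folds < 2:
            raise ConfigurationError("n_folds must be >= 2")
        if self.n_repetitions < 1:
            raise ConfigurationError("n_repetitions must be >= 1")
        if self.ranking_mode not in ("within_fold", "global"):
            raise ConfigurationError(f"unknown ranking_mode {self.ranking_mode!r}")
        for k in self.subset_sizes:
            if not 1 <= k <= n_features:
                raise ConfigurationError(
                    f"subset size {k} out of range 1..{n_features}"
                )


def filter_rank(features: pd.DataFrame | np.ndarray, labels: Sequence[int]) -> np.ndarray:
    """Rank features (rows) by two-group t-test p-value, best first.

    Ties broken by descending |t|, then by feature order/id, so the ranking is
    deterministic and invariant to swapping the label encoding.  Degenerate
    features (undefined test) sort last.
    """
    X = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) else np.asarray(features, dtype=float)
    y = np.asarray(labels)
    uniq = np.unique(y)
    if uniq.size != 2:
        raise InputError("filter_rank needs exactly two classes")
    xa, xb = X[:, y == uniq[1]], X[:, y == uniq[0]]
    if xa.shape[1] < 2 or xb.shape[1] < 2:
        raise InputError("each class needs >= 2 samples")
    ts = two_group_stats(xa, xb)
    p = ts["p"].copy()
    p[ts["degenerate"]] = np.inf  # rank degenerate features last
    order = np.lexsort((np.arange(X.shape[0]), -np.abs(ts["t"]), p))
    if isinstance(features, pd.DataFrame):
        return features.index.to_numpy()[order]
    return order


@dataclass
class ClassifierEvaluation:
    """Long-format metrics for real and permutation runs plus best-run detail."""

    config: ClassifierConfig
    results: pd.DataFrame  # subset_size, repetition, permutation, accuracy, ...
    selected_features: dict[tuple[int, int], tuple[str, ...]]
    best_size: int
    best_repetition: int
    best_auc: float
    best_decisions: pd.DataFrame  # sample_id, y_true, decision_value


def _make_svm(config: ClassifierConfig) -> SVC:
    return SVC(kernel=config.kernel, C=config.svm_cost, gamma="scale")


def _cv_metrics(
    X: np.ndarray,
    y: np.ndarray,
    config: ClassifierConfig,
    sizes: Sequence[int],
    fold_seed: int,
    global_order: np.ndarray | None,
) -> dict[int, dict]:
    """One cross-validation pass; returns per-size metrics and pooled decisions."""
    n_folds = min(config.n_folds, int(np.bincount(y).min()))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=fold_seed)
    n = y.size
    decisions = {k: np.zeros(n) for k in sizes}
    preds = {k: np.zeros(n, dtype=int) for k in sizes}
    for train, test in skf.split(X.T, y):
        if global_order is not None:
            order = global_order
        else:
            order = filter_rank(X[:, train], y[train])
        for k in sizes:
            feats = order[:k]
            clf = _make_svm(config)
            clf.fit(X[np.ix_(feats, train)].T, y[train])
            Xt = X[np.ix_(feats, test)].T
            decisions[k][test] = clf.decision_function(Xt)
            preds[k][test] = clf.predict(Xt)
    out = {}
    for k in sizes:
        yhat = preds[k]
        acc = float(np.mean(yhat == y))
        sens = float(np.mean(yhat[y == 1] == 1))
        spec = float(np.mean(yhat[y == 0] == 0))
        auc, _, _ = auc_mann_whitney(decisions[k][y == 1], decisions[k][y == 0])
        out[k] = {
            "accuracy": acc,
            "sensitivity": sens,
            "specificity": spec,
            "auc": auc,
            "decisions": decisions[k],
        }
    return out


def evaluate(
    config: ClassifierConfig,
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    class_a,
    class_b,
) -> ClassifierEvaluation:
    """Repeated cross-validated SVM evaluation of ``class_a`` (cases) vs ``class_b``.

    Per repetition the larger class is subsampled to the smaller's size (if
    ``equal_cohort``), folds are re-drawn, and every subset size is evaluated
    on real labels once and on ``n_permutations`` label permutations.  All
    randomness derives deterministically from ``config.seed``.
    """
    config.validate(matrix.shape[0])
    mask_a = resolve_selector(annotation, class_a)
    mask_b = resolve_selector(annotation, class_b)
    if np.any(mask_a & mask_b):
        raise InputError("class selectors overlap")
    cols = annotation["sample_id"].to_numpy()
    ids_a, ids_b = cols[mask_a], cols[mask_b]
    if ids_a.size < 2 or ids_b.size < 2:
        raise InputError("each class needs >= 2 samples")

    rows = []
    selected: dict[tuple[int, int], tuple[str, ...]] = {}
    best = (-1.0, None)  # (auc, (size, rep, decisions, sample_ids, y))
    for rep in range(config.n_repetitions):
        rng = substream(config.seed, "classifier", rep)
        a, b = ids_a, ids_b
        if config.equal_cohort:
            m = min(a.size, b.size)
            if a.size > m:
                a = rng.choice(a, size=m, replace=False)
            if b.size > m:
                b = rng.choice(b, size=m, replace=False)
        sample_ids = np.concatenate([a, b])
        y = np.concatenate([np.ones(a.size, dtype=int), np.zeros(b.size, dtype=int)])
        X = matrix[list(sample_ids)].to_numpy(dtype=float)
        fold_seed = int(rng.integers(0, 2**31 - 1))

        idx_of = {fid: i for i, fid in enumerate(matrix.index)}
        full_order = filter_rank(pd.DataFrame(X, index=matrix.index), y)
        global_order = None
        if config.ranking_mode == "global":
            global_order = np.array([idx_of[f] for f in full_order])

        real = _cv_metrics(X, y, config, config.subset_sizes, fold_seed, global_order)
        for k in config.subset_sizes:
            m = real[k]
            rows.append(
                {
                    "subset_size": k,
                    "repetition": rep,
                    "permutation": -1,
                    "accuracy": m["accuracy"],
                    "sensitivity": m["sensitivity"],
                    "specificity": m["specificity"],
                    "auc": m["auc"],
                }
            )
            selected[(k, rep)] = tuple(full_order[:k])
            if m["auc"] > best[0]:
                best = (m["auc"], (k, rep, m["decisions"], sample_ids, y))
        for pi in range(config.n_permutations):
            yp = rng.permutation(y)
            pseed = int(rng.integers(0, 2**31 - 1))
            if config.ranking_mode == "global":
                perm_order = filter_rank(pd.DataFrame(X, index=matrix.index), yp)
                g = np.array([idx_of[f] for f in perm_order])
            else:
                g = None
            perm = _cv_metrics(X, yp, config, config.subset_sizes, pseed, g)
            for k in config.subset_sizes:
                m = perm[k]
                rows.append(
                    {
                        "subset_size": k,
                        "repetition": rep,
                        "permutation": pi,
                        "accuracy": m["accuracy"],
                        "sensitivity": m["sensitivity"],
                        "specificity": m["specificity"],
                        "auc": m["auc"],
                    }
                )

    best_auc, (bk, brep, bdec, bids, by) = best
    best_decisions = pd.DataFrame(
        {"sample_id": bids, "y_true": by, "decision_value": bdec}
    )
    return ClassifierEvaluation(
        config=config,
        results=pd.DataFrame(rows),
        selected_features=selected,
        best_size=bk,
        best_repetition=brep,
        best_auc=float(best_auc),
        best_decisions=best_decisions,
    )


def classification_report(evaluation: ClassifierEvaluation) -> dict:
    """Summaries of an evaluation: quartiles per metric, best-run ROC, decisions.

    The best run is the real run with maximal AUC (ties: first by repetition
    index, enforced during evaluation).  Row count of ``evaluation.results``
    is #sizes x #repetitions x (1 + #permutations).
    """
    from .diffexp import roc_curve

    res = evaluation.results.copy()
    res["kind"] = np.where(res["permutation"] < 0, "real", "permutation")
    long = res.melt(
        id_vars=["subset_size", "repetition", "permutation", "kind"],
        value_vars=["accuracy", "sensitivity", "specificity", "auc"],
        var_name="metric",
    )
    summary = (
        long.groupby(["kind", "metric"])["value"]
        .describe(percentiles=[0.25, 0.5, 0.75])
        .reset_index()
    )
    dec = evaluation.best_decisions
    fpr, tpr = roc_curve(
        dec.loc[dec["y_true"] == 1, "decision_value"],
        dec.loc[dec["y_true"] == 0, "decision_value"],
    )
    return {
        "summary": summary,
        "long": long,
        "best": {
            "subset_size": evaluation.best_size,
            "repetition": evaluation.best_repetition,
            "auc": evaluation.best_auc,
        },
        "roc": pd.DataFrame({"fpr": fpr, "tpr": tpr}),
        "decisions": dec,
    }
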