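"""Classification metrics, feature analyses and cluster-aware cross-validation.

Metrics follow the conventions of the catalytic-residue literature:
sensitivity and precision on the percent scale, F1 as their harmonic mean
(also on the percent scale), and the Matthews correlation coefficient
(MCC) on [-1, 1] with the zero-marginal convention MCC = 0.  Residues
removed by the conservation prefilter always count as negative calls, so
the evaluation universe is the full input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

FEATURE_COLUMNS = ["conserv", "distance", "closeness", "between", "pagerank", "rsa"]
TABLE1_COLUMNS = FEATURE_COLUMNS + ["function"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricSet:
    mcc: float
    sensitivity: float | None  # percent
    precision: float | None  # percent
    f1: float | None  # percent scale


def confusion_counts(calls, truth) -> ConfusionCounts:
    """Tally TP/TN/FP/FN from binary call and truth vectors."""
    calls = np.asarray(calls, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if calls.shape != truth.shape:
        raise ValueError("calls and truth must have equal length")
    tp = int(np.sum((calls == 1) & (truth == 1)))
    tn = int(np.sum((calls == 0) & (truth == 0)))
    fp = int(np.sum((calls == 1) & (truth == 0)))
    fn = int(np.sum((calls == 0) & (truth == 1)))
    return ConfusionCounts(tp, tn, fp, fn)


def matthews_cc(c: ConfusionCounts) -> float:
    """MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)); 0 if a marginal is 0."""
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def f1_percent(sensitivity: float, precision: float) -> float:
    """Harmonic mean of sensitivity and precision, both on the percent scale."""
    if sensitivity + precision == 0:
        return 0.0
    return 2.0 * sensitivity * precision / (sensitivity + precision)


def classification_metrics(c: ConfusionCounts) -> MetricSet:
    """Sensitivity, precision (percent), F1 (percent scale) and MCC."""
    sens = 100.0 * c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    prec = 100.0 * c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    if sens is None or prec is None:
        f1 = None
    else:
        f1 = f1_percent(sens, prec)
    return MetricSet(matthews_cc(c), sens, prec, f1)


def feature_correlations(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix over conservation, geometry, centrality
    percentiles, RSA and the functional label.

    Computed over rows with all features present; a zero-variance column
    yields NaN for its pairs.
    """
    cols = [c for c in TABLE1_COLUMNS if c in table.columns]
    if "function" not in cols:
        raise ValueError("feature table must carry the functional label column")
    sub = table[cols].dropna()
    if len(sub) < 3:
        raise ValueError("need at least 3 complete rows")
    return sub.astype(float).corr(method="pearson")


def cumulative_separation(values, labels) -> dict:
    """ECDFs of a feature for functional vs non-functional residues.

    Both curves are evaluated on the pooled sorted values; the relative
    difference is (ECDF_nonfunctional − ECDF_functional) divided by the
    maximum absolute gap between the curves (recorded in the metadata).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not (labels == 1).any() or not (labels == 0).any():
        raise ValueError("both classes must be non-empty")
    grid = np.sort(values)
    pos = np.sort(values[labels == 1])
    neg = np.sort(values[labels == 0])
    ecdf_pos = np.searchsorted(pos, grid, side="right") / pos.size
    ecdf_neg = np.searchsorted(neg, grid, side="right") / neg.size
    gap = ecdf_neg - ecdf_pos
    max_gap = float(np.abs(gap).max())
    rel = gap / max_gap if max_gap > 0 else np.zeros_like(gap)
    return {
        "grid": grid,
        "ecdf_functional": ecdf_pos,
        "ecdf_nonfunctional": ecdf_neg,
        "relative_difference": rel,
        "metadata": {
            "normalization": "difference divided by max absolute ECDF gap",
            "max_abs_gap": max_gap,
        },
    }


def assign_cluster_folds(clusters: list, k: int, seed: int) -> list[list]:
    """Shuffle clusters and split them into *k* folds differing by ≤ 1 cluster."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    uniq = sorted(set(clusters))
    if len(uniq) < k:
        raise ValueError(f"fewer clusters ({len(uniq)}) than folds ({k})")
    rng = np.random.default_rng(seed)
    order = [uniq[i] for i in rng.permutation(len(uniq))]
    return [list(part) for part in np.array_split(order, k)]


def cross_validate(
    table: pd.DataFrame,
    cluster_of: dict,
    k: int,
    cfg,
    conservation_threshold: float = 3.8,
    verification_fraction: float = 0.2,
) -> tuple[list[MetricSet], MetricSet]:
    """Cluster-aware k-fold cross-validation of the full training protocol.

    Sequence-identity clusters — not structures — are assigned to folds, so
    related structures never straddle a train/test boundary.  Within each
    training split a fraction of clusters is reserved as the verification
    set used for epoch selection.  Test-fold residues failing the
    conservation prefilter count as negative calls.
    """
    from .net import predict_calls, train_network  # local import avoids a cycle

    missing = set(table["structure_id"]) - set(cluster_of)
    if missing:
        raise ValueError(f"structures without a cluster id: {sorted(missing)}")
    folds = assign_cluster_folds(
        [cluster_of[s] for s in table["structure_id"].unique()], k, cfg.seed
    )
    per_fold: list[MetricSet] = []
    rng = np.random.default_rng(cfg.seed + 1)
    for fold_clusters in folds:
        fold_set = set(fold_clusters)
        in_test = table["structure_id"].map(cluster_of).isin(fold_set)
        test = table[in_test]
        pool = table[~in_test]
        pool_clusters = sorted({cluster_of[s] for s in pool["structure_id"].unique()})
        n_ver = max(1, int(round(verification_fraction * len(pool_clusters))))
        ver_set = set(
            pool_clusters[i] for i in rng.permutation(len(pool_clusters))[:n_ver]
        )
        in_ver = pool["structure_id"].map(cluster_of).isin(ver_set)
        model = train_network(pool[~in_ver], pool[in_ver], cfg)
        calls = predict_calls(model, test, conservation_threshold)
        per_fold.append(
            classification_metrics(confusion_counts(calls, test["function"].to_numpy()))
        )
    def _mean(attr):
        vals = [getattr(m, attr) for m in per_fold if getattr(m, attr) is not None]
        return float(np.mean(vals)) if vals else None
    mean = MetricSet(_mean("mcc"), _mean("sensitivity"), _mean("precision"), _mean("f1"))
    return per_fold, mean


def metrics_report(metrics: MetricSet) -> str:
    """Machine-readable key-value summary of a metric set."""
    def fmt(v):
        return "NA" if v is None else f"{v:.4f}"
    return (
        f"mcc\t{fmt(metrics.mcc)}\n"
        f"sensitivity_pct\t{fmt(metrics.sensitivity)}\n"
        f"precision_pct\t{fmt(metrics.precision)}\n"
        f"f1\t{fmt(metrics.f1)}\n"
    )
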