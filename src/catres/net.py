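"""Feed-forward classifier for catalytic residues.

The predictor is a one-hidden-layer (ten sigmoid units) network over a
21-dimensional input: a 20-way residue-type indicator plus the z-scored
Cα-to-GCM distance.  Training uses classic online back propagation with
squared-error loss on a class-balanced sample (positives are ~1% of
residues, so negatives are subsampled 1:1), and the returned weights are
those of the epoch with the best Matthews correlation on a verification
set of held-out structures.

`CatalyticNetClassifier` is a scikit-learn style estimator and composes
with sklearn tooling; `train_network` / `predict_scores` wrap it at the
feature-table level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .conservation import AA_ORDER, conservation_prefilter
from .evaluation import ConfusionCounts, confusion_counts, matthews_cc

logger = logging.getLogger(__name__)

_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

MODEL_FORMAT_VERSION = 1

#: Columns of a serialized feature table, in order.
FEATURE_TABLE_HEADER = [
    "structure_id", "resnum", "icode", "aa",
    "conserv", "distance", "closeness", "between", "pagerank", "rsa",
    "function",
]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class CatalyticNetClassifier(ClassifierMixin, BaseEstimator):
    """One-hidden-layer sigmoid network trained by online back propagation.

    Parameters
    ----------
    hidden_units : int
        Width of the single hidden layer (ten in the reference protocol).
    learning_rate : float
        Step size of the per-pattern gradient updates.
    max_epochs : int
        Number of passes over the (shuffled) training patterns.
    random_state : int
        Seeds weight initialization and the per-epoch shuffles.
    decision_threshold : float
        Output score above which a residue is called positive.

    Attributes
    ----------
    W1_ : ndarray of shape (n_features, hidden_units)
    b1_ : ndarray of shape (hidden_units,)
    w2_ : ndarray of shape (hidden_units,)
    b2_ : float
    best_epoch_ : int
        Epoch whose weights were retained (by verification MCC when a
        verification set is given, else the final epoch).
    validation_mcc_ : float or None
    """

    def __init__(
        self,
        hidden_units: int = 10,
        learning_rate: float = 0.05,
        max_epochs: int = 500,
        random_state: int = 0,
        decision_threshold: float = 0.5,
    ):
        self.hidden_units = hidden_units
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.random_state = random_state
        self.decision_threshold = decision_threshold

    def fit(self, X, y, X_val=None, y_val=None, val_prior_counts=(0, 0)):
        """Train; with a verification set, keep the best-MCC epoch's weights.

        ``val_prior_counts = (tn, fn)`` adds fixed negative-call tallies to
        every epoch's verification confusion counts — used when part of the
        verification set is removed by a prefilter upstream and therefore
        counts as negative calls.
        """
        X, y = check_X_y(X, y)
        y = y.astype(float)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("labels must be binary 0/1")
        prior_tn, prior_fn = val_prior_counts
        if X_val is not None:
            y_val = np.asarray(y_val, dtype=int)
            n_pos = int(y_val.sum()) + prior_fn
            n_neg = int((y_val == 0).sum()) + prior_tn
            if n_pos == 0 or n_neg == 0:
                raise ValueError(
                    "verification set contains a single class; MCC is undefined"
                )
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        rng = np.random.default_rng(self.random_state)
        n, d = X.shape
        h = self.hidden_units
        W1 = rng.uniform(-0.5, 0.5, size=(d, h))
        b1 = rng.uniform(-0.5, 0.5, size=h)
        w2 = rng.uniform(-0.5, 0.5, size=h)
        b2 = rng.uniform(-0.5, 0.5)

        best = None  # (mcc, epoch, weights)
        lr = self.learning_rate
        for epoch in range(1, self.max_epochs + 1):
            for i in rng.permutation(n):
                x = X[i]
                hid = _sigmoid(x @ W1 + b1)
                out = _sigmoid(hid @ w2 + b2)
                # squared-error loss: delta terms of classic back propagation
                d_out = (out - y[i]) * out * (1.0 - out)
                d_hid = d_out * w2 * hid * (1.0 - hid)
                w2 -= lr * d_out * hid
                b2 -= lr * d_out
                W1 -= lr * np.outer(x, d_hid)
                b1 -= lr * d_hid
            if X_val is not None:
                hid = _sigmoid(X_val @ W1 + b1)
                out = _sigmoid(hid @ w2 + b2)
                calls = (out >= self.decision_threshold).astype(int)
                c = confusion_counts(calls, y_val)
                mcc = matthews_cc(
                    ConfusionCounts(c.tp, c.tn + prior_tn, c.fp, c.fn + prior_fn)
                )
                if best is None or mcc > best[0]:
                    best = (mcc, epoch, (W1.copy(), b1.copy(), w2.copy(), b2))

        if best is not None:
            self.validation_mcc_, self.best_epoch_, (W1, b1, w2, b2) = best
        else:
            self.validation_mcc_, self.best_epoch_ = None, self.max_epochs
        self.W1_, self.b1_, self.w2_, self.b2_ = W1, b1, w2, float(b2)
        self.n_features_in_ = d
        self.classes_ = np.array([0, 1])
        return self

    def decision_function(self, X):
        check_is_fitted(self, "W1_")
        X = check_array(X)
        hid = _sigmoid(X @ self.W1_ + self.b1_)
        return _sigmoid(hid @ self.w2_ + self.b2_)

    def predict_proba(self, X):
        p = self.decision_function(X)
        return np.column_stack((1.0 - p, p))

    def predict(self, X):
        return (self.decision_function(X) >= self.decision_threshold).astype(int)


@dataclass
class TrainingConfig:
    """Hyperparameters of the training protocol."""

    learning_rate: float = 0.05
    max_epochs: int = 500
    seed: int = 0
    prefilter_threshold: float = 3.5  # conservation floor on training residues
    ratio: int = 1  # negatives per positive in the balanced sample
    hidden_units: int = 10
    decision_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.ratio < 1:
            raise ValueError("sampling ratio must be at least 1")


@dataclass
class NetworkModel:
    """Trained classifier plus the input-scaling parameters it expects."""

    clf: CatalyticNetClassifier
    distance_mean: float
    distance_std: float
    metadata: dict = field(default_factory=dict)


def encode_features(
    residue_type: str,
    distance: float,
    distance_mean: float = 0.0,
    distance_std: float = 1.0,
) -> np.ndarray:
    """21-dimensional input: 20-way type indicator + z-scored GCM distance."""
    idx = _AA_INDEX.get(residue_type)
    if idx is None:
        raise ValueError(f"unknown residue type: {residue_type!r}")
    vec = np.zeros(21)
    vec[idx] = 1.0
    vec[20] = (distance - distance_mean) / distance_std
    return vec


def encode_table(
    table: pd.DataFrame, distance_mean: float, distance_std: float
) -> np.ndarray:
    """Encode every feature-table row; rows must carry ``aa`` and ``distance``."""
    X = np.zeros((len(table), 21))
    for k, (aa, dist) in enumerate(zip(table["aa"], table["distance"])):
        X[k] = encode_features(aa, float(dist), distance_mean, distance_std)
    return X


def balanced_sample(labels, ratio: int = 1, seed: int = 0) -> np.ndarray:
    """All positives plus ratio× as many seeded-random negatives, without replacement.

    Returns sorted row indices.  If the pool has too few negatives they are
    all used, with a warning.
    """
    labels = np.asarray(labels, dtype=int)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if pos.size == 0:
        raise ValueError("balanced sampling requires at least one positive")
    want = ratio * pos.size
    rng = np.random.default_rng(seed)
    if neg.size < want:
        logger.warning(
            "only %d negatives available for %d requested; using all", neg.size, want
        )
        chosen = neg
    else:
        chosen = neg[rng.choice(neg.size, size=want, replace=False)]
    return np.sort(np.concatenate((pos, chosen)))


def train_network(
    train: pd.DataFrame, verification: pd.DataFrame, cfg: TrainingConfig
) -> NetworkModel:
    """Train on a balanced, conservation-prefiltered sample of *train* rows.

    Training and verification tables must be disjoint by structure id.  The
    per-epoch verification MCC that selects the returned weights is the
    deployed metric: it is computed over the full verification set with the
    conservation prefilter applied, prefiltered residues counting as
    negative calls.
    """
    overlap = set(train["structure_id"]) & set(verification["structure_id"])
    if overlap:
        raise ValueError(f"train/verification structures overlap: {sorted(overlap)}")
    ver_labels = verification["function"].to_numpy(dtype=int)
    if len(np.unique(ver_labels)) < 2:
        raise ValueError("verification set contains a single class; MCC is undefined")
    keep = conservation_prefilter(
        train["conserv"].to_numpy(), cfg.prefilter_threshold
    )
    filtered = train.iloc[keep]
    idx = balanced_sample(filtered["function"].to_numpy(), cfg.ratio, cfg.seed)
    sample = filtered.iloc[idx]
    mean = float(sample["distance"].mean())
    std = float(sample["distance"].std(ddof=0))
    if std == 0:
        std = 1.0
    X = encode_table(sample, mean, std)
    y = sample["function"].to_numpy(dtype=int)
    ver_keep = conservation_prefilter(
        verification["conserv"].to_numpy(), cfg.prefilter_threshold
    )
    ver_surv = verification.iloc[ver_keep]
    removed = ver_labels.sum() - int(ver_surv["function"].sum()), (
        int((ver_labels == 0).sum()) - int((ver_surv["function"] == 0).sum())
    )
    prior_fn, prior_tn = removed
    X_val = encode_table(ver_surv, mean, std)
    y_val = ver_surv["function"].to_numpy(dtype=int)
    clf = CatalyticNetClassifier(
        hidden_units=cfg.hidden_units,
        learning_rate=cfg.learning_rate,
        max_epochs=cfg.max_epochs,
        random_state=cfg.seed,
        decision_threshold=cfg.decision_threshold,
    ).fit(X, y, X_val=X_val, y_val=y_val, val_prior_counts=(prior_tn, prior_fn))
    meta = {
        "seed": cfg.seed,
        "max_epochs": cfg.max_epochs,
        "best_epoch": clf.best_epoch_,
        "validation_mcc": clf.validation_mcc_,
        "prefilter_threshold": cfg.prefilter_threshold,
        "n_train_patterns": len(sample),
    }
    return NetworkModel(clf, mean, std, meta)


def predict_scores(model: NetworkModel, rows: pd.DataFrame) -> np.ndarray:
    """Network output in [0, 1] for every feature-table row."""
    X = encode_table(rows, model.distance_mean, model.distance_std)
    return model.clf.decision_function(X)


def predict_calls(
    model: NetworkModel, rows: pd.DataFrame, conservation_threshold: float
) -> np.ndarray:
    """Binary calls over all rows; prefilter-removed rows are negative calls."""
    calls = np.zeros(len(rows), dtype=int)
    keep = conservation_prefilter(rows["conserv"].to_numpy(), conservation_threshold)
    if keep.size:
        scores = predict_scores(model, rows.iloc[keep])
        calls[keep] = (scores >= model.clf.decision_threshold).astype(int)
    return calls


def threshold_grid(lo: float, hi: float, step: float) -> np.ndarray:
    """The scan grid {lo, lo+step, ...} up to hi inclusive (fp-safe)."""
    if lo >= hi and not np.isclose(lo, hi):
        raise ValueError("lo must be below hi")
    if step <= 0:
        raise ValueError("step must be positive")
    n = int(np.floor((hi - lo) / step + 1e-9)) + 1
    return np.round(lo + step * np.arange(n), 10)


def scan_entropy_threshold(
    data: pd.DataFrame,
    model: NetworkModel,
    lo: float = 2.5,
    hi: float = 4.0,
    step: float = 0.1,
) -> tuple[float, pd.DataFrame]:
    """Recalibrate the conservation prefilter against a labeled set.

    Every threshold in the grid is applied as a prefilter, the network is
    run on the survivors, and the MCC is computed over *all* residues
    (prefiltered-out functional residues count as false negatives).  The
    MCC-maximizing threshold is returned; ties go to the larger threshold.
    """
    truth = data["function"].to_numpy(dtype=int)
    conserv = data["conserv"].to_numpy(dtype=float)
    rows = []
    best_t, best_mcc = None, -np.inf
    for t in threshold_grid(lo, hi, step):
        calls = predict_calls(model, data, float(t))
        mcc = matthews_cc(confusion_counts(calls, truth))
        rows.append(
            {"threshold": float(t), "mcc": mcc, "survivors": int(np.sum(conserv >= t))}
        )
        if mcc >= best_mcc:  # >= : ties resolve to the larger threshold
            best_t, best_mcc = float(t), mcc
    return best_t, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plain-text persistence


def _fmt_matrix(name: str, arr: np.ndarray) -> str:
    arr = np.atleast_2d(np.asarray(arr, dtype=float))
    head = f"{name} {arr.shape[0]} {arr.shape[1]}\n"
    return head + "\n".join(" ".join(f"{v:.17g}" for v in row) for row in arr) + "\n"


def save_model(model: NetworkModel, path) -> None:
    """Serialize a trained model as a versioned plain-text key-value file."""
    clf = model.clf
    meta = model.metadata
    with open(path, "w") as fh:
        fh.write(f"format_version {MODEL_FORMAT_VERSION}\n")
        fh.write(f"hidden_units {clf.hidden_units}\n")
        fh.write(f"decision_threshold {repr(clf.decision_threshold)}\n")
        fh.write(f"distance_mean {repr(model.distance_mean)}\n")
        fh.write(f"distance_std {repr(model.distance_std)}\n")
        for key in ("seed", "max_epochs", "best_epoch", "validation_mcc",
                    "prefilter_threshold", "n_train_patterns"):
            if key in meta and meta[key] is not None:
                fh.write(f"meta_{key} {meta[key]}\n")
        fh.write(_fmt_matrix("W1", clf.W1_))
        fh.write(_fmt_matrix("b1", clf.b1_))
        fh.write(_fmt_matrix("w2", clf.w2_))
        fh.write(_fmt_matrix("b2", np.array([clf.b2_])))


def load_model(path) -> NetworkModel:
    with open(path) as fh:
        lines = fh.read().splitlines()
    scalars: dict[str, str] = {}
    matrices: dict[str, np.ndarray] = {}
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if parts and parts[0] in ("W1", "b1", "w2", "b2"):
            name, r, c = parts[0], int(parts[1]), int(parts[2])
            block = [
                [float(v) for v in lines[i + 1 + k].split()] for k in range(r)
            ]
            matrices[name] = np.array(block).reshape(r, c)
            i += 1 + r
        else:
            if len(parts) == 2:
                scalars[parts[0]] = parts[1]
            i += 1
    if int(scalars.get("format_version", -1)) != MODEL_FORMAT_VERSION:
        raise ValueError("unsupported model format version")
    clf = CatalyticNetClassifier(
        hidden_units=int(scalars["hidden_units"]),
        decision_threshold=float(scalars["decision_threshold"]),
    )
    clf.W1_ = matrices["W1"]
    clf.b1_ = matrices["b1"].ravel()
    clf.w2_ = matrices["w2"].ravel()
    clf.b2_ = float(matrices["b2"].ravel()[0])
    clf.n_features_in_ = clf.W1_.shape[0]
    clf.classes_ = np.array([0, 1])
    clf.best_epoch_ = int(scalars.get("meta_best_epoch", 0))
    clf.validation_mcc_ = (
        float(scalars["meta_validation_mcc"]) if "meta_validation_mcc" in scalars else None
    )
    meta = {
        k[len("meta_"):]: scalars[k] for k in scalars if k.startswith("meta_")
    }
    return NetworkModel(
        clf, float(scalars["distance_mean"]), float(scalars["distance_std"]), meta
    )
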