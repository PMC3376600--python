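"""Evaluation protocols, confusion matrices and per-class metrics.

Two protocols measure classifier quality at the 100 ms-sequence level:

* **day split** — train on day 1, test on day 2; probes generalisation to
  a different recording session;
* **mixed k-fold** — pool both days and cross-validate with stratified,
  sequence-level folds; probes overall performance.

From the 3×3 confusion matrix (rows observed, columns predicted, class
order flushing/landing/foraging) three per-class measures derive:
accuracy (TP+TN)/total, precision TP/(TP+FP) and sensitivity TP/(TP+FN).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .classifier import TrainConfig, predict_sequences, train_model_set
from .errors import ValidationError
from .labels import CLASS_ORDER

METRIC_NAMES = ("accuracy", "precision", "sensitivity")


@dataclass
class ConfusionMatrix:
    """Observed-vs-predicted sequence counts in canonical class order."""

    counts: np.ndarray  # (3, 3) ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(CLASS_ORDER),) * 2 or (self.counts < 0).any():
            raise ValidationError("confusion matrix must be 3x3 with non-negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts)

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(CLASS_ORDER), columns=list(CLASS_ORDER))


def build_confusion(observed, predicted) -> ConfusionMatrix:
    """Count observed-vs-predicted label pairs (aligned lists of sequences)."""
    observed = list(observed)
    predicted = list(predicted)
    if len(observed) != len(predicted):
        raise ValidationError(
            f"observed ({len(observed)}) and predicted ({len(predicted)}) lengths differ"
        )
    index = {c: i for i, c in enumerate(CLASS_ORDER)}
    counts = np.zeros((len(CLASS_ORDER),) * 2, dtype=np.int64)
    for obs, pred in zip(observed, predicted):
        counts[index[obs], index[pred]] += 1
    return ConfusionMatrix(counts)


def per_class_metrics(cm: ConfusionMatrix, cls: str) -> tuple[float, float, float]:
    """(accuracy, precision, sensitivity) of one behaviour class.

    Precision and sensitivity are NaN when their denominator is zero.
    """
    if cm.total == 0:
        raise ValidationError("cannot compute metrics of an empty confusion matrix")
    c = CLASS_ORDER.index(cls)
    tp = cm.counts[c, c]
    fp = cm.counts[:, c].sum() - tp
    fn = cm.counts[c, :].sum() - tp
    tn = cm.total - tp - fp - fn
    accuracy = (tp + tn) / cm.total
    precision = tp / (tp + fp) if tp + fp > 0 else float("nan")
    sensitivity = tp / (tp + fn) if tp + fn > 0 else float("nan")
    return float(accuracy), float(precision), float(sensitivity)


def metrics_table(cm: ConfusionMatrix) -> pd.DataFrame:
    """All three metrics for all three classes, one row per behaviour."""
    rows = {cls: per_class_metrics(cm, cls) for cls in CLASS_ORDER}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(METRIC_NAMES))


def round_half_up(x: float, decimals: int = 2) -> float:
    """Report rounding: half-up at the given precision (0.005 → 0.01)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# protocols

@dataclass
class SplitPlan:
    """How to partition sequences into train/test."""

    strategy: str = "day_split"  # or "mixed_kfold"
    k: int = 5
    seed: int = 0
    train_day: str | None = None  # default: lexicographically first day tag


@dataclass
class ProtocolResult:
    confusion: ConfusionMatrix
    metrics: pd.DataFrame
    plan: SplitPlan
    predictions: pd.DataFrame  # sequence_id, label, predicted


def _fit_and_predict(train: pd.DataFrame, test: pd.DataFrame,
                     config: TrainConfig) -> pd.DataFrame:
    model_set = train_model_set(train, config)
    return predict_sequences(model_set, test)


def _sequence_table(features: pd.DataFrame) -> pd.DataFrame:
    seq = features.drop_duplicates("sequence_id")[["sequence_id", "label", "day_tag"]]
    return seq.sort_values("sequence_id").reset_index(drop=True)


def run_protocol(features: pd.DataFrame, plan: SplitPlan,
                 config: TrainConfig | None = None) -> ProtocolResult:
    """Run one evaluation protocol end to end on a labelled feature table.

    The full pipeline (selection → normalisation → tuning → training →
    DAG classification → majority vote) is refit inside every training
    partition; nothing from a test partition leaks into its model.
    """
    config = config or TrainConfig()
    if features.empty:
        raise ValidationError("empty feature table")
    seq = _sequence_table(features)

    if plan.strategy == "day_split":
        days = sorted(seq["day_tag"].unique())
        if len(days) < 2:
            raise ValidationError("day_split needs at least two distinct day tags")
        train_day = plan.train_day or days[0]
        train_mask = features["day_tag"] == train_day
        preds = _fit_and_predict(features[train_mask], features[~train_mask], config)
    elif plan.strategy == "mixed_kfold":
        if plan.k < 2:
            raise ValidationError("mixed_kfold needs k >= 2")
        rng = np.random.default_rng(plan.seed)
        fold_of_seq: dict = {}
        for cls in sorted(seq["label"].unique()):
            ids = seq.loc[seq["label"] == cls, "sequence_id"].to_numpy()
            order = rng.permutation(ids.size)
            for i, sid in enumerate(ids[order]):
                fold_of_seq[sid] = i % plan.k
        fold_id = features["sequence_id"].map(fold_of_seq)
        parts = []
        for f in range(plan.k):
            fold_config = TrainConfig(**{**config.__dict__, "seed": config.seed * 31 + f})
            parts.append(
                _fit_and_predict(features[fold_id != f], features[fold_id == f], fold_config)
            )
        preds = pd.concat(parts, ignore_index=True)
    else:
        raise ValidationError(f"unknown protocol strategy {plan.strategy!r}")

    cm = build_confusion(preds["label"], preds["predicted"])
    return ProtocolResult(confusion=cm, metrics=metrics_table(cm), plan=plan,
                          predictions=preds)


# ---------------------------------------------------------------------------
# PCA view

def pca_project(features: np.ndarray, n_components: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Project mean-centred data onto its top principal axes.

    Returns (projected coordinates, explained variances); the variances
    equal the leading eigenvalues of the sample covariance and are
    non-increasing.
    """
    from sklearn.decomposition import PCA

    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] < n_components:
        raise ValidationError(
            f"need at least {n_components} feature columns, got shape {X.shape}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    proj = pca.fit_transform(X)
    return proj, pca.explained_variance_


def plot_pca(features: pd.DataFrame, model_set, path) -> None:
    """Scatter the first three principal components of the selected features."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    Xn = model_set.transform(features)
    proj, _ = pca_project(Xn, 3)
    fig = plt.figure(figsize=(7, 6))
    ax = fig.add_subplot(projection="3d")
    for cls in CLASS_ORDER:
        m = features["label"].to_numpy() == cls
        ax.scatter(proj[m, 0], proj[m, 1], proj[m, 2], s=4, label=cls, alpha=0.5)
    ax.set_xlabel("PC 1")
    ax.set_ylabel("PC 2")
    ax.set_zlabel("PC 3")
    ax.legend()
    fig.savefig(path, dpi=120)
    plt.close(fig)
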