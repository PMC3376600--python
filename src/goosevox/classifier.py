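"""Normalisation, pairwise RBF-SVM training and one-vs-one DAG classification.

Three soft-margin SVMs with RBF kernel k(x, x') = exp(−γ‖x − x'‖²) are
trained, one per behaviour pair.  Per-class misclassification costs are
scaled against class imbalance as

    C1 = N / (2 N1),   C2 = N / (2 N2),

so that C1·N1 = C2·N2; the grid-searched base cost C multiplies these
weights.  (C, γ) are tuned per pair on a 21×21 power-of-two grid
2⁻¹⁰ … 2¹⁰ by stratified, sequence-grouped 5-fold cross-validation.

A new frame is classified through a directed graph: the flushing-vs-landing
model is evaluated first and its winner is then played against foraging in
the corresponding pairwise model — exactly two evaluations per frame.  A
100 ms sequence takes the majority vote over its frames.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .errors import ConfigError, ValidationError
from .gfcc import FEATURE_COLUMNS
from .labels import CLASS_ORDER, FLUSHING, FORAGING, LANDING
from .selection import SelectionResult, branch_and_bound_select

#: The three pairwise models; the first pair is the DAG root.
PAIR_ORDER = ((FLUSHING, LANDING), (FLUSHING, FORAGING), (LANDING, FORAGING))


# ---------------------------------------------------------------------------
# normalisation

@dataclass(frozen=True)
class NormalizationStats:
    """Per-feature training mean and standard deviation (population, ddof=0)."""

    mean: np.ndarray
    std: np.ndarray


def fit_normalization(train_features: np.ndarray) -> NormalizationStats:
    """Fit zero-mean/unit-variance statistics on training features.

    Raises on constant features: a zero-variance coordinate cannot be
    scaled to unit variance and would carry no information anyway.
    """
    X = np.asarray(train_features, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("need a 2-D array with at least two training rows")
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    bad = np.flatnonzero(std < 1e-12)
    if bad.size:
        raise ValidationError(f"zero-variance feature(s) at index {bad.tolist()}")
    return NormalizationStats(mean=mean, std=std)


def apply_normalization(features: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    X = np.asarray(features, dtype=np.float64)
    return (X - stats.mean) / stats.std


# ---------------------------------------------------------------------------
# class-imbalance weights

@dataclass(frozen=True)
class ClassWeights:
    C1: float
    C2: float
    N: int
    N1: int
    N2: int


def class_weights(N1: int, N2: int) -> ClassWeights:
    """Imbalance-compensating per-class costs with C1·N1 = C2·N2 = N/2."""
    if N1 <= 0 or N2 <= 0:
        raise ValidationError(f"class counts must be positive, got ({N1}, {N2})")
    N = N1 + N2
    return ClassWeights(C1=N / (2.0 * N1), C2=N / (2.0 * N2), N=N, N1=N1, N2=N2)


# ---------------------------------------------------------------------------
# hyperparameter grid search

@dataclass
class GridSearchResult:
    best_C: float
    best_gamma: float
    cv_table: pd.DataFrame  # columns C, gamma, mean_accuracy


def _grouped_stratified_folds(
    y: np.ndarray, groups: np.ndarray, folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Assign each row to a fold so that whole groups (sequences) stay
    together and every fold sees both classes."""
    fold_of_group: dict = {}
    for cls in np.unique(y):
        cls_groups = np.unique(groups[y == cls])
        if cls_groups.size < folds:
            raise ValidationError(
                f"class {cls!r} has only {cls_groups.size} sequences; "
                f"cannot build {folds} stratified folds"
            )
        order = rng.permutation(cls_groups.size)
        for i, g in enumerate(cls_groups[order]):
            fold_of_group[g] = i % folds
    return np.asarray([fold_of_group[g] for g in groups])


def _stratified_group_subsample(
    y: np.ndarray, groups: np.ndarray, max_rows: int, folds: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Row mask keeping whole sequences, class shares, and ≥ ``folds``
    sequences per class, with about ``max_rows`` rows in total."""
    n = y.size
    if n <= max_rows:
        return np.ones(n, dtype=bool)
    keep_groups: list = []
    for cls in np.unique(y):
        cls_groups = np.unique(groups[y == cls])
        share = (y == cls).sum() / n
        rows_per_group = (y == cls).sum() / cls_groups.size
        want = max(folds, int(round(share * max_rows / rows_per_group)))
        order = rng.permutation(cls_groups.size)
        keep_groups.extend(cls_groups[order[: min(want, cls_groups.size)]])
    keep = set(keep_groups)
    return np.asarray([g in keep for g in groups])


def power_grid(grid_min: int = -10, grid_max: int = 10) -> np.ndarray:
    return 2.0 ** np.arange(grid_min, grid_max + 1)


def grid_search_pair(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 5,
    seed: int = 0,
    groups: np.ndarray | None = None,
    grid_min: int = -10,
    grid_max: int = 10,
    weights: ClassWeights | None = None,
    subsample_max: int | None = 600,
) -> GridSearchResult:
    """Tune (C, γ) for one behaviour pair by grouped, stratified k-fold CV.

    The RBF kernel is precomputed per γ from a cached squared-distance
    matrix, so each grid cell costs one small SVM fit.  When the pair's
    training set exceeds ``subsample_max`` rows, tuning runs on a seeded
    sequence-grouped stratified subsample (the final model is always refit
    on the full data by the caller).  Ties break toward smaller C, then
    smaller γ.  Fixed seed ⇒ bitwise-identical cv_table.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValidationError(f"grid search needs exactly 2 classes, got {classes.size}")
    if groups is None:
        groups = np.arange(y.size)
    rng = np.random.default_rng(seed)
    if subsample_max is not None:
        mask = _stratified_group_subsample(y, groups, subsample_max, folds, rng)
        X, y, groups = X[mask], y[mask], groups[mask]
    if weights is None:
        weights = class_weights(int((y == classes[0]).sum()), int((y == classes[1]).sum()))
    cw = {classes[0]: weights.C1, classes[1]: weights.C2}

    fold_id = _grouped_stratified_folds(y, groups, folds, rng)
    sq = (X**2).sum(axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (X @ X.T), 0.0)

    Cs = power_grid(grid_min, grid_max)
    gammas = power_grid(grid_min, grid_max)
    acc = np.zeros((Cs.size, gammas.size))
    fold_slices = [
        (np.flatnonzero(fold_id != f), np.flatnonzero(fold_id == f))
        for f in range(folds)
    ]
    for gi, gamma in enumerate(gammas):
        K = np.exp(-gamma * d2)
        for tr, va in fold_slices:
            K_tr = K[np.ix_(tr, tr)]
            K_va = K[np.ix_(va, tr)]
            y_tr, y_va = y[tr], y[va]
            for ci, C in enumerate(Cs):
                svc = SVC(kernel="precomputed", C=C, class_weight=cw)
                svc.fit(K_tr, y_tr)
                acc[ci, gi] += (svc.predict(K_va) == y_va).mean()
    acc /= folds

    best_ci, best_gi, best = 0, 0, -1.0
    for ci in range(Cs.size):
        for gi in range(gammas.size):
            if acc[ci, gi] > best:
                best_ci, best_gi, best = ci, gi, acc[ci, gi]
    table = pd.DataFrame(
        {
            "C": np.repeat(Cs, gammas.size),
            "gamma": np.tile(gammas, Cs.size),
            "mean_accuracy": acc.ravel(),
        }
    )
    return GridSearchResult(best_C=float(Cs[best_ci]), best_gamma=float(gammas[best_gi]),
                            cv_table=table)


# ---------------------------------------------------------------------------
# training

@dataclass
class TrainConfig:
    """Tunables of the training pipeline."""

    d_target: int = 6
    folds: int = 5
    grid_min: int = -10
    grid_max: int = 10
    seed: int = 0
    subsample_max: int | None = 600
    feature_columns: tuple[str, ...] = tuple(FEATURE_COLUMNS)


@dataclass
class PairModel:
    """One trained pairwise decision function and its tuning record."""

    pair: tuple[str, str]
    svc: SVC
    C: float
    gamma: float
    weights: ClassWeights
    cv_table: pd.DataFrame | None = None


@dataclass
class TrainedModelSet:
    """The three pairwise SVMs plus everything needed to classify new audio."""

    pairs: dict[tuple[str, str], PairModel]
    norm: NormalizationStats
    selected: SelectionResult
    feature_columns: tuple[str, ...]
    config: TrainConfig

    def transform(self, features: pd.DataFrame) -> np.ndarray:
        """Selected + normalised feature matrix for a feature table."""
        X = features.loc[:, list(self.feature_columns)].to_numpy(dtype=np.float64)
        return apply_normalization(X[:, list(self.selected.selected_indices)], self.norm)


def _standardize_for_selection(X: np.ndarray) -> np.ndarray:
    """Unit-variance scaling with a zero-variance guard.

    Constant coordinates (e.g. the structurally zero top cepstral
    coefficient of a 20-band cosine transform) are mapped to zero so they
    contribute nothing to the separability criterion and are never
    selected.
    """
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    safe = np.where(std < 1e-12, 1.0, std)
    Z = (X - mean) / safe
    Z[:, std < 1e-12] = 0.0
    return Z


def train_model_set(features: pd.DataFrame, config: TrainConfig | None = None) -> TrainedModelSet:
    """Full training pipeline on a labelled feature table.

    Selection (branch and bound, d coordinates) runs on standardised
    training features; z-normalisation statistics are then
    fitted on the selected coordinates; finally one RBF SVM per behaviour
    pair is tuned and trained with imbalance-scaled per-class costs.
    """
    config = config or TrainConfig()
    present = set(features["label"].unique())
    if set(CLASS_ORDER) - present:
        raise ValidationError(
            f"training data must contain all of {CLASS_ORDER}, missing "
            f"{sorted(set(CLASS_ORDER) - present)}"
        )
    X_all = features.loc[:, list(config.feature_columns)].to_numpy(dtype=np.float64)
    y = features["label"].to_numpy()
    groups = features["sequence_id"].to_numpy()

    Z = _standardize_for_selection(X_all)
    selected = branch_and_bound_select(Z, y, d_target=config.d_target)
    idx = list(selected.selected_indices)
    norm = fit_normalization(X_all[:, idx])
    Xn = apply_normalization(X_all[:, idx], norm)

    pairs: dict[tuple[str, str], PairModel] = {}
    for pi, (a, b) in enumerate(PAIR_ORDER):
        mask = (y == a) | (y == b)
        Xp, yp, gp = Xn[mask], y[mask], groups[mask]
        w = class_weights(int((yp == a).sum()), int((yp == b).sum()))
        gs = grid_search_pair(
            Xp, yp,
            folds=config.folds,
            seed=config.seed * 7919 + pi,
            groups=gp,
            grid_min=config.grid_min,
            grid_max=config.grid_max,
            weights=w,
            subsample_max=config.subsample_max,
        )
        svc = SVC(kernel="rbf", C=gs.best_C, gamma=gs.best_gamma,
                  class_weight={a: w.C1, b: w.C2})
        svc.fit(Xp, yp)
        pairs[(a, b)] = PairModel(
            pair=(a, b), svc=svc, C=gs.best_C, gamma=gs.best_gamma,
            weights=w, cv_table=gs.cv_table,
        )
    return TrainedModelSet(
        pairs=pairs, norm=norm, selected=selected,
        feature_columns=tuple(config.feature_columns), config=config,
    )


# ---------------------------------------------------------------------------
# DAG classification

def _pair_decide(svc, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Winner label and |decision value| per row for one pairwise model."""
    dec = np.asarray(svc.decision_function(X), dtype=np.float64)
    winners = np.asarray(svc.classes_)[(dec > 0).astype(int)]
    return winners, np.abs(dec)


def dag_classify_frames(
    X: np.ndarray, models: dict[tuple[str, str], "PairModel"]
) -> tuple[np.ndarray, np.ndarray]:
    """Classify normalised frame vectors through the one-vs-one graph.

    The flushing-vs-landing model is evaluated first; its winner is played
    against foraging.  Returns (labels, mean |decision value| along the
    2-step path) per row.
    """
    for pair in PAIR_ORDER:
        if pair not in models:
            raise ValidationError(f"missing pairwise model {pair}")
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    n = X.shape[0]
    labels = np.empty(n, dtype=object)
    scores = np.zeros(n)
    w1, s1 = _pair_decide(models[(FLUSHING, LANDING)].svc, X)
    for first in (FLUSHING, LANDING):
        rows = np.flatnonzero(w1 == first)
        if rows.size == 0:
            continue
        w2, s2 = _pair_decide(models[(first, FORAGING)].svc, X[rows])
        labels[rows] = w2
        scores[rows] = 0.5 * (s1[rows] + s2)
    return labels, scores


def dag_classify_frame(x: np.ndarray, models: dict[tuple[str, str], "PairModel"]) -> str:
    """Single-frame convenience wrapper around :func:`dag_classify_frames`."""
    labels, _ = dag_classify_frames(np.atleast_2d(x), models)
    return str(labels[0])


def _majority_vote(labels: np.ndarray, scores: np.ndarray) -> str:
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    top = max(counts.values())
    tied = [lab for lab, c in counts.items() if c == top]
    if len(tied) == 1:
        return tied[0]
    # tie: prefer the label whose frames were furthest from the pairwise
    # hyperplanes along their DAG paths; final fallback is class order
    def key(lab: str):
        return (-float(np.mean(scores[labels == lab])), CLASS_ORDER.index(lab))
    return min(tied, key=key)


def predict_sequences(model_set: TrainedModelSet, features: pd.DataFrame) -> pd.DataFrame:
    """Sequence-level behaviour predictions for a feature table.

    Each frame is classified through the DAG; each sequence takes the
    majority vote of its frames (ties by mean path |decision value|).
    Returns one row per sequence: sequence_id, label (observed, may be
    None) and predicted.
    """
    if features.empty:
        return pd.DataFrame(columns=["sequence_id", "label", "predicted"])
    Xn = model_set.transform(features)
    frame_labels, frame_scores = dag_classify_frames(Xn, model_set.pairs)
    df = features.loc[:, ["sequence_id", "label"]].copy()
    df["_pred"] = frame_labels
    df["_score"] = frame_scores
    records = []
    for seq_id, grp in df.groupby("sequence_id", sort=True):
        vote = _majority_vote(grp["_pred"].to_numpy(), grp["_score"].to_numpy())
        records.append(
            {"sequence_id": seq_id, "label": grp["label"].iloc[0], "predicted": vote}
        )
    return pd.DataFrame.from_records(records)


def classify_sequence(window_features: pd.DataFrame, model_set: TrainedModelSet) -> str:
    """Classify one sequence's frames (errors if the table is empty)."""
    if window_features.empty:
        raise ValidationError("sequence has no frames to classify")
    return str(predict_sequences(model_set, window_features)["predicted"].iloc[0])


# ---------------------------------------------------------------------------
# persistence

_SCHEMA_VERSION = 1


def save_model_set(path: str | Path, model_set: TrainedModelSet) -> None:
    """Persist a trained model set (versioned joblib archive)."""
    payload = {"schema": _SCHEMA_VERSION, "model_set": model_set}
    joblib.dump(payload, path)


def load_model_set(path: str | Path) -> TrainedModelSet:
    payload = joblib.load(path)
    if not isinstance(payload, dict) or payload.get("schema") != _SCHEMA_VERSION:
        raise ConfigError(f"unrecognised model archive schema in {path}")
    return payload["model_set"]
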