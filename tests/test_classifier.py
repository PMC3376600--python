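import numpy as np
import pandas as pd
import pytest

from goosevox.classifier import (
    PAIR_ORDER,
    TrainConfig,
    apply_normalization,
    class_weights,
    dag_classify_frame,
    dag_classify_frames,
    fit_normalization,
    grid_search_pair,
    load_model_set,
    predict_sequences,
    save_model_set,
    train_model_set,
)
from goosevox.errors import ValidationError
from goosevox.labels import FLUSHING, FORAGING, LANDING

from conftest import make_feature_table


class TestNormalization:
    def test_two_point_column(self):
        stats = fit_normalization(np.array([[1.0], [3.0]]))
        assert stats.mean[0] == pytest.approx(2.0)
        assert stats.std[0] == pytest.approx(1.0)
        np.testing.assert_allclose(
            apply_normalization(np.array([[1.0], [3.0]]), stats), [[-1.0], [1.0]]
        )

    def test_training_set_becomes_zero_mean_unit_variance(self):
        rng = np.random.default_rng(0)
        X = rng.normal(5, 3, size=(200, 4))
        Z = apply_normalization(X, fit_normalization(X))
        assert np.abs(Z.mean(axis=0)).max() < 1e-9
        assert np.abs(Z.var(axis=0) - 1.0).max() < 1e-9

    def test_constant_column_error_names_index(self):
        X = np.ones((10, 3))
        X[:, 0] = np.arange(10)
        X[:, 2] = np.arange(10)
        with pytest.raises(ValidationError, match=r"\[1\]"):
            fit_normalization(X)


class TestClassWeights:
    def test_balanced_case(self):
        w = class_weights(50, 50)
        assert w.C1 == w.C2 == 1.0

    def test_hand_computed_imbalanced_case(self):
        w = class_weights(50, 100)
        assert w.C1 == pytest.approx(1.5)
        assert w.C2 == pytest.approx(0.75)

    def test_identity_holds_for_random_counts(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n1, n2 = int(rng.integers(1, 10_000)), int(rng.integers(1, 10_000))
            w = class_weights(n1, n2)
            assert w.C1 * n1 == pytest.approx(w.C2 * n2)
            assert w.C1 * n1 == pytest.approx((n1 + n2) / 2)

    def test_zero_count_rejected(self):
        with pytest.raises(ValidationError):
            class_weights(0, 5)


def _pair_cloud(separation, n_seq=30, seed=0):
    """Two Gaussian sequence clouds (3 frames each) a given distance apart."""
    rng = np.random.default_rng(seed)
    X, y, groups = [], [], []
    for label, mu in ((FLUSHING, 0.0), (LANDING, separation)):
        for s in range(n_seq):
            center = rng.normal(mu, 1.0, size=2)
            for _ in range(3):
                X.append(center + rng.normal(0, 0.3, 2))
                y.append(label)
                groups.append(f"{label}-{s}")
    return np.asarray(X), np.asarray(y), np.asarray(groups)


class TestGridSearch:
    def test_separable_clouds_reach_perfect_cv_accuracy(self):
        X, y, groups = _pair_cloud(separation=12.0)
        res = grid_search_pair(X, y, seed=3, groups=groups)
        assert res.cv_table["mean_accuracy"].max() == pytest.approx(1.0)

    def test_label_independent_features_score_near_chance(self):
        X, y, groups = _pair_cloud(separation=0.0, n_seq=40)
        res = grid_search_pair(X, y, seed=4, groups=groups)
        assert res.cv_table["mean_accuracy"].max() < 0.72  # chance ± sampling error

    def test_best_point_lies_inside_declared_grid(self):
        X, y, groups = _pair_cloud(separation=5.0)
        res = grid_search_pair(X, y, seed=5, groups=groups)
        grid = 2.0 ** np.arange(-10, 11)
        assert res.best_C in grid and res.best_gamma in grid
        assert len(res.cv_table) == 21 * 21

    def test_fixed_seed_reproduces_cv_table_bitwise(self):
        X, y, groups = _pair_cloud(separation=3.0)
        a = grid_search_pair(X, y, seed=6, groups=groups)
        b = grid_search_pair(X, y, seed=6, groups=groups)
        assert a.cv_table.equals(b.cv_table)
        assert (a.best_C, a.best_gamma) == (b.best_C, b.best_gamma)

    def test_tie_break_prefers_smaller_C_then_gamma(self):
        X, y, groups = _pair_cloud(separation=20.0)  # many grid cells tie at 1.0
        res = grid_search_pair(X, y, seed=7, groups=groups)
        t = res.cv_table
        best = t["mean_accuracy"].max()
        tied = t[t["mean_accuracy"] == best].sort_values(["C", "gamma"])
        assert res.best_C == tied["C"].iloc[0]
        assert res.best_gamma == tied["gamma"].iloc[0]

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValidationError):
            grid_search_pair(X, np.zeros(10))


class _StubModel:
    """Pairwise stub with a fixed preferred class, for DAG path tracing."""

    def __init__(self, classes, prefer, margin=1.0):
        self.classes_ = np.asarray(classes)
        self._prefer = prefer
        self._margin = margin

    def decision_function(self, X):
        sign = 1.0 if self._prefer == self.classes_[1] else -1.0
        return np.full(np.atleast_2d(X).shape[0], sign * self._margin)


class _StubPair:
    def __init__(self, classes, prefer, margin=1.0):
        self.svc = _StubModel(classes, prefer, margin)


def _stub_models(first_winner, second_winner):
    models = {}
    models[(FLUSHING, LANDING)] = _StubPair([FLUSHING, LANDING], first_winner)
    for other in (FLUSHING, LANDING):
        winner = second_winner if other == first_winner else other
        models[(other, FORAGING)] = _StubPair(sorted([other, FORAGING]), winner)
    return models


class TestDagClassification:
    def test_flushing_beaten_by_foraging(self):
        models = _stub_models(first_winner=FLUSHING, second_winner=FORAGING)
        assert dag_classify_frame(np.zeros(2), models) == FORAGING

    def test_landing_wins_both_rounds(self):
        models = _stub_models(first_winner=LANDING, second_winner=LANDING)
        assert dag_classify_frame(np.zeros(2), models) == LANDING

    @pytest.mark.parametrize("winner", [FLUSHING, LANDING, FORAGING])
    def test_unanimous_preference_wins(self, winner):
        models = {
            pair: _StubPair(sorted(pair), winner if winner in pair else pair[0])
            for pair in PAIR_ORDER
        }
        labels, scores = dag_classify_frames(np.zeros((4, 2)), models)
        assert set(labels) == {winner}
        assert scores.shape == (4,)

    def test_missing_model_rejected(self):
        models = _stub_models(FLUSHING, FORAGING)
        del models[(LANDING, FORAGING)]
        with pytest.raises(ValidationError):
            dag_classify_frame(np.zeros(2), models)

    def test_exactly_two_evaluations_per_frame(self):
        calls = []

        class Counting(_StubModel):
            def decision_function(self, X):
                calls.append(np.atleast_2d(X).shape[0])
                return super().decision_function(X)

        models = {
            (FLUSHING, LANDING): _StubPair([FLUSHING, LANDING], LANDING),
            (FLUSHING, FORAGING): _StubPair([FLUSHING, FORAGING], FLUSHING),
            (LANDING, FORAGING): _StubPair([FORAGING, LANDING], LANDING),
        }
        for pair in PAIR_ORDER:
            stub = models[pair].svc
            models[pair].svc = Counting(stub.classes_, stub._prefer)
        dag_classify_frames(np.zeros((5, 2)), models)
        assert sum(calls) == 10  # 5 frames x 2 evaluations


class TestTrainModelSet:
    @pytest.fixture(scope="class")
    def model_and_data(self, separated_features):
        config = TrainConfig(d_target=3, seed=1, subsample_max=300)
        return train_model_set(separated_features, config), separated_features

    def test_exactly_three_pairwise_models(self, model_and_data):
        model_set, _ = model_and_data
        assert set(model_set.pairs) == set(PAIR_ORDER)

    def test_separable_training_data_classified_perfectly(self, model_and_data):
        model_set, features = model_and_data
        preds = predict_sequences(model_set, features)
        assert (preds["label"] == preds["predicted"]).all()

    def test_selection_finds_the_informative_coordinates(self, model_and_data):
        model_set, _ = model_and_data
        assert model_set.selected.selected_indices == (0, 1, 2)

    def test_row_order_invariance(self, model_and_data, separated_features):
        model_set, features = model_and_data
        shuffled = features.sample(frac=1.0, random_state=9)
        a = predict_sequences(model_set, features).set_index("sequence_id")["predicted"]
        b = predict_sequences(model_set, shuffled).set_index("sequence_id")["predicted"]
        assert a.sort_index().equals(b.sort_index())

    def test_missing_class_rejected(self, separated_features):
        two = separated_features[separated_features["label"] != FORAGING]
        with pytest.raises(ValidationError, match="foraging"):
            train_model_set(two, TrainConfig(d_target=2))

    def test_persistence_round_trip(self, model_and_data, tmp_path):
        model_set, features = model_and_data
        path = tmp_path / "models.joblib"
        save_model_set(path, model_set)
        loaded = load_model_set(path)
        a = predict_sequences(model_set, features)
        b = predict_sequences(loaded, features)
        assert a.equals(b)

    def test_end_to_end_determinism(self, separated_features):
        cfg = TrainConfig(d_target=3, seed=5, subsample_max=300)
        m1 = train_model_set(separated_features, cfg)
        m2 = train_model_set(separated_features, cfg)
        a = predict_sequences(m1, separated_features)
        b = predict_sequences(m2, separated_features)
        assert a.equals(b)
        assert m1.selected == m2.selected


class TestSequenceVoting:
    def test_majority_and_single_frame(self, separated_features):
        cfg = TrainConfig(d_target=3, seed=2, subsample_max=300)
        model_set = train_model_set(separated_features, cfg)
        one = separated_features[separated_features["sequence_id"] == "flushing-0000"]
        assert predict_sequences(model_set, one)["predicted"].iloc[0] == FLUSHING
        single = one[one["frame_index"] == 0]
        assert predict_sequences(model_set, single)["predicted"].iloc[0] == FLUSHING

    def test_held_out_accuracy_on_well_separated_clouds(self):
        means = {FLUSHING: [8, 0, 0], LANDING: [0, 8, 0], FORAGING: [0, 0, 8]}
        train = make_feature_table(means, n_sequences=30, noise=1.0, seed=21)
        test = make_feature_table(means, n_sequences=20, noise=1.0, seed=22)
        model_set = train_model_set(train, TrainConfig(d_target=3, seed=3,
                                                       subsample_max=300))
        preds = predict_sequences(model_set, test)
        accuracy = (preds["label"] == preds["predicted"]).mean()
        assert accuracy >= 0.95
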