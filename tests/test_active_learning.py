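"""Tests for query scoring and the active-learning loop."""

import math

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from dropal import (
    ALConfig,
    BoundaryConfig,
    DropoutConfig,
    entropy_score,
    generate_linear_dataset,
    information_density_score,
    run_al_cycle,
)
from dropal.active_learning import ALState, select_query
from dropal.oracles import fit_ttb


class TestEntropyScore:
    @pytest.mark.parametrize(
        "probs, expected",
        [
            ((0.5, 0.5), math.log(2)),
            ((1.0, 0.0), 0.0),
            ((0.9, 0.1), 0.3250829733914482),
        ],
    )
    def test_values(self, probs, expected):
        assert entropy_score(probs) == pytest.approx(expected)

    def test_invariant_to_class_order(self):
        assert entropy_score((0.3, 0.7)) == pytest.approx(entropy_score((0.7, 0.3)))

    @pytest.mark.parametrize("bad", [(0.5, 0.6), (-0.1, 1.1), ()])
    def test_malformed_simplex_rejected(self, bad):
        with pytest.raises(ValueError):
            entropy_score(bad)


class TestInformationDensity:
    def test_degenerate_pool_of_copies_returns_entropy(self):
        x = [1.0, 2.0]
        assert information_density_score(x, [x, x, x], 0.42) == pytest.approx(0.42)

    def test_zero_entropy_gives_zero_score(self):
        assert information_density_score([0, 0], [[5, 5]], 0.0) == 0.0

    def test_hand_evaluated_similarity_average(self):
        # pool = {x, point at distance 1}: mean sim = (1 + 0.5) / 2
        score = information_density_score([0.0], [[0.0], [1.0]], math.log(2))
        assert score == pytest.approx(math.log(2) * 0.75)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            information_density_score([0.0], np.empty((0, 1)), 0.5)


def _state_with_probs(X, pool, probs_matrix, seed=0):
    class Stub:
        def __init__(self, probs):
            self._p = np.asarray(probs, float)

        def predict_proba(self, X):
            return self._p

    state = ALState(
        X=np.asarray(X, float),
        X_raw=np.asarray(X, float),
        labeled=[],
        labels={},
        pool=list(pool),
        rng=np.random.default_rng(seed),
        config=ALConfig(),
        classifier=Stub(probs_matrix),
    )
    return state


class TestSelectQuery:
    def test_entropy_argmax(self):
        X = np.zeros((4, 2))
        state = _state_with_probs(X, [1, 2], [[0.5, 0.5], [0.95, 0.05]])
        assert select_query(state, "entropy") == 1

    def test_ties_resolve_to_smallest_dataset_index(self):
        X = np.zeros((5, 2))
        state = _state_with_probs(X, [2, 4], [[0.5, 0.5], [0.5, 0.5]])
        assert select_query(state, "entropy") == 2

    def test_random_is_seed_reproducible(self):
        X = np.zeros((10, 2))
        picks = [
            select_query(_state_with_probs(X, [3, 7, 9], [[0.5, 0.5]] * 3, seed=11), "random")
            for _ in range(2)
        ]
        assert picks[0] == picks[1]
        assert picks[0] in (3, 7, 9)

    def test_empty_pool_rejected(self):
        state = _state_with_probs(np.zeros((2, 2)), [], np.empty((0, 2)))
        with pytest.raises(ValueError):
            select_query(state, "entropy")


class _SpyOracle:
    """Wraps an annotator, recording the visibility mask and label per query."""

    def __init__(self, inner):
        self.inner = inner
        self.seen: list[tuple[tuple[bool, ...], int]] = []

    def label(self, query):
        out = self.inner.label(query)
        self.seen.append((tuple(query.visible.tolist()), out))
        return out


@pytest.fixture(scope="module")
def dataset():
    return generate_linear_dataset(
        80, d=2, boundary=BoundaryConfig(theta_deg=60.0), seed=5
    )


class TestRunALCycle:
    def test_curve_accounting(self, dataset):
        oracle = fit_ttb(dataset)
        curve = run_al_cycle(dataset, "entropy", oracle, dropout_enabled=False, seed=1)
        assert len(curve.accuracies) == dataset.n - 5 + 1  # includes pre-query point
        assert curve.n_queries == dataset.n - 5
        assert len(set(curve.query_history)) == len(curve.query_history)

    def test_dropout_disabled_means_fully_visible_queries(self, dataset):
        spy = _SpyOracle(fit_ttb(dataset))
        run_al_cycle(dataset, "random", spy, dropout_enabled=False, seed=2)
        assert all(all(mask) for mask, _ in spy.seen)

    def test_dropout_changes_some_oracle_labels(self, small_bias_dataset):
        oracle = fit_ttb(small_bias_dataset)
        spies = []
        for flag in (False, True):
            spy = _SpyOracle(oracle)
            run_al_cycle(small_bias_dataset, "entropy", spy, dropout_enabled=flag, seed=3)
            spies.append(spy)
        masks_off = {m for m, _ in spies[0].seen}
        masks_on = {m for m, _ in spies[1].seen}
        assert masks_off == {tuple([True] * small_bias_dataset.d)}
        assert len(masks_on) > 1  # some queries were actually masked
        labels_off = [lab for _, lab in spies[0].seen]
        labels_on = [lab for _, lab in spies[1].seen]
        assert labels_off != labels_on

    def test_omniscient_oracle_reaches_full_data_training_accuracy(self, dataset):
        class TruthOracle:
            def __init__(self, ds):
                self._lookup = {tuple(row): int(y) for row, y in zip(ds.X, ds.y)}

            def label(self, query):
                return self._lookup[tuple(query.values)]

        mu, sd = dataset.X.mean(0), dataset.X.std(0)
        Xs = (dataset.X - mu) / sd
        ref = LogisticRegression(max_iter=500).fit(Xs, dataset.y)
        ref_acc = ref.score(Xs, dataset.y)
        for flag in (False, True):
            curve = run_al_cycle(dataset, "entropy", TruthOracle(dataset),
                                 dropout_enabled=flag, seed=4)
            assert curve.accuracies[-1] == pytest.approx(ref_acc)

    def test_same_seed_reproduces_run_exactly(self, small_bias_dataset):
        oracle = fit_ttb(small_bias_dataset)
        cfg = ALConfig(dropout=DropoutConfig())
        runs = [
            run_al_cycle(small_bias_dataset, "density", oracle,
                         dropout_enabled=True, config=cfg, seed=9)
            for _ in range(2)
        ]
        assert runs[0].query_history == runs[1].query_history
        assert np.array_equal(runs[0].accuracies, runs[1].accuracies)

    def test_init_size_must_leave_a_pool(self, dataset):
        oracle = fit_ttb(dataset)
        with pytest.raises(ValueError):
            run_al_cycle(dataset, "entropy", oracle,
                         config=ALConfig(init_size=dataset.n), seed=0)
        with pytest.raises(ValueError):
            run_al_cycle(dataset, "entropy", oracle,
                         config=ALConfig(init_size=1), seed=0)
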