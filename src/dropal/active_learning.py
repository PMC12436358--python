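"""Pool-based active learning with optional attribute drop-out at query time.

The loop starts from a small random labeled set, retrains a base classifier
(logistic regression by default) after every query, and records accuracy on
the full dataset against the ground-truth labels — the annotator sees the
(possibly masked) query, but the classifier is always trained on the full
attribute vectors with the annotator's labels.  Query strategies: ``random``,
``entropy`` (maximum predictive entropy), and ``density`` (entropy weighted
by average similarity to the pool).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.linear_model import LogisticRegression

from .datasets import TabularDataset
from .dropout import DropoutConfig, MaskedInstance, mask_query

__all__ = [
    "ALConfig",
    "ALState",
    "LearningCurve",
    "entropy_score",
    "information_density_score",
    "select_query",
    "run_al_cycle",
]

STRATEGIES = ("random", "entropy", "density")


def entropy_score(class_probabilities: Sequence[float]) -> float:
    """Shannon entropy (natural log) of a class-probability vector."""
    p = np.asarray(class_probabilities, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("class probabilities must be a non-empty 1-d vector")
    if (p < -1e-12).any() or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("class probabilities must be nonnegative and sum to 1")
    p = np.clip(p, 0.0, 1.0)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def _similarities(x: np.ndarray, pool: np.ndarray, kind: str, bandwidth: float) -> np.ndarray:
    dist = np.linalg.norm(pool - x, axis=1)
    if kind == "inverse_distance":
        return 1.0 / (1.0 + dist)
    if kind == "gaussian":
        return np.exp(-(dist ** 2) / (2.0 * bandwidth ** 2))
    raise ValueError(f"unknown similarity {kind!r}")


def information_density_score(
    x: Sequence[float],
    pool: Sequence[Sequence[float]],
    entropy: float,
    similarity: str = "inverse_distance",
    bandwidth: float = 1.0,
) -> float:
    """Entropy weighted by the average similarity of ``x`` to the pool.

    Similarity defaults to ``1 / (1 + Euclidean distance)``, bounded in
    (0, 1] and monotone in distance; ``x``'s own pool entry, when present,
    contributes similarity 1.
    """
    pool_arr = np.atleast_2d(np.asarray(pool, dtype=float))
    if pool_arr.shape[0] == 0:
        raise ValueError("pool must be non-empty")
    if entropy < 0:
        raise ValueError("entropy must be nonnegative")
    sims = _similarities(np.asarray(x, dtype=float), pool_arr, similarity, bandwidth)
    return float(entropy * sims.mean())


@dataclass(frozen=True)
class ALConfig:
    """Active-learning loop configuration.

    init_size:          size of the initial uniformly random labeled set.
    dropout:            drop-out mechanism settings (see DropoutConfig).
    similarity:         kernel used by the density strategy.
    bandwidth:          Gaussian-kernel bandwidth (ignored otherwise).
    classifier_factory: zero-argument callable returning an unfitted binary
                        classifier with predict / predict_proba; defaults to
                        logistic regression.
    standardize:        z-score attributes (full-dataset statistics) before
                        fitting and distance computation; medians for the
                        annotator and the drop-out stay on the raw scale.
    """

    init_size: int = 5
    dropout: DropoutConfig = field(default_factory=DropoutConfig)
    similarity: str = "inverse_distance"
    bandwidth: float = 1.0
    classifier_factory: Callable | None = None
    standardize: bool = True


@dataclass
class LearningCurve:
    """Accuracy after each retraining; index 0 is the pre-query model."""

    accuracies: np.ndarray
    query_history: list[int]

    @property
    def n_queries(self) -> int:
        return len(self.accuracies) - 1


@dataclass
class ALState:
    """The loop's bookkeeping: labeled set, pool, classifier, rng."""

    X: np.ndarray                      # standardized attributes (model space)
    X_raw: np.ndarray                  # raw attributes (annotator space)
    labeled: list[int]
    labels: dict[int, int]
    pool: list[int]                    # dataset indices, kept sorted ascending
    rng: np.random.Generator
    config: ALConfig
    classifier: object | None = None
    constant_class: int | None = None  # set while L holds a single class
    query_history: list[int] = field(default_factory=list)

    def pool_probabilities(self) -> np.ndarray:
        """Class-probability matrix over the pool (uniform when degenerate)."""
        if self.constant_class is not None or self.classifier is None:
            return np.full((len(self.pool), 2), 0.5)
        return self.classifier.predict_proba(self.X[self.pool])


def select_query(state: ALState, strategy: str) -> int:
    """Pick the next dataset index to query from the pool.

    Score-based strategies take the argmax over the pool, ties resolved to
    the smallest dataset index; ``random`` draws uniformly with the run's rng.
    """
    if not state.pool:
        raise ValueError("pool is empty")
    if strategy == "random":
        return state.pool[int(state.rng.integers(len(state.pool)))]
    probs = state.pool_probabilities()
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(probs > 0, np.log(probs), 0.0)
    entropies = -(probs * logs).sum(axis=1)
    if strategy == "entropy":
        scores = entropies
    elif strategy == "density":
        pool_X = state.X[state.pool]
        dists = cdist(pool_X, pool_X)
        if state.config.similarity == "inverse_distance":
            sims = 1.0 / (1.0 + dists)
        elif state.config.similarity == "gaussian":
            sims = np.exp(-(dists ** 2) / (2.0 * state.config.bandwidth ** 2))
        else:
            raise ValueError(f"unknown similarity {state.config.similarity!r}")
        scores = entropies * sims.mean(axis=1)
    else:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    return state.pool[int(np.argmax(scores))]  # first max -> smallest index


def _default_classifier() -> LogisticRegression:
    return LogisticRegression(max_iter=500)


def _retrain(state: ALState) -> None:
    y = np.array([state.labels[i] for i in state.labeled])
    classes = np.unique(y)
    if classes.size < 2:
        state.constant_class = int(classes[0])
        state.classifier = None
        return
    factory = state.config.classifier_factory or _default_classifier
    clf = factory()
    clf.fit(state.X[state.labeled], y)
    state.classifier = clf
    state.constant_class = None


def _predict_all(state: ALState) -> np.ndarray:
    if state.constant_class is not None:
        return np.full(state.X.shape[0], state.constant_class)
    return state.classifier.predict(state.X)


def run_al_cycle(
    dataset: TabularDataset,
    strategy: str,
    oracle,
    dropout_enabled: bool | None = None,
    config: ALConfig | None = None,
    seed: int = 0,
) -> LearningCurve:
    """Run one full active-learning pass until the pool is exhausted.

    ``oracle`` is any object with a ``label(MaskedInstance) -> int`` method
    (the fitted TTB / FFT annotators qualify).  Ground-truth labels are used
    only to score accuracy on the full dataset after each retraining.  The
    returned curve has ``pool size + 1`` points: index 0 is the model trained
    on the initial labeled set alone.  ``dropout_enabled`` overrides the
    config's ``dropout.enabled`` flag when given.
    """
    config = config or ALConfig()
    if dropout_enabled is None:
        dropout_enabled = config.dropout.enabled
    dropout_cfg = replace(config.dropout, enabled=True)
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    if config.init_size < 2:
        raise ValueError("initial labeled set must have at least 2 instances")
    n, d = dataset.X.shape
    if config.init_size >= n:
        raise ValueError("initial labeled set must leave a non-empty pool")

    if config.standardize:
        mu = dataset.X.mean(axis=0)
        sd = dataset.X.std(axis=0)
        sd[sd == 0] = 1.0
        X_model = (dataset.X - mu) / sd
    else:
        X_model = dataset.X

    scales = None
    if config.dropout.rescale:
        mad = np.median(np.abs(dataset.X - dataset.medians), axis=0)
        mad[mad == 0] = 1.0
        scales = mad

    rng = np.random.default_rng(seed)
    init = sorted(int(i) for i in rng.choice(n, size=config.init_size, replace=False))
    labels = {i: int(oracle.label(MaskedInstance(dataset.X[i]))) for i in init}
    state = ALState(
        X=X_model,
        X_raw=dataset.X,
        labeled=list(init),
        labels=labels,
        pool=sorted(set(range(n)) - set(init)),
        rng=rng,
        config=config,
    )

    accuracies: list[float] = []
    while True:
        _retrain(state)
        accuracies.append(float(np.mean(_predict_all(state) == dataset.y)))
        if not state.pool:
            break
        idx = select_query(state, strategy)
        if dropout_enabled:
            query = mask_query(dataset.X[idx], dataset.medians,
                               dropout_cfg, scales=scales)
        else:
            query = MaskedInstance(dataset.X[idx])
        state.labels[idx] = int(oracle.label(query))
        state.labeled.append(idx)
        state.pool.remove(idx)
        state.query_history.append(idx)

    return LearningCurve(np.asarray(accuracies), state.query_history)
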