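"""Tabular datasets: synthetic generators and a CSV reader.

The generators realize the geometric assumptions behind the mislabeling
model — two linearly separable classes whose true decision boundary passes
through the attribute medians, with (in two dimensions) a boundary angle
drawn uniformly between 45 and 90 degrees — so the rest of the package can be
exercised without external data.  A dedicated "bias fixture" builds a dataset
on which one salient attribute is highly predictive overall but misleading
near its median, the situation the drop-out mechanism targets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .mislabel import DeviationPair

__all__ = [
    "TabularDataset",
    "BoundaryConfig",
    "generate_linear_dataset",
    "generate_bias_fixture",
    "simulate_mislabel_frequency",
    "load_csv_dataset",
]

logger = logging.getLogger(__name__)


@dataclass
class TabularDataset:
    """A binary-classification table: attributes, labels, names, medians.

    ``medians`` is always recomputed from ``X`` (the per-attribute population
    median over all rows); both classes must be present and values finite.
    """

    X: np.ndarray
    y: np.ndarray
    names: list[str] = field(default_factory=list)
    medians: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or self.y.shape != (self.X.shape[0],):
            raise ValueError("X must be n x d and y of length n")
        if not np.isfinite(self.X).all():
            raise ValueError("X contains non-finite values")
        if set(np.unique(self.y)) != {0, 1}:
            raise ValueError("y must contain both classes, coded {0, 1}")
        if not self.names:
            self.names = [f"attr_{j}" for j in range(self.X.shape[1])]
        if len(self.names) != self.X.shape[1]:
            raise ValueError("names must match the number of attributes")
        self.medians = np.median(self.X, axis=0)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class BoundaryConfig:
    """A true decision boundary through the attribute medians.

    Either ``theta_deg`` (two attributes: the boundary's angle with the first
    attribute's axis, in [45, 90]) or ``weights`` (general d: a nonnegative
    normal vector of the separating hyperplane) must be given.
    """

    theta_deg: float | None = None
    weights: Sequence[float] | None = None
    centered_at_medians: bool = True

    def normal(self, d: int) -> np.ndarray:
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (d,):
                raise ValueError(f"weights must have length {d}")
            if (w < 0).any() or not (w > 0).any():
                raise ValueError("weights must be nonnegative with at least one positive")
            return w
        if self.theta_deg is None:
            raise ValueError("BoundaryConfig needs theta_deg or weights")
        if d != 2:
            raise ValueError("theta_deg only defines a boundary for d = 2")
        if not 45.0 <= self.theta_deg <= 90.0:
            raise ValueError("theta_deg must lie in [45, 90]")
        t = math.radians(self.theta_deg)
        # boundary line at angle theta from the first axis; positive side is
        # the one reached by increasing the first attribute
        return np.array([math.sin(t), -math.cos(t)])


def _label_by_boundary(X: np.ndarray, normal: np.ndarray) -> np.ndarray:
    med = np.median(X, axis=0)
    return ((X - med) @ normal > 0).astype(int)


def generate_linear_dataset(
    n: int,
    d: int = 2,
    boundary: BoundaryConfig | None = None,
    label_noise: float = 0.0,
    seed: int = 0,
    marginal: str = "uniform",
    scale: float = 1.0,
    max_retries: int = 20,
) -> TabularDataset:
    """Draw a linearly separable two-class dataset through the medians.

    Attributes are iid ``uniform`` on [-scale, scale] (or ``gaussian`` with
    standard deviation ``scale``); labels are the side of a hyperplane through
    the sample medians.  With ``boundary=None`` and d = 2 the boundary angle
    is drawn uniformly from [45, 90] degrees; for d > 2, nonnegative weights
    are drawn uniformly.  ``label_noise`` flips each label independently.  A
    degenerate single-class draw is resampled with an incremented seed.
    """
    if n < 10 or d < 2:
        raise ValueError("need n >= 10 and d >= 2")
    if not 0.0 <= label_noise < 0.5:
        raise ValueError("label_noise must be in [0, 0.5)")
    for attempt in range(max_retries):
        rng = np.random.default_rng(seed + attempt)
        if marginal == "uniform":
            X = rng.uniform(-scale, scale, size=(n, d))
        elif marginal == "gaussian":
            X = rng.normal(0.0, scale, size=(n, d))
        else:
            raise ValueError(f"unknown marginal {marginal!r}")
        if boundary is None:
            if d == 2:
                cfg = BoundaryConfig(theta_deg=float(rng.uniform(45.0, 90.0)))
            else:
                w = rng.uniform(0.0, 1.0, size=d)
                w[int(rng.integers(d))] += 0.5  # guarantee a nonzero weight
                cfg = BoundaryConfig(weights=w)
        else:
            cfg = boundary
        y = _label_by_boundary(X, cfg.normal(d))
        if label_noise > 0:
            y = np.where(rng.random(n) < label_noise, 1 - y, y)
        if 0 < y.sum() < n:
            return TabularDataset(X, y)
        logger.warning("degenerate single-class draw at seed %d; resampling", seed + attempt)
    raise RuntimeError("could not draw a two-class dataset; check the boundary")


#: boundary angle of the bias fixture, degrees from the salient attribute's axis
BIAS_FIXTURE_THETA_DEG = 70.0


def generate_bias_fixture(n: int, seed: int = 0) -> TabularDataset:
    """A dataset where a salient attribute misleads heuristic annotators.

    Four iid uniform attributes on [-1, 1]; the true boundary runs through the
    sample medians at 70 degrees from the ``salient`` axis in the (salient,
    support) plane, with zero weight on the two noise attributes.  The salient
    attribute's single-cue accuracy is about 0.91 — high enough that TTB and
    an FFT rank it first — but its errors are concentrated on rows whose
    salient value is near the median, exactly the rows the worst-case
    mislabeling probability flags (ratio of deviations inside 18 degrees of
    the support axis), so masking it reroutes the annotator to the support
    attribute, which decides those rows correctly.
    """
    if n < 100:
        raise ValueError("bias fixture needs n >= 100")
    t = math.radians(BIAS_FIXTURE_THETA_DEG)
    boundary = np.array([math.sin(t), -math.cos(t), 0.0, 0.0])
    for attempt in range(20):
        rng = np.random.default_rng(seed + attempt)
        X = rng.uniform(-1.0, 1.0, size=(n, 4))
        y = _label_by_boundary(X, boundary)
        if 0 < y.sum() < n:
            return TabularDataset(X, y, names=["salient", "support", "noise_1", "noise_2"])
        logger.warning("degenerate bias-fixture draw at seed %d; resampling", seed + attempt)
    raise RuntimeError("could not draw a two-class bias fixture")


def simulate_mislabel_frequency(
    pair: DeviationPair, n_draws: int = 10_000, seed: int = 0
) -> float:
    """Monte-Carlo frequency of mislabeling under a random true boundary.

    Draws the true-boundary angle uniformly from [45, 90] degrees.  For the
    annotator using the first attribute, the point (at inclination theta_x
    from that axis) is mislabeled when it falls in the wedge between the true
    boundary and the annotator's boundary, i.e. when theta_TDB < theta_x; the
    second attribute's case is the mirror image (theta_TDB < 90 - theta_x).
    The worst case over the two annotator choices is returned.

    Note the expected frequency is ``|theta_x - 45| / 45`` — exactly twice the
    closed form of :func:`dropal.mislabel.p_mislabel_worst` — so the simulator
    agrees with the closed form in *ordering* (which points are riskier), not
    in absolute value.  See docs/methods.md.
    """
    if pair.a == 0.0 and pair.b == 0.0:
        raise ValueError("frequency undefined at a = b = 0")
    if n_draws < 1000:
        raise ValueError("n_draws must be at least 1000")
    theta_x = math.degrees(math.atan2(pair.b, pair.a))
    rng = np.random.default_rng(seed)
    draws = rng.uniform(45.0, 90.0, size=n_draws)
    freq_used_a = float(np.mean(draws < theta_x))
    freq_used_b = float(np.mean(draws < 90.0 - theta_x))
    return max(freq_used_a, freq_used_b)


def load_csv_dataset(
    path, label_column: str, positive_label=None
) -> TabularDataset:
    """Read a CSV with a header row into a :class:`TabularDataset`.

    Rows with missing values are dropped (logged).  All attribute columns must
    be numeric; the label column must take exactly two values, mapped to 1 for
    ``positive_label`` and 0 otherwise.  ``positive_label`` may be omitted
    when the labels are already coded {0, 1}.
    """
    df = pd.read_csv(path)
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found in {path}")
    n_before = len(df)
    df = df.dropna()
    if len(df) < n_before:
        logger.warning("dropped %d rows with missing values", n_before - len(df))
    labels = df[label_column]
    values = sorted(labels.unique().tolist(), key=str)
    if len(values) != 2:
        raise ValueError(
            f"label column {label_column!r} must be binary, found {len(values)} values"
        )
    if positive_label is None:
        if set(values) == {0, 1}:
            positive_label = 1
        else:
            raise ValueError(
                f"labels {values!r} are not 0/1; pass positive_label explicitly"
            )
    if positive_label not in values:
        raise ValueError(f"positive_label {positive_label!r} not among {values!r}")
    y = (labels == positive_label).astype(int).to_numpy()
    attrs = df.drop(columns=[label_column])
    for col in attrs.columns:
        if not np.issubdtype(attrs[col].dtype, np.number):
            raise ValueError(f"attribute column {col!r} is not numeric")
    return TabularDataset(attrs.to_numpy(dtype=float), y, names=list(attrs.columns))
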