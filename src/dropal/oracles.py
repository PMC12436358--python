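"""Synthetic annotators built from fast-and-frugal heuristics.

Two heuristics from the behavioral-science literature stand in for a human
annotator.  Take-the-Best (TTB) ranks the attributes by single-cue decision
accuracy against a median split and labels with the highest-ranked attribute
that is visible in the query, falling through when a value sits exactly at
its median.  A fast-and-frugal tree (FFT) tests median-binarized cues in
accuracy order; each non-terminal node exits on its purer side with that
side's majority class and passes the rest on, the terminal node exits both
sides, and nodes whose attribute is hidden in a query are skipped.  Both
annotators always return a label — when no visible cue can decide they fall
back to the majority class of the data they were fitted on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .dropout import MaskedInstance

__all__ = [
    "TTBModel",
    "FFTModel",
    "FFTNode",
    "fit_ttb",
    "ttb_label",
    "fit_fft",
    "fft_label",
]


def _as_query(query) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(query, MaskedInstance):
        return query.values, query.visible
    values = np.asarray(query, dtype=float)
    return values, np.ones(values.shape, dtype=bool)


def _single_cue_stats(x: np.ndarray, y: np.ndarray) -> tuple[int, float, bool]:
    """Direction, accuracy, and constant-flag of the median-split classifier.

    Direction +1 predicts positive when the value strictly exceeds the median,
    -1 when it is strictly below.  Values at the median predict negative under
    both directions.  A zero-spread attribute is flagged constant with
    accuracy 0.5 and direction +1.
    """
    med = np.median(x)
    if np.all(x == x[0]):
        return 1, 0.5, True
    acc_plus = float(np.mean((x > med) == y))
    acc_minus = float(np.mean((x < med) == y))
    if acc_plus >= acc_minus:
        return 1, acc_plus, False
    return -1, acc_minus, False


def _rank_cues(X: np.ndarray, y: np.ndarray) -> tuple[list[int], list[int], list[float]]:
    d = X.shape[1]
    directions = [0] * d
    accuracies = [0.0] * d
    constant = [False] * d
    for j in range(d):
        directions[j], accuracies[j], constant[j] = _single_cue_stats(X[:, j], y)
    # constant attributes rank last among equal accuracies
    order = sorted(range(d), key=lambda j: (-accuracies[j], constant[j], j))
    return order, directions, accuracies


def _majority_class(y: np.ndarray) -> int:
    # ties resolved toward the positive class
    return int(np.sum(y == 1) >= np.sum(y == 0))


@dataclass(frozen=True)
class TTBModel:
    """A fitted Take-the-Best annotator.

    ``cue_order`` ranks attribute indices by direction-adjusted single-cue
    accuracy (descending, ties toward lower index, constant cues last);
    ``directions`` and ``thresholds`` (the population medians) define each
    cue's median-split rule; ``majority_class`` is the fallback label.
    """

    cue_order: tuple[int, ...]
    directions: tuple[int, ...]
    thresholds: tuple[float, ...]
    accuracies: tuple[float, ...]
    majority_class: int

    def label(self, query) -> int:
        return ttb_label(self, query)


def fit_ttb(dataset) -> TTBModel:
    """Fit a TTB annotator on a dataset with ground-truth binary labels."""
    X, y = dataset.X, dataset.y
    order, directions, accuracies = _rank_cues(X, y)
    return TTBModel(
        cue_order=tuple(order),
        directions=tuple(directions),
        thresholds=tuple(float(m) for m in dataset.medians),
        accuracies=tuple(accuracies),
        majority_class=_majority_class(y),
    )


def ttb_label(model: TTBModel, query) -> int:
    """Label a (possibly masked) query with the best visible cue.

    The highest-ranked visible cue whose value is off its median decides;
    values exactly at the median fall through to the next visible cue, and if
    every visible cue sits at its median the majority class is returned.
    """
    values, visible = _as_query(query)
    if not visible.any():
        raise ValueError("cannot label a query with no visible attributes")
    for j in model.cue_order:
        if not visible[j]:
            continue
        signed = model.directions[j] * (values[j] - model.thresholds[j])
        if signed > 0:
            return 1
        if signed < 0:
            return 0
    return model.majority_class


@dataclass(frozen=True)
class FFTNode:
    """One level of a fast-and-frugal tree: a median split with exit labels."""

    attribute: int
    threshold: float
    exit_side: str  # "above", "below", or "both" (terminal)
    exit_labels: Mapping[str, int]


@dataclass(frozen=True)
class FFTModel:
    nodes: tuple[FFTNode, ...]
    majority_class: int

    @property
    def depth(self) -> int:
        return len(self.nodes)

    def label(self, query) -> int:
        return fft_label(self, query)


def fit_fft(dataset, depth: int = 3) -> FFTModel:
    """Build a fast-and-frugal tree of the given depth.

    Nodes are the top-``depth`` attributes by direction-adjusted single-cue
    accuracy.  Each non-terminal node exits on the median side with the higher
    class purity among the rows that reach it (ties exit above), labeling with
    that side's majority class; the terminal node exits both sides.  Rows with
    a value exactly at the median fall on the "below" side.
    """
    X, y = dataset.X, dataset.y
    d = X.shape[1]
    if not 1 <= depth <= d:
        raise ValueError(f"depth must be in [1, {d}], got {depth}")
    order, _, _ = _rank_cues(X, y)
    overall = _majority_class(y)
    medians = np.asarray(dataset.medians, dtype=float)

    nodes: list[FFTNode] = []
    remaining = np.ones(X.shape[0], dtype=bool)
    for k, j in enumerate(order[:depth]):
        above = remaining & (X[:, j] > medians[j])
        below = remaining & ~(X[:, j] > medians[j])

        def side_stats(mask: np.ndarray) -> tuple[float, int]:
            if not mask.any():
                return -1.0, overall
            frac_pos = float(np.mean(y[mask] == 1))
            return max(frac_pos, 1 - frac_pos), _majority_class(y[mask])

        purity_above, label_above = side_stats(above)
        purity_below, label_below = side_stats(below)
        if k == depth - 1:
            nodes.append(
                FFTNode(j, float(medians[j]), "both",
                        {"above": label_above, "below": label_below})
            )
        elif purity_above >= purity_below:
            nodes.append(FFTNode(j, float(medians[j]), "above", {"above": label_above}))
            remaining = below
        else:
            nodes.append(FFTNode(j, float(medians[j]), "below", {"below": label_below}))
            remaining = above
    return FFTModel(nodes=tuple(nodes), majority_class=overall)


def fft_label(model: FFTModel, query) -> int:
    """Traverse the tree, skipping nodes whose attribute is hidden.

    The first exit reached yields the label; if every node is skipped or
    passed through, the majority class of the fitting data is returned.
    """
    values, visible = _as_query(query)
    if not visible.any():
        raise ValueError("cannot label a query with no visible attributes")
    for node in model.nodes:
        if not visible[node.attribute]:
            continue
        side = "above" if values[node.attribute] > node.threshold else "below"
        if node.exit_side == "both" or node.exit_side == side:
            return node.exit_labels[side]
    return model.majority_class
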