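"""Attribute drop-out: decide which attribute values to hide from the annotator.

For a queried instance, every unordered pair of attributes is scored with the
worst-case mislabeling probability of :mod:`dropal.mislabel` on the pair's
absolute deviations from the population medians.  Whenever a pair's
probability exceeds the drop threshold (default 0.3), the pair's
smaller-deviation attribute — the one a single-attribute annotator would be
most misled by — becomes a drop candidate.  Candidates are sorted by
probability, deduplicated, and at most ``max_drop`` (default 2) attributes
are hidden, never leaving fewer than one attribute visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .mislabel import DeviationPair, p_mislabel_worst

__all__ = [
    "DropCandidate",
    "DropoutConfig",
    "MaskedInstance",
    "rank_drop_candidates",
    "select_drop_attributes",
    "apply_dropout",
    "mask_query",
]


@dataclass(frozen=True)
class DropCandidate:
    """An attribute proposed for removal, with the pair that implicated it."""

    attribute_index: int
    probability: float
    source_pair: tuple[int, int]


@dataclass(frozen=True)
class DropoutConfig:
    """Configuration of the drop-out mechanism.

    enabled:   master switch; when off, queries are sent with all attributes.
    threshold: drop a candidate only when the pair's worst-case mislabeling
               probability strictly exceeds this value (default 0.3, the
               18-degree geometry).
    max_drop:  upper bound on the number of hidden attributes (default 2).
    rescale:   divide deviations by a per-attribute scale (median absolute
               deviation) before scoring, making cross-attribute ratios
               unit-free.  Off by default: the mechanism is defined on raw
               deviations.
    """

    enabled: bool = True
    threshold: float = 0.3
    max_drop: int = 2
    rescale: bool = False


@dataclass(frozen=True)
class MaskedInstance:
    """An attribute vector with a visibility mask — the query sent to the annotator."""

    values: np.ndarray
    visible: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if self.visible is None:
            visible = np.ones(values.shape, dtype=bool)
        else:
            visible = np.asarray(self.visible, dtype=bool)
        if values.ndim != 1 or visible.shape != values.shape:
            raise ValueError("values and visible must be 1-d arrays of equal length")
        if not visible.any():
            raise ValueError("a query must keep at least one attribute visible")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "visible", visible)

    @property
    def hidden_indices(self) -> list[int]:
        return [int(i) for i in np.flatnonzero(~self.visible)]


def _validate_vectors(instance: Sequence[float], medians: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(instance, dtype=float)
    m = np.asarray(medians, dtype=float)
    if x.ndim != 1 or x.shape != m.shape:
        raise ValueError("instance and medians must be 1-d arrays of equal length")
    if x.size < 2:
        raise ValueError("the pairwise drop-out mechanism needs at least 2 attributes")
    if not (np.isfinite(x).all() and np.isfinite(m).all()):
        raise ValueError("instance and medians must be finite")
    return x, m


def rank_drop_candidates(
    instance: Sequence[float],
    medians: Sequence[float],
    threshold: float = 0.3,
    scales: Sequence[float] | None = None,
) -> list[DropCandidate]:
    """Score every attribute pair and return drop candidates, best first.

    For each unordered pair whose worst-case mislabeling probability strictly
    exceeds ``threshold``, the smaller-deviation attribute (ties: lower index)
    is a candidate.  Candidates are returned sorted by probability descending;
    equal probabilities keep pair-enumeration order.
    """
    x, m = _validate_vectors(instance, medians)
    if not 0.0 < threshold < 0.5:
        raise ValueError(f"threshold must be in (0, 0.5), got {threshold!r}")
    dev = np.abs(x - m)
    if scales is not None:
        s = np.asarray(scales, dtype=float)
        if s.shape != x.shape or (s <= 0).any():
            raise ValueError("scales must be positive and match the instance length")
        dev = dev / s
    candidates: list[DropCandidate] = []
    d = x.size
    for i in range(d):
        for j in range(i + 1, d):
            p = p_mislabel_worst(DeviationPair(dev[i], dev[j])).probability
            if p > threshold:
                member = i if dev[i] <= dev[j] else j
                candidates.append(DropCandidate(member, p, (i, j)))
    candidates.sort(key=lambda c: -c.probability)  # stable: ties keep pair order
    return candidates


def select_drop_attributes(
    candidates: Sequence[DropCandidate], d: int, max_drop: int = 2
) -> list[int]:
    """Deduplicate ranked candidates and cap the drop list.

    Keeps each attribute's highest-probability occurrence (the first, since
    the input is sorted descending) and returns at most ``min(max_drop, d-1)``
    indices so the query never loses every attribute.
    """
    if d < 2:
        raise ValueError("need at least 2 attributes")
    seen: list[int] = []
    for cand in candidates:
        if cand.attribute_index not in seen:
            seen.append(cand.attribute_index)
    return seen[: max(0, min(max_drop, d - 1))]


def apply_dropout(instance: Sequence[float], droplist: Sequence[int]) -> MaskedInstance:
    """Hide the drop-list attributes of ``instance``; values are untouched."""
    x = np.asarray(instance, dtype=float)
    idx = list(droplist)
    if len(set(idx)) != len(idx):
        raise ValueError("droplist contains duplicate indices")
    if any(i < 0 or i >= x.size for i in idx):
        raise ValueError("droplist index out of range")
    if len(idx) >= x.size:
        raise ValueError("droplist would hide every attribute")
    visible = np.ones(x.size, dtype=bool)
    visible[idx] = False
    return MaskedInstance(x, visible)


def mask_query(
    instance: Sequence[float],
    medians: Sequence[float],
    config: DropoutConfig | None = None,
    scales: Sequence[float] | None = None,
) -> MaskedInstance:
    """Full mechanism: rank, select, and apply — the query-time entry point."""
    config = config or DropoutConfig()
    x = np.asarray(instance, dtype=float)
    if not config.enabled:
        return MaskedInstance(x)
    candidates = rank_drop_candidates(
        x, medians, threshold=config.threshold,
        scales=scales if config.rescale else None,
    )
    droplist = select_drop_attributes(candidates, x.size, max_drop=config.max_drop)
    return apply_dropout(x, droplist)
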