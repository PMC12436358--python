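"""Closed-form mislabeling probability for one-attribute annotators.

An annotator who labels a record by comparing a single attribute against its
population median implicitly draws an axis-aligned decision boundary.  When
the true class boundary passes through the attribute medians at an angle
between 45 and 90 degrees to an attribute axis, the chance that such an
annotator mislabels a point depends only on how the point's absolute
deviations from the two medians compare.  Writing ``a`` and ``b`` for the
deviations, the worst case over the (unknown) attribute the annotator used is

    P(a, b) = 1/2 - (1/90) * arctan_deg(min(a, b) / max(a, b))

with the arctangent in degrees (radian form: ``1/2 - (2/pi) * arctan``).
Points deviating equally from both medians (the 45-degree line) are never
caught between the heuristic boundary and the true boundary and have
probability zero; points sitting on one median while deviating on the other
are maximally at risk (probability 1/2).  The probability exceeds 0.30
exactly when the point is inclined within 18 degrees of an attribute axis,
which is the drop threshold used by :mod:`dropal.dropout`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

__all__ = [
    "DeviationPair",
    "MislabelEstimate",
    "deviation_pair",
    "p_mislabel_worst",
    "p_mislabel_directed",
    "worst_case_probability",
]

AttributeRole = Literal["A", "B"]


@dataclass(frozen=True)
class DeviationPair:
    """Absolute deviations of a point's two attribute values from their medians.

    Both deviations are in the raw units of the respective attribute and must
    be nonnegative and finite.
    """

    a: float
    b: float

    def __post_init__(self) -> None:
        for name, value in (("a", self.a), ("b", self.b)):
            if not math.isfinite(value):
                raise ValueError(f"deviation {name!r} must be finite, got {value!r}")
            if value < 0:
                raise ValueError(f"deviation {name!r} must be nonnegative, got {value!r}")


@dataclass(frozen=True)
class MislabelEstimate:
    """A mislabeling probability together with the point's inclination.

    ``point_angle_deg`` is the angle (degrees in [0, 90]) the deviation vector
    (a, b) makes with the first attribute's axis.  ``variant`` records whether
    the estimate is the worst case over the attribute the annotator used, or
    conditioned on a specific attribute (``used_A`` / ``used_B``).
    """

    probability: float
    point_angle_deg: float
    variant: str


def deviation_pair(
    value_a: float, median_a: float, value_b: float, median_b: float
) -> DeviationPair:
    """Build a :class:`DeviationPair` from raw attribute values and medians."""
    for name, value in (
        ("value_a", value_a),
        ("median_a", median_a),
        ("value_b", value_b),
        ("median_b", median_b),
    ):
        if not math.isfinite(value):
            raise ValueError(f"{name} must be finite, got {value!r}")
    return DeviationPair(abs(value_a - median_a), abs(value_b - median_b))


def _point_angle_deg(pair: DeviationPair) -> float:
    return math.degrees(math.atan2(pair.b, pair.a))


def p_mislabel_worst(pair: DeviationPair) -> MislabelEstimate:
    """Worst-case mislabeling probability over the attribute the annotator used.

    Equals ``0.5 - arctan_deg(min/max)/90``, which lies in [0, 0.5]: zero on
    the 45-degree line (equal deviations) and 0.5 on the axes.  A point with
    both deviations zero sits exactly at both medians; the 0/0 case is defined
    as the supremum 0.5 (maximal ambiguity).
    """
    angle = _point_angle_deg(pair)
    hi = max(pair.a, pair.b)
    if hi == 0.0:
        return MislabelEstimate(0.5, angle, "worst_case")
    ratio = min(pair.a, pair.b) / hi
    p = 0.5 - math.degrees(math.atan(ratio)) / 90.0
    p = min(max(p, 0.0), 0.5)
    return MislabelEstimate(p, angle, "worst_case")


def p_mislabel_directed(pair: DeviationPair, used: AttributeRole) -> MislabelEstimate:
    """Mislabeling probability given which attribute the annotator used.

    With attribute A used, the annotator's boundary is the B axis and the
    error probability is ``clip_[0,1](0.5 - theta/90)`` where ``theta`` is the
    point's inclination from the A axis — in particular zero whenever
    ``b > a``.  The roles swap for attribute B.  The maximum over the two
    directed variants equals :func:`p_mislabel_worst`.
    """
    if pair.a == 0.0 and pair.b == 0.0:
        raise ValueError(
            "directed mislabel probability is undefined at a = b = 0; "
            "use p_mislabel_worst"
        )
    angle = _point_angle_deg(pair)
    if used == "A":
        p = 0.5 - angle / 90.0
    elif used == "B":
        p = 0.5 - (90.0 - angle) / 90.0
    else:
        raise ValueError(f"used must be 'A' or 'B', got {used!r}")
    p = min(max(p, 0.0), 1.0)
    return MislabelEstimate(p, angle, f"used_{used}")


def worst_case_probability(a: float, b: float) -> float:
    """Convenience scalar form of :func:`p_mislabel_worst`."""
    return p_mislabel_worst(DeviationPair(a, b)).probability
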