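"""Distance functions on rankings and numerical estimate vectors.

Implements the halved sign-sum discordance distance on complete tied
rankings (``kemeny_snell``), the pairwise-intensity distance on complete
numerical vectors (``cook_kress``), their normalized projected extensions
to incomplete inputs (``npks``, ``npck``), the plain discordant-pair count,
and the [0, 1] normalized ground-truth accuracy metric ``d*``.

Conventions
-----------
* ``kemeny_snell`` counts a tie-vs-strict pair as 1 and a strictly reversed
  pair as 2 (the halved double sum over ordered pairs).
* ``discordant_pairs`` counts only strictly reversed unordered pairs, so a
  tie-vs-strict pair contributes 0; on strict rankings it equals
  ``kemeny_snell / 2``.
* ``ground_truth_accuracy`` divides the discordant-pair count by
  ``m(m-1)/2`` so its range is exactly [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from .core_model import NumericalBallot, common_support, project

__all__ = [
    "RangeInfo",
    "kemeny_snell",
    "discordant_pairs",
    "npks",
    "cook_kress",
    "npck",
    "ground_truth_accuracy",
    "range_of_inputs",
]


@dataclass(frozen=True)
class RangeInfo:
    """Range of the numerical estimates in an aggregation instance."""

    range_low: float
    range_high: float

    def __post_init__(self):
        if self.range_high < self.range_low:
            raise ValueError("range_high < range_low")

    @property
    def range_width(self) -> float:
        return self.range_high - self.range_low


def _sign(x: float) -> int:
    return (x > 0) - (x < 0)


def _check_same_support(u: Mapping, v: Mapping) -> list:
    if set(u) != set(v):
        raise ValueError(
            f"mismatched supports: {sorted(set(u) ^ set(v))} not shared"
        )
    return sorted(u)


def kemeny_snell(a1: Mapping[str, int], a2: Mapping[str, int]) -> float:
    """Halved sign-disagreement sum between two complete tied rankings.

    Equals ``(1/2) * sum_ij |sign(a1_i - a1_j) - sign(a2_i - a2_j)|``:
    each strictly reversed unordered pair contributes 2, each
    tie-vs-strict pair contributes 1.
    """
    items = _check_same_support(a1, a2)
    total = 0
    for k, i in enumerate(items):
        for j in items[k + 1 :]:
            total += abs(
                _sign(a1[i] - a1[j]) - _sign(a2[i] - a2[j])
            )
    return float(total)


def discordant_pairs(a1: Mapping[str, int], a2: Mapping[str, int]) -> int:
    """Number of unordered pairs ranked in strictly opposite order."""
    items = _check_same_support(a1, a2)
    count = 0
    for k, i in enumerate(items):
        for j in items[k + 1 :]:
            if _sign(a1[i] - a1[j]) * _sign(a2[i] - a2[j]) == -1:
                count += 1
    return count


def npks(a1: Mapping[str, int], a2: Mapping[str, int]) -> float:
    """Normalized projected discordance between possibly incomplete rankings.

    Projects both rankings onto their common support ``C``; if
    ``|C| >= 2`` returns ``kemeny_snell`` of the projections divided by
    ``|C|(|C|-1)/2``, otherwise 0.
    """
    common = common_support(a1, a2)
    c = len(common)
    if c < 2:
        return 0.0
    return kemeny_snell(project(a1, common), project(a2, common)) / (
        c * (c - 1) / 2
    )


def cook_kress(b1: Mapping[str, float], b2: Mapping[str, float]) -> float:
    """Halved sum of absolute pairwise-intensity differences.

    Equals ``(1/2) * sum_ij |(b1_i - b1_j) - (b2_i - b2_j)|``; invariant
    under adding a constant to either vector.
    """
    items = _check_same_support(b1, b2)
    total = 0.0
    for k, i in enumerate(items):
        for j in items[k + 1 :]:
            total += abs((b1[i] - b1[j]) - (b2[i] - b2[j]))
    return total


def npck(
    b1: Mapping[str, float],
    b2: Mapping[str, float],
    range_info: RangeInfo,
) -> float:
    """Normalized projected intensity distance between incomplete vectors.

    If the common support ``C`` has ``c >= 2`` items, returns
    ``cook_kress`` of the projections divided by
    ``4R * ceil(c/2) * floor(c/2)`` with ``R`` the instance-level range
    width; otherwise 0.
    """
    common = common_support(b1, b2)
    c = len(common)
    if c < 2:
        return 0.0
    ck = cook_kress({i: b1[i] for i in common}, {i: b2[i] for i in common})
    if range_info.range_width == 0:
        if ck == 0:
            return 0.0
        raise ValueError(
            "normalization undefined: zero estimate range with nonzero "
            "pairwise-intensity distance"
        )
    return ck / (4 * range_info.range_width * math.ceil(c / 2) * (c // 2))


def ground_truth_accuracy(
    estimate: Mapping[str, int], truth: Mapping[str, int]
) -> float:
    """Normalized discordance d* in [0, 1] against a ground-truth ranking.

    ``discordant_pairs(estimate, truth) / (m(m-1)/2)``: 0 for a perfect
    (sign-identical) estimate, 1 for a full reversal of a strict ranking.
    """
    _check_same_support(estimate, truth)
    m = len(estimate)
    if m < 2:
        raise ValueError("d* requires at least 2 items")
    return discordant_pairs(estimate, truth) / (m * (m - 1) / 2)


def range_of_inputs(ballots: Iterable[NumericalBallot]) -> RangeInfo:
    """Exact min/max range over every estimate in a ballot collection."""
    values = [
        float(v) for b in ballots for v in b.estimates.values()
    ]
    if not values:
        raise ValueError("no numerical estimates to compute a range from")
    return RangeInfo(range_low=min(values), range_high=max(values))
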