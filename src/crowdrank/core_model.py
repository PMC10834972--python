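"""Domain types for ballots, universes and crowd datasets.

Rankings are represented as mappings ``image_id -> position`` using the
*competition* convention for ties: each position equals ``1 + (number of
items ranked strictly ahead)``, so a three-way structure like ``(1, 1, 3)``
is valid while ``(1, 1, 2)`` is not.  Position 1 means "fewest dots".
Image identifiers are opaque strings; ties between identifiers are broken
lexicographically wherever a deterministic order is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "Universe",
    "OrdinalBallot",
    "NumericalBallot",
    "ParticipantRecord",
    "CrowdDataset",
    "rank_of",
    "project",
    "common_support",
    "is_valid_ranking",
    "validate_dataset",
]

JOINT = "joint"
INDEPENDENT = "independent"


def rank_of(values: Mapping[str, float]) -> dict[str, int]:
    """Convert a numerical vector into a tied (competition) ranking.

    The smallest value receives position 1; equal values share a position
    equal to ``1 + (count of strictly smaller values)``.

    Parameters
    ----------
    values
        Mapping from item id to a finite number.

    Returns
    -------
    dict
        Mapping from item id to 1-based rank position over the same keys.

    Raises
    ------
    ValueError
        If `values` is empty or contains non-finite entries.
    """
    if not values:
        raise ValueError("cannot rank an empty ballot")
    vals = list(values.values())
    for v in vals:
        if not (float("-inf") < float(v) < float("inf")):
            raise ValueError(f"non-finite value in ballot: {v!r}")
    return {
        i: 1 + sum(1 for w in vals if w < v) for i, v in values.items()
    }


def is_valid_ranking(positions: Mapping[str, int]) -> bool:
    """Check that ``positions`` is a valid competition-style tied ranking."""
    if not positions:
        return False
    vals = list(positions.values())
    return all(p == 1 + sum(1 for q in vals if q < p) for p in vals)


def project(ranking: Mapping[str, int], subset: Iterable[str]) -> dict[str, int]:
    """Restrict a tied ranking to ``subset`` and re-compact its positions.

    Relative order and tie structure among the retained items are
    preserved; the result is again a valid competition ranking.

    Raises
    ------
    ValueError
        If ``subset`` is not contained in the ranking's support.
    """
    sub = set(subset)
    missing = sub - set(ranking)
    if missing:
        raise ValueError(f"subset items not in ranking support: {sorted(missing)}")
    return rank_of({i: ranking[i] for i in sub})


def _support_of(x) -> set[str]:
    if hasattr(x, "support"):
        return set(x.support)
    return set(x)


def common_support(u, v) -> set[str]:
    """Set of items evaluated in both inputs (ballots or mappings/sets)."""
    return _support_of(u) & _support_of(v)


@dataclass(frozen=True)
class Universe:
    """The full set of images with their ground-truth dot counts."""

    alternatives: tuple[str, ...]
    true_counts: Mapping[str, int]

    def __post_init__(self):
        alts = tuple(self.alternatives)
        object.__setattr__(self, "alternatives", alts)
        counts = dict(self.true_counts)
        object.__setattr__(self, "true_counts", counts)
        if set(counts) != set(alts):
            raise ValueError("true_counts keys must equal alternatives")
        if len(set(counts.values())) != len(counts):
            raise ValueError("true counts must be distinct")

    def __len__(self) -> int:
        return len(self.alternatives)

    def truth_ranking(self) -> dict[str, int]:
        """Strict ground-truth ranking (position 1 = fewest dots)."""
        return rank_of(self.true_counts)


@dataclass(frozen=True)
class OrdinalBallot:
    """A participant's (possibly tied) ranking over an image subset."""

    participant_id: str
    positions: Mapping[str, int]

    def __post_init__(self):
        pos = dict(self.positions)
        object.__setattr__(self, "positions", pos)
        if not pos:
            raise ValueError("ordinal ballot support is empty")
        if not is_valid_ranking(pos):
            raise ValueError(
                f"positions of {self.participant_id!r} are not a valid "
                f"competition ranking: {pos}"
            )

    @property
    def support(self) -> set[str]:
        return set(self.positions)


@dataclass(frozen=True)
class NumericalBallot:
    """A participant's dot-count estimates over an image subset."""

    participant_id: str
    estimates: Mapping[str, float]

    def __post_init__(self):
        est = dict(self.estimates)
        object.__setattr__(self, "estimates", est)
        if not est:
            raise ValueError("numerical ballot support is empty")
        for i, v in est.items():
            if not (0 < float(v) < float("inf")):
                raise ValueError(
                    f"estimate for {i!r} must be finite and > 0, got {v!r}"
                )

    @property
    def support(self) -> set[str]:
        return set(self.estimates)

    def induced_ranking(self) -> dict[str, int]:
        """rank_of applied to the estimates (the data-conversion step)."""
        return rank_of(self.estimates)


@dataclass(frozen=True)
class ParticipantRecord:
    """One participant's paired ordinal and numerical ballots."""

    participant_id: str
    interface_condition: str
    task_size: int
    ordinal: OrdinalBallot
    numerical: NumericalBallot

    def __post_init__(self):
        if self.interface_condition not in (JOINT, INDEPENDENT):
            raise ValueError(
                f"interface_condition must be {JOINT!r} or {INDEPENDENT!r}"
            )
        if self.ordinal.support != self.numerical.support:
            raise ValueError(
                f"ordinal/numerical supports differ for {self.participant_id!r}"
            )
        if len(self.ordinal.support) != self.task_size:
            raise ValueError(
                f"support size != task_size for {self.participant_id!r}"
            )

    @property
    def support(self) -> set[str]:
        return self.ordinal.support


@dataclass
class CrowdDataset:
    """A universe plus every participant record gathered for one task size."""

    universe: Universe
    records: list[ParticipantRecord] = field(default_factory=list)
    task_size: int = 0

    def __len__(self) -> int:
        return len(self.records)


def validate_dataset(dataset: CrowdDataset) -> list[str]:
    """Validate all type invariants; return a report of violations.

    An empty report means the dataset is well-formed.  Each violation
    string names the offending record (or the dataset) and the rule.
    """
    report: list[str] = []
    universe_set = set(dataset.universe.alternatives)
    for rec in dataset.records:
        pid = rec.participant_id
        if rec.ordinal.support != rec.numerical.support:
            report.append(f"{pid}: ordinal and numerical supports differ")
        if not rec.ordinal.support <= universe_set:
            report.append(f"{pid}: ballot support not contained in universe")
        if len(rec.support) != dataset.task_size:
            report.append(
                f"{pid}: support size {len(rec.support)} != task size "
                f"{dataset.task_size}"
            )
        if not is_valid_ranking(rec.ordinal.positions):
            report.append(f"{pid}: ordinal positions are not a valid ranking")
    n_obs = len(dataset.records) * dataset.task_size
    if dataset.records and n_obs % len(dataset.universe) == 0:
        views: dict[str, int] = {i: 0 for i in dataset.universe.alternatives}
        for rec in dataset.records:
            for i in rec.support:
                views[i] += 1
        if len(set(views.values())) > 1:
            report.append(
                "dataset: per-image view counts unequal despite divisible "
                f"record total ({sorted(set(views.values()))})"
            )
    return report
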