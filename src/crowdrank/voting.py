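"""Plurality, Borda and Copeland rules on incomplete tied ballots.

Each rule maps a list of rankings (mappings ``item -> position``) over
subsets of a universe to a :class:`ScoreTable`; ``scores_to_ranking`` then
orders the universe by non-increasing score.  The multimodal extension
feeds each participant's ordinal ballot together with the ranking induced
from their numerical estimates into the same rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .core_model import ParticipantRecord, rank_of

__all__ = [
    "ScoreTable",
    "plurality_scores",
    "borda_scores",
    "copeland_scores",
    "scores_to_ranking",
    "aggregate_multimodal",
    "aggregate_mixed_groups",
    "RULES",
]

RULES = ("plurality", "borda", "copeland")


@dataclass(frozen=True)
class ScoreTable:
    """Per-alternative scores produced by one voting rule."""

    scores: Mapping[str, float]
    rule: str
    n_ballots: int

    def __post_init__(self):
        object.__setattr__(self, "scores", dict(self.scores))
        if self.rule not in RULES:
            raise ValueError(f"unknown rule {self.rule!r}")


def _check_ballots(
    ballots: Sequence[Mapping[str, int]], universe: Iterable[str]
) -> set[str]:
    if not ballots:
        raise ValueError("empty ballot list")
    uni = set(universe)
    for b in ballots:
        if not set(b) <= uni:
            raise ValueError(
                f"ballot support {sorted(set(b) - uni)} outside universe"
            )
    return uni


def plurality_scores(
    ballots: Sequence[Mapping[str, int]], universe: Iterable[str]
) -> ScoreTable:
    """Score = number of ballots placing the alternative first.

    Co-first tied items each receive a full first-place vote; unseen
    alternatives contribute nothing.
    """
    uni = _check_ballots(ballots, universe)
    scores = {i: 0.0 for i in uni}
    for b in ballots:
        for i, pos in b.items():
            if pos == 1:
                scores[i] += 1.0
    return ScoreTable(scores=scores, rule="plurality", n_ballots=len(ballots))


def borda_scores(
    ballots: Sequence[Mapping[str, int]], universe: Iterable[str]
) -> ScoreTable:
    """Score = sum over ballots of (ballot size − rank position).

    Each ballot of size m awards ``m − a_i`` to every item i it ranks, so
    its first-placed item earns m−1 and its last earns 0 when strict.
    """
    uni = _check_ballots(ballots, universe)
    scores = {i: 0.0 for i in uni}
    for b in ballots:
        m = len(b)
        for i, pos in b.items():
            scores[i] += m - pos
    return ScoreTable(scores=scores, rule="borda", n_ballots=len(ballots))


def copeland_scores(
    ballots: Sequence[Mapping[str, int]], universe: Iterable[str]
) -> ScoreTable:
    """Score = pairwise wins minus defeats, summed over ballots.

    A ballot contributes to the (i, j) tally only when it ranks both; a
    tie between i and j contributes 0 in both directions.
    """
    uni = _check_ballots(ballots, universe)
    scores = {i: 0.0 for i in uni}
    for b in ballots:
        items = list(b)
        for k, i in enumerate(items):
            for j in items[k + 1 :]:
                if b[i] < b[j]:
                    scores[i] += 1
                    scores[j] -= 1
                elif b[i] > b[j]:
                    scores[i] -= 1
                    scores[j] += 1
    return ScoreTable(scores=scores, rule="copeland", n_ballots=len(ballots))


_RULE_FUNCS = {
    "plurality": plurality_scores,
    "borda": borda_scores,
    "copeland": copeland_scores,
}


def scores_to_ranking(
    table: ScoreTable, tie_break: str = "by_id"
) -> dict[str, int]:
    """Order alternatives by non-increasing score.

    ``tie_break="by_id"`` breaks equal scores lexicographically by image
    id into a strict ranking; ``"keep_ties"`` leaves them tied
    (competition positions).
    """
    if tie_break == "keep_ties":
        return rank_of({i: -s for i, s in table.scores.items()})
    if tie_break == "by_id":
        ordered = sorted(table.scores, key=lambda i: (-table.scores[i], i))
        return {i: p for p, i in enumerate(ordered, start=1)}
    raise ValueError(f"unknown tie_break {tie_break!r}")


def _multimodal_ballots(
    records: Sequence[ParticipantRecord],
) -> list[Mapping[str, int]]:
    out: list[Mapping[str, int]] = []
    for rec in records:
        out.append(rec.ordinal.positions)
        out.append(rec.numerical.induced_ranking())
    return out


def aggregate_multimodal(
    records: Sequence[ParticipantRecord],
    rule: str,
    tie_break: str = "by_id",
    universe: Iterable[str] | None = None,
) -> dict[str, int]:
    """Aggregate both modalities of every record under one voting rule.

    The ballot multiset is the union of all ordinal ballots and all
    rankings induced from the numerical ballots (2·|records| ballots).
    """
    if not records:
        raise ValueError("no records to aggregate")
    if universe is None:
        universe = set().union(*(rec.support for rec in records))
    table = _RULE_FUNCS[rule](_multimodal_ballots(records), universe)
    return scores_to_ranking(table, tie_break)


def aggregate_mixed_groups(
    ordinal_records: Sequence[ParticipantRecord],
    numerical_records: Sequence[ParticipantRecord],
    rule: str,
    tie_break: str = "by_id",
    universe: Iterable[str] | None = None,
) -> dict[str, int]:
    """Mix ordinal ballots of group A with converted numerical ballots of B.

    The separate-estimate design: the two groups must be disjoint sets of
    participants; each contributes a single modality.
    """
    if not ordinal_records or not numerical_records:
        raise ValueError("both groups must be nonempty")
    ids_a = {r.participant_id for r in ordinal_records}
    ids_b = {r.participant_id for r in numerical_records}
    overlap = ids_a & ids_b
    if overlap:
        raise ValueError(
            f"separate-estimate groups share participants: {sorted(overlap)}"
        )
    ballots: list[Mapping[str, int]] = [
        r.ordinal.positions for r in ordinal_records
    ] + [r.numerical.induced_ranking() for r in numerical_records]
    if universe is None:
        universe = set().union(*(set(b) for b in ballots))
    table = _RULE_FUNCS[rule](ballots, universe)
    return scores_to_ranking(table, tie_break)
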