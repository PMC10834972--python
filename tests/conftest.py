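import numpy as np
import pytest

from crowdrank.core_model import (
    CrowdDataset,
    NumericalBallot,
    OrdinalBallot,
    ParticipantRecord,
    Universe,
    rank_of,
)


def make_record(
    pid: str,
    estimates: dict[str, float],
    positions: dict[str, int] | None = None,
    condition: str = "independent",
) -> ParticipantRecord:
    """Build a record; ordinal defaults to the ranking induced by the counts."""
    if positions is None:
        positions = rank_of(estimates)
    return ParticipantRecord(
        participant_id=pid,
        interface_condition=condition,
        task_size=len(estimates),
        ordinal=OrdinalBallot(participant_id=pid, positions=positions),
        numerical=NumericalBallot(participant_id=pid, estimates=estimates),
    )


@pytest.fixture
def small_universe() -> Universe:
    return Universe(
        alternatives=("A", "B", "C", "D"),
        true_counts={"A": 50, "B": 55, "C": 60, "D": 65},
    )


@pytest.fixture
def consistent_records() -> list[ParticipantRecord]:
    """Three records all consistent with the truth A < B < C."""
    return [
        make_record("p0", {"A": 50.0, "B": 55.0, "C": 60.0}),
        make_record("p1", {"A": 48.0, "B": 56.0, "C": 61.0}),
        make_record("p2", {"A": 52.0, "B": 57.0, "C": 63.0}),
    ]


@pytest.fixture
def mixed_records() -> list[ParticipantRecord]:
    """Three records with conflicting ordinal vs numerical information."""
    return [
        make_record(
            "p0",
            {"A": 50.0, "B": 55.0, "C": 60.0},
            positions={"A": 1, "B": 2, "C": 3},
        ),
        make_record(
            "p1",
            {"A": 58.0, "B": 54.0, "C": 60.0},
            positions={"B": 1, "A": 2, "C": 3},
        ),
        make_record(
            "p2",
            {"B": 52.0, "C": 57.0, "D": 49.0},
            positions={"C": 1, "B": 2, "D": 3},
        ),
    ]


@pytest.fixture
def small_dataset(small_universe) -> CrowdDataset:
    rng = np.random.default_rng(42)
    records = []
    for p in range(8):
        est = {
            i: float(small_universe.true_counts[i]) + rng.normal(0, 3)
            for i in small_universe.alternatives
        }
        est = {i: max(1.0, round(v)) for i, v in est.items()}
        records.append(make_record(f"p{p}", est))
    return CrowdDataset(universe=small_universe, records=records, task_size=4)


def random_strict_ranking(rng: np.random.Generator, m: int) -> dict[str, int]:
    ids = [f"i{k}" for k in range(m)]
    perm = rng.permutation(m)
    return {ids[k]: int(perm[k]) + 1 for k in range(m)}
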