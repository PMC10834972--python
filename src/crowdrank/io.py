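"""CSV serialization of crowd datasets.

Four UTF-8 comma-separated files with header rows:

* ``ground_truth.csv``: image_id, task_size, true_count
* ``ordinal.csv``: participant_id, image_id, rank_position
* ``numerical.csv``: participant_id, image_id, estimate
* ``participants.csv``: participant_id, interface_condition, task_size
  (an optional ``completion_seconds`` column is passed through untouched
  for the IQR cleaning utility)
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .core_model import (
    CrowdDataset,
    NumericalBallot,
    OrdinalBallot,
    ParticipantRecord,
    Universe,
)

__all__ = ["write_dataset", "read_dataset", "load_deposited_repository"]


def write_dataset(dataset: CrowdDataset, out_dir: str | Path) -> None:
    """Write the four-CSV representation of a dataset to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "image_id": i,
                "task_size": dataset.task_size,
                "true_count": dataset.universe.true_counts[i],
            }
            for i in dataset.universe.alternatives
        ]
    ).to_csv(out / "ground_truth.csv", index=False)
    ord_rows, num_rows, part_rows = [], [], []
    for rec in dataset.records:
        part_rows.append(
            {
                "participant_id": rec.participant_id,
                "interface_condition": rec.interface_condition,
                "task_size": rec.task_size,
            }
        )
        for i in sorted(rec.support):
            ord_rows.append(
                {
                    "participant_id": rec.participant_id,
                    "image_id": i,
                    "rank_position": rec.ordinal.positions[i],
                }
            )
            num_rows.append(
                {
                    "participant_id": rec.participant_id,
                    "image_id": i,
                    "estimate": rec.numerical.estimates[i],
                }
            )
    pd.DataFrame(ord_rows).to_csv(out / "ordinal.csv", index=False)
    pd.DataFrame(num_rows).to_csv(out / "numerical.csv", index=False)
    pd.DataFrame(part_rows).to_csv(out / "participants.csv", index=False)


def read_dataset(in_dir: str | Path) -> CrowdDataset:
    """Read a dataset previously written by :func:`write_dataset`."""
    src = Path(in_dir)
    truth = pd.read_csv(src / "ground_truth.csv", dtype={"image_id": str})
    ordinal = pd.read_csv(src / "ordinal.csv", dtype={"participant_id": str, "image_id": str})
    numerical = pd.read_csv(src / "numerical.csv", dtype={"participant_id": str, "image_id": str})
    participants = pd.read_csv(src / "participants.csv", dtype={"participant_id": str})

    task_size = int(truth["task_size"].iloc[0])
    universe = Universe(
        alternatives=tuple(truth["image_id"]),
        true_counts=dict(zip(truth["image_id"], truth["true_count"].astype(int))),
    )
    ord_by_pid = {
        pid: dict(zip(g["image_id"], g["rank_position"].astype(int)))
        for pid, g in ordinal.groupby("participant_id")
    }
    num_by_pid = {
        pid: dict(zip(g["image_id"], g["estimate"].astype(float)))
        for pid, g in numerical.groupby("participant_id")
    }
    records = []
    for row in participants.itertuples(index=False):
        pid = row.participant_id
        records.append(
            ParticipantRecord(
                participant_id=pid,
                interface_condition=row.interface_condition,
                task_size=int(row.task_size),
                ordinal=OrdinalBallot(participant_id=pid, positions=ord_by_pid[pid]),
                numerical=NumericalBallot(participant_id=pid, estimates=num_by_pid[pid]),
            )
        )
    return CrowdDataset(universe=universe, records=records, task_size=task_size)


def load_deposited_repository(path: str | Path) -> CrowdDataset:
    """Adapter stub for the study's deposited data files.

    The deposited schema is not documented; until it is inspected this
    raises with a pointer to the supported CSV layout.
    """
    raise NotImplementedError(
        "the deposited data schema is unknown; convert the files to the "
        "ground_truth/ordinal/numerical/participants CSV layout described "
        "in crowdrank.io and use read_dataset instead"
    )
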