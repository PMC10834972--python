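"""Evaluation pipelines: self-consistency, error distributions, sweeps.

All tabular results are plain pandas DataFrames so they serialize to CSV
byte-identically across runs with the same seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coa import coa_consensus
from .core_model import (
    CrowdDataset,
    ParticipantRecord,
    project,
    validate_dataset,
)
from .distances import discordant_pairs, ground_truth_accuracy
from .synthetic_data import SimulationConfig, simulate_crowd
from .voting import RULES, aggregate_mixed_groups, aggregate_multimodal

__all__ = [
    "ConsistencyTable",
    "SweepResult",
    "self_consistency",
    "individual_error_distribution",
    "group_size_sweep",
    "coupled_vs_separate",
    "iqr_outlier_filter",
    "run_pipeline",
]

log = logging.getLogger("crowdrank")

SWEEP_METHODS = RULES + ("coa",)


@dataclass
class ConsistencyTable:
    """Per-participant rank-correlation coefficients between modalities."""

    rows: pd.DataFrame  # participant_id, task_size, condition, kendall, spearman, pearson

    def medians(self) -> pd.DataFrame:
        """Median of each coefficient per (task_size, condition) cell.

        Undefined (NaN) coefficients — e.g. from all-tied vectors — are
        excluded from the medians.
        """
        return (
            self.rows.groupby(["task_size", "condition"])[
                ["kendall", "spearman", "pearson"]
            ]
            .median()
            .reset_index()
        )


@dataclass
class SweepResult:
    """Normalized ground-truth distances per (method, group size, replicate)."""

    rows: pd.DataFrame  # method, group_size, replicate, d_star

    def summaries(self) -> pd.DataFrame:
        return (
            self.rows.groupby(["method", "group_size"])["d_star"]
            .agg(["median", "min", "max"])
            .reset_index()
        )


def _paired_rank_vectors(rec: ParticipantRecord) -> tuple[np.ndarray, np.ndarray]:
    items = sorted(rec.support)
    a = np.array([rec.ordinal.positions[i] for i in items], dtype=float)
    rb_map = rec.numerical.induced_ranking()
    rb = np.array([rb_map[i] for i in items], dtype=float)
    return a, rb


def self_consistency(dataset: CrowdDataset) -> ConsistencyTable:
    """Correlate each participant's ordering with their converted counts.

    Kendall is the tie-adjusted tau-b form; coefficients are NaN
    (undefined) when either vector has zero variance.
    """
    if not dataset.records:
        raise ValueError("empty dataset")
    rows = []
    for rec in dataset.records:
        a, rb = _paired_rank_vectors(rec)
        if len(a) < 2 or a.std() == 0 or rb.std() == 0:
            tau = rho = r = float("nan")
        else:
            tau = stats.kendalltau(a, rb).statistic
            rho = stats.spearmanr(a, rb).statistic
            r = stats.pearsonr(a, rb).statistic
        rows.append(
            {
                "participant_id": rec.participant_id,
                "task_size": rec.task_size,
                "condition": rec.interface_condition,
                "kendall": tau,
                "spearman": rho,
                "pearson": r,
            }
        )
    return ConsistencyTable(rows=pd.DataFrame(rows))


def individual_error_distribution(
    dataset: CrowdDataset, source: str = "converted_numerical"
) -> pd.DataFrame:
    """Histogram of per-participant discordant-pair counts vs the truth.

    ``source`` selects the ballot compared against the projected
    ground-truth ordering: the submitted ordering (``"ordinal"``) or the
    ranking induced from the counts (``"converted_numerical"``).  Returns
    one row per (task_size, discordant_pairs) bin covering 0..m(m-1)/2
    with the percentage of that task size's participants in the bin.
    """
    if source not in ("ordinal", "converted_numerical"):
        raise ValueError(f"unknown source {source!r}")
    truth = dataset.universe.truth_ranking()
    counts: dict[tuple[int, int], int] = {}
    totals: dict[int, int] = {}
    for rec in dataset.records:
        ballot = (
            rec.ordinal.positions
            if source == "ordinal"
            else rec.numerical.induced_ranking()
        )
        sub_truth = project(truth, rec.support)
        d = discordant_pairs(ballot, sub_truth)
        counts[(rec.task_size, d)] = counts.get((rec.task_size, d), 0) + 1
        totals[rec.task_size] = totals.get(rec.task_size, 0) + 1
    rows = []
    for m in sorted(totals):
        max_d = m * (m - 1) // 2
        for d in range(max_d + 1):
            rows.append(
                {
                    "task_size": m,
                    "discordant_pairs": d,
                    "percent": 100.0 * counts.get((m, d), 0) / totals[m],
                }
            )
    return pd.DataFrame(rows)


def _draw_group(
    records: Sequence[ParticipantRecord],
    group_size: int,
    block: int,
    rng: np.random.Generator,
    exclude: frozenset[int] = frozenset(),
) -> list[int]:
    """Indices of a random group: whole allocation blocks first, then fill.

    Taking whole consecutive blocks preserves balanced image coverage;
    the remainder is drawn uniformly from the leftover participants.
    """
    available_blocks = [
        b
        for b in range(len(records) // block)
        if not any(i in exclude for i in range(b * block, (b + 1) * block))
    ]
    n_blocks = min(group_size // block, len(available_blocks))
    chosen = list(rng.choice(available_blocks, size=n_blocks, replace=False))
    picked = [i for b in chosen for i in range(b * block, (b + 1) * block)]
    remainder = group_size - len(picked)
    if remainder > 0:
        pool = [
            i
            for i in range(len(records))
            if i not in exclude and i not in set(picked)
        ]
        if remainder > len(pool):
            raise ValueError("group size exceeds available participants")
        picked += list(rng.choice(pool, size=remainder, replace=False))
    return picked


def group_size_sweep(
    dataset: CrowdDataset,
    methods: Iterable[str] = ("plurality", "borda", "copeland"),
    group_sizes: Iterable[int] = (30, 75, 150, 300),
    replicates: int = 20,
    seed: int = 0,
    coa_options: dict | None = None,
) -> SweepResult:
    """Accuracy of each aggregation method across crowd sizes.

    For every replicate a random participant subset of the requested size
    is drawn (whole permutation blocks first to preserve balance); each
    method aggregates both modalities of the subset and is scored with the
    normalized ground-truth distance d* over the full universe.  When the
    group size equals the dataset there is a single deterministic subset.
    """
    methods = list(methods)
    for m in methods:
        if m not in SWEEP_METHODS:
            raise ValueError(f"unknown method {m!r}")
    n = len(dataset.records)
    group_sizes = list(group_sizes)
    if any(g > n for g in group_sizes):
        raise ValueError("group size exceeds number of records")
    block = len(dataset.universe) // dataset.task_size
    truth = dataset.universe.truth_ranking()
    universe = set(dataset.universe.alternatives)
    coa_options = dict(coa_options or {})
    rng = np.random.default_rng(seed)
    rows = []
    for g in group_sizes:
        for rep in range(replicates):
            if g == n:
                idx = list(range(n))
            else:
                idx = _draw_group(dataset.records, g, block, rng)
            subset = [dataset.records[i] for i in idx]
            for method in methods:
                if method == "coa":
                    sol = coa_consensus(subset, universe=universe, **coa_options)
                    consensus = dict(sol.consensus_ranking)
                else:
                    consensus = aggregate_multimodal(
                        subset, rule=method, universe=universe
                    )
                rows.append(
                    {
                        "method": method,
                        "group_size": g,
                        "replicate": rep,
                        "d_star": ground_truth_accuracy(consensus, truth),
                    }
                )
    return SweepResult(rows=pd.DataFrame(rows))


def coupled_vs_separate(
    config: SimulationConfig,
    coupled_sizes: Iterable[int] = (100,),
    separate_size_pairs: Iterable[tuple[int, int]] = ((100, 100),),
    replicates: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Coupled-estimate groups vs separate-estimate groups (Borda).

    Coupled: one group of size g contributes both modalities (2g
    ballots).  Separate: disjoint groups of sizes (g1, g2) contribute the
    ordinal and converted numerical ballots respectively.  Per replicate a
    fresh crowd large enough for the largest setting is simulated and the
    groups are drawn block-aligned; the output has one row per (setting,
    replicate) with its d*.
    """
    coupled_sizes = list(coupled_sizes)
    pairs = [tuple(p) for p in separate_size_pairs]
    need = max(
        list(coupled_sizes) + [g1 + g2 for g1, g2 in pairs], default=0
    )
    if need == 0:
        raise ValueError("no settings requested")
    rows = []
    for rep in range(replicates):
        from dataclasses import replace

        cfg = replace(config, n_participants=need, seed=seed + 1000 * rep)
        dataset = simulate_crowd(cfg)
        block = cfg.n_images // cfg.task_size
        truth = dataset.universe.truth_ranking()
        universe = set(dataset.universe.alternatives)
        rng = np.random.default_rng(seed + 1000 * rep + 1)
        for g in coupled_sizes:
            idx = _draw_group(dataset.records, g, block, rng)
            consensus = aggregate_multimodal(
                [dataset.records[i] for i in idx], rule="borda", universe=universe
            )
            rows.append(
                {
                    "setting": "coupled",
                    "size_label": str(g),
                    "n_participants": g,
                    "replicate": rep,
                    "d_star": ground_truth_accuracy(consensus, truth),
                }
            )
        for g1, g2 in pairs:
            idx_a = _draw_group(dataset.records, g1, block, rng)
            idx_b = _draw_group(
                dataset.records, g2, block, rng, exclude=frozenset(idx_a)
            )
            consensus = aggregate_mixed_groups(
                [dataset.records[i] for i in idx_a],
                [dataset.records[i] for i in idx_b],
                rule="borda",
                universe=universe,
            )
            rows.append(
                {
                    "setting": "separate",
                    "size_label": f"({g1},{g2})",
                    "n_participants": g1 + g2,
                    "replicate": rep,
                    "d_star": ground_truth_accuracy(consensus, truth),
                }
            )
    return pd.DataFrame(rows)


def iqr_outlier_filter(values: Sequence[float]) -> tuple[list[float], list[bool]]:
    """Flag values outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR].

    Quartiles use the linear-interpolation convention (numpy's default
    ``"linear"`` method).  Returns the kept values and a per-input flag
    (True = outlier).
    """
    vals = [float(v) for v in values]
    if len(vals) < 4:
        raise ValueError("need at least 4 values for quartile fences")
    q1, q3 = np.percentile(vals, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    flags = [v < lo or v > hi for v in vals]
    kept = [v for v, f in zip(vals, flags) if not f]
    return kept, flags


def run_pipeline(
    config: SimulationConfig,
    out_dir: str | Path,
    methods: Iterable[str] = ("plurality", "borda", "copeland"),
    group_sizes: Iterable[int] | None = None,
    replicates: int = 20,
    compare_groups: bool = False,
    dataset: CrowdDataset | None = None,
) -> dict:
    """End-to-end run: simulate (or use a loaded dataset), validate,
    analyze, and write all artifacts to ``out_dir``.

    Writes ``consistency.csv``, ``error_hist.csv``, ``sweep.csv``,
    optionally ``coupled_vs_separate.csv``, and ``summary.json``; returns
    the summary dict.  Reruns with the same config are byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if dataset is None:
        log.info("simulating crowd: %s", config)
        dataset = simulate_crowd(config)
    else:
        log.info("using provided dataset (%d records)", len(dataset.records))
    violations = validate_dataset(dataset)
    if violations:
        raise RuntimeError(f"validate: dataset invalid: {violations[:5]}")

    consistency = self_consistency(dataset)
    consistency.rows.to_csv(out / "consistency.csv", index=False)

    hist = individual_error_distribution(dataset, source="converted_numerical")
    hist.to_csv(out / "error_hist.csv", index=False)

    if group_sizes is None:
        n = len(dataset.records)
        group_sizes = sorted({max(2, n // 10), max(2, n // 4), max(2, n // 2), n})
    sweep = group_size_sweep(
        dataset,
        methods=methods,
        group_sizes=group_sizes,
        replicates=replicates,
        seed=config.seed + 17,
    )
    sweep.rows.to_csv(out / "sweep.csv", index=False)

    summary = {
        "n_records": len(dataset.records),
        "task_size": dataset.task_size,
        "condition": config.noise.condition,
        "seed": config.seed,
        "consistency_medians": consistency.medians().to_dict(orient="records"),
        "sweep_summaries": sweep.summaries().to_dict(orient="records"),
    }
    if compare_groups:
        cmp = coupled_vs_separate(config, replicates=replicates, seed=config.seed + 29)
        cmp.to_csv(out / "coupled_vs_separate.csv", index=False)
        summary["coupled_vs_separate"] = (
            cmp.groupby(["setting", "size_label"])["d_star"]
            .agg(["median", "min", "max"])
            .reset_index()
            .to_dict(orient="records")
        )
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
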