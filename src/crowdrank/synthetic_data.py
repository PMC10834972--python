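"""Synthetic crowds emulating the dot-ordering study's structure.

Builds 30-image universes with distinct integer dot counts, allocates
image subsets to participants by the permutation-partition scheme (so all
images are viewed equally often whenever the arithmetic allows), and draws
participant ballots under multiplicative log-normal perception noise.

Two elicitation conditions are modeled.  Under ``independent`` the ordinal
and numerical errors are statistically independent.  Under ``joint`` the
numerical values are, with probability ``consistency_lambda``, re-sorted
to agree with the submitted ordering (value multiset preserved), raising
ordinal/numerical self-consistency without changing the marginal
numerical error — the anchoring effect of seeing one's own ordering while
entering counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .core_model import (
    INDEPENDENT,
    JOINT,
    CrowdDataset,
    NumericalBallot,
    OrdinalBallot,
    ParticipantRecord,
    Universe,
)

__all__ = [
    "AllocationPlan",
    "NoiseProfile",
    "SimulationConfig",
    "make_universe",
    "allocate_tasks",
    "simulate_participant",
    "simulate_crowd",
    "DEFAULT_NOISE",
]


@dataclass(frozen=True)
class AllocationPlan:
    """Assignment of one image subset to each participant index."""

    assignments: tuple[tuple[int, tuple[str, ...]], ...]
    task_size: int
    n_images: int
    seed: int

    def view_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, subset in self.assignments:
            for img in subset:
                counts[img] = counts.get(img, 0) + 1
        return counts

    def n_observations(self) -> int:
        return sum(len(subset) for _, subset in self.assignments)


@dataclass(frozen=True)
class NoiseProfile:
    """Perception-noise parameters for one elicitation condition.

    ``complementarity`` anti-correlates a participant's numerical
    log-errors with their ordinal percept errors, modeling the
    within-person error-counteracting complementarity of answering the
    same question in two modalities; it is what gives coupled-estimate
    groups their edge over separate-estimate groups of equal ballot
    count.
    """

    sigma_ordinal: float = 0.10
    sigma_numerical: float = 0.15
    consistency_lambda: float = 0.8
    complementarity: float = 0.8
    condition: str = INDEPENDENT

    def __post_init__(self):
        if self.sigma_ordinal < 0 or self.sigma_numerical < 0:
            raise ValueError("noise sigmas must be >= 0")
        if not 0 <= self.consistency_lambda <= 1:
            raise ValueError("consistency_lambda must be in [0, 1]")
        if not 0 <= self.complementarity <= 1:
            raise ValueError("complementarity must be in [0, 1]")
        if self.condition not in (JOINT, INDEPENDENT):
            raise ValueError(f"unknown condition {self.condition!r}")


DEFAULT_NOISE = {
    JOINT: NoiseProfile(condition=JOINT),
    INDEPENDENT: NoiseProfile(condition=INDEPENDENT),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to draw one reproducible synthetic crowd."""

    n_participants: int = 300
    task_size: int = 5
    n_images: int = 30
    count_min: int = 50
    count_max: int = 79
    noise: NoiseProfile = field(default_factory=NoiseProfile)
    seed: int = 0

    def __post_init__(self):
        if self.count_max - self.count_min + 1 < self.n_images:
            raise ValueError(
                "count range cannot host distinct counts for every image"
            )


def make_universe(
    n_images: int = 30,
    count_min: int = 50,
    count_max: int = 79,
    seed: int = 0,
) -> Universe:
    """Draw a universe of ``n_images`` distinct integer dot counts.

    When the range is exactly as wide as the image count (the defaults:
    30 images over 50..79) every integer in the range is used; otherwise
    a seeded draw without replacement.
    """
    span = count_max - count_min + 1
    if span < n_images:
        raise ValueError(
            f"range [{count_min}, {count_max}] cannot give {n_images} "
            "distinct integer counts"
        )
    rng = np.random.default_rng(seed)
    if span == n_images:
        counts = np.arange(count_min, count_max + 1)
    else:
        counts = rng.choice(np.arange(count_min, count_max + 1), size=n_images,
                            replace=False)
    rng.shuffle(counts)
    width = len(str(n_images - 1))
    ids = [f"img{k:0{width}d}" for k in range(n_images)]
    return Universe(
        alternatives=tuple(ids),
        true_counts={i: int(c) for i, c in zip(ids, counts)},
    )


def allocate_tasks(
    n_participants: int,
    task_size: int,
    n_images: int = 30,
    seed: int = 0,
    image_ids: Sequence[str] | None = None,
) -> AllocationPlan:
    """Permutation-partition task allocation.

    Each block of ``n_images / task_size`` participants partitions a fresh
    random permutation of the images into consecutive subsets of
    ``task_size``; a trailing partial block consumes the prefix of a new
    permutation.  Whenever ``n_participants * task_size`` is divisible by
    ``n_images`` all per-image view counts are exactly equal; a partial
    block makes them differ by at most one.
    """
    if n_images % task_size != 0:
        raise ValueError(
            f"task size {task_size} does not divide the universe size "
            f"{n_images}"
        )
    if image_ids is None:
        width = len(str(n_images - 1))
        image_ids = [f"img{k:0{width}d}" for k in range(n_images)]
    elif len(image_ids) != n_images:
        raise ValueError("image_ids length must equal n_images")
    rng = np.random.default_rng(seed)
    block = n_images // task_size
    assignments: list[tuple[int, tuple[str, ...]]] = []
    perm: np.ndarray | None = None
    for p in range(n_participants):
        slot = p % block
        if slot == 0:
            perm = rng.permutation(n_images)
        lo = slot * task_size
        subset = tuple(image_ids[k] for k in perm[lo : lo + task_size])
        assignments.append((p, subset))
    return AllocationPlan(
        assignments=tuple(assignments),
        task_size=task_size,
        n_images=n_images,
        seed=seed,
    )


def simulate_participant(
    universe: Universe,
    subset: Iterable[str],
    profile: NoiseProfile,
    rng: np.random.Generator,
    participant_id: str = "p0",
) -> ParticipantRecord:
    """Draw one participant's paired ballots over ``subset``.

    The ordering comes from latent percepts ``c_i * exp(sigma_ordinal *
    eps_i)`` (strict: percept ties are broken by id); the counts from an
    independent draw ``round(c_i * exp(sigma_numerical * eps'_i))``
    clipped to >= 1.  Under the joint condition the counts are re-sorted
    to match the submitted ordering with probability
    ``consistency_lambda``.
    """
    items = sorted(subset)
    missing = set(items) - set(universe.alternatives)
    if missing:
        raise ValueError(f"subset outside universe: {sorted(missing)}")
    counts = np.array([universe.true_counts[i] for i in items], dtype=float)
    m = len(items)

    eps = rng.standard_normal(m)
    percepts = counts * np.exp(profile.sigma_ordinal * eps)
    order = np.lexsort((items, percepts))  # strict; id breaks exact ties
    positions = {items[k]: p + 1 for p, k in enumerate(order)}

    c = profile.complementarity
    eps_num = -c * eps + math.sqrt(1.0 - c * c) * rng.standard_normal(m)
    raw = counts * np.exp(profile.sigma_numerical * eps_num)
    estimates = np.maximum(np.rint(raw), 1.0)
    if (
        profile.condition == JOINT
        and rng.random() < profile.consistency_lambda
    ):
        # re-sort the drawn values so their order matches the ordering
        sorted_vals = np.sort(estimates)
        est_map = {
            items[k]: float(sorted_vals[positions[items[k]] - 1])
            for k in range(m)
        }
    else:
        est_map = {items[k]: float(estimates[k]) for k in range(m)}

    return ParticipantRecord(
        participant_id=participant_id,
        interface_condition=profile.condition,
        task_size=m,
        ordinal=OrdinalBallot(participant_id=participant_id, positions=positions),
        numerical=NumericalBallot(participant_id=participant_id, estimates=est_map),
    )


def simulate_crowd(config: SimulationConfig) -> CrowdDataset:
    """Compose universe, allocation and participant draws into a dataset.

    Fully reproducible per seed: one universe, one allocation plan and a
    single pseudo-random stream consumed in participant (allocation)
    order.
    """
    universe = make_universe(
        n_images=config.n_images,
        count_min=config.count_min,
        count_max=config.count_max,
        seed=config.seed,
    )
    plan = allocate_tasks(
        n_participants=config.n_participants,
        task_size=config.task_size,
        n_images=config.n_images,
        seed=config.seed + 1,
        image_ids=universe.alternatives,
    )
    rng = np.random.default_rng(config.seed + 2)
    width = len(str(max(config.n_participants - 1, 1)))
    records = [
        simulate_participant(
            universe,
            subset,
            config.noise,
            rng,
            participant_id=f"p{p:0{width}d}",
        )
        for p, subset in plan.assignments
    ]
    return CrowdDataset(
        universe=universe, records=records, task_size=config.task_size
    )


def config_for_condition(
    config: SimulationConfig, condition: str
) -> SimulationConfig:
    """Copy of ``config`` with the noise profile switched to ``condition``."""
    return replace(config, noise=replace(config.noise, condition=condition))
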