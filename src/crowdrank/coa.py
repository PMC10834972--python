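"""Cardinal-and-ordinal aggregation (COA) consensus optimization.

Finds a numerical consensus vector ``r`` over the universe whose induced
ranking jointly minimizes the cumulative normalized projected intensity
distance to the numerical ballots plus the cumulative normalized projected
discordance to the ordinal ballots:

    min_r  w_card * sum_l npck(b_l, r)  +  w_ord * sum_l npks(a_l, rank(r))

Two solution paths are provided:

* :func:`brute_force_coa` — exact oracle for small universes: enumerates
  every strict ordering and solves the inner continuous problem (the
  cardinal term subject to monotone, epsilon-separated consensus values)
  as a linear program.
* :func:`solve_coa` — anytime mixed-integer program (HiGHS branch and
  bound) with binary pairwise-precedence variables, transitivity
  constraints, big-M linking of precedences to the continuous consensus
  values, and linearized absolute values; reports the incumbent and its
  optimality gap when stopped at the time limit.

The consensus ranking is always strict: consecutive consensus values are
separated by at least ``epsilon`` (default 1, the dot-count granularity).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .core_model import NumericalBallot, OrdinalBallot, ParticipantRecord, rank_of
from .distances import RangeInfo, npck, npks, range_of_inputs

__all__ = [
    "COAInstance",
    "COASolution",
    "objective_value",
    "brute_force_coa",
    "solve_coa",
    "coa_consensus",
]

_OBJ_TOL = 1e-9


@dataclass(frozen=True)
class COAInstance:
    """One consensus-optimization problem over a fixed universe."""

    universe: tuple[str, ...]
    ordinal_ballots: Sequence[OrdinalBallot]
    numerical_ballots: Sequence[NumericalBallot]
    range_info: RangeInfo
    term_weights: tuple[float, float] = (1.0, 1.0)
    epsilon: float = 1.0
    time_limit_seconds: float = 600.0

    def __post_init__(self):
        object.__setattr__(self, "universe", tuple(sorted(self.universe)))
        uni = set(self.universe)
        for b in list(self.ordinal_ballots) + list(self.numerical_ballots):
            if not b.support <= uni:
                raise ValueError(
                    f"ballot of {b.participant_id!r} ranks items outside "
                    "the universe"
                )
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.range_info.range_width <= 0:
            raise ValueError("estimate range width must be > 0")
        need = (len(self.universe) - 1) * self.epsilon
        if need > self.range_info.range_width:
            raise ValueError(
                f"epsilon separation infeasible: need width >= {need}, "
                f"have {self.range_info.range_width}"
            )


@dataclass(frozen=True)
class COASolution:
    """Consensus values, induced ranking and solver certificates."""

    consensus_values: Mapping[str, float]
    consensus_ranking: Mapping[str, int]
    objective: float
    gap: float
    status: str  # optimal | time_limit | infeasible

    def __post_init__(self):
        object.__setattr__(self, "consensus_values", dict(self.consensus_values))
        object.__setattr__(self, "consensus_ranking", dict(self.consensus_ranking))


def objective_value(
    instance: COAInstance, candidate_values: Mapping[str, float]
) -> float:
    """Evaluate the COA objective at a complete candidate vector."""
    missing = set(instance.universe) - set(candidate_values)
    if missing:
        raise ValueError(f"candidate missing alternatives: {sorted(missing)}")
    w_ord, w_card = instance.term_weights
    cand = {i: float(candidate_values[i]) for i in instance.universe}
    cand_rank = rank_of(cand)
    card = sum(
        npck(b.estimates, cand, instance.range_info)
        for b in instance.numerical_ballots
    )
    ordn = sum(npks(a.positions, cand_rank) for a in instance.ordinal_ballots)
    return w_card * card + w_ord * ordn


def _cardinal_norm(m: int, range_width: float) -> float:
    return 4.0 * range_width * math.ceil(m / 2) * (m // 2)


def _ordinal_cost_of_ordering(
    instance: COAInstance, position: Mapping[str, int]
) -> float:
    """Ordinal term for a strict consensus ordering given as positions."""
    total = 0.0
    for a in instance.ordinal_ballots:
        items = sorted(a.support)
        m = len(items)
        if m < 2:
            continue
        norm = m * (m - 1) / 2
        d = 0.0
        for k, i in enumerate(items):
            for j in items[k + 1 :]:
                s_a = (a.positions[i] > a.positions[j]) - (
                    a.positions[i] < a.positions[j]
                )
                s_r = (position[i] > position[j]) - (position[i] < position[j])
                d += abs(s_a - s_r)
        total += d / norm
    return total


def _inner_cardinal_lp(
    instance: COAInstance, ordering: Sequence[str]
) -> tuple[float, dict[str, float]]:
    """Min cardinal term s.t. consensus monotone along ``ordering``.

    Variables: r (one per universe item) then one z per (ballot, pair)
    linearizing |(b_i - b_j) - (r_i - r_j)|.  Returns (cardinal objective
    at the weight w_card, optimal consensus values).
    """
    ids = list(instance.universe)
    idx = {i: k for k, i in enumerate(ids)}
    n = len(ids)
    R = instance.range_info.range_width
    _, w_card = instance.term_weights

    rows: list[np.ndarray] = []
    rhs: list[float] = []
    costs: list[float] = [0.0] * n

    nz = 0
    z_rows: list[tuple[int, int, float]] = []  # (idx_i, idx_j, d)
    for b in instance.numerical_ballots:
        items = sorted(b.support)
        m = len(items)
        if m < 2:
            continue
        norm = _cardinal_norm(m, R)
        for k, i in enumerate(items):
            for j in items[k + 1 :]:
                z_rows.append((idx[i], idx[j], b.estimates[i] - b.estimates[j]))
                costs.append(w_card / norm)
                nz += 1

    nvar = n + nz
    A = np.zeros(((n - 1) + 2 * nz, nvar))
    bvec = np.zeros((n - 1) + 2 * nz)
    # chain: r at ordering[k] must sit at least epsilon below ordering[k+1]
    for k in range(n - 1):
        A[k, idx[ordering[k]]] = 1.0
        A[k, idx[ordering[k + 1]]] = -1.0
        bvec[k] = -instance.epsilon
    # |d - (r_i - r_j)| <= z  as two inequalities
    for t, (ii, jj, d) in enumerate(z_rows):
        r1 = (n - 1) + 2 * t
        A[r1, ii] = -1.0
        A[r1, jj] = 1.0
        A[r1, n + t] = -1.0
        bvec[r1] = -d
        r2 = r1 + 1
        A[r2, ii] = 1.0
        A[r2, jj] = -1.0
        A[r2, n + t] = -1.0
        bvec[r2] = d

    bounds = [(instance.range_info.range_low, instance.range_info.range_high)] * n
    bounds += [(0.0, None)] * nz
    res = linprog(
        np.array(costs), A_ub=A, b_ub=bvec, bounds=bounds, method="highs"
    )
    if not res.success:  # cannot happen for a valid instance
        raise RuntimeError(f"inner LP failed: {res.message}")
    values = {ids[k]: float(res.x[k]) for k in range(n)}
    return float(res.fun), values


def brute_force_coa(instance: COAInstance, max_universe: int = 7) -> COASolution:
    """Exact consensus by exhaustive enumeration of strict orderings.

    For every permutation of the universe the ordinal term is a constant
    and the cardinal term is minimized by a linear program over monotone,
    epsilon-separated consensus values.  The first optimal ordering in
    lexicographic enumeration order is returned.
    """
    n = len(instance.universe)
    if n > max_universe:
        raise ValueError(
            f"universe of size {n} exceeds brute-force limit {max_universe}"
        )
    w_ord, _ = instance.term_weights
    best_obj = math.inf
    best_values: dict[str, float] | None = None
    for ordering in itertools.permutations(sorted(instance.universe)):
        position = {i: k + 1 for k, i in enumerate(ordering)}
        ord_cost = w_ord * _ordinal_cost_of_ordering(instance, position)
        if ord_cost >= best_obj - _OBJ_TOL:
            continue  # cardinal term is nonnegative
        card_cost, values = _inner_cardinal_lp(instance, ordering)
        total = ord_cost + card_cost
        if total < best_obj - _OBJ_TOL:
            best_obj = total
            best_values = values
    assert best_values is not None
    return COASolution(
        consensus_values=best_values,
        consensus_ranking=rank_of(best_values),
        objective=objective_value(instance, best_values),
        gap=0.0,
        status="optimal",
    )


def solve_coa(instance: COAInstance) -> COASolution:
    """Solve the COA model as a mixed-integer program (HiGHS backend).

    Formulation: one binary x_{ij} per unordered pair (i < j
    lexicographically; x_{ij} = 1 means i takes fewer dots than j),
    transitivity 0 <= x_{ij} + x_{jk} - x_{ik} <= 1 per triple, continuous
    consensus values r in [range_low, range_high] linked to precedences by
    big-M constraints with M = range_width + epsilon, and one auxiliary
    z >= |(b_i - b_j) - (r_i - r_j)| per (numerical ballot, pair).

    Returns the incumbent with its relative optimality gap when the time
    limit preempts the proof of optimality.
    """
    ids = list(instance.universe)
    n = len(ids)
    idx = {i: k for k, i in enumerate(ids)}
    pair_idx: dict[tuple[str, str], int] = {}
    for a, b in itertools.combinations(ids, 2):
        pair_idx[(a, b)] = len(pair_idx)
    npair = len(pair_idx)
    R = instance.range_info.range_width
    eps = instance.epsilon
    big_m = R + eps
    w_ord, w_card = instance.term_weights

    # variable layout: [x (npair binaries) | r (n) | z (per ballot pair)]
    z_specs: list[tuple[int, int, float, float]] = []  # (idx_i, idx_j, d, cost)
    for b in instance.numerical_ballots:
        items = sorted(b.support)
        m = len(items)
        if m < 2:
            continue
        norm = _cardinal_norm(m, R)
        for i, j in itertools.combinations(items, 2):
            z_specs.append(
                (idx[i], idx[j], b.estimates[i] - b.estimates[j], w_card / norm)
            )
    nz = len(z_specs)
    nvar = npair + n + nz

    cost = np.zeros(nvar)
    constant = 0.0
    for a in instance.ordinal_ballots:
        items = sorted(a.support)
        m = len(items)
        if m < 2:
            continue
        norm = m * (m - 1) / 2
        for i, j in itertools.combinations(items, 2):
            p = pair_idx[(i, j)]
            if a.positions[i] < a.positions[j]:
                # concordant when x_ij = 1; reversal costs 2/norm
                cost[p] += -2.0 * w_ord / norm
                constant += 2.0 * w_ord / norm
            elif a.positions[i] > a.positions[j]:
                cost[p] += 2.0 * w_ord / norm
            else:  # ballot tie vs strict consensus: constant 1 either way
                constant += 1.0 * w_ord / norm
    for t, (_, _, _, c) in enumerate(z_specs):
        cost[npair + n + t] = c

    constraints: list[LinearConstraint] = []

    if n >= 3:
        triples = list(itertools.combinations(ids, 3))
        A_tr = np.zeros((len(triples), nvar))
        for row, (i, j, k) in enumerate(triples):
            A_tr[row, pair_idx[(i, j)]] = 1.0
            A_tr[row, pair_idx[(j, k)]] = 1.0
            A_tr[row, pair_idx[(i, k)]] = -1.0
        constraints.append(LinearConstraint(A_tr, 0.0, 1.0))

    # linking: x_ij = 1 -> r_j - r_i >= eps ; x_ij = 0 -> r_i - r_j >= eps
    A_link = np.zeros((2 * npair, nvar))
    lb_link = np.zeros(2 * npair)
    for (i, j), p in pair_idx.items():
        A_link[2 * p, p] = -big_m
        A_link[2 * p, npair + idx[j]] = 1.0
        A_link[2 * p, npair + idx[i]] = -1.0
        lb_link[2 * p] = eps - big_m
        A_link[2 * p + 1, p] = big_m
        A_link[2 * p + 1, npair + idx[i]] = 1.0
        A_link[2 * p + 1, npair + idx[j]] = -1.0
        lb_link[2 * p + 1] = eps
    constraints.append(LinearConstraint(A_link, lb_link, np.inf))

    if nz:
        A_z = np.zeros((2 * nz, nvar))
        lb_z = np.zeros(2 * nz)
        for t, (ii, jj, d, _) in enumerate(z_specs):
            # z + (r_i - r_j) >= d  and  z - (r_i - r_j) >= -d
            A_z[2 * t, npair + n + t] = 1.0
            A_z[2 * t, npair + ii] = 1.0
            A_z[2 * t, npair + jj] = -1.0
            lb_z[2 * t] = d
            A_z[2 * t + 1, npair + n + t] = 1.0
            A_z[2 * t + 1, npair + ii] = -1.0
            A_z[2 * t + 1, npair + jj] = 1.0
            lb_z[2 * t + 1] = -d
        constraints.append(LinearConstraint(A_z, lb_z, np.inf))

    lb = np.concatenate(
        [
            np.zeros(npair),
            np.full(n, instance.range_info.range_low),
            np.zeros(nz),
        ]
    )
    ub = np.concatenate(
        [
            np.ones(npair),
            np.full(n, instance.range_info.range_high),
            np.full(nz, np.inf),
        ]
    )
    integrality = np.concatenate([np.ones(npair), np.zeros(n + nz)])

    res = milp(
        cost,
        constraints=constraints,
        integrality=integrality,
        bounds=Bounds(lb, ub),
        options={"time_limit": float(instance.time_limit_seconds)},
    )
    if res.status == 2:
        return COASolution(
            consensus_values={},
            consensus_ranking={},
            objective=math.inf,
            gap=math.inf,
            status="infeasible",
        )
    if res.x is None:
        raise RuntimeError(
            f"MIP solver returned no incumbent (status {res.status}: "
            f"{res.message})"
        )
    values = {ids[k]: float(res.x[npair + k]) for k in range(n)}
    objective = objective_value(instance, values)
    if res.status == 0:
        status, gap = "optimal", 0.0
    else:
        status = "time_limit"
        gap = float(res.mip_gap) if res.mip_gap is not None else math.inf
    return COASolution(
        consensus_values=values,
        consensus_ranking=rank_of(values),
        objective=objective,
        gap=gap,
        status=status,
    )


def coa_consensus(
    records: Sequence[ParticipantRecord],
    universe: Iterable[str] | None = None,
    exact: bool = False,
    epsilon: float = 1.0,
    time_limit_seconds: float = 600.0,
    term_weights: tuple[float, float] = (1.0, 1.0),
    max_universe_exact: int = 7,
) -> COASolution:
    """Assemble a :class:`COAInstance` from records and solve it.

    The estimate range is computed over all numerical ballots in the
    records.  With ``exact=True`` and a universe of at most
    ``max_universe_exact`` items the enumeration oracle is used; otherwise
    the mixed-integer solver.
    """
    if not records:
        raise ValueError("no records to aggregate")
    if universe is None:
        universe = set().union(*(r.support for r in records))
    numerical = [r.numerical for r in records]
    instance = COAInstance(
        universe=tuple(universe),
        ordinal_ballots=[r.ordinal for r in records],
        numerical_ballots=numerical,
        range_info=range_of_inputs(numerical),
        term_weights=term_weights,
        epsilon=epsilon,
        time_limit_seconds=time_limit_seconds,
    )
    if exact:
        return brute_force_coa(instance, max_universe=max_universe_exact)
    return solve_coa(instance)
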