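"""Discrete-time cohort state-transition (Markov) engine.

Both concrete models run on this engine: a deterministic cohort trace
(matrix multiplication of the occupancy vector) and a microsimulation mode
(individual-level categorical sampling) that serves as an internal
validation oracle for the cohort arithmetic.

Conventions
-----------
* ``occupancy[t]`` is the cohort distribution at the *start* of cycle ``t``;
  state rewards for cycle ``t`` accrue on ``occupancy[t]`` (no half-cycle
  correction by default; an averaged variant is available via
  ``RewardSpec.half_cycle``).
* Event costs attach to *entries* into a state: the flow from a different
  state during the transition at the end of cycle ``t`` is costed in cycle
  ``t``.  The initial distribution accrues no entry events.
* The discount factor for cycle ``t`` is ``(1+rate)**(-t*cycle_length)``;
  cycle 0 is undiscounted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

_ROW_TOL = 1e-12


class ModelStructureError(ValueError):
    """Raised for malformed state spaces, schedules, or rewards."""


@dataclass(frozen=True)
class StateSpace:
    """An ordered set of health states, some of which are absorbing."""

    states: tuple[str, ...]
    absorbing: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if len(set(self.states)) != len(self.states):
            raise ModelStructureError(f"duplicate state labels in {self.states}")
        stray = self.absorbing - set(self.states)
        if stray:
            raise ModelStructureError(f"absorbing states not in state list: {sorted(stray)}")

    @property
    def n(self) -> int:
        return len(self.states)

    def index(self, state: str) -> int:
        return self.states.index(state)

    @property
    def absorbing_indices(self) -> tuple[int, ...]:
        return tuple(i for i, s in enumerate(self.states) if s in self.absorbing)


class TransitionSchedule:
    """Per-cycle row-stochastic transition matrices over a StateSpace."""

    def __init__(self, space: StateSpace, matrices: np.ndarray):
        matrices = np.asarray(matrices, dtype=float)
        if matrices.ndim == 2:
            matrices = matrices[None, :, :]
        if matrices.ndim != 3 or matrices.shape[1:] != (space.n, space.n):
            raise ModelStructureError(
                f"matrices must have shape (n_cycles, {space.n}, {space.n}), "
                f"got {matrices.shape}"
            )
        self.space = space
        self.matrices = matrices
        self.validate()

    @classmethod
    def constant(cls, space: StateSpace, matrix: np.ndarray, n_cycles: int
                 ) -> "TransitionSchedule":
        m = np.asarray(matrix, dtype=float)
        return cls(space, np.repeat(m[None, :, :], n_cycles, axis=0))

    @property
    def n_cycles(self) -> int:
        return self.matrices.shape[0]

    def matrix(self, cycle: int) -> np.ndarray:
        return self.matrices[cycle]

    def validate(self) -> None:
        for t, m in enumerate(self.matrices):
            if np.any(m < -_ROW_TOL) or np.any(m > 1 + _ROW_TOL):
                raise ModelStructureError(f"cycle {t}: entries outside [0, 1]")
            bad = np.where(np.abs(m.sum(axis=1) - 1.0) > _ROW_TOL)[0]
            if bad.size:
                i = int(bad[0])
                raise ModelStructureError(
                    f"cycle {t}: row {i} ({self.space.states[i]!r}) sums to "
                    f"{m[i].sum():.15f}, not 1"
                )
            for i in self.space.absorbing_indices:
                if abs(m[i, i] - 1.0) > _ROW_TOL:
                    raise ModelStructureError(
                        f"cycle {t}: absorbing state {self.space.states[i]!r} "
                        f"has self-transition {m[i, i]}"
                    )


@dataclass
class RewardSpec:
    """Costs and utilities attached to states and state entries.

    ``state_cost`` and ``state_utility`` may be a vector over states or a
    ``(n_cycles, n_states)`` matrix for time-varying rewards.  Utilities are
    dimensionless weights in [0, 1], converted to QALYs through
    ``cycle_length_years``.  ``entry_cost`` is paid once per entry into a
    state (transition from a *different* state).
    """

    state_cost: np.ndarray
    state_utility: np.ndarray
    entry_cost: np.ndarray
    cycle_length_years: float
    half_cycle: bool = False
    #: states whose self-transitions count as fresh entries (within-cycle
    #: tunnel states: staying put means a new episode, not continuation)
    tunnel_entry: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.state_cost = np.asarray(self.state_cost, dtype=float)
        self.state_utility = np.asarray(self.state_utility, dtype=float)
        self.entry_cost = np.asarray(self.entry_cost, dtype=float)
        if self.tunnel_entry is not None:
            self.tunnel_entry = np.asarray(self.tunnel_entry, dtype=bool)
        if self.cycle_length_years <= 0:
            raise ModelStructureError("cycle_length_years must be > 0")
        if np.any(self.state_utility < 0) or np.any(self.state_utility > 1):
            raise ModelStructureError("state utilities must lie in [0, 1]")

    def cost_row(self, cycle: int) -> np.ndarray:
        return self.state_cost if self.state_cost.ndim == 1 else self.state_cost[cycle]

    def utility_row(self, cycle: int) -> np.ndarray:
        return (self.state_utility if self.state_utility.ndim == 1
                else self.state_utility[cycle])


def discounted_sum(values: Sequence[float], rate: float,
                   cycle_length_years: float = 1.0) -> float:
    """Sum of per-cycle values discounted at an annual rate.

    ``sum_t v[t] * (1+rate)**(-t*cycle_length_years)``; cycle 0 is
    undiscounted.
    """
    if rate < 0:
        raise ValueError(f"discount rate must be >= 0, got {rate}")
    v = np.asarray(values, dtype=float)
    t = np.arange(v.size)
    return float(np.sum(v * (1.0 + rate) ** (-t * cycle_length_years)))


@dataclass
class CohortTrace:
    """Cycle-by-state occupancy and reward accruals for one model arm."""

    space: StateSpace
    occupancy: np.ndarray          # (n_cycles+1, n_states), rows sum to 1
    entries: np.ndarray            # (n_cycles, n_states) flows into each state
    cost_per_cycle: np.ndarray     # undiscounted CNY, length n_cycles
    qaly_per_cycle: np.ndarray     # undiscounted QALY, length n_cycles
    discount_rate: float
    cycle_length_years: float
    standard_errors: dict = field(default_factory=dict)  # microsim only

    @property
    def n_cycles(self) -> int:
        return len(self.cost_per_cycle)

    @property
    def total_cost(self) -> float:
        return discounted_sum(self.cost_per_cycle, self.discount_rate,
                              self.cycle_length_years)

    @property
    def total_qalys(self) -> float:
        return discounted_sum(self.qaly_per_cycle, self.discount_rate,
                              self.cycle_length_years)

    def cumulative_entries(self, state: str) -> float:
        """Expected number of entries per patient into ``state`` over the run."""
        return float(self.entries[:, self.space.index(state)].sum())

    def state_occupancy(self, state: str) -> np.ndarray:
        return self.occupancy[:, self.space.index(state)]

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per (cycle, state)."""
        T, n = self.occupancy.shape
        rows = []
        for t in range(T):
            for j, s in enumerate(self.space.states):
                rows.append({
                    "cycle": t,
                    "state": s,
                    "occupancy": self.occupancy[t, j],
                    "cost": self.cost_per_cycle[t] if t < self.n_cycles else 0.0,
                    "qaly": self.qaly_per_cycle[t] if t < self.n_cycles else 0.0,
                    "discount_rate": self.discount_rate,
                    "cycle_length_years": self.cycle_length_years,
                })
        return pd.DataFrame(rows)


def run_cohort(space: StateSpace, schedule: TransitionSchedule,
               initial: np.ndarray, rewards: RewardSpec,
               n_cycles: int | None = None,
               discount_rate: float = 0.0) -> CohortTrace:
    """Deterministic cohort trace: ``occupancy[t+1] = occupancy[t] @ M[t]``."""
    if n_cycles is None:
        n_cycles = schedule.n_cycles
    if n_cycles > schedule.n_cycles:
        raise ModelStructureError(
            f"schedule defines {schedule.n_cycles} cycles, {n_cycles} requested")
    initial = np.asarray(initial, dtype=float)
    if initial.shape != (space.n,) or abs(initial.sum() - 1.0) > 1e-9 \
            or np.any(initial < 0):
        raise ModelStructureError("initial distribution must be a probability "
                                  f"vector over {space.n} states")
    if discount_rate < 0:
        raise ValueError(f"discount rate must be >= 0, got {discount_rate}")

    n = space.n
    occ = np.zeros((n_cycles + 1, n))
    occ[0] = initial
    entries = np.zeros((n_cycles, n))
    cost = np.zeros(n_cycles)
    qaly = np.zeros(n_cycles)
    keep_self = (rewards.tunnel_entry if rewards.tunnel_entry is not None
                 else np.zeros(n, dtype=bool))
    for t in range(n_cycles):
        m = schedule.matrix(t)
        flow = occ[t][:, None] * m
        occ[t + 1] = flow.sum(axis=0)
        # arrivals from other states; tunnel states also count self-flows
        entries[t] = flow.sum(axis=0) - np.where(keep_self, 0.0, np.diag(flow))
        weight = (0.5 * (occ[t] + occ[t + 1]) if rewards.half_cycle else occ[t])
        cost[t] = weight @ rewards.cost_row(t) + entries[t] @ rewards.entry_cost
        qaly[t] = (weight @ rewards.utility_row(t)) * rewards.cycle_length_years
    return CohortTrace(space, occ, entries, cost, qaly,
                       discount_rate, rewards.cycle_length_years)


def run_microsim(space: StateSpace, schedule: TransitionSchedule,
                 initial: np.ndarray, rewards: RewardSpec,
                 n_cycles: int | None = None, n_patients: int = 10_000,
                 seed: int = 0, discount_rate: float = 0.0) -> CohortTrace:
    """Monte-Carlo estimate of the cohort trace from individual trajectories.

    Patients are sampled independently through the same transition
    schedule; occupancy, costs and QALYs are averaged over patients, and
    standard errors of the discounted totals are reported in
    ``trace.standard_errors`` (keys ``total_cost``, ``total_qalys`` and
    ``occupancy``, the latter a per-cycle/state matrix).
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if n_cycles is None:
        n_cycles = schedule.n_cycles
    initial = np.asarray(initial, dtype=float)
    if abs(initial.sum() - 1.0) > 1e-9 or np.any(initial < 0):
        raise ModelStructureError("initial distribution must be a probability vector")
    if discount_rate < 0:
        raise ValueError(f"discount rate must be >= 0, got {discount_rate}")

    rng = np.random.default_rng(seed)
    n = space.n
    state = rng.choice(n, size=n_patients, p=initial / initial.sum())
    occ = np.zeros((n_cycles + 1, n))
    entries = np.zeros((n_cycles, n))
    occ[0] = np.bincount(state, minlength=n) / n_patients
    pat_cost = np.zeros(n_patients)
    pat_qaly = np.zeros(n_patients)
    cost = np.zeros(n_cycles)
    qaly = np.zeros(n_cycles)
    cl = rewards.cycle_length_years
    keep_self = (rewards.tunnel_entry if rewards.tunnel_entry is not None
                 else np.zeros(n, dtype=bool))
    for t in range(n_cycles):
        m = schedule.matrix(t)
        cum = np.cumsum(m, axis=1)
        u = rng.random(n_patients)
        nxt = (u[:, None] > cum[state]).sum(axis=1)
        moved = (nxt != state) | keep_self[nxt]
        entry_cost = np.where(moved, rewards.entry_cost[nxt], 0.0)
        df = (1.0 + discount_rate) ** (-t * cl)
        c_t = rewards.cost_row(t)[state] + entry_cost
        q_t = rewards.utility_row(t)[state] * cl
        cost[t] = c_t.mean()
        qaly[t] = q_t.mean()
        pat_cost += c_t * df
        pat_qaly += q_t * df
        entries[t] = np.bincount(nxt[moved], minlength=n) / n_patients
        state = nxt
        occ[t + 1] = np.bincount(state, minlength=n) / n_patients

    se = {
        "total_cost": float(pat_cost.std(ddof=1) / np.sqrt(n_patients))
        if n_patients > 1 else float("nan"),
        "total_qalys": float(pat_qaly.std(ddof=1) / np.sqrt(n_patients))
        if n_patients > 1 else float("nan"),
        "occupancy": np.sqrt(occ * (1 - occ) / n_patients),
    }
    return CohortTrace(space, occ, entries, cost, qaly,
                       discount_rate, cl, standard_errors=se)
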