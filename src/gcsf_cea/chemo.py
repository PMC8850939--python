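"""The 12-week chemotherapy Markov model (model 1).

Four 3-week cycles of TC chemotherapy (docetaxel 75 mg/m² +
cyclophosphamide 600 mg/m²) with G-CSF primary prophylaxis.  In each cycle
a patient may develop febrile neutropenia (FN); an FN episode may progress
to infection; FN and infection each carry a within-cycle case fatality.
Survivors resume chemotherapy the next cycle; after the fourth cycle
survivors move to an absorbing "completed" state.  Costs are not
discounted over the 12-week horizon.

FN and infection are within-cycle tunnel states: the state occupied during
a cycle records the complication experienced in that cycle, so the cycle's
utility (0.33 instead of 0.70) and the per-event costs (FN admission,
infection treatment) attach to it.  The cohort therefore enters the model
already split across {uncomplicated, FN, FN+infection} by the first
cycle's event tree, and the entry events of that first cycle are accounted
for explicitly since the engine costs entries only on transitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cea import CEAResult, compare
from .markov import (CohortTrace, RewardSpec, StateSpace, TransitionSchedule,
                     run_cohort, run_microsim)
from .params import ParameterSet, ParameterError, _norm_arm

STATES = ("OnChemo", "FN", "FNInfection", "Dead", "Completed")
ABSORBING = frozenset({"Dead", "Completed"})


@dataclass(frozen=True)
class ChemoParams:
    """Inputs of one arm of the chemotherapy model."""

    p_fn: float                     # per-cycle FN probability
    p_infection_given_fn: float
    p_death_fn: float               # case fatality, FN without infection
    p_death_infection: float        # case fatality, infection (instead of FN death)
    cost_gcsf_per_cycle: float
    cost_chemo_per_cycle: float     # drug acquisition, vial-rounded
    cost_fn_inpatient: float
    cost_infection_given_fn: float
    cost_hospitalization_per_cycle: float
    u_chemo: float
    u_fn: float
    u_infection: float
    n_cycles: int
    cycle_length_years: float
    discount_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_fn", "p_infection_given_fn", "p_death_fn",
                     "p_death_infection", "u_chemo", "u_fn", "u_infection"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        for name in ("cost_gcsf_per_cycle", "cost_chemo_per_cycle",
                     "cost_fn_inpatient", "cost_infection_given_fn",
                     "cost_hospitalization_per_cycle"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.n_cycles < 1 or self.cycle_length_years <= 0:
            raise ParameterError("n_cycles must be >= 1 and cycle length > 0")


def chemo_drug_cost_per_cycle(params: ParameterSet) -> float:
    """Per-cycle TC drug acquisition cost with vial rounding.

    Doses are body-surface-area scaled and rounded *up* to whole vials,
    since partial vials are billed whole.
    """
    bsa = params.body_surface_area_m2
    doc_vials = math.ceil(params.docetaxel_dose_mg_per_m2 * bsa
                          / params.docetaxel_vial_mg - 1e-9)
    cyc_vials = math.ceil(params.cyclophosphamide_dose_mg_per_m2 * bsa
                          / params.cyclophosphamide_vial_mg - 1e-9)
    return (doc_vials * params.cost_docetaxel_per_vial
            + cyc_vials * params.cost_cyclophosphamide_per_vial)


def arm_params(params: ParameterSet, arm: str) -> ChemoParams:
    """Extract one arm's chemotherapy-model inputs from a ParameterSet."""
    arm = _norm_arm(arm)
    return ChemoParams(
        p_fn=params.p_fn(arm),
        p_infection_given_fn=params.p_infection_given_fn(arm),
        p_death_fn=params.p_death_fn,
        p_death_infection=params.p_death_infection,
        cost_gcsf_per_cycle=params.cost_gcsf_per_cycle(arm),
        cost_chemo_per_cycle=chemo_drug_cost_per_cycle(params),
        cost_fn_inpatient=params.cost_fn_inpatient,
        cost_infection_given_fn=params.cost_infection_given_fn,
        cost_hospitalization_per_cycle=params.cost_hospitalization_per_cycle,
        u_chemo=params.utility_chemotherapy,
        u_fn=params.utility_fn,
        u_infection=params.utility_infection,
        n_cycles=params.n_chemo_cycles,
        cycle_length_years=params.chemo_cycle_years,
        discount_rate=params.chemo_discount_rate,
    )


def cycle_entry_distribution(cp: ChemoParams) -> np.ndarray:
    """Distribution over states at the start of a chemotherapy cycle.

    The within-cycle event tree: FN with probability ``p_fn``; given FN,
    infection with probability ``p_infection_given_fn``.
    """
    p_fn, p_inf = cp.p_fn, cp.p_infection_given_fn
    return np.array([1.0 - p_fn,
                     p_fn * (1.0 - p_inf),
                     p_fn * p_inf,
                     0.0, 0.0])


def build_chemo_model(cp: ChemoParams
                      ) -> tuple[StateSpace, TransitionSchedule, RewardSpec, np.ndarray]:
    """Assemble the state space, schedule, rewards and entry split for one arm.

    Occupancy row ``t`` (``t`` in 0..n_cycles-1) is the complication status
    during chemotherapy cycle ``t+1``; the final row is the end state
    (completed or dead).
    """
    space = StateSpace(STATES, ABSORBING)
    entry = cycle_entry_distribution(cp)
    surv_fn = 1.0 - cp.p_death_fn
    surv_inf = 1.0 - cp.p_death_infection
    i_dead, i_done = space.index("Dead"), space.index("Completed")

    def mid_cycle_matrix() -> np.ndarray:
        m = np.zeros((5, 5))
        m[0] = entry                                     # uncomplicated -> next cycle
        m[1] = surv_fn * entry
        m[1, i_dead] = cp.p_death_fn
        m[2] = surv_inf * entry
        m[2, i_dead] = cp.p_death_infection
        m[i_dead, i_dead] = 1.0
        m[i_done, i_done] = 1.0
        return m

    def final_matrix() -> np.ndarray:
        m = np.zeros((5, 5))
        m[0, i_done] = 1.0
        m[1, i_done], m[1, i_dead] = surv_fn, cp.p_death_fn
        m[2, i_done], m[2, i_dead] = surv_inf, cp.p_death_infection
        m[i_dead, i_dead] = 1.0
        m[i_done, i_done] = 1.0
        return m

    mats = np.stack([mid_cycle_matrix() for _ in range(cp.n_cycles - 1)]
                    + [final_matrix()])
    schedule = TransitionSchedule(space, mats)

    per_cycle = (cp.cost_chemo_per_cycle + cp.cost_gcsf_per_cycle
                 + cp.cost_hospitalization_per_cycle)
    state_cost = np.array([per_cycle, per_cycle, per_cycle, 0.0, 0.0])
    # infection episodes also incur the FN admission (infection follows FN)
    entry_cost = np.array([0.0, cp.cost_fn_inpatient,
                           cp.cost_fn_inpatient + cp.cost_infection_given_fn,
                           0.0, 0.0])
    state_utility = np.array([cp.u_chemo, cp.u_fn, cp.u_infection, 0.0, 0.0])
    # FN and infection are within-cycle tunnel states: remaining in one
    # across a transition is a new episode and incurs the event cost again
    tunnel = np.array([False, True, True, False, False])
    rewards = RewardSpec(state_cost=state_cost, state_utility=state_utility,
                         entry_cost=entry_cost,
                         cycle_length_years=cp.cycle_length_years,
                         tunnel_entry=tunnel)
    return space, schedule, rewards, entry


@dataclass(frozen=True)
class ChemoOutcome:
    """Per-patient totals and per-1000 event counts for one arm."""

    total_cost: float
    total_qalys: float
    fn_per_1000: float
    inf_per_1000: float
    deaths_per_1000: float
    p_fn_course: float           # probability of >=1 FN during the course
    trace: CohortTrace

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("total_cost", "total_qalys", "fn_per_1000", "inf_per_1000",
                 "deaths_per_1000", "p_fn_course")}


def fn_course_probability(p_fn_cycle: float, n_cycles: int) -> float:
    """Probability of at least one FN episode over the chemotherapy course."""
    return 1.0 - (1.0 - p_fn_cycle) ** n_cycles


def run_chemo_arm(cp: ChemoParams, microsim: bool = False,
                  n_patients: int = 100_000, seed: int = 0) -> ChemoOutcome:
    """Run one arm through the chemotherapy model.

    Event counts accumulate expected entries into the FN, infection and
    death states, including the first cycle's entry split (which the
    engine, costing entries only on transitions, does not see).
    """
    space, schedule, rewards, entry = build_chemo_model(cp)
    if microsim:
        trace = run_microsim(space, schedule, entry, rewards,
                             n_patients=n_patients, seed=seed,
                             discount_rate=cp.discount_rate)
    else:
        trace = run_cohort(space, schedule, entry, rewards,
                           discount_rate=cp.discount_rate)

    # first-cycle entry events (cycle-0 occupancy counts as entries here)
    fn0 = trace.occupancy[0, space.index("FN")]
    inf0 = trace.occupancy[0, space.index("FNInfection")]
    entry_event_cost = (fn0 + inf0) * cp.cost_fn_inpatient \
        + inf0 * cp.cost_infection_given_fn
    total_cost = trace.total_cost + entry_event_cost

    fn_entries = fn0 + inf0 \
        + trace.cumulative_entries("FN") + trace.cumulative_entries("FNInfection")
    inf_entries = inf0 + trace.cumulative_entries("FNInfection")
    deaths = trace.cumulative_entries("Dead")

    return ChemoOutcome(
        total_cost=total_cost,
        total_qalys=trace.total_qalys,
        fn_per_1000=1000.0 * fn_entries,
        inf_per_1000=1000.0 * inf_entries,
        deaths_per_1000=1000.0 * deaths,
        p_fn_course=fn_course_probability(cp.p_fn, cp.n_cycles),
        trace=trace,
    )


def run_chemo(params: ParameterSet, **kwargs) -> dict[str, ChemoOutcome]:
    """Run both arms from a shared ParameterSet."""
    return {arm: run_chemo_arm(arm_params(params, arm), **kwargs)
            for arm in ("PEG", "RHG")}


def compare_arms(outcome_peg: ChemoOutcome, outcome_rhg: ChemoOutcome,
                 wtp: float) -> CEAResult:
    """Incremental comparison, long- vs short-acting arm."""
    return compare(outcome_peg.total_cost, outcome_peg.total_qalys,
                   outcome_rhg.total_cost, outcome_rhg.total_qalys, wtp)
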