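"""Chemotherapy-model structure, costs, event counts and CEA metrics."""

import numpy as np
import pytest

from gcsf_cea.cea import compare
from gcsf_cea.chemo import (ChemoParams, arm_params, build_chemo_model,
                            chemo_drug_cost_per_cycle, compare_arms,
                            fn_course_probability, run_chemo_arm)
from gcsf_cea.params import ParameterError, ParameterSet

CYCLE_YEARS = 3.0 / 52.18


def make_params(p_fn=0.0116, p_inf=0.0547, p_death_fn=0.034,
                p_death_inf=0.034, n_cycles=4, **kw):
    defaults = dict(
        cost_gcsf_per_cycle=3315.74, cost_chemo_per_cycle=11360.19,
        cost_fn_inpatient=25000.0, cost_infection_given_fn=50000.0,
        cost_hospitalization_per_cycle=14811.10,
        u_chemo=0.70, u_fn=0.33, u_infection=0.33,
        n_cycles=n_cycles, cycle_length_years=CYCLE_YEARS)
    defaults.update(kw)
    return ChemoParams(p_fn=p_fn, p_infection_given_fn=p_inf,
                       p_death_fn=p_death_fn, p_death_infection=p_death_inf,
                       **defaults)


def enumerate_course(cp: ChemoParams):
    """Independent oracle: walk the full within-cycle event tree of the
    course (depth-first, all branches) and accumulate expected FN /
    infection / death counts and per-patient cost and QALY."""
    per_cycle_cost = (cp.cost_chemo_per_cycle + cp.cost_gcsf_per_cycle
                      + cp.cost_hospitalization_per_cycle)
    # per-cycle outcome branches: (label, probability, event_cost, utility,
    # within-cycle death probability)
    branches = [
        ("ok", 1 - cp.p_fn, 0.0, cp.u_chemo, 0.0),
        ("fn", cp.p_fn * (1 - cp.p_infection_given_fn), cp.cost_fn_inpatient,
         cp.u_fn, cp.p_death_fn),
        ("inf", cp.p_fn * cp.p_infection_given_fn,
         cp.cost_fn_inpatient + cp.cost_infection_given_fn,
         cp.u_infection, cp.p_death_infection),
    ]
    totals = {"fn": 0.0, "inf": 0.0, "dead": 0.0, "cost": 0.0, "qaly": 0.0}

    def walk(cycle: int, prob: float) -> None:
        if cycle == cp.n_cycles or prob == 0.0:
            return
        for label, p_branch, ev_cost, util, p_die in branches:
            p_here = prob * p_branch
            if p_here == 0.0:
                continue
            totals["cost"] += p_here * (per_cycle_cost + ev_cost)
            totals["qaly"] += p_here * util * cp.cycle_length_years
            if label in ("fn", "inf"):
                totals["fn"] += p_here
            if label == "inf":
                totals["inf"] += p_here
            totals["dead"] += p_here * p_die
            walk(cycle + 1, p_here * (1.0 - p_die))

    walk(0, 1.0)
    return totals


class TestBuildModel:
    def test_no_fn_limit_costs_are_pure_drug_and_bed(self):
        cp = make_params(p_fn=0.0)
        out = run_chemo_arm(cp)
        per_cycle = (cp.cost_chemo_per_cycle + cp.cost_gcsf_per_cycle
                     + cp.cost_hospitalization_per_cycle)
        assert out.total_cost == pytest.approx(4 * per_cycle)
        assert out.fn_per_1000 == 0.0
        assert out.total_qalys == pytest.approx(4 * 0.70 * CYCLE_YEARS)

    def test_certain_event_kills_cohort_in_first_cycle(self):
        cp = make_params(p_fn=1.0, p_inf=1.0, p_death_fn=1.0, p_death_inf=1.0)
        out = run_chemo_arm(cp)
        space = out.trace.space
        assert out.trace.occupancy[1, space.index("Dead")] == pytest.approx(1.0)
        assert out.deaths_per_1000 == pytest.approx(1000.0)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ParameterError):
            make_params(p_fn=1.3)

    def test_vial_rounding_in_drug_cost(self):
        ps = ParameterSet()   # BSA 1.6: 120 mg docetaxel = 6 vials; 960 mg
        # cyclophosphamide = 4.8 -> 5 vials
        expected = 6 * 1792.74 + 5 * 120.75
        assert chemo_drug_cost_per_cycle(ps) == pytest.approx(expected)

    def test_schedule_rows_stochastic(self, params):
        for arm in ("PEG", "RHG"):
            _, sched, _, entry = build_chemo_model(arm_params(params, arm))
            assert entry.sum() == pytest.approx(1.0)
            sched.validate()


class TestEventTreeOracle:
    @pytest.mark.parametrize("p_fn,p_inf,p_death", [
        (0.5, 0.5, 0.0),
        (0.0404, 0.547, 0.034),
        (0.0116, 0.0547, 0.034),
        (0.3, 0.9, 0.2),
    ])
    def test_two_cycle_counts_match_enumeration(self, p_fn, p_inf, p_death):
        cp = make_params(p_fn=p_fn, p_inf=p_inf, p_death_fn=p_death,
                         p_death_inf=p_death, n_cycles=2)
        oracle = enumerate_course(cp)
        out = run_chemo_arm(cp)
        assert out.fn_per_1000 / 1000 == pytest.approx(oracle["fn"], abs=1e-12)
        assert out.inf_per_1000 / 1000 == pytest.approx(oracle["inf"], abs=1e-12)
        assert out.deaths_per_1000 / 1000 == pytest.approx(oracle["dead"],
                                                           abs=1e-12)
        assert out.total_cost == pytest.approx(oracle["cost"], abs=1e-6)
        assert out.total_qalys == pytest.approx(oracle["qaly"], abs=1e-12)

    def test_expected_fn_episodes_half_half(self):
        # p_fn=.5, no deaths, 2 cycles: one FN episode expected per patient
        cp = make_params(p_fn=0.5, p_inf=0.5, p_death_fn=0.0, p_death_inf=0.0,
                         n_cycles=2)
        out = run_chemo_arm(cp)
        assert out.fn_per_1000 == pytest.approx(1000.0, abs=1e-9)

    def test_four_cycle_counts_match_enumeration(self, params):
        for arm in ("PEG", "RHG"):
            cp = arm_params(params, arm)
            oracle = enumerate_course(cp)
            out = run_chemo_arm(cp)
            assert out.fn_per_1000 / 1000 == pytest.approx(oracle["fn"],
                                                           abs=1e-12)
            assert out.total_cost == pytest.approx(oracle["cost"], abs=1e-6)


class TestArmComparison:
    def test_peg_has_fewer_events_than_rhg(self, params):
        peg = run_chemo_arm(arm_params(params, "PEG"))
        rhg = run_chemo_arm(arm_params(params, "RHG"))
        assert peg.fn_per_1000 < rhg.fn_per_1000
        assert peg.inf_per_1000 < rhg.inf_per_1000
        assert peg.deaths_per_1000 < rhg.deaths_per_1000
        assert peg.total_qalys > rhg.total_qalys

    def test_infection_only_follows_fn(self, params):
        for arm in ("PEG", "RHG"):
            out = run_chemo_arm(arm_params(params, arm))
            assert out.inf_per_1000 <= out.fn_per_1000
            assert out.deaths_per_1000 <= out.fn_per_1000

    def test_cost_decomposition_without_events(self):
        kw = dict(p_inf=0.0, p_death_fn=0.0, p_death_inf=0.0, p_fn=0.0,
                  cost_fn_inpatient=0.0, cost_infection_given_fn=0.0)
        peg = run_chemo_arm(make_params(cost_gcsf_per_cycle=3315.74, **kw))
        rhg = run_chemo_arm(make_params(cost_gcsf_per_cycle=734.34, **kw))
        assert peg.total_cost - rhg.total_cost == pytest.approx(
            4 * (3315.74 - 734.34))

    def test_monotone_in_infection_risk(self):
        costs, qalys = [], []
        for p_inf in np.linspace(0.0, 1.0, 6):
            out = run_chemo_arm(make_params(p_fn=0.1, p_inf=p_inf))
            costs.append(out.total_cost)
            qalys.append(out.total_qalys)
        assert np.all(np.diff(costs) >= -1e-9)
        assert np.all(np.diff(qalys) <= 1e-12)

    def test_fn_counts_strictly_increase_with_fn_risk(self):
        grid = [run_chemo_arm(make_params(p_fn=p)) for p in
                np.linspace(0.0, 0.5, 6)]
        fn = [o.fn_per_1000 for o in grid]
        q = [o.total_qalys for o in grid]
        assert np.all(np.diff(fn) > 0)
        assert np.all(np.diff(q) < 0)

    def test_identical_params_give_zero_increments(self, params):
        same = params.replace(p_fn_peg=params.p_fn_rhg,
                              p_infection_given_fn_peg=params.p_infection_given_fn_rhg,
                              cost_gcsf_peg_per_cycle=params.cost_gcsf_rhg_per_cycle)
        peg = run_chemo_arm(arm_params(same, "PEG"))
        rhg = run_chemo_arm(arm_params(same, "RHG"))
        r = compare_arms(peg, rhg, wtp=72371.0)
        assert r.delta_cost == 0.0
        assert r.delta_qalys == 0.0

    def test_cohort_matches_microsim_both_arms(self, params):
        n = 100_000
        for arm in ("PEG", "RHG"):
            cp = arm_params(params, arm)
            det = run_chemo_arm(cp)
            sim = run_chemo_arm(cp, microsim=True, n_patients=n, seed=5)
            se_c = sim.trace.standard_errors["total_cost"]
            se_q = sim.trace.standard_errors["total_qalys"]
            assert abs(det.total_cost - sim.total_cost) < 4 * se_c
            assert abs(det.total_qalys - sim.total_qalys) < 4 * se_q
            for field in ("fn_per_1000", "inf_per_1000", "deaths_per_1000"):
                p = getattr(det, field) / 1000
                se = np.sqrt(max(p * (1 - p), 1e-9) / n) * 1000
                # event counts can exceed one per patient; binomial SE is a
                # first-order bound, widened slightly for multi-episode runs
                assert abs(getattr(det, field) - getattr(sim, field)) \
                    < 4 * se + 0.5


class TestCEAMetrics:
    def test_published_increment_arithmetic(self):
        r = compare(146091.0, 3.456, 146055.0, 3.352, wtp=72371.0)
        assert r.delta_cost == pytest.approx(36.0)
        assert r.delta_qalys == pytest.approx(0.104)
        assert r.icer == pytest.approx(36 / 0.104)
        assert r.icer == pytest.approx(346.15, abs=0.01)

    def test_zero_cost_dominance(self):
        r = compare(100.0, 1.1, 100.0, 1.0, wtp=50_000.0)
        assert r.icer == 0.0
        assert r.dominant

    def test_negative_cost_labelled_dominant(self):
        r = compare(90.0, 1.1, 100.0, 1.0, wtp=50_000.0)
        assert r.dominant
        assert r.nmb == pytest.approx(0.1 * 50_000 + 10)

    def test_zero_delta_qaly_flags_undefined_icer(self):
        r = compare(110.0, 1.0, 100.0, 1.0, wtp=50_000.0)
        assert not r.icer_defined
        assert np.isnan(r.icer)


def test_fn_course_probability():
    assert fn_course_probability(0.0, 4) == 0.0
    assert fn_course_probability(1.0, 4) == 1.0
    assert fn_course_probability(0.0404, 4) == pytest.approx(
        1 - (1 - 0.0404) ** 4)
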