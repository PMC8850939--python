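"""Distribution fitting, DSA tornado, PSA cloud, CEAC and CE-plane."""

import numpy as np
import pytest

from gcsf_cea.analyze import run_base_case
from gcsf_cea.params import ParameterError
from gcsf_cea.sensitivity import (DistributionSpec, DSARange, PSACloud,
                                  beta_from_moments, ce_plane, ceac,
                                  default_dsa_ranges, default_psa_specs,
                                  fit_distribution, fixed_psa_specs,
                                  gamma_from_moments, one_way_dsa,
                                  probability_cost_effective, run_psa,
                                  tornado_frame)


class TestDistributions:
    def test_tabulated_beta_means(self):
        assert fit_distribution(DistributionSpec("beta", alpha=289, beta=881)
                                ).mean() == pytest.approx(289 / 1170)
        assert fit_distribution(DistributionSpec("beta", alpha=289, beta=881)
                                ).mean() == pytest.approx(0.2470, abs=1e-4)
        assert fit_distribution(DistributionSpec("beta", alpha=40, beta=6)
                                ).mean() == pytest.approx(0.8696, abs=1e-4)
        assert fit_distribution(DistributionSpec("beta", alpha=191, beta=191)
                                ).mean() == pytest.approx(0.5)

    def test_tabulated_beta_sample_means_within_1pct(self):
        rng = np.random.default_rng(5)
        for a, b in ((289, 881), (40, 6)):
            s = fit_distribution(DistributionSpec("beta", alpha=a, beta=b))
            draws = s.rvs(100_000, rng)
            assert abs(draws.mean() - a / (a + b)) / (a / (a + b)) < 0.01

    def test_gamma_moment_mode_recovers_moments(self):
        rng = np.random.default_rng(6)
        s = fit_distribution(DistributionSpec("gamma", mean=25_000, se=3_750))
        draws = s.rvs(100_000, rng)
        assert abs(draws.mean() - 25_000) / 25_000 < 0.01
        assert abs(draws.std(ddof=1) - 3_750) / 3_750 < 0.02

    def test_beta_moment_mode_recovers_moments(self):
        rng = np.random.default_rng(7)
        s = fit_distribution(DistributionSpec("beta", mean=0.0404,
                                              se=0.15 * 0.0404))
        draws = s.rvs(100_000, rng)
        assert abs(draws.mean() - 0.0404) / 0.0404 < 0.01
        assert np.all((draws >= 0) & (draws <= 1))

    def test_moment_matching_formulas(self):
        a, b = beta_from_moments(0.25, 0.05)
        assert a / (a + b) == pytest.approx(0.25)
        assert np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1))) \
            == pytest.approx(0.05)
        shape, scale = gamma_from_moments(100.0, 10.0)
        assert shape * scale == pytest.approx(100.0)
        assert np.sqrt(shape) * scale == pytest.approx(10.0)

    def test_mean_outside_support_rejected(self):
        with pytest.raises(ParameterError):
            beta_from_moments(1.5, 0.1)
        with pytest.raises(ParameterError):
            gamma_from_moments(-5.0, 1.0)

    def test_fixed_spec_returns_constant(self):
        s = fit_distribution(DistributionSpec("fixed", value=3.14))
        rng = np.random.default_rng(0)
        assert np.all(s.rvs(10, rng) == 3.14)


class TestDSA:
    def test_irrelevant_parameter_has_zero_swing(self, params, life_table):
        entries = one_way_dsa(
            params, life_table,
            [DSARange("utility_years_gt5", 0.8, 0.99)],
            outcome="incremental_cost")
        assert entries[0].swing == pytest.approx(0.0, abs=1e-9)

    def test_peg_price_dominates_incremental_cost(self, params, life_table):
        entries = one_way_dsa(params, life_table, default_dsa_ranges(params),
                              outcome="incremental_cost")
        cost_params = {e.parameter for e in entries if e.parameter.startswith("cost")}
        top_cost = next(e for e in entries if e.parameter in cost_params)
        assert top_cost.parameter == "cost_gcsf_peg_per_cycle"

    def test_linear_parameter_swings_symmetrically(self, params, life_table):
        base = run_base_case(params, life_table).delta_cost
        delta = 0.15 * params.cost_gcsf_peg_per_cycle
        [entry] = one_way_dsa(
            params, life_table,
            [DSARange("cost_gcsf_peg_per_cycle",
                      params.cost_gcsf_peg_per_cycle - delta,
                      params.cost_gcsf_peg_per_cycle + delta)],
            outcome="incremental_cost")
        assert (entry.outcome_high - base) == pytest.approx(
            base - entry.outcome_low, abs=1e-9)

    def test_entries_sorted_by_descending_swing(self, params, life_table):
        entries = one_way_dsa(params, life_table, default_dsa_ranges(params),
                              outcome="incremental_qaly_total")
        swings = [e.swing for e in entries]
        assert swings == sorted(swings, reverse=True)
        assert len(entries) == len(default_dsa_ranges(params))

    def test_rdi_risk_drives_incremental_qalys(self, params, life_table):
        entries = one_way_dsa(params, life_table, default_dsa_ranges(params),
                              outcome="incremental_qaly_postchemo")
        top = entries[0].parameter
        assert top in ("p_rdi_low_if_fn", "hr_mortality_rdi_low",
                       "p_rdi_low_no_fn_lt65")

    def test_unknown_parameter_rejected_with_names(self, params, life_table):
        with pytest.raises(ParameterError, match="p_fn_peg"):
            one_way_dsa(params, life_table,
                        [DSARange("nonexistent", 0.0, 1.0)],
                        outcome="incremental_cost")

    def test_discount_range_lowers_qalys_at_high_rate(self, params, life_table):
        [entry] = one_way_dsa(
            params, life_table,
            [DSARange("postchemo_discount_rate", 0.03, 0.07,
                      source="discount_3_7")],
            outcome="incremental_qaly_postchemo")
        assert entry.outcome_low > entry.outcome_high


class TestPSA:
    def test_fixed_specs_reproduce_base_case_bitwise(self, params, life_table):
        base = run_base_case(params, life_table)
        cloud = run_psa(params, life_table, fixed_psa_specs(params),
                        n_draws=3, seed=0)
        assert np.all(cloud.delta_cost == base.delta_cost)
        assert np.all(cloud.delta_qalys == base.delta_qalys_total)

    def test_same_seed_same_cloud(self, params, life_table):
        specs = default_psa_specs(params)
        a = run_psa(params, life_table, specs, n_draws=20, seed=4)
        b = run_psa(params, life_table, specs, n_draws=20, seed=4)
        assert np.array_equal(a.delta_cost, b.delta_cost)
        assert np.array_equal(a.delta_qalys, b.delta_qalys)

    def test_mean_centred_draws_recover_base_case(self, params, life_table):
        """With mean-centred distributions the PSA ΔQALY mean lands within
        4 SE of the base-case ΔQALY."""
        base = run_base_case(params, life_table)
        cloud = run_psa(params, life_table, default_psa_specs(params),
                        n_draws=400, seed=12)
        se = cloud.delta_qalys.std(ddof=1) / np.sqrt(cloud.n)
        assert abs(cloud.delta_qalys.mean() - base.delta_qalys_total) < 4 * se

    def test_draw_frame_shape(self, params, life_table):
        cloud = run_psa(params, life_table, default_psa_specs(params),
                        n_draws=10, seed=1)
        assert cloud.n == 10
        assert len(cloud.parameter_draws) == 10
        assert "p_fn_peg" in cloud.parameter_draws.columns


class TestCEAC:
    def single_cloud(self, dc, dq):
        return PSACloud(delta_cost=np.array([dc]), delta_qalys=np.array([dq]),
                        delta_qalys_chemo=np.array([dq]),
                        delta_qalys_postchemo=np.array([0.0]),
                        parameter_draws=None, seed=0)

    def test_single_draw_accepts_at_high_wtp(self):
        cloud = self.single_cloud(36.0, 0.104)
        assert probability_cost_effective(cloud, 72_371.0) == 1.0

    def test_costly_draws_rejected_at_zero_wtp(self):
        cloud = self.single_cloud(36.0, 0.104)
        assert probability_cost_effective(cloud, 0.0) == 0.0

    def test_monotone_when_all_draws_gain_qalys(self, params, life_table):
        cloud = run_psa(params, life_table, default_psa_specs(params),
                        n_draws=200, seed=3)
        keep = cloud.delta_qalys >= 0
        filtered = PSACloud(delta_cost=cloud.delta_cost[keep],
                            delta_qalys=cloud.delta_qalys[keep],
                            delta_qalys_chemo=cloud.delta_qalys_chemo[keep],
                            delta_qalys_postchemo=cloud.delta_qalys_postchemo[keep],
                            parameter_draws=None, seed=3)
        grid = np.linspace(0, 300_000, 31)
        p = ceac(filtered, grid)["probability_cost_effective"].to_numpy()
        assert np.all(np.diff(p) >= 0)
        assert np.all((p >= 0) & (p <= 1))

    def test_empty_grid_rejected(self):
        with pytest.raises(ParameterError):
            ceac(self.single_cloud(1.0, 1.0), [])


class TestCEPlane:
    def test_quadrant_labels(self):
        cloud = PSACloud(delta_cost=np.array([36.0, -10.0, 5.0, -5.0]),
                         delta_qalys=np.array([0.104, 0.1, -0.1, -0.1]),
                         delta_qalys_chemo=np.zeros(4),
                         delta_qalys_postchemo=np.zeros(4),
                         parameter_draws=None, seed=0)
        plane = ce_plane(cloud)
        assert list(plane["quadrant"]) == ["NE", "SE", "NW", "SW"]
        assert len(plane) == cloud.n
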