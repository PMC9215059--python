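"""Monte Carlo propagation: input draws, PIF simulation, summaries."""

import math

import numpy as np
import pytest

from ebwcost import (
    MonteCarloConfig,
    PrevalenceTable,
    RelativeRiskEstimate,
    ScenarioSpec,
    categorical_profile,
    draw_log_rr,
    draw_prevalence,
    pif_subtype,
    rescale_rr,
    simulate_pif,
)
from ebwcost.uncertainty import log_rr_se


class TestLogRRDraws:
    def test_se_back_calculated_from_ci(self, endometrium_rr):
        # (ln 1.59 − ln 1.42) / (2 × 1.959964)
        assert log_rr_se(endometrium_rr) == pytest.approx(0.0288467, abs=1e-6)

    def test_zero_width_ci_gives_degenerate_draws(self):
        est = RelativeRiskEstimate("c", "F", 5.0, 1.3, 1.3, 1.3)
        rng = np.random.default_rng(0)
        assert all(draw_log_rr(est, rng).rr == 1.3 for _ in range(5))

    def test_draw_mean_matches_log_rr(self, endometrium_rr):
        rng = np.random.default_rng(1)
        n = 100_000
        draws = np.log([draw_log_rr(endometrium_rr, rng).rr for _ in range(n)])
        se = log_rr_se(endometrium_rr)
        assert abs(draws.mean() - math.log(1.50)) < 3 * se / math.sqrt(n)


class TestPrevalenceDraws:
    def test_fixed_seed_reproducible(self, baseline_table):
        config = MonteCarloConfig(seed=5)
        a = draw_prevalence(baseline_table, config, np.random.default_rng(5))
        b = draw_prevalence(baseline_table, config, np.random.default_rng(5))
        assert a.proportions == b.proportions

    def test_degenerate_proportions_are_fixed_points(self, schema):
        table = PrevalenceTable("F", schema.labels, (1.0, 0.0, 0.0, 0.0), effective_n=100)
        drawn = draw_prevalence(table, MonteCarloConfig(), np.random.default_rng(2))
        assert drawn.proportions == (1.0, 0.0, 0.0, 0.0)

    def test_large_n_concentrates_on_truth(self, schema):
        table = PrevalenceTable("F", schema.labels, (0.4, 0.3, 0.2, 0.1), effective_n=10**8)
        drawn = draw_prevalence(table, MonteCarloConfig(), np.random.default_rng(3))
        np.testing.assert_allclose(drawn.values, table.values, atol=1e-3)

    def test_multinomial_mode_partitions_exactly(self, baseline_table):
        config = MonteCarloConfig(prevalence_resampling="multinomial")
        drawn = draw_prevalence(baseline_table, config, np.random.default_rng(4))
        counts = np.array(drawn.proportions) * baseline_table.effective_n
        np.testing.assert_allclose(counts, np.round(counts), atol=1e-9)

    def test_missing_effective_n_raises(self, schema):
        table = PrevalenceTable("F", schema.labels, (0.4, 0.3, 0.2, 0.1))
        with pytest.raises(ValueError, match="effective_n"):
            draw_prevalence(table, MonteCarloConfig(), np.random.default_rng(0))


class TestSimulatePif:
    def test_zero_variance_collapses_to_deterministic(self, schema, baseline_table, paf_scenario):
        rr = RelativeRiskEstimate("endometrium", "F", 5.0, 1.50, 1.50, 1.50)
        big = PrevalenceTable(
            "F", schema.labels, baseline_table.proportions, effective_n=10**8, year=2019
        )
        est = simulate_pif(big, paf_scenario, rr, schema, MonteCarloConfig(n_iterations=500, seed=0))
        profile = categorical_profile(rescale_rr(rr, 1.0), schema)
        det = pif_subtype(big, paf_scenario.target, profile)
        for value in (est.point, est.ci_low, est.ci_high):
            assert value == pytest.approx(det, abs=2e-4)

    def test_determinism_under_fixed_seed(self, schema, baseline_table, endometrium_rr, paf_scenario):
        config = MonteCarloConfig(n_iterations=1000, seed=99)
        a = simulate_pif(baseline_table, paf_scenario, endometrium_rr, schema, config)
        b = simulate_pif(baseline_table, paf_scenario, endometrium_rr, schema, config)
        assert a == b

    def test_truncation_keeps_interval_nonnegative(self, schema, baseline_table, endometrium_rr):
        # freeze-at-baseline: every draw's PIF scatters around 0, half negative
        spec = ScenarioSpec(kind="hold_reference", label="freeze", reference=baseline_table)
        est = simulate_pif(
            baseline_table, spec, endometrium_rr, schema, MonteCarloConfig(n_iterations=2000, seed=1)
        )
        assert est.ci_low >= 0.0

    def test_truncation_off_allows_negative_draws(self, schema, baseline_table, endometrium_rr):
        spec = ScenarioSpec(kind="hold_reference", label="freeze", reference=baseline_table)
        config = MonteCarloConfig(n_iterations=2000, seed=1, truncate_negative=False)
        est, draws = simulate_pif(
            baseline_table, spec, endometrium_rr, schema, config, return_draws=True
        )
        assert (draws < 0).any()
        assert est.ci_low < 0 < est.ci_high

    def test_counterfactual_equal_baseline_is_identically_zero(
        self, schema, baseline_table, endometrium_rr
    ):
        spec = ScenarioSpec(kind="hold_reference", label="freeze")  # no reference table
        est = simulate_pif(
            baseline_table, spec, endometrium_rr, schema, MonteCarloConfig(n_iterations=200, seed=0)
        )
        assert est.point == est.ci_low == est.ci_high == 0.0

    def test_mc_error_shrinks_with_iterations(self, schema, baseline_table, endometrium_rr, paf_scenario):
        # sd of the median across seeds should scale roughly as 1/sqrt(n)
        def median_sd(n_iter):
            meds = [
                simulate_pif(
                    baseline_table, paf_scenario, endometrium_rr, schema,
                    MonteCarloConfig(n_iterations=n_iter, seed=s),
                ).point
                for s in range(12)
            ]
            return np.std(meds)

        sd_small, sd_large = median_sd(500), median_sd(8000)
        assert sd_large < sd_small

    def test_mean_shift_scenario_lowers_pif_vs_paf(self, schema, baseline_table, endometrium_rr, paf_scenario):
        shift = ScenarioSpec(kind="mean_shift", label="shift1")
        config = MonteCarloConfig(n_iterations=2000, seed=11)
        paf = simulate_pif(baseline_table, paf_scenario, endometrium_rr, schema, config)
        shifted = simulate_pif(baseline_table, shift, endometrium_rr, schema, config)
        assert 0 < shifted.point < paf.point
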