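"""Goal simulation: gaps, effect-model sampling, RRR/ARR/residual arithmetic."""

import numpy as np
import pytest

from residualrisk import (
    ACC_AHA_70,
    ESC_EAS_55,
    EXPLORATORY_40,
    EffectDistribution,
    GoalScenario,
    default_cohort_spec,
    generate_cohort,
    required_reduction,
    residual_risk_below_70,
    rrr_for_reduction,
    sample_rate_ratios,
    simulate_scenario,
)

from conftest import make_patient


@pytest.fixture(scope="module")
def small_cohort():
    return generate_cohort(default_cohort_spec(n=400, seed=31))


def deterministic_effect(rr=0.78):
    return EffectDistribution(rr_per_39=rr, ci_low=rr, ci_high=rr, seed=0)


class TestRequiredReduction:
    def test_median_patient_to_69(self):
        gap = required_reduction(93.0, ACC_AHA_70)
        assert gap.delta_ldl == pytest.approx(24.0)
        assert gap.rel_reduction == pytest.approx(24 / 93, abs=1e-9)

    def test_lower_quartile_patient_to_54(self):
        assert required_reduction(81.0, ESC_EAS_55).delta_ldl == pytest.approx(27.0)

    def test_boundary_patient(self):
        gap = required_reduction(70.0, ACC_AHA_70)
        assert gap.delta_ldl == pytest.approx(1.0)
        assert gap.rel_reduction == pytest.approx(1 / 70)

    def test_below_threshold_rejected(self):
        with pytest.raises(ValueError):
            required_reduction(69.9, ACC_AHA_70)

    def test_scenario_must_sit_below_threshold(self):
        with pytest.raises(ValueError):
            GoalScenario("bad", 75.0)


class TestEffectDistribution:
    def test_degenerate_ci_draws_point_estimate(self):
        draws = sample_rate_ratios(deterministic_effect(), n=50)
        assert np.all(draws == 0.78)

    def test_lognormal_quantile_recovery(self):
        effect = EffectDistribution(rr_per_39=0.78, ci_low=0.76, ci_high=0.80, seed=12)
        draws = sample_rate_ratios(effect, n=10**5)
        assert np.median(draws) == pytest.approx(0.78, abs=0.002)
        lo, hi = np.quantile(draws, [0.025, 0.975])
        assert lo == pytest.approx(0.76, abs=0.003)
        assert hi == pytest.approx(0.80, abs=0.003)
        assert (draws > 0).all()

    def test_same_seed_identical_draws(self):
        effect = EffectDistribution(seed=5)
        assert np.array_equal(sample_rate_ratios(effect, 100), sample_rate_ratios(effect, 100))

    def test_inconsistent_ci_rejected(self):
        with pytest.raises(ValueError):
            EffectDistribution(rr_per_39=0.78, ci_low=0.79, ci_high=0.80)


class TestRrrForReduction:
    def test_one_unit_reduction_anchors_at_22_percent(self):
        assert rrr_for_reduction(39.0, 0.78) == pytest.approx(0.22, abs=1e-12)

    def test_no_reduction_no_benefit(self):
        assert rrr_for_reduction(0.0, 0.78) == 0.0

    def test_median_gap_value(self):
        # 1 − exp((24/39)·ln 0.78) = 0.141782…, the 14% headline
        assert rrr_for_reduction(24.0, 0.78) == pytest.approx(0.1418, abs=5e-5)

    def test_monotone_in_delta(self):
        deltas = np.linspace(0, 80, 50)
        vals = rrr_for_reduction(deltas, 0.78)
        assert (np.diff(vals) > 0).all()

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            rrr_for_reduction(-1.0, 0.78)


class TestSimulateScenario:
    def test_hand_arithmetic_chain(self, flat_risk_coeffs):
        """p120 = 0.32, LDL 93, goal 54, no effect uncertainty:
        Δ = 39, RRR = 0.22, ARR = 0.0704, residual = 0.2496."""
        cohort = [make_patient(ldl_c=93.0)]
        res = simulate_scenario(
            cohort, flat_risk_coeffs, ESC_EAS_55, deterministic_effect(), n_replicates=1
        )
        row = res.iloc[0]
        assert row["delta_ldl"] == pytest.approx(39.0)
        assert row["rrr"] == pytest.approx(0.22, abs=1e-12)
        assert row["arr"] == pytest.approx(0.0704, abs=1e-12)
        assert row["residual_p120"] == pytest.approx(0.2496, abs=1e-12)

    def test_conservation_every_row(self, small_cohort, flat_risk_coeffs):
        res = simulate_scenario(
            small_cohort, flat_risk_coeffs, ACC_AHA_70,
            EffectDistribution(seed=2), n_replicates=5,
        )
        np.testing.assert_allclose(
            res["arr"] + res["residual_p120"], res["baseline_p120"], rtol=0, atol=1e-15
        )
        assert ((res["residual_p120"] >= 0) & (res["residual_p120"] <= res["baseline_p120"])).all()

    def test_scenario_dominance_per_patient(self, small_cohort, flat_risk_coeffs):
        """Same seed ⇒ same draws; deeper goals give pointwise larger RRR/ARR."""
        effect = EffectDistribution(seed=8)
        frames = {
            s.label: simulate_scenario(
                small_cohort, flat_risk_coeffs, s, effect, n_replicates=3, seed=8
            )
            for s in (ACC_AHA_70, ESC_EAS_55, EXPLORATORY_40)
        }
        assert (frames["ESC_EAS_55"]["rrr"].to_numpy() >= frames["ACC_AHA_70"]["rrr"].to_numpy()).all()
        assert (frames["EXPLORATORY_40"]["arr"].to_numpy() >= frames["ESC_EAS_55"]["arr"].to_numpy()).all()

    def test_quantile_transport_of_the_gap(self, small_cohort, flat_risk_coeffs):
        """required_reduction is monotone in LDL-C, so the median gap equals
        (median eligible LDL-C) − achieved level (sort-based oracle)."""
        res = simulate_scenario(
            small_cohort, flat_risk_coeffs, ACC_AHA_70, deterministic_effect(), n_replicates=1
        )
        eligible_ldl = sorted(r.ldl_c for r in small_cohort if r.ldl_c >= 70)
        oracle = float(np.median(eligible_ldl)) - 69.0
        assert res["delta_ldl"].median() == pytest.approx(oracle, abs=1e-9)

    def test_deterministic_limit_median_rrr(self, small_cohort, flat_risk_coeffs):
        """With log_sd = 0 the median RRR is exactly 1 − rr^(median Δ / 39)."""
        res = simulate_scenario(
            small_cohort, flat_risk_coeffs, ESC_EAS_55, deterministic_effect(), n_replicates=1
        )
        expected = rrr_for_reduction(res["delta_ldl"].median(), 0.78)
        assert res["rrr"].median() == pytest.approx(expected, abs=1e-12)

    def test_excludes_below_threshold_and_errors_when_empty(self, flat_risk_coeffs):
        cohort = [make_patient(patient_id="a", ldl_c=50.0), make_patient(patient_id="b", ldl_c=90.0)]
        res = simulate_scenario(cohort, flat_risk_coeffs, ACC_AHA_70, deterministic_effect(), n_replicates=2)
        assert set(res["patient_id"]) == {"b"}
        with pytest.raises(ValueError):
            simulate_scenario(
                [make_patient(ldl_c=50.0)], flat_risk_coeffs, ACC_AHA_70,
                deterministic_effect(), n_replicates=1,
            )

    def test_shared_draw_mode_one_draw_per_replicate(self, small_cohort, flat_risk_coeffs):
        res = simulate_scenario(
            small_cohort, flat_risk_coeffs, ACC_AHA_70,
            EffectDistribution(seed=4), n_replicates=3, shared_draws=True,
        )
        assert res.groupby("replicate")["rate_ratio"].nunique().eq(1).all()


class TestResidualRiskBelow70:
    def test_constant_risk_cohort(self, flat_risk_coeffs):
        cohort = [make_patient(patient_id=str(i), ldl_c=60.0) for i in range(4)]
        stat = residual_risk_below_70(cohort, flat_risk_coeffs)
        assert stat.median == stat.q1 == stat.q3 == pytest.approx(0.32, abs=1e-12)
        assert stat.n == 4

    def test_two_patient_median(self, age_only_coeffs):
        cohort = [
            make_patient(patient_id="a", ldl_c=60.0, age=40.0),
            make_patient(patient_id="b", ldl_c=65.0, age=80.0),
        ]
        stat = residual_risk_below_70(cohort, age_only_coeffs)
        assert stat.n == 2
        p = [1 - (0.95 ** np.exp(0.01 * a)) for a in (40.0, 80.0)]
        p120 = [1 - (1 - x) ** 6 for x in p]
        assert stat.median == pytest.approx(float(np.mean(p120)), abs=1e-12)

    def test_empty_subcohort_is_error(self, flat_risk_coeffs):
        with pytest.raises(ValueError):
            residual_risk_below_70([make_patient(ldl_c=95.0)], flat_risk_coeffs)
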