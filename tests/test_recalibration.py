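"""Recalibration strategies A-D and coefficient re-estimation."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from picniccval.model import linear_predictor, predicted_risk
from picniccval.pooling import reml_pool
from picniccval.recalibration import (
    reestimate_coefficients,
    solve_prevalence_intercept,
    strategy_a,
    strategy_b,
    strategy_c,
    strategy_d,
)
from picniccval.simulate import SyntheticConfig, generate_cohorts
from picniccval.validation import (
    c_statistic,
    calibration_slope_intercept,
    complete_cases,
    e_o_ratio,
)


@pytest.fixture(scope="module")
def miscal_cohorts(spec):
    """Five moderately sized studies under the miscalibrated generator."""
    cfg = SyntheticConfig(
        study_sizes=(120, 150, 200, 180, 250),
        target_mdi=(0.20, 0.30, 0.25, 0.18, 0.27),
        slope=0.5,
        seed=7,
    )
    return generate_cohorts(cfg, spec)


class TestStrategyA:
    def test_identical_intercepts_pool_to_that_value(self, spec):
        recal = strategy_a(spec, [-1.2, -1.2, -1.2], [0.01] * 3)
        assert recal.intercepts["global"] == pytest.approx(-1.2)

    def test_matches_reml_pool_oracle(self, spec):
        intercepts, variances = [-1.0, -1.4, -1.2], [0.01] * 3
        recal = strategy_a(spec, intercepts, variances)
        expected = reml_pool(intercepts, variances).estimate
        assert recal.intercepts["global"] == pytest.approx(expected, abs=1e-12)

    def test_single_intercept_used_directly(self, spec):
        recal = strategy_a(spec, [-1.7], [0.02])
        assert recal.intercepts["global"] == pytest.approx(-1.7)
        assert recal.notes

    def test_betas_untouched(self, spec):
        recal = strategy_a(spec, [-1.0, -1.4], [0.01, 0.01])
        pd.testing.assert_series_equal(
            recal.specs["global"].beta_vector(), spec.beta_vector()
        )


class TestStrategyB:
    def test_perfectly_calibrated_cohort_is_fixed_point(self, spec,
                                                        correct_spec_cohort):
        recal = strategy_b(spec, {"s": correct_spec_cohort})
        # at n=20000 the observed rate equals mean risk to MC error, so the
        # solved intercept sits within a tight band of the original
        assert recal.intercepts["s"] == pytest.approx(spec.intercept, abs=0.06)

    def test_eo_becomes_one_by_construction(self, spec, miscal_cohorts):
        recal = strategy_b(spec, miscal_cohorts)
        for sid, cohort in miscal_cohorts.items():
            cc = complete_cases(cohort)
            risks = predicted_risk(recal.specs[sid], cc).to_numpy()
            assert e_o_ratio(risks, cc["mdi"].to_numpy(float)) == pytest.approx(
                1.0, abs=1e-6
            )

    def test_matches_independent_bisection_oracle(self, spec):
        cfg = SyntheticConfig(study_sizes=(400,), target_mdi=(0.31,), seed=3)
        cohort = generate_cohorts(cfg, spec)["study1"]
        cc = complete_cases(cohort)
        lp0 = linear_predictor(spec, cc, include_intercept=False).to_numpy()
        rate = cc["mdi"].mean()
        # plain bisection on the monotone mean-risk function
        lo, hi = -30.0, 30.0
        for _ in range(80):
            mid = (lo + hi) / 2
            if expit(mid + lp0).mean() < rate:
                lo = mid
            else:
                hi = mid
        assert solve_prevalence_intercept(lp0, rate) == pytest.approx(
            (lo + hi) / 2, abs=1e-8
        )

    def test_shortcut_close_but_not_identical(self, spec, miscal_cohorts):
        exact = strategy_b(spec, miscal_cohorts, method="root")
        approx = strategy_b(spec, miscal_cohorts, method="shortcut")
        for sid in exact.intercepts:
            assert approx.intercepts[sid] != exact.intercepts[sid]
            assert approx.intercepts[sid] == pytest.approx(
                exact.intercepts[sid], abs=1.0
            )

    def test_degenerate_outcomes_flagged(self, spec, correct_spec_cohort):
        bad = correct_spec_cohort.head(20).copy()
        bad["mdi"] = 0
        recal = strategy_b(spec, {"bad": bad})
        assert "bad" not in recal.intercepts
        assert recal.notes

    def test_betas_untouched(self, spec, miscal_cohorts):
        recal = strategy_b(spec, miscal_cohorts)
        for s in recal.specs.values():
            pd.testing.assert_series_equal(s.beta_vector(), spec.beta_vector())


class TestStrategyC:
    def test_same_proportion_studies_all_get_pooled_mean(self, spec):
        cfg = SyntheticConfig(
            study_sizes=(300, 300, 300), target_mdi=(0.25, 0.25, 0.25),
            slope=0.5, seed=21,
        )
        cohorts = generate_cohorts(cfg, spec)
        recal = strategy_c(spec, cohorts)
        vals = list(recal.intercepts.values())
        # realised proportions differ slightly; intercepts must be close to
        # the common fitted line around one proportion
        assert np.ptp(vals) < 0.6

    def test_agrees_with_strategy_b_when_linear_relation_holds(
        self, spec, miscal_cohorts
    ):
        b = strategy_b(spec, miscal_cohorts)
        c = strategy_c(spec, miscal_cohorts)
        for sid in b.intercepts:
            assert c.intercepts[sid] == pytest.approx(b.intercepts[sid], abs=0.35)

    def test_needs_three_studies(self, spec, miscal_cohorts):
        two = dict(list(miscal_cohorts.items())[:2])
        with pytest.raises(ValueError, match="3 studies"):
            strategy_c(spec, two)

    def test_betas_untouched(self, spec, miscal_cohorts):
        recal = strategy_c(spec, miscal_cohorts)
        for s in recal.specs.values():
            pd.testing.assert_series_equal(s.beta_vector(), spec.beta_vector())


class TestStrategyD:
    def test_refit_slope_is_one_per_study(self, spec, miscal_cohorts):
        recal = strategy_d(spec, miscal_cohorts)
        for sid, cohort in miscal_cohorts.items():
            cc = complete_cases(cohort)
            lp = linear_predictor(recal.specs[sid], cc).to_numpy()
            slope, *_ = calibration_slope_intercept(lp, cc["mdi"].to_numpy(float))
            assert slope == pytest.approx(1.0, abs=1e-4)

    def test_c_statistic_unchanged_for_positive_slopes(self, spec, miscal_cohorts):
        recal = strategy_d(spec, miscal_cohorts)
        for sid, cohort in miscal_cohorts.items():
            if recal.slope_multipliers[sid] <= 0:
                continue
            cc = complete_cases(cohort)
            y = cc["mdi"].to_numpy(float)
            before = c_statistic(predicted_risk(spec, cc).to_numpy(), y)
            after = c_statistic(predicted_risk(recal.specs[sid], cc).to_numpy(), y)
            assert after == pytest.approx(before, abs=1e-12)

    def test_unit_slopes_reproduce_original_betas(self, spec, correct_spec_cohort,
                                                  monkeypatch):
        # two copies of a large well-calibrated cohort: slopes near 1
        cohorts = {"a": correct_spec_cohort.iloc[:6000],
                   "b": correct_spec_cohort.iloc[6000:12000]}
        recal = strategy_d(spec, cohorts)
        for sid in cohorts:
            assert recal.slope_multipliers[sid] == pytest.approx(1.0, abs=0.1)

    def test_shared_intercept_across_studies(self, spec, miscal_cohorts):
        recal = strategy_d(spec, miscal_cohorts)
        assert len(set(recal.intercepts.values())) == 1

    def test_negative_slope_warns(self, spec, rng):
        # build a cohort whose outcomes anti-correlate with the LP
        cfg = SyntheticConfig(study_sizes=(150, 150), target_mdi=(0.3, 0.3),
                              slope=-1.0, seed=13)
        cohorts = generate_cohorts(cfg, spec)
        with pytest.warns(UserWarning, match="negative calibration slope"):
            strategy_d(spec, cohorts)


class TestIntercpetOnlyLimits:
    def test_intercept_updates_cannot_fix_slope(self, spec, miscal_cohorts):
        """Intercept-only strategies move E/O toward 1 but leave the refit
        slope near the generator's shrinkage factor."""
        recal = strategy_b(spec, miscal_cohorts)
        slopes = []
        for sid, cohort in miscal_cohorts.items():
            cc = complete_cases(cohort)
            lp = linear_predictor(recal.specs[sid], cc).to_numpy()
            slope, *_ = calibration_slope_intercept(lp, cc["mdi"].to_numpy(float))
            slopes.append(slope)
        assert np.mean(slopes) == pytest.approx(0.5, abs=0.2)


class TestReestimate:
    def test_parameter_recovery_at_large_n(self, spec):
        cfg = SyntheticConfig(
            study_sizes=(12000,), target_mdi=None, slope=1.0, intercept_shift=0.0,
            seed=31,
        )
        cohorts = generate_cohorts(cfg, spec)
        table = reestimate_coefficients(cohorts, spec)
        well_populated = table[(table.episodes >= 150) & (table.validation_se < 5)]
        assert len(well_populated) >= 6
        z = (well_populated.validation_beta - well_populated.derivation_beta) \
            / well_populated.validation_se
        assert (z.abs() < 2.5).mean() > 0.9

    def test_separation_reported_with_huge_se(self, spec, miscal_cohorts):
        cohorts = {k: v.copy() for k, v in miscal_cohorts.items()}
        first = next(iter(cohorts))
        df = cohorts[first]
        # force a tiny all-event category
        idx = df.index[:2]
        df.loc[idx, "tumour_type"] = "Sarcoma"
        df.loc[idx, "mdi"] = 1
        for k, v in cohorts.items():
            if k != first:
                cohorts[k] = v[v.tumour_type != "Sarcoma"]
        table = reestimate_coefficients(cohorts, spec)
        row = table[table["item"] == "Sarcoma"].iloc[0]
        assert row["validation_se"] > 50
        assert "separation" in row["flag"]

    def test_episode_counts_match_direct_tally(self, spec, miscal_cohorts):
        table = reestimate_coefficients(miscal_cohorts, spec)
        stacked = pd.concat(
            [complete_cases(df) for df in miscal_cohorts.values()]
        )
        counts = stacked["tumour_type"].value_counts()
        for _, row in table.iterrows():
            if row["item"] in counts.index:
                assert row["episodes"] == counts[row["item"]]

    def test_absent_category_reported_missing(self, spec, miscal_cohorts):
        cohorts = {
            k: v[v.tumour_type != "Retinoblastoma"] for k, v in miscal_cohorts.items()
        }
        table = reestimate_coefficients(cohorts, spec)
        row = table[table["item"] == "Retinoblastoma"].iloc[0]
        assert np.isnan(row["validation_beta"])
        assert "absent" in row["flag"]
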