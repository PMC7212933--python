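"""Per-study metrics: complete cases, C-statistic, E/O, calibration,
bootstrap uncertainty, confusion counts, calibration plot bins."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from picniccval.model import linear_predictor, predicted_risk
from picniccval.validation import (
    MetricUndefinedError,
    bootstrap_se,
    c_statistic,
    calibration_in_the_large,
    calibration_plot_data,
    calibration_slope_intercept,
    complete_cases,
    confusion_at_threshold,
    e_o_ratio,
    hanley_mcneil_se,
    validate_study,
)

from .conftest import make_episode


def brute_force_c(risks, outcomes):
    """Exhaustive event x non-event pair enumeration with half credit."""
    risks = np.asarray(risks, float)
    outcomes = np.asarray(outcomes, int)
    events = risks[outcomes == 1]
    nonevents = risks[outcomes == 0]
    total = 0.0
    for e in events:
        for ne in nonevents:
            total += 1.0 if e > ne else 0.5 if e == ne else 0.0
    return total / (len(events) * len(nonevents))


def irls_logistic(X, y, tol=1e-12, maxiter=200):
    """Independent iteratively-reweighted least-squares logistic fit."""
    beta = np.zeros(X.shape[1])
    for _ in range(maxiter):
        p = expit(X @ beta)
        W = p * (1 - p)
        z = X @ beta + (y - p) / W
        XtW = X.T * W
        new = np.linalg.solve(XtW @ X, XtW @ z)
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    p = expit(X @ beta)
    cov = np.linalg.inv((X.T * (p * (1 - p))) @ X)
    return beta, np.sqrt(np.diag(cov))


class TestCompleteCases:
    def test_rows_with_missing_covariate_dropped(self, small_cohorts):
        df = pd.concat([make_episode() for _ in range(10)], ignore_index=True)
        df.loc[[2, 5], "amc"] = np.nan
        assert len(complete_cases(df)) == 8

    def test_identity_when_nothing_missing(self):
        df = pd.concat([make_episode() for _ in range(5)], ignore_index=True)
        pd.testing.assert_frame_equal(complete_cases(df), df)

    def test_all_missing_outcome_gives_empty(self):
        df = pd.concat([make_episode(mdi=np.nan) for _ in range(4)],
                       ignore_index=True)
        assert complete_cases(df).empty


class TestCStatistic:
    def test_perfect_separation(self):
        assert c_statistic([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert c_statistic([0.3] * 6, [1, 0, 1, 0, 0, 1]) == 0.5

    def test_cross_class_tie_gets_half_credit(self):
        risks = [0.9, 0.5, 0.5, 0.4, 0.2, 0.1]
        outcomes = [1, 1, 0, 0, 0, 1]
        assert c_statistic(risks, outcomes) == pytest.approx(
            brute_force_c(risks, outcomes)
        )

    def test_single_class_raises(self):
        with pytest.raises(MetricUndefinedError):
            c_statistic([0.2, 0.4], [1, 1])

    def test_complement_symmetry_on_tie_free_data(self, rng):
        risks = rng.random(30)
        outcomes = rng.integers(0, 2, 30)
        if outcomes.min() == outcomes.max():
            outcomes[0] = 1 - outcomes[0]
        assert c_statistic(risks, outcomes) + c_statistic(risks, 1 - outcomes) \
            == pytest.approx(1.0)


class TestEORatio:
    def test_balanced_gives_one(self):
        assert e_o_ratio([0.5] * 10, [1] * 5 + [0] * 5) == pytest.approx(1.0)

    def test_direct_arithmetic(self):
        assert e_o_ratio([0.6, 0.6], [1, 0]) == pytest.approx(1.2)

    def test_zero_events_undefined(self):
        with pytest.raises(MetricUndefinedError):
            e_o_ratio([0.2, 0.3], [0, 0])

    def test_ideal_value_under_correct_specification(self, rng):
        risks = rng.uniform(0.05, 0.6, 50000)
        outcomes = rng.binomial(1, risks)
        assert e_o_ratio(risks, outcomes) == pytest.approx(1.0, abs=0.02)


class TestCalibrationFit:
    def test_self_consistency_limit(self, rng):
        lp = rng.normal(-1.0, 1.2, 50000)
        y = rng.binomial(1, expit(lp))
        slope, _, intercept, _, conv = calibration_slope_intercept(lp, y)
        assert conv
        assert slope == pytest.approx(1.0, abs=0.05)
        assert intercept == pytest.approx(0.0, abs=0.07)

    def test_recovers_half_slope_generator(self, rng):
        lp = rng.normal(-1.0, 1.5, 50000)
        y = rng.binomial(1, expit(0.5 * lp))
        slope, se, *_ = calibration_slope_intercept(lp, y)
        assert slope == pytest.approx(0.5, abs=3 * se)

    def test_matches_independent_irls_oracle_on_toy_table(self):
        lp = np.array([-2.0, -1.5, -1.0, -0.5, 0.0, 0.5, 1.0, 1.5])
        y = np.array([0, 0, 1, 0, 1, 0, 1, 1], float)
        slope, slope_se, intercept, intercept_se, _ = calibration_slope_intercept(lp, y)
        X = np.column_stack([np.ones_like(lp), lp])
        beta, se = irls_logistic(X, y)
        assert intercept == pytest.approx(beta[0], abs=1e-6)
        assert slope == pytest.approx(beta[1], abs=1e-6)
        assert intercept_se == pytest.approx(se[0], rel=1e-4)
        assert slope_se == pytest.approx(se[1], rel=1e-4)

    def test_constant_lp_undefined(self):
        with pytest.raises(MetricUndefinedError):
            calibration_slope_intercept([0.3] * 8, [0, 1] * 4)

    def test_intercept_update_matches_observed_rate(self, rng):
        lp = rng.normal(-1.5, 1.0, 4000)
        y = rng.binomial(1, expit(lp + 0.7))
        a, se = calibration_in_the_large(lp, y)
        assert a == pytest.approx(0.7, abs=3.5 * se)
        # after shifting, mean predicted equals observed rate (score equation)
        assert expit(lp + a).mean() == pytest.approx(y.mean(), abs=1e-8)


class TestBootstrap:
    def test_constant_statistic_has_zero_se(self, small_cohorts):
        out = bootstrap_se(lambda df: 3.14, small_cohorts["study1"], draws=50, seed=1)
        assert out["se"] == pytest.approx(0.0, abs=1e-12)

    def test_seeded_reproducibility(self, small_cohorts):
        df = small_cohorts["study3"]
        metric = lambda d: d["mdi"].mean()
        a = bootstrap_se(metric, df, draws=200, seed=7)
        b = bootstrap_se(metric, df, draws=200, seed=7)
        assert a == b

    def test_c_statistic_se_near_hanley_mcneil(self, spec, rng):
        from picniccval.simulate import SyntheticConfig, generate_cohorts

        cfg = SyntheticConfig(study_sizes=(40,), target_mdi=(0.3,), slope=1.0,
                              seed=11)
        df = generate_cohorts(cfg, spec)["study1"]

        def metric(sample):
            r = predicted_risk(spec, sample).to_numpy()
            return c_statistic(r, sample["mdi"].to_numpy(float))

        boot = bootstrap_se(metric, df, draws=2000, seed=5)
        r = predicted_risk(spec, df).to_numpy()
        y = df["mdi"].to_numpy(float)
        analytic = hanley_mcneil_se(
            c_statistic(r, y), int(y.sum()), int(len(y) - y.sum())
        )
        assert boot["se"] == pytest.approx(analytic, rel=0.15)

    def test_se_shrinks_with_sample_size(self, spec):
        from picniccval.simulate import SyntheticConfig, generate_cohorts

        def eo_se(n, seed):
            cfg = SyntheticConfig(study_sizes=(n,), target_mdi=(0.25,), seed=seed)
            df = generate_cohorts(cfg, spec)["study1"]

            def metric(sample):
                r = predicted_risk(spec, sample).to_numpy()
                return e_o_ratio(r, sample["mdi"].to_numpy(float))

            return bootstrap_se(metric, df, draws=400, seed=1)["se"]

        assert eo_se(400, 3) < eo_se(100, 3)


class TestConfusion:
    def test_clean_split(self):
        out = confusion_at_threshold([0.05, 0.2, 0.5, 0.08], [0, 1, 1, 0])
        assert (out["TP"], out["FN"], out["TN"], out["FP"]) == (2, 0, 2, 0)
        assert out["sensitivity"] == 1.0 and out["specificity"] == 1.0

    def test_everyone_high_risk(self):
        out = confusion_at_threshold([0.3, 0.4, 0.9], [1, 0, 0])
        assert out["specificity"] == 0.0
        assert out["low_risk_fraction"] == 0.0

    def test_matches_enumeration_oracle(self, rng):
        risks = rng.random(20)
        outcomes = rng.integers(0, 2, 20)
        out = confusion_at_threshold(risks, outcomes, threshold=0.4)
        tp = sum(1 for r, y in zip(risks, outcomes) if r > 0.4 and y == 1)
        fn = sum(1 for r, y in zip(risks, outcomes) if r <= 0.4 and y == 1)
        tn = sum(1 for r, y in zip(risks, outcomes) if r <= 0.4 and y == 0)
        fp = sum(1 for r, y in zip(risks, outcomes) if r > 0.4 and y == 0)
        assert (out["TP"], out["FN"], out["TN"], out["FP"]) == (tp, fn, tn, fp)

    def test_counts_partition_events(self, small_cohorts, spec):
        df = small_cohorts["study4"]
        r = predicted_risk(spec, df).to_numpy()
        y = df["mdi"].to_numpy(float)
        out = confusion_at_threshold(r, y)
        assert out["TP"] + out["FN"] == int(y.sum())
        assert out["TN"] + out["FP"] == int(len(y) - y.sum())

    def test_boundary_risk_is_low_risk(self):
        out = confusion_at_threshold([0.10], [1], threshold=0.10)
        assert out["FN"] == 1 and out["TP"] == 0


class TestCalibrationPlot:
    def test_bin_counts_sum_to_n(self, rng):
        risks = rng.random(100)
        outcomes = rng.integers(0, 2, 100)
        plot = calibration_plot_data(risks, outcomes, bins=10)
        assert plot.bin_counts.sum() == 100
        assert np.all((plot.observed_proportion >= 0) & (plot.observed_proportion <= 1))

    def test_constant_risks_single_bin(self):
        plot = calibration_plot_data([0.2] * 30, [0, 1] * 15, bins=5)
        assert len(plot.mean_predicted) == 1
        assert plot.observed_proportion[0] == 0.5

    def test_five_bins_match_hand_oracle(self, rng):
        risks = rng.random(100)
        outcomes = rng.integers(0, 2, 100)
        plot = calibration_plot_data(risks, outcomes, bins=5)
        edges = np.quantile(risks, np.linspace(0, 1, 6))
        for b, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
            mask = (risks >= lo) & (risks < hi) if b < 4 else (risks >= lo) & (risks <= hi)
            assert plot.mean_predicted[b] == pytest.approx(risks[mask].mean())
            assert plot.observed_proportion[b] == pytest.approx(outcomes[mask].mean())

    def test_well_calibrated_points_near_diagonal(self, correct_spec_cohort, spec):
        r = predicted_risk(spec, correct_spec_cohort).to_numpy()
        y = correct_spec_cohort["mdi"].to_numpy(float)
        plot = calibration_plot_data(r, y, bins=10)
        # Monte-Carlo band: 4 binomial SDs per bin
        band = 4 * np.sqrt(plot.mean_predicted * (1 - plot.mean_predicted)
                           / plot.bin_counts)
        assert np.all(np.abs(plot.observed_proportion - plot.mean_predicted) < band)


class TestValidateStudy:
    def test_analytic_and_bootstrap_ses_agree_roughly(self, spec, small_cohorts):
        df = small_cohorts["study7"]
        boot = validate_study("s", df, spec, bootstrap_draws=400, seed=0)
        ana = validate_study("s", df, spec, se_method="analytic")
        assert boot.c_se == pytest.approx(ana.c_se, rel=0.35)
        assert boot.e_o_se == pytest.approx(ana.e_o_se, rel=0.35)

    def test_unusable_study_flagged(self, spec):
        df = make_episode(mdi=np.nan)
        perf = validate_study("empty", df, spec)
        assert not perf.usable
        assert "unusable" in perf.flags
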