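"""Curve fitting, model-family selection, slope sets and RT instability."""

import numpy as np
import pandas as pd
import pytest

from moodcue import (LearningCurveModel, across_day_slopes, fit_curve,
                     novel_rt_instability, schedule_study,
                     select_family_by_mse, simulate_rt_trials,
                     weekly_epoch_means, within_day_slopes)
from moodcue.design import StudyDesign

from conftest import quiet_params


def grid_oracle_power(x, y, b_lo=-0.3, b_hi=0.1, step=1e-3):
    """Exhaustive grid search over the exponent with the exactly profiled
    level parameter: for fixed b, the least-squares a is closed-form."""
    best = (np.inf, None, None)
    for b in np.arange(b_lo, b_hi + step / 2, step):
        xb = x ** b
        a = float(np.dot(y, xb) / np.dot(xb, xb))
        mse = float(np.mean((a * xb - y) ** 2))
        if mse < best[0]:
            best = (mse, a, b)
    return {"mse": best[0], "a": best[1], "b": best[2]}


class TestFitCurve:
    def test_noiseless_power_identifiability(self):
        x = np.arange(1, 11, dtype=float)
        y = 1300.0 * x ** -0.05
        fit = fit_curve(x, y, "power")
        assert abs(fit.b - (-0.05)) < 1e-6
        assert fit.a == pytest.approx(1300.0, abs=1e-3)
        assert fit.mse < 1e-10

    def test_constant_series_flat_fit(self):
        fit = fit_curve(np.arange(1, 8), np.full(7, 900.0), "power")
        assert abs(fit.b) < 1e-6 and fit.mse < 1e-12

    def test_grid_oracle_equivalence(self):
        """Nonlinear fits agree with the exhaustive grid oracle within one
        grid step on 20 random instances."""
        rng = np.random.default_rng(42)
        x = np.arange(1, 11, dtype=float)
        for _ in range(20):
            a_true = rng.uniform(500, 2500)
            # keep the least-squares optimum interior to the oracle's grid
            b_true = rng.uniform(-0.27, 0.07)
            y = a_true * x ** b_true * (1 + rng.normal(0, 0.03, x.size))
            fit = fit_curve(x, y, "power")
            oracle = grid_oracle_power(x, y)
            assert abs(fit.b - oracle["b"]) <= 1e-3 + 1e-9
            assert fit.mse <= oracle["mse"] + 1e-9 * oracle["mse"]

    def test_exponential_and_linear_families(self):
        x = np.arange(1, 11, dtype=float)
        fit = fit_curve(x, 800.0 * np.exp(-0.07 * x), "exponential")
        assert fit.b == pytest.approx(-0.07, abs=1e-6)
        fit = fit_curve(x, 1000.0 - 12.0 * x, "linear")
        assert fit.b == pytest.approx(-12.0, abs=1e-9)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_curve([1, 2], [3, 4], "power")       # too few points
        with pytest.raises(ValueError):
            fit_curve([0, 1, 2], [3, 4, 5], "power")  # non-positive abscissa
        with pytest.raises(ValueError):
            fit_curve([1, 2, 3], [1, 2, 3], "cubic")

    def test_sklearn_estimator_protocol(self):
        x = np.arange(1, 11, dtype=float)
        y = 1200.0 * x ** -0.1
        model = LearningCurveModel(family="power").fit(x, y)
        assert model.get_params()["family"] == "power"
        assert np.allclose(model.predict(x), y, rtol=1e-6)
        assert model.n_points_ == 10 and model.converged_


class TestFamilySelection:
    def test_power_generated_data_selects_power(self):
        """Power-law data: power wins MSE in >= 95% of 200 series at the
        noise level of condition-mean curves (family comparison is run on
        mean curves, where weekly means pool many trials), and is still the
        modal choice at single-participant noise."""
        x = np.arange(1, 11, dtype=float)
        for sigma, threshold in ((0.01, 0.95), (0.035, 0.5)):
            rng = np.random.default_rng(3)
            wins = 0
            for _ in range(200):
                y = 1362.0 * x ** rng.uniform(-0.15, -0.02) \
                    * (1 + rng.normal(0, sigma, x.size))
                fits = [fit_curve(x, y, fam)
                        for fam in ("power", "exponential", "linear")]
                wins += select_family_by_mse(fits) == "power"
            assert wins >= threshold * 200

    def test_exactly_linear_selects_linear(self):
        x = np.arange(1, 11, dtype=float)
        y = 1000.0 - 12.0 * x
        fits = [fit_curve(x, y, fam)
                for fam in ("power", "exponential", "linear")]
        assert fits[2].mse < 1e-18
        assert select_family_by_mse(fits) == "linear"

    def test_constant_tie_prefers_power(self):
        x = np.arange(1, 11, dtype=float)
        y = np.full(10, 950.0)
        fits = [fit_curve(x, y, fam)
                for fam in ("power", "exponential", "linear")]
        assert select_family_by_mse(fits) == "power"


@pytest.fixture(scope="module")
def noiseless_trials(design):
    sched = schedule_study(design, seed=9)
    params = quiet_params(b_prac=-0.027, b_daily=-0.047, b_alt=-0.033,
                          b_within=-0.054, b_novel_within=0.0)
    trials, _ = simulate_rt_trials(params, sched, seed=0)
    trials["participant_id"] = "p1"
    return trials


class TestEpochsAndSlopes:
    def test_noiseless_weekly_means_follow_power_law(self, noiseless_trials):
        weekly = weekly_epoch_means(noiseless_trials)
        daily = weekly[weekly.condition == "daily"].sort_values("week")
        assert np.allclose(daily.mean_rt, 1362.0 * daily.week ** -0.047)

    def test_missing_week_gives_nine_epochs(self, design):
        sched = schedule_study(design, seed=9)
        params = quiet_params()
        trials, _ = simulate_rt_trials(
            params, sched, seed=0,
            attended_sessions=[s for s in range(1, 51) if not 6 <= s <= 10])
        trials["participant_id"] = "p1"
        weekly = weekly_epoch_means(trials)
        assert weekly[weekly.condition == "daily"].week.nunique() == 9

    def test_axis_consistency_noiseless_recovery(self, noiseless_trials):
        """Configured exponents recovered to 6 decimals on noiseless data."""
        weekly = weekly_epoch_means(noiseless_trials)
        slopes = across_day_slopes(weekly)
        assert slopes.b_daily.item() == pytest.approx(-0.047, abs=1e-6)
        assert slopes.b_alternate.item() == pytest.approx(-0.033, abs=1e-6)
        assert slopes.b_novel.item() == pytest.approx(-0.027, abs=1e-6)
        assert slopes.normalized_daily.item() == pytest.approx(-0.02, abs=1e-6)
        within = within_day_slopes(noiseless_trials)
        assert within.b_within.item() == pytest.approx(-0.054, abs=1e-6)
        assert within.normalized_within.item() == pytest.approx(-0.054, abs=1e-6)

    def test_null_effect_zero_normalized_slopes(self, design):
        sched = schedule_study(design, seed=4)
        params = quiet_params(b_prac=-0.03, b_daily=-0.03, b_alt=-0.03)
        trials, _ = simulate_rt_trials(params, sched, seed=0)
        trials["participant_id"] = "p1"
        slopes = across_day_slopes(weekly_epoch_means(trials))
        assert slopes.normalized_daily.item() == pytest.approx(0.0, abs=1e-9)
        assert slopes.normalized_alternate.item() == pytest.approx(0.0, abs=1e-9)

    def test_practice_factor_invariance(self, design):
        """A shared multiplicative week-axis practice factor leaves the
        normalized across-day slopes unchanged."""
        sched = schedule_study(design, seed=4)
        base = dict(b_daily=-0.02, b_alt=-0.01)
        out = {}
        for tag, prac in (("without", 0.0), ("with", -0.03)):
            params = quiet_params(b_prac=prac,
                                  b_daily=base["b_daily"] + prac,
                                  b_alt=base["b_alt"] + prac)
            trials, _ = simulate_rt_trials(params, sched, seed=0)
            trials["participant_id"] = "p1"
            out[tag] = across_day_slopes(weekly_epoch_means(trials))
        assert out["with"].normalized_daily.item() == pytest.approx(
            out["without"].normalized_daily.item(), abs=1e-7)

    def test_weekly_practice_invariance_within_day(self, design):
        sched = schedule_study(design, seed=4)
        out = {}
        for tag, prac in (("without", 0.0), ("with", -0.03)):
            params = quiet_params(b_prac=prac, b_within=-0.05)
            trials, _ = simulate_rt_trials(params, sched, seed=0)
            trials["participant_id"] = "p1"
            out[tag] = within_day_slopes(trials)
        assert out["with"].normalized_within.item() == pytest.approx(
            out["without"].normalized_within.item(), abs=1e-4)

    def test_rescaling_invariance(self, small_cohort):
        from moodcue import clean_pipeline
        rt = clean_pipeline(small_cohort.trials, small_cohort.mood).rt_trials
        weekly = weekly_epoch_means(rt)
        base = across_day_slopes(weekly)
        scaled_rt = rt.copy()
        scaled_rt["rt_ms"] *= 3.7
        scaled = across_day_slopes(weekly_epoch_means(scaled_rt))
        pd.testing.assert_series_equal(base.normalized_daily,
                                       scaled.normalized_daily,
                                       atol=1e-7, check_exact=False)


class TestNovelRtInstability:
    def test_noiseless_zero(self, noiseless_trials):
        # novel RT varies only between weeks; within week 1 it is constant,
        # so restrict to a flat simulation
        flat = noiseless_trials.copy()
        flat["rt_ms"] = 1000.0
        out = novel_rt_instability(flat)
        assert out.rt_trmssd.item() == 0.0

    def test_planted_noisy_participant_flagged(self, design):
        sched = schedule_study(design, seed=6).to_frame()
        frames = []
        rng = np.random.default_rng(17)
        for p in range(12):
            sigma = 2.5 if p == 0 else 0.25
            params = quiet_params(rt_noise_sigma=sigma)
            t, _ = simulate_rt_trials(params, sched, rng=rng)
            t["participant_id"] = f"p{p:02d}"
            frames.append(t)
        out = novel_rt_instability(pd.concat(frames, ignore_index=True))
        assert out.loc[out.participant_id == "p00", "is_extreme_outlier"].item()
        assert out.is_extreme_outlier.sum() == 1

    def test_equal_noise_groups_rarely_differ(self, design):
        """Null calibration: the group test on RT instability is
        non-significant in >= 90% of simulated cohorts."""
        from moodcue import two_sample_t
        sched = schedule_study(design, seed=6).to_frame()
        # restrict to novel trials to keep the null simulation fast
        sched = sched[sched.condition == "novel"].reset_index(drop=True)
        rng = np.random.default_rng(23)
        params = quiet_params(rt_noise_sigma=0.25, compliance=0.9)
        rejections = 0
        n_cohorts = 60
        for _ in range(n_cohorts):
            frames = []
            for p in range(16):
                t, _ = simulate_rt_trials(params, sched, rng=rng)
                t["participant_id"] = f"p{p:02d}"
                frames.append(t)
            out = novel_rt_instability(pd.concat(frames, ignore_index=True))
            out["group"] = ["a"] * 8 + ["b"] * 8
            keep = out[~out.is_extreme_outlier]
            res = two_sample_t(keep.rt_trmssd, keep.group)
            rejections += res.p < 0.05
        assert rejections <= 0.10 * n_cohorts
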