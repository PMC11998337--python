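"""Logistic growth-curve fitting and growth-parameter screening."""

import numpy as np
import pandas as pd
import pytest

from phenoscreen import (DegenerateGeometryError, ScreeningConfig, fit_lgc,
                         fit_population, generate_growth_series,
                         generate_population, lgc_predict, screen_growth_params)
from phenoscreen.growth_model import IneligibleSeriesError, InsufficientDataError

H, X1, X2 = 100.0, 50.0, 0.4
DAYS = np.arange(0, 30, 2, dtype=float)


def _series(h=H, x1=X1, x2=X2, days=DAYS, pid="P1"):
    area = h / (1 + x1 * np.exp(-x2 * days))
    return pd.DataFrame({"plant_id": pid, "day": days, "leaf_area": area})


class TestFitLGC:
    def test_noiseless_parameters_recovered_exactly(self):
        fit = fit_lgc(_series())
        assert fit.converged
        assert fit.h == pytest.approx(H, rel=1e-6)
        assert fit.x1 == pytest.approx(X1, rel=1e-6)
        assert fit.x2 == pytest.approx(X2, rel=1e-6)
        assert abs(fit.k) < 1e-6 and abs(fit.s) < 1e-6

    def test_anchor_times_are_median_and_last_day(self):
        fit = fit_lgc(_series())
        assert fit.p1 == np.median(DAYS)
        assert fit.p2 == DAYS[-1]

    def test_too_few_points_rejected(self):
        with pytest.raises(IneligibleSeriesError, match="< 4"):
            fit_lgc(_series(days=np.array([0.0, 2.0, 4.0])))

    def test_all_zero_series_rejected(self):
        df = pd.DataFrame({"plant_id": "P1", "day": DAYS,
                           "leaf_area": np.zeros_like(DAYS)})
        with pytest.raises(IneligibleSeriesError, match="all-zero"):
            fit_lgc(df)

    def test_constant_series_flagged_degenerate_not_raised(self):
        df = pd.DataFrame({"plant_id": "P1", "day": DAYS,
                           "leaf_area": np.full_like(DAYS, 40.0)})
        fit = fit_lgc(df)
        assert not fit.converged
        assert fit.degenerate

    def test_noisy_recovery_median_error_under_five_percent(self):
        cfg = ScreeningConfig(n_plants=30, n_mutant_plants=0, n_mutant_lines=0,
                              noise_cv=0.02, days=tuple(range(0, 30, 2)), seed=21)
        _, truth = generate_population(cfg)
        series, params = generate_growth_series(cfg, truth)
        fits = fit_population(series, seed=21).set_index("plant_id")
        p = params.set_index("plant_id")
        rel_h = np.abs(fits["h"] - p["h"]) / p["h"]
        rel_x2 = np.abs(fits["x2"] - p["x2"]) / p["x2"]
        assert fits["converged"].all()
        assert rel_h.median() < 0.05
        assert rel_x2.median() < 0.05

    def test_recovery_degrades_with_noise(self):
        medians = []
        for cv in (0.0, 0.05, 0.15):
            cfg = ScreeningConfig(n_plants=20, n_mutant_plants=0,
                                  n_mutant_lines=0, noise_cv=cv, seed=23)
            _, truth = generate_population(cfg)
            series, params = generate_growth_series(cfg, truth)
            fits = fit_population(series, seed=23).set_index("plant_id")
            p = params.set_index("plant_id")
            medians.append(float((np.abs(fits["h"] - p["h"]) / p["h"]).median()))
        assert medians[0] <= medians[1] <= medians[2]

    def test_time_shift_covariance(self):
        # same observations relabeled to days t + delta: h and x2 must not
        # move, while x1 absorbs the shift as x1 * exp(x2 * delta)
        delta = 4.0
        base = fit_lgc(_series())
        relabeled = _series()
        relabeled["day"] = DAYS + delta
        shifted = fit_lgc(relabeled)
        assert shifted.h == pytest.approx(base.h, rel=1e-5)
        assert shifted.x2 == pytest.approx(base.x2, rel=1e-5)
        assert shifted.x1 == pytest.approx(base.x1 * np.exp(base.x2 * delta),
                                           rel=1e-4)

    def test_two_window_variant_reports_early_asymptote(self):
        fit = fit_lgc(_series(), two_window=True)
        assert fit.h_window is not None
        assert fit.h_window > 0


class TestPredict:
    def test_inflection_identity(self):
        fit = fit_lgc(_series())
        assert lgc_predict(fit, np.log(fit.x1) / fit.x2) == pytest.approx(
            fit.h / 2, rel=1e-9)

    def test_asymptote(self):
        fit = fit_lgc(_series())
        t_far = 40.0 / fit.x2
        assert lgc_predict(fit, t_far) == pytest.approx(fit.h, rel=1e-12)

    def test_direct_evaluation_at_zero(self):
        fit = fit_lgc(_series())
        assert lgc_predict(fit, 0.0) == pytest.approx(100.0 / 51.0, rel=1e-5)

    def test_monotone_increasing(self):
        fit = fit_lgc(_series())
        t = np.linspace(0, 40, 200)
        assert np.all(np.diff(lgc_predict(fit, t)) > 0)

    def test_unconverged_fit_rejected(self):
        df = pd.DataFrame({"plant_id": "P1", "day": DAYS,
                           "leaf_area": np.full_like(DAYS, 5.0)})
        fit = fit_lgc(df)
        with pytest.raises(ValueError, match="converge"):
            lgc_predict(fit, 10.0)


@pytest.fixture(scope="module")
def fits_with_outlier():
    """30 near-WT plants plus one with a doubled asymptote, with mild
    multiplicative noise so every screened parameter has real spread."""
    rng = np.random.default_rng(31)
    frames = []
    for i in range(30):
        h = 100 * (2.0 if i == 0 else rng.uniform(0.95, 1.05))
        x1 = 50 * rng.uniform(0.9, 1.1)
        x2 = 0.4 * rng.uniform(0.95, 1.05)
        s = _series(h=h, x1=x1, x2=x2, pid=f"P{i:03d}")
        s["leaf_area"] *= 1 + 0.01 * rng.standard_normal(len(s))
        frames.append(s)
    return fit_population(pd.concat(frames), seed=31)


class TestScreenGrowthParams:
    def test_doubled_h_plant_flagged(self, fits_with_outlier):
        calls = screen_growth_params(fits_with_outlier, [0.95])[0.95]
        assert "P000" in calls.flagged

    def test_flag_nesting_inherited(self, fits_with_outlier):
        calls = screen_growth_params(fits_with_outlier, [0.9, 0.99])
        assert calls[0.99].flagged <= calls[0.9].flagged

    def test_identical_plants_raise_degenerate_geometry(self):
        frames = [_series(pid=f"P{i}") for i in range(12)]
        fits = fit_population(pd.concat(frames), seed=0)
        with pytest.raises(DegenerateGeometryError):
            screen_growth_params(fits, [0.95])

    def test_too_few_converged_fits_rejected(self):
        frames = [_series(h=100 + i, pid=f"P{i}") for i in range(5)]
        fits = fit_population(pd.concat(frames), seed=0)
        with pytest.raises(InsufficientDataError):
            screen_growth_params(fits, [0.95])

    def test_fit_failures_reported_not_merged(self, fits_with_outlier):
        flat = pd.DataFrame({"plant_id": "BAD", "day": DAYS,
                             "leaf_area": np.full_like(DAYS, 7.0)})
        fits = pd.concat([fits_with_outlier,
                          fit_population(flat, seed=0)], ignore_index=True)
        calls = screen_growth_params(fits, [0.95])[0.95]
        assert "BAD" in calls.fit_failures
        assert "BAD" not in calls.flagged

    def test_short_series_skipped_by_population_fitter(self):
        short = pd.DataFrame({"plant_id": "S1", "day": [0, 2, 4],
                              "leaf_area": [1.0, 2.0, 3.0]})
        fits = fit_population(pd.concat([_series(), short]), seed=0)
        row = fits.set_index("plant_id").loc["S1"]
        assert row["ineligible"] and not row["converged"]
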