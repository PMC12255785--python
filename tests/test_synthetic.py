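import dataclasses
import datetime as dt

import numpy as np
import pytest

from betadrift.distributions import BinGrid, daily_distributions
from betadrift.eda import fit_powerlaw_split, power_spectrum, threshold_fractions
from betadrift.forecaster import make_forecast_dataset
from betadrift.io_core import slice_by_epoch, split_into_days
from betadrift.synthetic import (SyntheticPatientConfig, generate_colored_noise,
                                 generate_synthetic_patient,
                                 generate_toy_settings)
from betadrift import profiles


class TestColoredNoise:
    def test_seed_reproducible(self):
        a = generate_colored_noise(1.0, 256, seed=5)
        b = generate_colored_noise(1.0, 256, seed=5)
        assert np.array_equal(a, b)

    def test_unit_variance(self):
        x = generate_colored_noise(1.5, 4096, seed=0)
        assert x.std() == pytest.approx(1.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            generate_colored_noise(1.0, 32, seed=0)

    def test_alpha_out_of_range(self):
        with pytest.raises(ValueError):
            generate_colored_noise(3.5, 256, seed=0)


class TestGeneratorStructure:
    def test_identical_config_bit_identical_output(self):
        cfg = SyntheticPatientConfig(n_days=4, seed=9)
        s1, e1, t1 = generate_synthetic_patient(cfg)
        s2, e2, t2 = generate_synthetic_patient(cfg)
        assert np.array_equal(s1.power, s2.power)
        assert e1 == e2
        assert np.array_equal(t1.drift, t2.drift)

    def test_day_count_and_minute_resolution(self):
        cfg = SyntheticPatientConfig(n_days=3, seed=0)
        series, _, truth = generate_synthetic_patient(cfg)
        assert len(series) == 3 * 1440
        assert len(truth.day_mu) == 3
        steps = np.diff(series.timestamps.astype("int64"))
        assert (steps == 60).all()

    def test_epoch_lengths_respected(self):
        cfg = SyntheticPatientConfig(n_days=10, epochs=(4, 6), seed=0)
        series, eps, truth = generate_synthetic_patient(cfg)
        assert [ep.n_days for ep in eps] == [4, 6]
        assert truth.epoch_day_ranges == ((0, 4), (4, 10))
        # slicing by each epoch partitions the series
        assert sum(len(slice_by_epoch(series, ep)) for ep in eps) == len(series)

    def test_bad_epoch_lengths_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            SyntheticPatientConfig(n_days=10, epochs=(4, 4), seed=0)

    def test_thresholds_at_day0_percentiles(self):
        cfg = SyntheticPatientConfig(n_days=5, seed=3)
        series, (ep,), _ = generate_synthetic_patient(cfg)
        day0 = series.power[:1440]
        assert ep.beta_min == pytest.approx(np.percentile(day0, 10))
        assert ep.beta_max == pytest.approx(np.percentile(day0, 90))

    def test_power_window_contains_all_samples(self):
        cfg = SyntheticPatientConfig(n_days=5, seed=4)
        series, _, truth = generate_synthetic_patient(cfg)
        lo, hi = truth.p_window
        assert lo < series.power.min() and series.power.max() < hi


class TestDriftRegimes:
    def test_no_drift_zero_noise_constant_days(self):
        cfg = SyntheticPatientConfig(n_days=4, drift_kind="none",
                                     baseline_sigma=0.0, seed=0)
        series, _, truth = generate_synthetic_patient(cfg)
        grid = BinGrid.from_window(*truth.p_window, n_bins=30)
        dists = daily_distributions(series, grid)
        # every daily distribution identical -> zero-order error is 0
        from betadrift.baselines import zero_order_predict
        from betadrift.evaluation import wmape
        for a, b in zip(dists, dists[1:]):
            assert wmape(a.normalized, zero_order_predict([b.normalized])) == 0.0

    def test_linear_drift_is_nearly_per_bin_linear(self):
        """On the frozen linear-drift profile the two-day closed-form map
        predicts the next day to a few percent."""
        from betadrift.baselines import fit_linear_per_bin, linear_predict
        from betadrift.evaluation import wmape
        series, _, truth = generate_synthetic_patient(profiles.LINEAR_PATIENT)
        grid = BinGrid.from_window(*truth.p_window,
                                   n_bins=profiles.DESK_N_BINS)
        dists = daily_distributions(series, grid)
        errs = []
        for a, b, c in zip(dists, dists[1:], dists[2:]):
            coeffs = fit_linear_per_bin([a.normalized, b.normalized])
            errs.append(wmape(c.normalized,
                              linear_predict(coeffs, b.normalized, 1)))
        assert np.mean(errs) < 0.05

    def test_nonlinear_regime_shifts_fractions_past_tolerance(
            self, nonlinear_patient):
        """The drifting profile is an alarm-triggering fixture: threshold
        fractions leave the 10-point band on many days."""
        series, (ep,), _ = nonlinear_patient
        days = list(split_into_days(series).values())
        fracs = [threshold_fractions(d, ep.beta_min, ep.beta_max)
                 for d in days]
        ref = fracs[0]
        exceed = [f for f in fracs
                  if f[0] - ref[0] > 0.10 or f[2] - ref[2] > 0.10]
        assert len(exceed) >= 5

    def test_smoothed_random_walk_runs(self):
        cfg = SyntheticPatientConfig(n_days=6, drift_kind="smoothed_random_walk",
                                     seed=2)
        _, _, truth = generate_synthetic_patient(cfg)
        assert np.isfinite(truth.drift).all()

    def test_short_correlated_noise_gives_steeper_short_term_exponent(self):
        """With a sub-day noise correlation time the spectrum is steep
        within a day and flat beyond it, so the split fit shows
        alpha_short > alpha_long — the short-term-correlated /
        long-term-uncorrelated pattern the generator can emulate."""
        cfg = SyntheticPatientConfig(n_days=30, drift_kind="none",
                                     noise_corr_minutes=120.0,
                                     baseline_sigma=0.3,
                                     circadian_amplitude=0.0,
                                     medication_amplitude=0.0, seed=6)
        series, _, _ = generate_synthetic_patient(cfg)
        logp = np.log(series.power)
        fit = fit_powerlaw_split(power_spectrum(logp - logp.mean()))
        assert fit.alpha_short > 1.0 > fit.alpha_long
        assert fit.alpha_long == pytest.approx(0.0, abs=0.5)


class TestToySettings:
    def test_ordered_disjoint(self):
        eps = generate_toy_settings(3, days_per_epoch=7)
        for a, b in zip(eps, eps[1:]):
            assert a.end_date < b.start_date

    def test_single_epoch_rejected_by_multi_setting_training(self):
        from betadrift.forecaster import (ForecasterConfig,
                                          train_multi_setting)
        cfg = SyntheticPatientConfig(n_days=8, seed=0)
        series, _, truth = generate_synthetic_patient(cfg)
        grid = BinGrid.from_window(*truth.p_window, n_bins=8)
        ds = make_forecast_dataset({"e": daily_distributions(series, grid)},
                                   2, 1)
        fcfg = ForecasterConfig(n_bins=8, n_history=2, horizon=1,
                                feedforward_width=16, epochs=2)
        with pytest.raises(ValueError, match=">= 2"):
            train_multi_setting({"e": ds}, "e", fcfg, seed=0)

    def test_n_epochs_positive(self):
        with pytest.raises(ValueError):
            generate_toy_settings(0)
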