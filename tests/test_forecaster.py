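import datetime as dt
import itertools

import numpy as np
import pytest

from betadrift.distributions import BinGrid, DailyDistribution
from betadrift.forecaster import (DistributionTransformer, ForecastDataset,
                                  ForecasterConfig, TrainedForecaster,
                                  make_forecast_dataset, predict_k_ahead,
                                  select_optimal_history, split_train_val,
                                  train_multi_setting, train_single_setting,
                                  wmape_loss)

GRID = BinGrid.from_window(0.0, 1.0, n_bins=8)


def make_days(dates, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for d in dates:
        counts = rng.integers(0, 50, GRID.n_bins)
        counts[rng.integers(GRID.n_bins)] += 50  # guarantee non-constant
        out.append(DailyDistribution(d, counts, GRID))
    return out


def date_range(start, n):
    d0 = dt.date.fromisoformat(start)
    return [d0 + dt.timedelta(days=i) for i in range(n)]


def brute_force_windows(dates, n, k):
    """Enumerate all (input-days, label-day) windows by exhaustive scan.

    A window covers n + k consecutive calendar days (inputs, the skipped
    horizon days, and the label) and every one of them must be recorded —
    windows may not span calendar gaps.
    """
    ds = set(dates)
    wins = []
    for d in dates:
        span = [d + dt.timedelta(days=i) for i in range(n + k)]
        if all(x in ds for x in span):
            wins.append((tuple(span[:n]), span[-1]))
    return wins


class TestDatasetConstruction:
    def test_count_closed_form(self):
        days = make_days(date_range("2024-01-01", 10))
        ds = make_forecast_dataset({"e": days}, 2, 1)
        assert len(ds) == 10 - 2 - 1 + 1 == 8

    def test_two_epochs_no_boundary_crossing(self):
        a = make_days(date_range("2024-01-01", 5), seed=1)
        b = make_days(date_range("2024-02-01", 5), seed=2)
        ds = make_forecast_dataset({"a": a, "b": b}, 2, 1)
        assert len(ds) == 3 + 3
        assert all(ex.epoch_id in ("a", "b") for ex in ds.examples)

    def test_calendar_gap_splits_run(self):
        dates = date_range("2024-01-01", 5) + date_range("2024-01-07", 5)
        ds = make_forecast_dataset({"e": make_days(dates)}, 2, 1)
        assert len(ds) == 3 + 3

    @pytest.mark.parametrize("n,k", list(itertools.product([1, 2, 3],
                                                           [1, 2, 3])))
    def test_agrees_with_bruteforce_enumerator(self, n, k):
        dates = (date_range("2024-01-01", 7) + date_range("2024-01-10", 4)
                 + date_range("2024-01-20", 2))
        days = make_days(dates, seed=3)
        try:
            ds = make_forecast_dataset({"e": days}, n, k)
            got = {(tuple(ex.input_dates), ex.label_date)
                   for ex in ds.examples}
        except ValueError:
            got = set()
        assert got == set(brute_force_windows(dates, n, k))

    def test_label_exactly_k_days_after_input(self):
        days = make_days(date_range("2024-01-01", 9))
        ds = make_forecast_dataset({"e": days}, 2, 3)
        for ex in ds.examples:
            assert (ex.label_date - ex.input_dates[-1]).days == 3

    def test_no_valid_windows_reports_counts(self):
        days = make_days(date_range("2024-01-01", 2))
        with pytest.raises(ValueError, match="2 usable day"):
            make_forecast_dataset({"e": days}, 2, 1)

    def test_horizon_bounds(self):
        days = make_days(date_range("2024-01-01", 20))
        with pytest.raises(ValueError, match="1, 6"):
            make_forecast_dataset({"e": days}, 2, 7)


class TestSplit:
    def _dataset(self, n):
        days = make_days(date_range("2024-01-01", n + 2))
        return make_forecast_dataset({"e": days}, 2, 1)

    def test_85_15_floor_arithmetic(self):
        ds = self._dataset(20)
        train, val = split_train_val(ds, 0.85, seed=0)
        assert (len(train), len(val)) == (17, 3)

    def test_half_split_of_two(self):
        ds = ForecastDataset(self._dataset(20).examples[:2], 2, 1)
        train, val = split_train_val(ds, 0.5, seed=0)
        assert (len(train), len(val)) == (1, 1)

    def test_validation_is_chronological_tail(self):
        ds = self._dataset(20)
        train, val = split_train_val(ds, 0.85, seed=4)
        latest_train = max(ex.label_date for ex in train.examples)
        assert all(ex.label_date > latest_train for ex in val.examples)

    def test_same_seed_same_shuffle(self):
        ds = self._dataset(20)
        t1, _ = split_train_val(ds, 0.85, seed=9)
        t2, _ = split_train_val(ds, 0.85, seed=9)
        assert [e.label_date for e in t1.examples] == \
               [e.label_date for e in t2.examples]

    def test_no_overlap(self):
        ds = self._dataset(20)
        train, val = split_train_val(ds, 0.85, seed=1)
        ids = {id(e) for e in ds.examples}
        assert len(set(e.label_date for e in train.examples)
                   & set(e.label_date for e in val.examples)) == 0


class TestWmapeLoss:
    def test_perfect_prediction(self):
        y = np.array([0.2, 0.8, 0.0])
        assert wmape_loss(y, y) == 0.0

    def test_zero_prediction_gives_one(self):
        y = np.array([0.2, 0.8, 0.5])
        assert wmape_loss(y, np.zeros(3)) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        y = np.array([0.0, 0.5, 1.0])
        p = np.array([0.1, 0.5, 0.7])
        assert wmape_loss(y, p) == pytest.approx(0.4 / 1.5)

    def test_all_zero_target_rejected(self):
        with pytest.raises(ValueError):
            wmape_loss(np.zeros(3), np.ones(3))


CFG = ForecasterConfig(n_bins=8, n_history=2, horizon=1, attention_heads=2,
                       feedforward_width=16, epochs=40, eval_every=20)


class TestForward:
    def test_output_in_unit_interval(self):
        model = DistributionTransformer(CFG, seed=0)
        out = model.predict(np.random.default_rng(0).random((2, 8)))
        assert out.shape == (8,)
        assert (out > 0).all() and (out < 1).all()

    def test_inference_deterministic(self):
        model = DistributionTransformer(CFG, seed=0)
        x = np.random.default_rng(1).random((2, 8))
        assert np.array_equal(model.predict(x), model.predict(x))

    def test_positional_encoding_breaks_permutation_symmetry(self):
        model = DistributionTransformer(CFG, seed=0)
        x = np.random.default_rng(2).random((2, 8))
        assert not np.allclose(model.predict(x), model.predict(x[::-1]))

    def test_shape_mismatch_names_expectation(self):
        model = DistributionTransformer(CFG, seed=0)
        with pytest.raises(ValueError, match=r"\(2, 8\)"):
            model.predict(np.zeros((3, 8)))


def tiny_dataset(n_days=12, seed=5):
    days = make_days(date_range("2024-01-01", n_days), seed=seed)
    return make_forecast_dataset({"e": days}, 2, 1)


class TestTraining:
    def test_same_seed_identical_weights_and_history(self):
        ds = tiny_dataset()
        r1 = train_single_setting(ds, CFG, seed=3)
        r2 = train_single_setting(ds, CFG, seed=3)
        for p1, p2 in zip(r1.model.parameters(), r2.model.parameters()):
            assert np.array_equal(p1.data, p2.data)
        assert r1.history == r2.history

    def test_loss_curve_finite_and_decreasing(self):
        ds = tiny_dataset()
        trained = train_single_setting(ds, CFG, seed=0)
        losses = [v[0] for _, v in sorted(trained.history.items())]
        assert all(np.isfinite(losses))
        assert losses[-1] < losses[0]

    def test_config_dataset_mismatch(self):
        ds = tiny_dataset()
        bad = ForecasterConfig(n_bins=8, n_history=3, horizon=1,
                               feedforward_width=16, epochs=5)
        with pytest.raises(ValueError, match="match"):
            train_single_setting(ds, bad, seed=0)

    def test_checkpoint_roundtrip(self, tmp_path):
        ds = tiny_dataset()
        trained = train_single_setting(ds, CFG, seed=1)
        trained.save(tmp_path / "ck.npz")
        back = TrainedForecaster.load(tmp_path / "ck.npz")
        x = ds.examples[0].input
        np.testing.assert_allclose(back.predict(x), trained.predict(x))


class TestMultiSetting:
    def test_requires_two_epochs(self):
        ds = tiny_dataset()
        with pytest.raises(ValueError, match=">= 2 epochs"):
            train_multi_setting({"only": ds}, "only", CFG, seed=0)

    def test_phase2_half_split(self):
        a = tiny_dataset(14, seed=1)   # 11 examples
        b = tiny_dataset(13, seed=2)   # 10 examples held out -> 5 / 5
        cfg = ForecasterConfig(n_bins=8, n_history=2, horizon=1,
                               feedforward_width=16, epochs=5,
                               finetune_epochs=5, eval_every=5)
        trained = train_multi_setting({"a": a, "b": b}, "b", cfg, seed=0)
        assert len(trained.history["phase2"]) == 5
        assert np.isfinite(trained.validation_wmape)


class TestPredictKAhead:
    def test_horizon_must_match_trained_model(self):
        ds = tiny_dataset()
        trained = train_single_setting(ds, CFG, seed=0)
        with pytest.raises(ValueError, match="K=1"):
            predict_k_ahead(trained, ds.examples[0].input, 2)

    def test_horizon_range_enforced(self):
        ds = tiny_dataset()
        trained = train_single_setting(ds, CFG, seed=0)
        with pytest.raises(ValueError, match=r"\[1, 6\]"):
            predict_k_ahead(trained, ds.examples[0].input, 7)

    def test_output_length_is_n_bins(self):
        ds = tiny_dataset()
        trained = train_single_setting(ds, CFG, seed=0)
        out = predict_k_ahead(trained, ds.examples[0].input, 1)
        assert out.shape == (8,)


class TestOptimalHistory:
    def test_smallest_within_one_sd_of_best(self):
        wmapes = {1: [0.50, 0.52], 2: [0.40, 0.42], 3: [0.39, 0.41]}
        # best is N=3 (mean 0.40), but N=2 (mean 0.41) is within one sd
        assert select_optimal_history(wmapes) == 2

    def test_clear_winner(self):
        wmapes = {1: [0.9, 0.9], 2: [0.2, 0.2], 3: [0.5, 0.5]}
        assert select_optimal_history(wmapes) == 2
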