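"""Metrics, threshold alarms and benchmark tables.

The primary similarity metric is the weighted mean absolute percentage
error (wMAPE) between observed and predicted distribution vectors,

    wMAPE(y, yhat) = sum_i |y_i - yhat_i| / sum_i |y_i|,

whose actual-magnitude weighting leaves genuinely zero bins at zero
penalty.  The functional metrics translate forecasts into the quantities a
clinician programs against: the 10th/90th percentile identification error
(as a percentage of the power-window span, so the metric is bounded) and
the threshold-deviation alarm that flags forecast days whose predicted
tail fractions drift beyond a safe range around the calibration reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distributions import (BinGrid, DailyDistribution, percentile_from_mass,
                            percentile_from_distribution)
from .eda import fractions_from_mass
from .io_core import SettingEpoch

__all__ = [
    "wmape",
    "percentile_inaccuracy",
    "prediction_to_mass",
    "AlarmFlag",
    "threshold_alarm",
    "BenchmarkReport",
    "benchmark_single_setting",
]


def wmape(y_true, y_pred) -> float:
    """Weighted mean absolute percentage error between two vectors."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"shape mismatch {y_true.shape} vs {y_pred.shape}")
    denom = np.abs(y_true).sum()
    if denom == 0:
        raise ValueError("wMAPE undefined for an all-zero reference")
    return float(np.abs(y_true - y_pred).sum() / denom)


def prediction_to_mass(predicted: np.ndarray) -> np.ndarray:
    """Renormalise a predicted (min–max-scale) vector to a unit-mass vector.

    Min–max-normalised histograms are not probability masses; percentile
    and tail-fraction extraction first clips negatives (baseline outputs
    are unconstrained) and rescales to sum 1.
    """
    mass = np.clip(np.asarray(predicted, dtype=float), 0.0, None)
    total = mass.sum()
    if total <= 0:
        raise ValueError("predicted distribution has no positive mass")
    return mass / total


def percentile_inaccuracy(observed, predicted: np.ndarray, q: float,
                          grid: BinGrid | None = None,
                          normalization: str = "span") -> float:
    """Percentage error in locating the q-th percentile of the prediction.

    ``100 * |v_pred(q) - v_obs(q)| / (p_window_max - p_window_min)`` with
    ``normalization="span"`` (default, bounded in [0, 100]); dividing by
    the observed percentile value instead is available as
    ``normalization="value"``.
    """
    if isinstance(observed, DailyDistribution):
        grid = observed.grid
        v_obs = percentile_from_distribution(observed, q)
    else:
        if grid is None:
            raise ValueError("grid required when observed is a plain vector")
        v_obs = percentile_from_mass(prediction_to_mass(observed), grid, q)
    if grid.span <= 0:
        raise ValueError("degenerate grid span")
    v_pred = percentile_from_mass(prediction_to_mass(predicted), grid, q)
    if normalization == "span":
        return 100.0 * abs(v_pred - v_obs) / grid.span
    if normalization == "value":
        if v_obs == 0:
            raise ValueError("observed percentile is zero; use span normalization")
        return 100.0 * abs(v_pred - v_obs) / abs(v_obs)
    raise ValueError(f"unknown normalization {normalization!r}")


@dataclass(frozen=True)
class AlarmFlag:
    horizon: int            # days ahead (1-based)
    f_below: float
    f_above: float
    alarm_below: bool
    alarm_above: bool

    @property
    def alarm(self) -> bool:
        return self.alarm_below or self.alarm_above


def threshold_alarm(predicted_dists, grid: BinGrid, epoch: SettingEpoch,
                    reference_fractions, safe_range_pp: float = 10.0,
                    ) -> list[AlarmFlag]:
    """Flag forecast days whose predicted tail fractions exceed tolerance.

    ``predicted_dists`` holds the predicted distributions for days
    +1..+H; an entry of ``None`` (missing horizon model) yields a gap in
    the report rather than a failure.  A day alarms when its predicted
    fraction below beta_min or above beta_max deviates from the reference
    (day-0 calibration) fraction by more than ``safe_range_pp`` percentage
    points.
    """
    ref_below, ref_above = reference_fractions[0], reference_fractions[-1]
    tol = safe_range_pp / 100.0
    flags: list[AlarmFlag] = []
    for k, pred in enumerate(predicted_dists, start=1):
        if pred is None:
            continue
        mass = prediction_to_mass(pred)
        f_below, _, f_above = fractions_from_mass(
            mass, grid, epoch.beta_min, epoch.beta_max)
        flags.append(AlarmFlag(
            horizon=k, f_below=f_below, f_above=f_above,
            alarm_below=f_below - ref_below > tol,
            alarm_above=f_above - ref_above > tol))
    return flags


# ---------------------------------------------------------------------------
# benchmarking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BenchmarkEntry:
    model: str
    n_history: int
    horizon: int
    seed: int | None
    wmape: float


@dataclass
class BenchmarkReport:
    entries: list[BenchmarkEntry]

    def aggregate(self) -> dict[tuple[str, int, int], tuple[float, float]]:
        """(model, N, K) -> (mean, sd) of wMAPE over seeds."""
        groups: dict[tuple[str, int, int], list[float]] = {}
        for e in self.entries:
            groups.setdefault((e.model, e.n_history, e.horizon), []).append(e.wmape)
        return {k: (float(np.mean(v)), float(np.std(v)))
                for k, v in groups.items()}

    def median(self, model: str, n_history: int, horizon: int) -> float:
        vals = [e.wmape for e in self.entries
                if (e.model, e.n_history, e.horizon) == (model, n_history, horizon)]
        if not vals:
            raise KeyError((model, n_history, horizon))
        return float(np.median(vals))

    def to_rows(self) -> list[dict]:
        return [e.__dict__ for e in self.entries]


def _baseline_wmapes(train, val, horizon: int, rfa_seed: int | None):
    """Evaluate zero-order / linear / RFA on the validation examples.

    The linear baseline is fitted per example on its N input days and
    collapses to the zero-order regressor when N = 1; the random-forest
    baseline (one-day horizon only) learns per-bin (day t -> day t+1) maps
    from the training examples.
    """
    from .baselines import (fit_linear_per_bin, linear_predict,
                            rfa_fit_predict, zero_order_predict)
    out: dict[str, float] = {}
    zero_errs, lin_errs = [], []
    for ex in val.examples:
        zero_errs.append(wmape(ex.label, zero_order_predict(ex.input)))
        if train.n_history >= 2:
            coeffs = fit_linear_per_bin(ex.input)
            lin_errs.append(wmape(ex.label,
                                  linear_predict(coeffs, ex.input[-1], horizon)))
        else:
            lin_errs.append(zero_errs[-1])  # N = 1: collapses to zero-order
    out["zero"] = float(np.mean(zero_errs))
    out["linear"] = float(np.mean(lin_errs))
    if rfa_seed is not None and horizon == 1:
        pairs = [(ex.input[-1], ex.label) for ex in train.examples]
        errs = [wmape(ex.label,
                      rfa_fit_predict(pairs, ex.input[-1], seed=rfa_seed))
                for ex in val.examples]
        out["rfa"] = float(np.mean(errs))
    return out


def benchmark_single_setting(dataset, config, seeds,
                             include_rfa: bool = True) -> BenchmarkReport:
    """Paired forecaster-vs-baselines comparison on one setting epoch.

    For every seed the forecaster is trained on the seed's shuffled split
    and all models are evaluated on byte-identical validation examples
    (the chronological-last split does not depend on the seed, so the
    deterministic baselines are recorded once with ``seed=None``).
    """
    from .forecaster import split_train_val, train_single_setting
    entries: list[BenchmarkEntry] = []
    n, k = config.n_history, config.horizon
    base_train, base_val = split_train_val(dataset, config.train_fraction,
                                           seed=0)
    baselines = _baseline_wmapes(base_train, base_val, k,
                                 rfa_seed=0 if include_rfa else None)
    for name, value in baselines.items():
        entries.append(BenchmarkEntry(name, n, k, None, value))
    for seed in seeds:
        trained = train_single_setting(dataset, config, seed)
        entries.append(BenchmarkEntry("forecaster", n, k, seed,
                                      trained.validation_wmape))
    return BenchmarkReport(entries)
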