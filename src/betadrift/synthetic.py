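"""Synthetic patients for testing the forecasting pipeline end-to-end.

Chronic device exports cannot be shared, so every other module is exercised
on generated recordings.  The generator emulates the structure that matters
for daily-distribution forecasting: minute-resolution beta power that is
positive and right-skewed (lognormal), with a circadian sinusoid, faster
medication-cycle oscillations, coloured 1/f^alpha minute-to-minute noise,
and a slow day-level drift of the distribution's location.  Drift comes in
four flavours: ``none``, ``linear`` (constant daily increment, the regime a
per-bin affine baseline captures), ``nonlinear_regime`` (stochastic
switching between two attracting levels, smoothed over a couple of days —
predictable from recent history but poorly captured by per-bin linear
maps), and ``smoothed_random_walk``.

Thresholds for each generated setting epoch are placed at the 10th/90th
percentiles of the epoch's first day, mirroring day-0 calibration practice.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np

from .distributions import BinGrid
from .io_core import Hemisphere, MinuteSeries, SettingEpoch

__all__ = [
    "SyntheticPatientConfig",
    "GroundTruth",
    "generate_colored_noise",
    "generate_synthetic_patient",
    "generate_toy_settings",
]


@dataclass(frozen=True)
class SyntheticPatientConfig:
    n_days: int = 60
    minutes_per_day: int = 1440
    start_date: dt.date = dt.date(2024, 1, 1)
    baseline_mu: float = 1.0          # log-power location
    baseline_sigma: float = 0.08      # minute-noise scale, log-power units
    circadian_amplitude: float = 0.35  # log-power units, 24 h period
    medication_cycles_per_day: float = 3.0
    medication_amplitude: float = 0.12
    drift_kind: str = "nonlinear_regime"  # none|linear|nonlinear_regime|smoothed_random_walk
    drift_target: str = "location"    # location | scale (what the drift moves)
    drift_scale: float = 0.6          # total log-power excursion of the drift
    regime_switch_prob: float = 0.08  # per-day switching probability
    regime_smooth_days: int = 2
    noise_alpha: float = 1.0          # spectral exponent of the minute noise
    noise_corr_minutes: float | None = None  # AR(1) noise with this
    # correlation time instead of power-law noise: steep (~f^-2) spectrum
    # within a day, flat beyond it — the short-term-correlated regime
    frozen_noise: bool = False        # reuse one intra-day noise pattern daily
    epochs: tuple[int, ...] = ()      # epoch lengths in days; () = single epoch
    patient_id: str = "SYN1"
    seed: int = 0

    def __post_init__(self):
        if self.drift_kind not in {"none", "linear", "nonlinear_regime",
                                   "smoothed_random_walk"}:
            raise ValueError(f"unknown drift_kind {self.drift_kind!r}")
        if not 0.0 <= self.noise_alpha <= 2.0:
            raise ValueError("noise_alpha must lie in [0, 2]")
        if self.drift_target not in {"location", "scale"}:
            raise ValueError(f"unknown drift_target {self.drift_target!r}")
        if self.epochs and sum(self.epochs) != self.n_days:
            raise ValueError(
                f"epoch lengths {self.epochs} must sum to n_days={self.n_days}")


@dataclass(frozen=True)
class GroundTruth:
    """Per-day generating parameters, aligned with the generated days."""

    day_mu: np.ndarray           # true log-power location per day
    drift: np.ndarray            # drift component per day
    epoch_day_ranges: tuple[tuple[int, int], ...]  # [start, end) day indices
    noise_alpha: float
    p_window: tuple[float, float]


def generate_colored_noise(alpha: float, n: int, seed: int | None = None,
                           rng: np.random.Generator | None = None,
                           ) -> np.ndarray:
    """Unit-variance series whose expected periodogram follows f^-alpha.

    Spectral synthesis: independent complex Gaussian Fourier coefficients
    scaled by f^(-alpha/2), inverse-transformed to the time domain.
    """
    if not 0.0 <= alpha <= 3.0:
        raise ValueError(f"alpha must lie in [0, 3], got {alpha}")
    if n < 64:
        raise ValueError(f"series too short (n={n} < 64)")
    if rng is None:
        rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-alpha / 2.0)
    coeffs = (rng.standard_normal(len(freqs))
              + 1j * rng.standard_normal(len(freqs))) * scale
    coeffs[0] = 0.0
    if n % 2 == 0:
        coeffs[-1] = coeffs[-1].real
    x = np.fft.irfft(coeffs, n=n)
    return x / x.std()


def _drift_trajectory(cfg: SyntheticPatientConfig,
                      rng: np.random.Generator) -> np.ndarray:
    d = np.arange(cfg.n_days, dtype=float)
    if cfg.drift_kind == "none":
        return np.zeros(cfg.n_days)
    if cfg.drift_kind == "linear":
        if cfg.n_days == 1:
            return np.zeros(1)
        return cfg.drift_scale * (d / (cfg.n_days - 1) - 0.5)
    if cfg.drift_kind == "nonlinear_regime":
        state = rng.integers(2)
        levels = np.array([-0.5, 0.5]) * cfg.drift_scale
        raw = np.empty(cfg.n_days)
        for i in range(cfg.n_days):
            if i > 0 and rng.random() < cfg.regime_switch_prob:
                state = 1 - state
            raw[i] = levels[state]
        return _smooth(raw, cfg.regime_smooth_days)
    # smoothed_random_walk
    steps = rng.standard_normal(cfg.n_days) * (
        cfg.drift_scale / np.sqrt(max(cfg.n_days, 2)))
    return _smooth(np.cumsum(steps), cfg.regime_smooth_days)


def _smooth(x: np.ndarray, window_days: int) -> np.ndarray:
    if window_days <= 1:
        return x
    kernel = np.ones(window_days) / window_days
    padded = np.concatenate([np.full(window_days - 1, x[0]), x])
    return np.convolve(padded, kernel, mode="valid")


def generate_synthetic_patient(cfg: SyntheticPatientConfig,
                               ) -> tuple[MinuteSeries, list[SettingEpoch], GroundTruth]:
    """Generate one patient: minute log, setting epochs, and ground truth."""
    rng = np.random.default_rng(cfg.seed)
    n_min = cfg.n_days * cfg.minutes_per_day
    t = np.arange(n_min, dtype=float)

    drift = _drift_trajectory(cfg, rng)
    day_index = (t // cfg.minutes_per_day).astype(int)
    circadian = cfg.circadian_amplitude * np.sin(
        2 * np.pi * t / cfg.minutes_per_day)
    medication = cfg.medication_amplitude * np.sin(
        2 * np.pi * cfg.medication_cycles_per_day * t / cfg.minutes_per_day)
    if cfg.baseline_sigma <= 0:
        noise = np.zeros(n_min)
    elif cfg.noise_corr_minutes is not None:
        phi = np.exp(-1.0 / cfg.noise_corr_minutes)
        eps = rng.standard_normal(n_min) * np.sqrt(1.0 - phi * phi)
        noise = np.empty(n_min)
        noise[0] = rng.standard_normal()
        for i in range(1, n_min):  # AR(1) recursion
            noise[i] = phi * noise[i - 1] + eps[i]
        noise *= cfg.baseline_sigma
    elif cfg.frozen_noise:
        # one day-long noise pattern tiled across days: smooths the daily
        # histogram without day-to-day sampling variance, so the histogram
        # sequence is a deterministic function of the drift trajectory —
        # the clean control regime for the linear baselines
        pattern = cfg.baseline_sigma * generate_colored_noise(
            cfg.noise_alpha, cfg.minutes_per_day, rng=rng)
        noise = np.tile(pattern, cfg.n_days)
    else:
        noise = cfg.baseline_sigma * generate_colored_noise(
            cfg.noise_alpha, n_min, rng=rng)
    intraday = circadian + medication + noise
    if cfg.drift_target == "scale":
        # drift multiplies the intra-day spread (distribution width)
        log_power = cfg.baseline_mu + (1.0 + drift[day_index]) * intraday
    else:
        # drift shifts the distribution location
        log_power = cfg.baseline_mu + intraday + drift[day_index]
    power = np.exp(log_power)

    start = np.datetime64(cfg.start_date, "s")
    timestamps = start + (t.astype("int64") * np.timedelta64(60, "s"))
    series = MinuteSeries(cfg.patient_id, Hemisphere.CH1, timestamps, power)

    epoch_lengths = cfg.epochs if cfg.epochs else (cfg.n_days,)
    epochs: list[SettingEpoch] = []
    ranges: list[tuple[int, int]] = []
    day0 = 0
    for j, length in enumerate(epoch_lengths):
        first_day = power[day0 * cfg.minutes_per_day:(day0 + 1) * cfg.minutes_per_day]
        beta_min = float(np.percentile(first_day, 10))
        beta_max = float(np.percentile(first_day, 90))
        epochs.append(SettingEpoch(
            start_date=cfg.start_date + dt.timedelta(days=day0),
            end_date=cfg.start_date + dt.timedelta(days=day0 + length - 1),
            beta_min=beta_min, beta_max=beta_max,
            a_min=1.0, a_max=3.0, driver_channel=Hemisphere.CH1,
            label=f"set{j}"))
        ranges.append((day0, day0 + length))
        day0 += length

    margin = 0.02 * np.ptp(power)
    p_window = (float(power.min() - margin), float(power.max() + margin))
    truth = GroundTruth(day_mu=cfg.baseline_mu + drift, drift=drift,
                        epoch_day_ranges=tuple(ranges),
                        noise_alpha=cfg.noise_alpha, p_window=p_window)
    return series, epochs, truth


def generate_toy_settings(n_epochs: int, days_per_epoch: int = 10,
                          start_date: dt.date = dt.date(2024, 1, 1),
                          ) -> list[SettingEpoch]:
    """Disjoint, ordered epochs with distinct thresholds, for structure tests."""
    if n_epochs < 1:
        raise ValueError("need at least one epoch")
    epochs = []
    for j in range(n_epochs):
        s = start_date + dt.timedelta(days=j * days_per_epoch)
        epochs.append(SettingEpoch(
            start_date=s, end_date=s + dt.timedelta(days=days_per_epoch - 1),
            beta_min=2.0 + 0.2 * j, beta_max=6.0 + 0.3 * j,
            a_min=1.0, a_max=3.0, label=f"toy{j}"))
    return epochs


def default_grid(truth: GroundTruth, n_bins: int = 206) -> BinGrid:
    """Uniform grid over the generated patient's power window."""
    return BinGrid.from_window(*truth.p_window, n_bins=n_bins)
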