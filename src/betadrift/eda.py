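"""Drift diagnostics for chronic beta-power recordings.

Two complementary views of long-term variability:

* **Threshold fractions** — for each day, the fraction of minutes spent
  below beta_min (understimulation, current pinned at A_min), between the
  thresholds (adaptive modulation), and above beta_max (overstimulation,
  current pinned at A_max).  A day deviating from the calibration-day
  reference by more than a tolerance (default 10 percentage points, i.e.
  2.4 h of a 24 h day) counts as a clinically meaningful shift; the
  per-epoch variability sigma is the percentage of such days.

* **Spectral exponents** — the periodogram of the minute-resolution series
  is split at the circadian cutoff (1/1440 cycles/minute) and each side is
  fitted with a power law C f^-alpha by ordinary least squares in log10
  space.  alpha ~ 0 indicates white (uncorrelated) fluctuations, ~1 pink,
  ~2 Brownian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .distributions import DailyDistribution
from .io_core import MinuteSeries

__all__ = [
    "VariabilityReport",
    "SpectralFit",
    "threshold_fractions",
    "fractions_from_mass",
    "setting_variability",
    "power_spectrum",
    "fit_powerlaw_split",
]

CIRCADIAN_CUTOFF = 1.0 / 1440.0  # cycles per minute (24 h period)


@dataclass(frozen=True)
class VariabilityReport:
    m_setting: int
    m_below: int
    m_above: int
    sigma_below: float       # percent of days
    sigma_above: float       # percent of days
    reference_fractions: tuple[float, float, float]
    tolerance_pp: float = 10.0


@dataclass(frozen=True)
class SpectralFit:
    freqs: np.ndarray        # cycles/minute, ascending, DC excluded
    power: np.ndarray
    cutoff: float = CIRCADIAN_CUTOFF
    alpha_short: float = np.nan
    c_short: float = np.nan
    alpha_long: float = np.nan
    c_long: float = np.nan

    @property
    def delta_f(self) -> float:
        return float(self.freqs[0])

    @property
    def f_nyquist(self) -> float:
        return float(self.freqs[-1])


def threshold_fractions(day, beta_min: float, beta_max: float,
                        ) -> tuple[float, float, float]:
    """(f_below, f_between, f_above) for one day.

    Computed on raw minute samples when ``day`` is a :class:`MinuteSeries`,
    or on histogram counts (with sub-bin interpolation at the thresholds)
    when it is a :class:`DailyDistribution`.  Samples exactly at a threshold
    count as "between": at the limit the device still modulates.
    """
    if not beta_min < beta_max:
        raise ValueError("beta_min must be < beta_max")
    if isinstance(day, MinuteSeries):
        if len(day) == 0:
            raise ValueError("empty day")
        p = day.power
        f_below = float((p < beta_min).mean())
        f_above = float((p > beta_max).mean())
        return f_below, 1.0 - f_below - f_above, f_above
    if isinstance(day, DailyDistribution):
        if day.n_samples == 0:
            raise ValueError("empty day")
        mass = day.counts / day.counts.sum()
        return fractions_from_mass(mass, day.grid, beta_min, beta_max)
    raise TypeError(f"unsupported day type {type(day)!r}")


def fractions_from_mass(mass: np.ndarray, grid, beta_min: float,
                        beta_max: float) -> tuple[float, float, float]:
    """Threshold fractions for a mass vector, interpolating inside bins."""
    mass = np.asarray(mass, dtype=float)
    total = mass.sum()
    if total <= 0:
        raise ValueError("mass vector sums to zero")
    cdf = np.concatenate([[0.0], np.cumsum(mass / total)])

    def cdf_at(x: float) -> float:
        if x <= grid.edges[0]:
            return 0.0
        if x >= grid.edges[-1]:
            return 1.0
        width = grid.span / grid.n_bins
        pos = (x - grid.edges[0]) / width
        i = min(int(pos), grid.n_bins - 1)
        return float(cdf[i] + (pos - i) * (cdf[i + 1] - cdf[i]))

    f_below = cdf_at(beta_min)
    f_above = 1.0 - cdf_at(beta_max)
    return f_below, 1.0 - f_below - f_above, f_above


def setting_variability(daily_fractions, reference, tolerance_pp: float = 10.0,
                        two_sided: bool = False) -> VariabilityReport:
    """Percentage of days in an epoch exceeding the deviation tolerance.

    ``daily_fractions`` is a sequence of per-day ``(f_below, f_above)``
    pairs (a trailing "between" entry is ignored if present) and
    ``reference`` the calibration-day fractions in the same layout.  A day
    counts as shifted below when its f_below exceeds the reference by more
    than ``tolerance_pp`` percentage points — excess time only, matching
    the reading of a 10 % shift as 2.4 extra hours at A_min/A_max; set
    ``two_sided=True`` to also count deficits.
    """
    if not 0.0 < tolerance_pp < 100.0:
        raise ValueError(f"tolerance_pp must be in (0, 100), got {tolerance_pp}")
    daily = [(f[0], f[-1]) for f in daily_fractions]
    if not daily:
        raise ValueError("need at least one day")
    ref_below, ref_above = reference[0], reference[-1]
    tol = tolerance_pp / 100.0

    def exceeds(value: float, ref: float) -> bool:
        if two_sided:
            return abs(value - ref) > tol
        return value - ref > tol

    m_below = sum(exceeds(fb, ref_below) for fb, _ in daily)
    m_above = sum(exceeds(fa, ref_above) for _, fa in daily)
    m = len(daily)
    return VariabilityReport(
        m_setting=m, m_below=m_below, m_above=m_above,
        sigma_below=100.0 * m_below / m, sigma_above=100.0 * m_above / m,
        reference_fractions=(ref_below, 1.0 - ref_below - ref_above, ref_above),
        tolerance_pp=tolerance_pp)


def power_spectrum(series, max_gap_fraction: float = 0.05) -> SpectralFit:
    """One-sided periodogram of the minute series, DC excluded.

    Frequency grid runs from delta_f = 1/T to the Nyquist frequency of
    1-minute sampling (0.5 cycles/minute) in steps of delta_f.  The mean is
    removed; no taper is applied.  Accepts a :class:`MinuteSeries` (which
    must be nearly gap-free) or a plain array already on a regular grid.
    """
    if isinstance(series, MinuteSeries):
        from .io_core import count_gaps
        n_gaps = count_gaps(series)
        if n_gaps > max_gap_fraction * len(series):
            raise ValueError(
                f"{n_gaps} missing minutes exceed the usable-gap budget; "
                "drop incomplete days and concatenate before the spectrum")
        x = series.power
    else:
        x = np.asarray(series, dtype=float)
    if len(x) < 2880:
        raise ValueError("need at least two days (2880 minutes) of samples")
    freqs, pxx = signal.periodogram(x, fs=1.0, window="boxcar",
                                    detrend="constant", scaling="density")
    return SpectralFit(freqs=freqs[1:], power=pxx[1:])


def fit_powerlaw_split(spec: SpectralFit, cutoff: float = CIRCADIAN_CUTOFF,
                       min_points: int = 10) -> SpectralFit:
    """Fit C f^-alpha separately above (short-term) and at/below (long-term)
    the circadian cutoff; OLS of log10 power on log10 frequency, unweighted.
    """
    freqs, power = spec.freqs, spec.power
    if not (freqs[0] < cutoff < freqs[-1]):
        raise ValueError("cutoff must lie inside the frequency range")
    long_mask = freqs <= cutoff
    short_mask = ~long_mask
    pos = power > 0
    for name, mask in (("long-term", long_mask & pos),
                       ("short-term", short_mask & pos)):
        if mask.sum() < min_points:
            raise ValueError(
                f"insufficient frequency points on the {name} side "
                f"({int(mask.sum())} < {min_points})")

    def fit(mask):
        slope, intercept = np.polyfit(np.log10(freqs[mask]),
                                      np.log10(power[mask]), 1)
        return -slope, 10.0 ** intercept

    alpha_long, c_long = fit(long_mask & pos)
    alpha_short, c_short = fit(short_mask & pos)
    return SpectralFit(freqs=freqs, power=power, cutoff=cutoff,
                       alpha_short=alpha_short, c_short=c_short,
                       alpha_long=alpha_long, c_long=c_long)
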