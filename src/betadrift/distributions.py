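"""Daily beta-power distributions on a fixed bin grid.

Each calendar day of minute samples becomes a histogram over a fixed,
uniform grid of ``n_bins`` (206 by default) spanning the patient's power
window, then min–max normalised to [0, 1].  The raw counts are retained so
that percentiles and threshold fractions are computed on counts, never on
the normalised vector.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass

import numpy as np

from .io_core import MinuteSeries, split_into_days

__all__ = [
    "BinGrid",
    "DailyDistribution",
    "bin_day",
    "minmax_normalize",
    "percentile_from_distribution",
    "percentile_from_mass",
    "display_downsample",
    "daily_distributions",
]

DEFAULT_N_BINS = 206


@dataclass(frozen=True)
class BinGrid:
    """Uniform histogram grid over the patient power window."""

    edges: np.ndarray  # n_bins + 1 ascending values

    def __post_init__(self):
        edges = np.asarray(self.edges, dtype=float)
        object.__setattr__(self, "edges", edges)
        if edges.ndim != 1 or len(edges) < 2:
            raise ValueError("need at least two edges")
        widths = np.diff(edges)
        if (widths <= 0).any():
            raise ValueError("edges must be strictly increasing")
        if not np.allclose(widths, widths[0], rtol=1e-9):
            raise ValueError("grid must be uniform")

    @classmethod
    def from_window(cls, p_min: float, p_max: float,
                    n_bins: int = DEFAULT_N_BINS) -> "BinGrid":
        if not p_min < p_max:
            raise ValueError("power window must satisfy min < max")
        return cls(np.linspace(p_min, p_max, n_bins + 1))

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def span(self) -> float:
        return float(self.edges[-1] - self.edges[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass(frozen=True)
class DailyDistribution:
    """One day's histogram: raw counts plus the min–max normalised vector."""

    date: dt.date
    counts: np.ndarray
    grid: BinGrid
    n_clipped: int = 0

    def __post_init__(self):
        counts = np.asarray(self.counts)
        object.__setattr__(self, "counts", counts)
        if len(counts) != self.grid.n_bins:
            raise ValueError(
                f"counts length {len(counts)} != n_bins {self.grid.n_bins}")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())

    @property
    def normalized(self) -> np.ndarray:
        return minmax_normalize(self.counts)


def bin_day(day_samples: MinuteSeries, grid: BinGrid) -> DailyDistribution:
    """Histogram one day of minute samples onto ``grid``.

    Bins are half-open ``[e_i, e_{i+1})`` with the last bin closed.
    Samples outside the grid span are clipped into the end bins and counted
    in ``n_clipped`` — the power window is defined to contain all of a
    patient's distributions, so clipping should be rare and visible.
    """
    if len(day_samples) == 0:
        raise ValueError("cannot bin an empty day")
    days = np.unique(day_samples.dates)
    if len(days) != 1:
        raise ValueError(f"bin_day expects one calendar date, got {len(days)}")
    power = day_samples.power
    lo, hi = grid.edges[0], grid.edges[-1]
    n_clipped = int(((power < lo) | (power > hi)).sum())
    clipped = np.clip(power, lo, hi)
    idx = np.minimum(
        np.floor((clipped - lo) / (grid.span / grid.n_bins)).astype(int),
        grid.n_bins - 1)
    counts = np.bincount(idx, minlength=grid.n_bins)
    return DailyDistribution(date=days[0].astype(dt.date), counts=counts,
                             grid=grid, n_clipped=n_clipped)


def minmax_normalize(counts: np.ndarray) -> np.ndarray:
    """``(c - min c) / (max c - min c)``; a constant vector maps to zeros.

    The all-zeros convention for the degenerate case keeps outputs inside
    [0, 1], matching the sigmoid range of the forecaster head.
    """
    c = np.asarray(counts, dtype=float)
    lo, hi = c.min(), c.max()
    if hi == lo:
        return np.zeros_like(c)
    return (c - lo) / (hi - lo)


def percentile_from_distribution(dist: DailyDistribution, q: float) -> float:
    """Invert the histogram CDF at ``q`` percent (linear within the bin)."""
    if not 0.0 < q < 100.0:
        raise ValueError(f"q must be in (0, 100), got {q}")
    if dist.n_samples < 1:
        raise ValueError("empty distribution")
    mass = dist.counts / dist.counts.sum()
    return percentile_from_mass(mass, dist.grid, q)


def percentile_from_mass(mass: np.ndarray, grid: BinGrid, q: float) -> float:
    """CDF inversion for an arbitrary non-negative mass vector on ``grid``."""
    if not 0.0 < q < 100.0:
        raise ValueError(f"q must be in (0, 100), got {q}")
    mass = np.asarray(mass, dtype=float)
    total = mass.sum()
    if total <= 0:
        raise ValueError("mass vector sums to zero")
    cdf = np.concatenate([[0.0], np.cumsum(mass / total)])
    target = q / 100.0
    i = int(np.searchsorted(cdf, target, side="left"))
    i = min(max(i, 1), grid.n_bins)
    frac_bin = cdf[i] - cdf[i - 1]
    if frac_bin <= 0:
        return float(grid.edges[i - 1])
    frac = (target - cdf[i - 1]) / frac_bin
    width = grid.span / grid.n_bins
    return float(grid.edges[i - 1] + frac * width)


def display_downsample(vector: np.ndarray) -> np.ndarray:
    """Average successive pairs of bins (presentation-resolution halving)."""
    v = np.asarray(vector, dtype=float)
    if len(v) % 2:
        warnings.warn("odd-length vector: dropping the last element")
        v = v[:-1]
    return 0.5 * (v[0::2] + v[1::2])


def daily_distributions(series: MinuteSeries, grid: BinGrid,
                        expected_per_day: int = 1440,
                        min_coverage: float = 0.8,
                        ) -> list[DailyDistribution]:
    """Bin every calendar day that meets the coverage requirement.

    A day is usable when it holds at least ``min_coverage`` of the expected
    sample count (1440 for whole-day logs, 720 for a 9:00–21:00 window);
    partially recorded days would otherwise yield degenerate histograms.
    """
    out = []
    for _, day_series in split_into_days(series).items():
        if len(day_series) >= min_coverage * expected_per_day:
            out.append(bin_day(day_series, grid))
    return out
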