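"""Deterministic baselines for daily-distribution forecasting.

Three references against which the attention forecaster is judged:

* **zero-order** — tomorrow's distribution equals today's (a = 1, b = 0);
* **linear** — an independent affine map ``x_{t+1,i} = a_i x_{t,i} + b_i``
  per bin, fitted by least squares on consecutive-day pairs (closed form
  for a two-day history);
* **random forest** — an independent per-bin ensemble regression
  ``x_{t+1,i} = f_i(x_{t,i})``, one-day-ahead only, which captures
  nonlinear per-bin maps without any sequence awareness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestRegressor

__all__ = [
    "LinearCoefficients",
    "zero_order_predict",
    "fit_linear_per_bin",
    "linear_predict",
    "rfa_fit_predict",
]


@dataclass(frozen=True)
class LinearCoefficients:
    a: np.ndarray  # per-bin slopes
    b: np.ndarray  # per-bin intercepts
    num_days: int

    def __post_init__(self):
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("a and b must be 1-D with equal length")
        if not (np.isfinite(a).all() and np.isfinite(b).all()):
            raise ValueError("coefficients must be finite")


def _as_matrix(history) -> np.ndarray:
    mat = np.asarray([np.asarray(getattr(d, "normalized", d), dtype=float)
                      for d in history])
    if mat.ndim != 2:
        raise ValueError("history must be a sequence of equal-length vectors")
    return mat


def zero_order_predict(history) -> np.ndarray:
    """Return the last distribution unchanged."""
    mat = _as_matrix(history)
    if len(mat) == 0:
        raise ValueError("empty history")
    return mat[-1].copy()


def fit_linear_per_bin(history) -> LinearCoefficients:
    """Fit the per-bin affine next-day map from ``m >= 2`` consecutive days.

    For m = 2 the closed form is ``a_i = x_2i / x_1i, b_i = 0`` when
    ``x_1i != 0`` and ``a_i = 0, b_i = x_2i`` otherwise.  For m > 2 each
    bin solves ordinary least squares over the m-1 pairs (day t -> t+1),
    via the pseudo-inverse of the [x 1] design.  Bins with zero variance
    across the design days fall back to ``a_i = 0, b_i = mean(target)``,
    which reduces continuously to the zero-order value.
    """
    mat = _as_matrix(history)
    m, n_bins = mat.shape
    if m < 2:
        raise ValueError(f"need at least 2 days of history, got {m}")
    a = np.zeros(n_bins)
    b = np.zeros(n_bins)
    if m == 2:
        x1, x2 = mat[0], mat[1]
        nz = x1 != 0
        a[nz] = x2[nz] / x1[nz]
        b[~nz] = x2[~nz]
        return LinearCoefficients(a=a, b=b, num_days=m)
    X = mat[:-1]  # (m-1, n_bins): day t
    Y = mat[1:]   # (m-1, n_bins): day t+1
    for i in range(n_bins):
        xi, yi = X[:, i], Y[:, i]
        if np.ptp(xi) == 0.0:
            a[i], b[i] = 0.0, yi.mean()
            continue
        design = np.column_stack([xi, np.ones_like(xi)])
        coef, *_ = np.linalg.lstsq(design, yi, rcond=None)
        a[i], b[i] = coef
    return LinearCoefficients(a=a, b=b, num_days=m)


def linear_predict(coeffs: LinearCoefficients, last_day, steps: int = 1,
                   ) -> np.ndarray:
    """Iterate the fitted one-step map ``x <- a x + b`` for ``steps`` days."""
    if steps < 1:
        raise ValueError("steps must be >= 1")
    x = np.asarray(getattr(last_day, "normalized", last_day), dtype=float).copy()
    if x.shape != coeffs.a.shape:
        raise ValueError(f"grid mismatch: {x.shape} vs {coeffs.a.shape}")
    for _ in range(steps):
        x = coeffs.a * x + coeffs.b
    return x


def rfa_fit_predict(train_pairs, query, n_trees: int = 100, seed: int = 0,
                    steps: int = 1) -> np.ndarray:
    """Per-bin random-forest one-day-ahead prediction.

    ``train_pairs`` is a sequence of ``(x_t, x_{t+1})`` distribution pairs;
    for each bin an independent forest of ``n_trees`` trees regresses the
    next-day value on the scalar current value, and the prediction for
    ``query`` is the mean over trees.  The forests carry no notion of
    sequence, so only the one-day horizon is supported.
    """
    if steps != 1:
        raise ValueError("the random-forest baseline supports the one-day "
                         "horizon only (steps=1)")
    pairs = [( np.asarray(getattr(x, "normalized", x), dtype=float),
               np.asarray(getattr(y, "normalized", y), dtype=float))
             for x, y in train_pairs]
    if len(pairs) < 2:
        raise ValueError("need at least 2 training pairs")
    X = np.stack([p[0] for p in pairs])  # (n_pairs, n_bins)
    Y = np.stack([p[1] for p in pairs])
    q = np.asarray(getattr(query, "normalized", query), dtype=float)
    n_bins = X.shape[1]
    out = np.empty(n_bins)
    rng = np.random.default_rng(seed)
    for i in range(n_bins):
        if np.ptp(Y[:, i]) == 0.0:  # constant target: skip the forest
            out[i] = Y[0, i]
            continue
        forest = RandomForestRegressor(
            n_estimators=n_trees,
            random_state=int(rng.integers(2**31 - 1)))
        forest.fit(X[:, i:i + 1], Y[:, i])
        out[i] = forest.predict(q[i:i + 1].reshape(1, 1))[0]
    return out
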