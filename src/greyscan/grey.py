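"""GM(1,1) grey forecasting with posterior-deviation validation.

The single-variable first-order grey model fits an exponential trend to the
accumulated (cumulative-sum) series.  Writing x_0..x_n for the observed
series and y_t = sum_{j<=t} x_j, the model is the whitened differential
equation dy/dt + alpha*y = mu, discretized through the consecutive-mean
sequence z_t = (y_t + y_{t-1})/2 as the linear system

    x_t + alpha * z_t = mu,   t = 1..n,

solved for (alpha, mu) by least squares.  The fitted accumulated series is
y_hat_t = (x_0 - mu/alpha) e^{-alpha t} + mu/alpha, and fitted/forecast
values of the original series come from first differences of y_hat.  The fit
is graded by the posterior deviation ratio c = s2/s1 (residual over series
standard deviation, population convention) and the small error probability
p = P(|delta - mean(delta)| < 0.6745 * s1), thresholded into excellent /
good / marginal / unreliable.

A grey model needs at least four observations and a strictly positive
series; the development coefficient alpha < 0 corresponds to growth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import DomainError

#: |alpha| below this uses the exact linear (alpha -> 0) limit.
ALPHA_DEGENERATE = 1e-10

DEGREE_EXCELLENT = "excellent"
DEGREE_GOOD = "good"
DEGREE_MARGINAL = "marginal"
DEGREE_UNRELIABLE = "unreliable"


@dataclass(frozen=True)
class GreySeries:
    """An ordered positive time sequence x_0..x_n (n >= 3)."""

    values: Tuple[float, ...]
    label: str = ""

    def __post_init__(self):
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", vals)
        if len(vals) < 4:
            raise DomainError(
                f"series '{self.label}': GM(1,1) needs at least 4 observations, got {len(vals)}"
            )
        if any(v <= 0 for v in vals):
            raise DomainError(f"series '{self.label}': all values must be > 0")

    def __len__(self):
        return len(self.values)


@dataclass
class GM11Model:
    """A fitted grey model with its reconstruction and validation state."""

    alpha: float
    mu: float
    x0: float
    n: int  # last index of the input series (length n+1)
    accumulated: np.ndarray
    mean_seq: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    label: str = ""
    s1: Optional[float] = None
    s2: Optional[float] = None
    c: Optional[float] = None
    p: Optional[float] = None
    degree: Optional[str] = None

    def accumulated_at(self, t) -> np.ndarray:
        """Fitted accumulated value y_hat(t) of the continuous solution."""
        t = np.asarray(t, dtype=float)
        if abs(self.alpha) < ALPHA_DEGENERATE:
            return self.x0 + self.mu * t
        level = self.mu / self.alpha
        return (self.x0 - level) * np.exp(-self.alpha * t) + level


def _values(series) -> np.ndarray:
    if isinstance(series, GreySeries):
        return np.asarray(series.values, dtype=float)
    return np.asarray(series, dtype=float)


def accumulated_generation(series) -> np.ndarray:
    """Cumulative-sum (1-AGO) sequence; strictly increasing for a positive
    series.  First-differencing it recovers the input exactly."""
    return np.cumsum(_values(series))


def mean_sequence(accumulated) -> np.ndarray:
    """Consecutive means z_t = (y_t + y_{t-1}) / 2, t = 1..n."""
    y = np.asarray(accumulated, dtype=float)
    if y.size < 2:
        raise DomainError("mean sequence needs at least 2 accumulated values")
    return (y[1:] + y[:-1]) / 2.0


def fit_gm11(series: Union[GreySeries, Sequence[float]], label: str = "") -> GM11Model:
    """Fit GM(1,1) by least squares on x_t + alpha z_t = mu, t = 1..n.

    The normal-equation solution is computed with :func:`numpy.linalg.lstsq`.
    When |alpha| falls below ``ALPHA_DEGENERATE`` (e.g. a constant series)
    the exact linear limit y_hat_t = x_0 + mu t is used, so fitted values are
    all mu.
    """
    if not isinstance(series, GreySeries):
        series = GreySeries(tuple(float(v) for v in series), label=label)
    x = _values(series)
    n = x.size - 1
    y = accumulated_generation(x)
    z = mean_sequence(y)
    B = np.column_stack([-z, np.ones_like(z)])
    rhs = x[1:]
    sol, _, rank, _ = np.linalg.lstsq(B, rhs, rcond=None)
    if rank < 2 and np.ptp(z) > 0:
        raise DomainError("singular grey system")
    alpha, mu = float(sol[0]), float(sol[1])

    model = GM11Model(
        alpha=alpha, mu=mu, x0=float(x[0]), n=n,
        accumulated=y, mean_seq=z,
        fitted=np.empty(0), residuals=np.empty(0),
        label=series.label or label,
    )
    t = np.arange(n + 1, dtype=float)
    y_hat = model.accumulated_at(t)
    fitted = np.empty(n + 1)
    fitted[0] = x[0]
    fitted[1:] = np.diff(y_hat)
    model.fitted = fitted
    model.residuals = x - fitted
    return model


def validate_gm11(
    model: GM11Model, series: Union[GreySeries, Sequence[float]]
) -> Tuple[float, float, float, float]:
    """Posterior-deviation validation: (s1, s2, c, p).

    s1 is the population standard deviation of the observed series, s2 that
    of the residuals delta_t = x_t - x_hat_t over t = 0..n (delta_0 = 0 by
    construction); c = s2/s1; p is the fraction of residuals within
    0.6745*s1 of the mean residual.  The results are stored on the model.
    """
    x = _values(series)
    if x.size != model.fitted.size:
        raise DomainError("series length does not match the fitted model")
    delta = x - model.fitted
    s1 = float(x.std())  # population convention; c is invariant to this choice
    s2 = float(delta.std())
    if s1 == 0.0:
        warnings.warn("zero-variance series: posterior deviation ratio undefined")
        c = np.nan
    else:
        c = s2 / s1
    p = float(np.mean(np.abs(delta - delta.mean()) < 0.6745 * s1)) if s1 > 0 else 1.0
    model.s1, model.s2, model.c, model.p = s1, s2, float(c), p
    model.residuals = delta
    model.degree = classify_degree(c, p) if s1 > 0 else None
    return s1, s2, float(c), p


def classify_degree(c: float, p: float) -> str:
    """Four-level grading of a grey fit from (c, p).

    excellent: p > 0.95 and c < 0.35; good: p > 0.80 and c < 0.50;
    marginal: p > 0.70 and c < 0.65; otherwise unreliable.  Monotone:
    decreasing c or increasing p never worsens the grade.
    """
    if c < 0:
        raise DomainError("c must be >= 0")
    if not 0 <= p <= 1:
        raise DomainError("p must be in [0, 1]")
    if p > 0.95 and c < 0.35:
        return DEGREE_EXCELLENT
    if p > 0.80 and c < 0.50:
        return DEGREE_GOOD
    if p > 0.70 and c < 0.65:
        return DEGREE_MARGINAL
    return DEGREE_UNRELIABLE


def forecast(model: GM11Model, horizon: int) -> np.ndarray:
    """Out-of-sample values x_hat_{n+1}..x_hat_{n+horizon} by differencing
    the fitted continuous accumulated solution."""
    if horizon < 1:
        raise DomainError(f"horizon must be >= 1, got {horizon}")
    t = np.arange(model.n, model.n + horizon + 1, dtype=float)
    return np.diff(model.accumulated_at(t))


def fit_and_validate(series, label: str = "") -> GM11Model:
    """Convenience: fit, validate, and grade in one call."""
    model = fit_gm11(series, label=label)
    validate_gm11(model, series if isinstance(series, GreySeries) else _values(series))
    return model


def burden(
    forecast_admissions: Mapping[str, Sequence[float]],
    hospitals: Mapping[str, int],
) -> Dict[str, np.ndarray]:
    """Mean admissions per hospital: elementwise division of each district's
    forecast admissions by its hospital count.  A hospital service-load
    proxy; the ranking by burden can differ from the ranking by admissions
    when hospital counts differ."""
    out: Dict[str, np.ndarray] = {}
    for district, values in forecast_admissions.items():
        vals = np.asarray(values, dtype=float)
        h = int(hospitals.get(district, 0))
        if h < 1:
            if np.any(vals != 0):
                raise DomainError(
                    f"district '{district}' forecasts admissions but has no hospitals"
                )
            out[district] = np.zeros_like(vals)
        else:
            out[district] = vals / h
    return out
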