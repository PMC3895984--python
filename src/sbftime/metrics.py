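"""Quantifying output functions: envelopes, Gaussian fits, half-widths, slopes.

The behavioural observables of the timing model are properties of the output
function: where it peaks (accuracy), how wide it is (precision), whether it is
symmetric (criterion noise) or long-tailed (frequency noise), and whether the
width grows linearly with the criterion time (scalar property).  Two width
conventions coexist and every result names its own: the Gaussian-fit SD
``sigma_gauss`` (used for simulated traces) and the half-height full width
``x2 - x1`` (used for the analytic frequency-noise sweeps, usually in
normalized time t / t_peak).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import argrelextrema, hilbert

from .core import OutputTrace
from .exceptions import EnvelopeError, FitError, TruncationError, ValidationError

__all__ = [
    "PeakCharacterization",
    "GaussianFit",
    "ScalarFit",
    "QuadraticFit",
    "upper_envelope",
    "fit_gaussian",
    "half_width_points",
    "scalar_regression",
    "skew_quadratic_fit",
    "width_linear_fit",
]


@dataclass(frozen=True)
class PeakCharacterization:
    """Peak location, half-height geometry and skewness of an output function.

    ``tau1 = t_peak - x1`` and ``tau2 = x2 - t_peak`` are the left and right
    half-widths; their ratio measures the long tail (1 for a symmetric peak).
    If built in normalized time, all time-like fields are in units of t_peak.
    """

    t_peak: float
    x1: float
    x2: float
    normalized: bool = False

    def __post_init__(self) -> None:
        if not (self.x1 < self.t_peak < self.x2):
            raise ValidationError("require x1 < t_peak < x2")

    @property
    def tau1(self) -> float:
        return self.t_peak - self.x1

    @property
    def tau2(self) -> float:
        return self.x2 - self.t_peak

    @property
    def fwhm(self) -> float:
        return self.x2 - self.x1

    @property
    def skew_ratio(self) -> float:
        return self.tau2 / self.tau1


@dataclass(frozen=True)
class GaussianFit:
    """Least-squares Gaussian ``A exp(-(t-mu)^2 / (2 sigma^2))``."""

    mu: float
    sigma: float
    amplitude: float
    r2: float


@dataclass(frozen=True)
class ScalarFit:
    """Ordinary least-squares line through (abscissa, width) pairs."""

    slope: float
    intercept: float
    r2: float
    pairs: tuple = ()


@dataclass(frozen=True)
class QuadraticFit:
    """Least-squares quadratic ``c0 + c1 x + c2 x^2``."""

    c0: float
    c1: float
    c2: float
    r2: float


def _r2(y: np.ndarray, y_hat: np.ndarray) -> float:
    ss_res = float(np.sum((y - y_hat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot


def upper_envelope(trace: OutputTrace, method: str = "peaks") -> OutputTrace:
    """Upper envelope of an oscillatory trace on its original grid.

    ``peaks``: linear interpolation through the local maxima of the raw
    values, then the pointwise maximum with the raw trace (so the envelope
    never dips below it).  ``hilbert``: magnitude of the analytic signal,
    smoother for carrier-modulated traces.  Requires at least three local
    maxima; flatter traces should be fitted directly.
    """
    t, y = trace.times, trace.values
    if method == "hilbert":
        env = np.abs(hilbert(y))
        return OutputTrace(t, env, trace.metadata | {"envelope": "hilbert"})
    if method != "peaks":
        raise ValidationError(f"unknown envelope method {method!r}")
    (idx,) = argrelextrema(y, np.greater)
    if idx.size < 3:
        raise EnvelopeError(
            f"only {idx.size} local maxima; need >= 3 for an envelope"
        )
    env = np.interp(t, t[idx], y[idx])
    env = np.maximum(env, y)
    return OutputTrace(t, env, trace.metadata | {"envelope": "peaks"})


def fit_gaussian(trace: OutputTrace, window_frac: float = 0.1) -> GaussianFit:
    """Nonlinear least-squares Gaussian fit around the peak.

    Restricted to the contiguous sub-trace around the global maximum with
    values ``>= window_frac * max``, so neither a long tail nor secondary
    echoes bias the fit; initialized from moments of that window.
    """
    t, y = trace.times, trace.values
    i_max = int(np.argmax(y))
    above = y >= window_frac * y[i_max]
    lo = i_max
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = i_max
    while hi < len(y) - 1 and above[hi + 1]:
        hi += 1
    mask = np.zeros_like(above)
    mask[lo : hi + 1] = True
    tt, yy = t[mask], y[mask]
    if tt.size < 4:
        raise FitError("too few points above the fit window")
    mu0 = t[i_max]
    w = np.clip(yy, 0, None)
    sigma0 = float(np.sqrt(np.sum(w * (tt - mu0) ** 2) / np.sum(w)))
    p0 = [float(y[i_max]), float(mu0), max(sigma0, np.diff(t).min())]

    def model(x, A, mu, sigma):
        return A * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))

    try:
        popt, _ = curve_fit(model, tt, yy, p0=p0, maxfev=10000)
    except RuntimeError as exc:
        resid = float(np.sum((yy - model(tt, *p0)) ** 2))
        raise FitError(str(exc), initial_guess=p0, residual=resid) from exc
    A, mu, sigma = popt
    return GaussianFit(
        mu=float(mu),
        sigma=float(abs(sigma)),
        amplitude=float(A),
        r2=_r2(yy, model(tt, *popt)),
    )


def _cross_left(t, y, i_peak, level) -> float:
    below = np.nonzero(y[:i_peak] < level)[0]
    if below.size == 0:
        raise TruncationError("left")
    j = below[-1]
    return float(np.interp(level, [y[j], y[j + 1]], [t[j], t[j + 1]]))


def _cross_right(t, y, i_peak, level) -> float:
    below = np.nonzero(y[i_peak:] < level)[0]
    if below.size == 0:
        raise TruncationError("right")
    j = i_peak + below[0]
    return float(np.interp(level, [y[j], y[j - 1]], [t[j], t[j - 1]]))


def half_width_points(
    trace: OutputTrace, normalize_time: bool = False
) -> PeakCharacterization:
    """Locate the peak and the two half-height crossings by interpolation.

    ``x1 < t_peak < x2`` solve ``out(x) = out(t_peak) / 2`` on either side of
    the (unique global) maximum, found by linear interpolation between the
    bracketing grid points.  With ``normalize_time`` the result is expressed
    in units of the peak time (the peak maps to 1).
    """
    t, y = trace.times, trace.values
    i_peak = int(np.argmax(y))
    if i_peak == 0 or i_peak == len(y) - 1:
        raise ValidationError("global maximum lies on the grid boundary")
    half = 0.5 * y[i_peak]
    x1 = _cross_left(t, y, i_peak, half)
    x2 = _cross_right(t, y, i_peak, half)
    t_peak = float(t[i_peak])
    if normalize_time:
        return PeakCharacterization(1.0, x1 / t_peak, x2 / t_peak, normalized=True)
    return PeakCharacterization(t_peak, x1, x2)


def scalar_regression(pairs: Sequence[tuple[float, float]]) -> ScalarFit:
    """OLS regression of width on criterion time (or on noise SD).

    A linear width-vs-T relation with near-zero intercept and high R^2 is the
    hallmark of time-scale invariance.
    """
    pairs = tuple((float(a), float(b)) for a, b in pairs)
    if len(pairs) < 3:
        raise ValidationError("need at least 3 (abscissa, width) pairs")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.ptp(x) == 0:
        raise ValidationError("degenerate abscissa: all values equal")
    slope, intercept = np.polyfit(x, y, 1)
    return ScalarFit(
        slope=float(slope),
        intercept=float(intercept),
        r2=_r2(y, slope * x + intercept),
        pairs=pairs,
    )


def skew_quadratic_fit(
    sigmas: np.ndarray, ratios: np.ndarray
) -> QuadraticFit:
    """Quadratic fit of the half-width ratio tau2/tau1 against sigma_f."""
    sigmas = np.asarray(sigmas, dtype=float)
    ratios = np.asarray(ratios, dtype=float)
    if sigmas.size < 3:
        raise ValidationError("need at least 3 points for a quadratic fit")
    c2, c1, c0 = np.polyfit(sigmas, ratios, 2)
    return QuadraticFit(
        c0=float(c0),
        c1=float(c1),
        c2=float(c2),
        r2=_r2(ratios, c0 + c1 * sigmas + c2 * sigmas**2),
    )


def width_linear_fit(sigmas: np.ndarray, widths: np.ndarray) -> ScalarFit:
    """Linear fit of the (normalized-time) half-height width against sigma_f."""
    return scalar_regression(list(zip(np.asarray(sigmas), np.asarray(widths))))
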