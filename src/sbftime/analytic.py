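"""Closed-form output functions and peak predictions.

These are the analytic counterparts of the simulated coincidence output, used
both as predictions and as the oracle surface the Monte-Carlo simulator is
checked against.

Noiseless circuit
-----------------
For equally spaced frequencies ``f_k = f_min + k df`` the coincidence output
with weights ``cos(2 pi f_k T)`` is, by the cosine sum over an arithmetic
progression,

    out0(t) = (1/2) [ S(t - T) + S(t + T) ],
    S(x) = cos(a0 x) sin(b0 x) / sin(b0 x / N)

with ``a0 = pi (f_max + f_min - df)`` and ``b0 = pi (f_max - f_min)``.  The
slowly varying factor ``sin(b0 x) / (2 sin(b0 x / N))`` is the envelope; it
tends to ``N/2`` at the peak and its half-height half-width depends only on
``b0`` -- the noiseless width is independent of the criterion time, which is
the violation of scalar timing the noise repairs.

Criterion-time noise (Gaussian, fractional SD sigma_T)
------------------------------------------------------
Averaging the weights over ``T_j = T (1 + xi_j)`` damps each oscillator by
``exp(-2 pi^2 f^2 T^2 sigma_T^2)``.  With an unbounded uniform frequency
continuum the output is the pure Gaussian ``exp(-(t-T)^2 / (2 (T sigma_T)^2))``
centred exactly on T: accurate, symmetric, width proportional to T.  For a
finite band the same integral acquires a band-limited amplitude expressed by
a difference of two complex error functions, evaluated here through the
Faddeeva function for numerical stability.

Frequency noise (Gaussian, fractional SD sigma_f, probe trials only)
--------------------------------------------------------------------
The expected output damps each oscillator by ``exp(-2 pi^2 f^2 sigma_f^2 t^2)``
(time-dependent).  The unbounded-band form is the long-tailed

    out(t)  proportional to  (1/t) exp(-(t-T)^2 / (2 sigma_f^2 t^2)),

a Gaussian-like peak just below T with a slow right tail; the finite-band
form again carries an erf-difference amplitude.  The peak for arbitrary noise
is predicted at ``T / (1 + gamma_f)`` with ``gamma_f = sigma_f^2`` for
Gaussian noise; the exact argmax of the form above is
``T (sqrt(1 + 4 sigma_f^2) - 1) / (2 sigma_f^2)``, which agrees with the
prediction to O(sigma_f^4).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import brentq
from scipy.special import wofz

from .bank import OscillatorBankSpec, make_frequencies
from .core import OutputTrace
from .exceptions import ValidationError

__all__ = [
    "NoiselessClosedForm",
    "AnalyticPrediction",
    "noiseless_output",
    "noiseless_envelope",
    "noiseless_width",
    "criterion_output_infinite",
    "criterion_output_finite",
    "frequency_output_infinite",
    "frequency_output_finite",
    "frequency_peak_time",
    "predicted_peak",
]


@dataclass(frozen=True)
class NoiselessClosedForm:
    """Constants of the noiseless closed form for a given bank and criterion."""

    a0: float  # rad/s: pi (f_max + f_min - df)
    b0: float  # rad/s: pi (f_max - f_min)
    n_in: int
    T: float

    @classmethod
    def from_spec(cls, spec: OscillatorBankSpec, T: float) -> "NoiselessClosedForm":
        return cls(
            a0=np.pi * (spec.f_max + spec.f_min - spec.df),
            b0=np.pi * (spec.f_max - spec.f_min),
            n_in=spec.n_osc,
            T=T,
        )


@dataclass(frozen=True)
class AnalyticPrediction:
    """Predicted peak location (and width where available) of the output."""

    peak_time: float
    noise_target: Literal["criterion", "frequency"]
    gamma: float
    width: float | None = None

    def __post_init__(self) -> None:
        if self.peak_time <= 0:
            raise ValidationError("predicted peak must be positive")
        if self.width is not None and self.width < 0:
            raise ValidationError("predicted width must be >= 0")


def _dirichlet_ratio(y: np.ndarray, n: int) -> np.ndarray:
    """``sin(y) / sin(y / n)`` with the removable singularity at y = 0 handled.

    Uses ``sin(y)/sin(y/n) = n sinc(y/pi)/sinc(y/(n pi))``, finite wherever
    the denominator sinc is nonzero (true on any window short of the first
    aliasing revival at ``y = n pi``).
    """
    return n * np.sinc(y / np.pi) / np.sinc(y / (n * np.pi))


def noiseless_envelope(
    spec: OscillatorBankSpec, T: float, t: np.ndarray
) -> np.ndarray:
    """Envelope ``sin(b0 (t-T)) / (2 sin(b0 (t-T)/N))`` of the noiseless output."""
    cf = NoiselessClosedForm.from_spec(spec, T)
    t = np.asarray(t, dtype=float)
    return 0.5 * _dirichlet_ratio(cf.b0 * (t - T), cf.n_in)


def noiseless_output(
    spec: OscillatorBankSpec,
    T: float,
    t: np.ndarray,
    normalize_weights: bool = True,
) -> OutputTrace:
    """Noiseless coincidence output of the sine bank, in closed form.

    Equals the direct double sum ``a * sum_i cos(2 pi f_i T) cos(2 pi f_i t)``
    divided by ``max_i |cos(2 pi f_i T)|`` (the simulator's weight
    normalization) when ``normalize_weights`` is set.
    """
    cf = NoiselessClosedForm.from_spec(spec, T)
    t = np.asarray(t, dtype=float)

    def S(x: np.ndarray) -> np.ndarray:
        return np.cos(cf.a0 * x) * _dirichlet_ratio(cf.b0 * x, cf.n_in)

    out = 0.5 * (S(t - T) + S(t + T))
    scale = spec.amplitude
    if normalize_weights:
        scale /= float(np.max(np.abs(np.cos(2 * np.pi * make_frequencies(spec) * T))))
    return OutputTrace(
        t, scale * out, {"provenance": "analytic", "form": "noiseless", "T": T}
    )


def noiseless_width(spec: OscillatorBankSpec, T: float | None = None) -> float:
    """Half-height width of the noiseless envelope; independent of T.

    Solves ``env(T + sigma/2) = env(T)/2`` on the envelope by bracketed root
    finding.  Scales as 1/b0: widening the band narrows the peak.
    """
    n = spec.n_osc
    b0 = np.pi * (spec.f_max - spec.f_min)
    peak = 0.5 * n

    def g(u: float) -> float:
        return 0.5 * _dirichlet_ratio(np.asarray(u), n) - 0.5 * peak

    # first zero of the envelope is at u = pi; the half crossing lies inside
    u_half = brentq(g, 1e-9, np.pi - 1e-9, xtol=1e-14)
    return 2.0 * u_half / b0


def criterion_output_infinite(
    T: float, sigma_T: float, t: np.ndarray
) -> OutputTrace:
    """Unbounded-band output under Gaussian criterion noise: a pure Gaussian.

    ``exp(-(t - T)^2 / (2 (T sigma_T)^2))``, peaked exactly at T (accurate
    timing), symmetric, with SD ``T sigma_T`` (scalar property).
    """
    if sigma_T <= 0:
        raise ValidationError("sigma_T must be > 0")
    t = np.asarray(t, dtype=float)
    s = T * sigma_T
    vals = np.exp(-((t - T) ** 2) / (2.0 * s**2))
    return OutputTrace(
        t,
        vals,
        {"provenance": "analytic", "form": "criterion_infinite", "T": T,
         "sigma_T": sigma_T},
    )


def _banded_gauss_cos(x: np.ndarray, s: np.ndarray, f_lo: float, f_hi: float):
    """Stable ``integral_{f_lo}^{f_hi} exp(-(s f)^2) cos(2 pi f x) df``.

    Equals ``(sqrt(pi)/(2 s)) e^{-c^2} Re[erf(s f + i c)]`` between the band
    edges, with ``c = pi x / s``.  Written via the Faddeeva function
    ``w(z) = e^{-z^2} erfc(-i z)`` as
    ``e^{-c^2} Re erf(a + i c) = e^{-c^2} - e^{-a^2} Re[e^{-2 i a c} w(-c + i a)]``
    so the exponentially large complex erf never appears.
    """
    c = np.pi * x / s

    def edge(a):
        with np.errstate(under="ignore"):
            damp = np.exp(-(a**2))
        live = damp > 0
        res = np.zeros(np.broadcast(c, a).shape)
        if np.any(live):
            cc = np.broadcast_to(c, res.shape)[live]
            aa = np.broadcast_to(a, res.shape)[live]
            res[live] = damp[live] * np.real(
                np.exp(-2j * aa * cc) * wofz(-cc + 1j * aa)
            )
        return res

    pref = np.sqrt(np.pi) / (2.0 * s)
    return pref * (edge(np.broadcast_to(s * f_lo, c.shape))
                   - edge(np.broadcast_to(s * f_hi, c.shape)))


def criterion_output_finite(
    spec: OscillatorBankSpec, T: float, sigma_T: float, t: np.ndarray
) -> OutputTrace:
    """Finite-band output under Gaussian criterion noise.

    The band-limited Gaussian-damped cosine transform: the infinite-band
    Gaussian times a difference of two (complex) error functions.  Converges
    pointwise to :func:`criterion_output_infinite` as the band widens.
    """
    if sigma_T <= 0:
        raise ValidationError("sigma_T must be > 0")
    t = np.asarray(t, dtype=float)
    s = np.sqrt(2.0) * np.pi * T * sigma_T  # alpha = s^2 in exp(-alpha f^2)
    s = np.broadcast_to(s, t.shape)
    vals = 0.5 * (
        _banded_gauss_cos(t - T, s, spec.f_min, spec.f_max)
        + _banded_gauss_cos(t + T, s, spec.f_min, spec.f_max)
    )
    return OutputTrace(
        t,
        vals,
        {"provenance": "analytic", "form": "criterion_finite", "T": T,
         "sigma_T": sigma_T, "band": (spec.f_min, spec.f_max)},
    )


def frequency_output_infinite(
    T: float, sigma_f: float, t: np.ndarray
) -> OutputTrace:
    """Unbounded-band output under Gaussian frequency noise.

    ``(1/t) exp(-(t - T)^2 / (2 sigma_f^2 t^2))`` -- a Gaussian-like peak with
    a long right tail, skewness growing with sigma_f.  Defined as 0 at t = 0.
    """
    if sigma_f <= 0:
        raise ValidationError("sigma_f must be > 0")
    t = np.asarray(t, dtype=float)
    vals = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    with np.errstate(under="ignore"):
        vals[pos] = (1.0 / tp) * np.exp(
            -((tp - T) ** 2) / (2.0 * sigma_f**2 * tp**2)
        )
    return OutputTrace(
        t,
        vals,
        {"provenance": "analytic", "form": "frequency_infinite", "T": T,
         "sigma_f": sigma_f},
    )


def frequency_output_finite(
    spec: OscillatorBankSpec, T: float, sigma_f: float, t: np.ndarray
) -> OutputTrace:
    """Finite-band output under Gaussian frequency noise.

    Band-limited counterpart of :func:`frequency_output_infinite` (the damping
    scale grows with t, so the erf-difference amplitude is time-dependent);
    converges to the unbounded form as the band widens toward (0, inf).
    """
    if sigma_f <= 0:
        raise ValidationError("sigma_f must be > 0")
    t = np.asarray(t, dtype=float)
    vals = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    s = np.sqrt(2.0) * np.pi * sigma_f * tp
    vals[pos] = 0.5 * (
        _banded_gauss_cos(tp - T, s, spec.f_min, spec.f_max)
        + _banded_gauss_cos(tp + T, s, spec.f_min, spec.f_max)
    )
    return OutputTrace(
        t,
        vals,
        {"provenance": "analytic", "form": "frequency_finite", "T": T,
         "sigma_f": sigma_f, "band": (spec.f_min, spec.f_max)},
    )


def frequency_peak_time(T: float, sigma_f: float) -> float:
    """Exact argmax of the unbounded-band frequency-noise form.

    ``T (sqrt(1 + 4 sigma_f^2) - 1) / (2 sigma_f^2)``; equals the general
    prediction ``T / (1 + sigma_f^2)`` to O(sigma_f^4).
    """
    if sigma_f == 0:
        return T
    return T * (np.sqrt(1.0 + 4.0 * sigma_f**2) - 1.0) / (2.0 * sigma_f**2)


def predicted_peak(
    noise_target: Literal["criterion", "frequency"],
    T: float,
    gamma: float | None = None,
    sigma: float | None = None,
) -> AnalyticPrediction:
    """Predicted output peak: ``T (1 + gamma_T)`` or ``T / (1 + gamma_f)``.

    For Gaussian noise the constants specialize to ``gamma_T = 0`` (criterion
    noise: accurate timing at exactly T) and ``gamma_f = sigma_f^2``.  Pass
    either ``gamma`` directly or ``sigma`` to use the Gaussian specialization.
    The width field carries ``T sigma_T`` for Gaussian criterion noise.
    """
    if gamma is None:
        if sigma is None:
            raise ValidationError("provide gamma or sigma")
        gamma = 0.0 if noise_target == "criterion" else float(sigma) ** 2
    if gamma < 0:
        raise ValidationError("gamma must be >= 0")
    if noise_target == "criterion":
        peak = T * (1.0 + gamma)
        width = T * sigma if sigma is not None else None
    elif noise_target == "frequency":
        peak = T / (1.0 + gamma)
        width = None
    else:
        raise ValidationError(f"unknown noise target {noise_target!r}")
    return AnalyticPrediction(
        peak_time=peak, noise_target=noise_target, gamma=gamma, width=width
    )
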