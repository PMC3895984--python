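"""Morris-Lecar conductance-based input neurons.

The biophysical variant of the SBF input population replaces the cosine phase
oscillators with Morris-Lecar (ML) neurons: a two-variable conductance model
(membrane potential V and a slow potassium gating variable w) driven by a
constant bias current.  The parameter set is the standard type-II (Hopf)
regime, in which the neuron fires periodically above a threshold current, with
a firing rate that increases monotonically with the bias.  The recovery-rate
scale ``phi`` is set so the achievable firing band covers the cortical alpha
band (8-12 Hz).

Dynamics (time in ms, voltages in mV, currents in uA/cm^2)::

    C dV/dt = I - g_L (V - E_L) - g_Ca m_inf(V) (V - E_Ca) - g_K w (V - E_K)
    dw/dt   = phi (w_inf(V) - w) cosh((V - v3) / (2 v4))
    m_inf(V) = (1 + tanh((V - v1)/v2)) / 2
    w_inf(V) = (1 + tanh((V - v3)/v4)) / 2

Integration is a fixed-step explicit fourth-order Runge-Kutta scheme,
vectorized across a bank of neurons.  Spike times are upward threshold
crossings of V, located by linear interpolation inside the step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .exceptions import (
    CalibrationError,
    FrequencyRangeError,
    IntegrationError,
    ValidationError,
)

__all__ = [
    "MorrisLecarParams",
    "MLTrace",
    "MLBank",
    "ml_integrate",
    "firing_rate",
    "f_i_curve",
    "calibrate_bias",
    "calibrate_bank",
    "ml_states",
]


@dataclass(frozen=True)
class MorrisLecarParams:
    """Morris-Lecar parameters (type-II / Hopf regime).

    Conductances in mS/cm^2, potentials in mV, capacitance in uF/cm^2, bias
    current in uA/cm^2, ``phi`` in 1/ms, ``dt_ms`` in ms.
    """

    capacitance: float = 20.0
    g_leak: float = 2.0
    e_leak: float = -60.0
    g_ca: float = 4.4
    e_ca: float = 120.0
    g_k: float = 8.0
    e_k: float = -84.0
    v1: float = -1.2
    v2: float = 18.0
    v3: float = 2.0
    v4: float = 30.0
    phi: float = 0.031
    i_bias: float = 95.0
    dt_ms: float = 0.1
    spike_threshold: float = 0.0
    # current range searched during rate calibration (monotone f-I segment)
    i_search: tuple[float, float] = (87.6, 180.0)

    def __post_init__(self) -> None:
        for name in ("g_leak", "g_ca", "g_k"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not self.dt_ms > 0:
            raise ValidationError("dt_ms must be > 0")
        if not self.capacitance > 0:
            raise ValidationError("capacitance must be > 0")


@dataclass
class MLTrace:
    """Result of integrating a single ML neuron."""

    times_s: np.ndarray
    voltage: np.ndarray
    spike_times_s: np.ndarray


def _derivs(p: MorrisLecarParams, v: np.ndarray, w: np.ndarray, i_bias: np.ndarray):
    m_inf = 0.5 * (1.0 + np.tanh((v - p.v1) / p.v2))
    w_inf = 0.5 * (1.0 + np.tanh((v - p.v3) / p.v4))
    rate = p.phi * np.cosh((v - p.v3) / (2.0 * p.v4))
    dv = (
        i_bias
        - p.g_leak * (v - p.e_leak)
        - p.g_ca * m_inf * (v - p.e_ca)
        - p.g_k * w * (v - p.e_k)
    ) / p.capacitance
    dw = rate * (w_inf - w)
    return dv, dw


def _integrate(
    p: MorrisLecarParams,
    i_bias: np.ndarray,
    duration_ms: float,
    dt_ms: float | None = None,
    store_stride: int = 1,
    v0: float = -40.0,
    w0: float = 0.1,
):
    """RK4 integration of a bank of ML neurons with per-neuron bias currents.

    Returns ``(t_stored_ms, V_stored, spike_times_ms)`` where ``V_stored`` has
    shape ``(n_stored, n_neurons)`` and ``spike_times_ms`` is a list of arrays.
    """
    dt = p.dt_ms if dt_ms is None else dt_ms
    i_bias = np.atleast_1d(np.asarray(i_bias, dtype=float))
    n = i_bias.shape[0]
    n_steps = int(round(duration_ms / dt))
    v = np.full(n, v0)
    w = np.full(n, w0)
    thr = p.spike_threshold

    n_stored = n_steps // store_stride + 1
    V = np.empty((n_stored, n))
    V[0] = v
    t_stored = np.arange(n_stored) * (dt * store_stride)
    spikes: list[list[float]] = [[] for _ in range(n)]

    half = 0.5 * dt
    sixth = dt / 6.0
    for k in range(n_steps):
        dv1, dw1 = _derivs(p, v, w, i_bias)
        dv2, dw2 = _derivs(p, v + half * dv1, w + half * dw1, i_bias)
        dv3, dw3 = _derivs(p, v + half * dv2, w + half * dw2, i_bias)
        dv4, dw4 = _derivs(p, v + dt * dv3, w + dt * dw3, i_bias)
        vn = v + sixth * (dv1 + 2.0 * dv2 + 2.0 * dv3 + dv4)
        wn = w + sixth * (dw1 + 2.0 * dw2 + 2.0 * dw3 + dw4)
        crossed = (v < thr) & (vn >= thr)
        if crossed.any():
            t0 = k * dt
            for i in np.nonzero(crossed)[0]:
                frac = (thr - v[i]) / (vn[i] - v[i])
                spikes[i].append(t0 + frac * dt)
        v, w = vn, wn
        if (k + 1) % store_stride == 0:
            V[(k + 1) // store_stride] = v

    if not np.all(np.isfinite(v)):
        raise IntegrationError(
            "non-finite membrane potential; reduce dt_ms or check parameters"
        )
    return t_stored, V, [np.asarray(s) for s in spikes]


def ml_integrate(
    params: MorrisLecarParams,
    duration_s: float,
    i_bias: float | None = None,
    dt_ms: float | None = None,
) -> MLTrace:
    """Integrate a single ML neuron for ``duration_s`` seconds.

    Uses ``params.i_bias`` unless ``i_bias`` is given.  Spike times are upward
    crossings of ``params.spike_threshold``.
    """
    if not duration_s > 0:
        raise ValidationError("duration_s must be > 0")
    ib = params.i_bias if i_bias is None else i_bias
    t_ms, V, spikes = _integrate(params, np.array([ib]), duration_s * 1e3, dt_ms)
    return MLTrace(t_ms * 1e-3, V[:, 0], spikes[0] * 1e-3)


def _rates_from_spikes(
    spike_ms: Sequence[np.ndarray], duration_ms: float, discard_frac: float = 0.5
) -> np.ndarray:
    """Steady-state firing rate in Hz from spike times, discarding the transient."""
    t_cut = discard_frac * duration_ms
    rates = np.zeros(len(spike_ms))
    for i, s in enumerate(spike_ms):
        s = s[s > t_cut]
        if s.size >= 3:
            rates[i] = 1e3 * (s.size - 1) / (s[-1] - s[0])
    return rates


def firing_rate(
    params: MorrisLecarParams,
    i_bias: float | np.ndarray,
    duration_s: float = 4.0,
) -> np.ndarray:
    """Steady-state firing rate (Hz) at one or more bias currents."""
    i_bias = np.atleast_1d(np.asarray(i_bias, dtype=float))
    dur_ms = duration_s * 1e3
    _, _, spikes = _integrate(params, i_bias, dur_ms, store_stride=10**9)
    return _rates_from_spikes(spikes, dur_ms)


def f_i_curve(
    params: MorrisLecarParams, n_points: int = 25, duration_s: float = 4.0
):
    """Sample the f-I curve over the calibration current range.

    Returns ``(i_grid, rates)``; within the type-II oscillatory segment the
    curve is monotone increasing.
    """
    lo, hi = params.i_search
    i_grid = np.linspace(lo, hi, n_points)
    return i_grid, firing_rate(params, i_grid, duration_s)


def calibrate_bias(
    target_f: float,
    params: MorrisLecarParams,
    rel_tol: float = 0.005,
    duration_s: float = 4.0,
    max_iter: int = 40,
) -> float:
    """Bias current at which the neuron fires at ``target_f`` Hz (bisection).

    The measured rate at the returned current is within ``rel_tol`` (relative)
    of the target; raises :class:`FrequencyRangeError` if the target lies
    outside the achievable band of the monotone f-I segment.
    """
    lo, hi = params.i_search
    f_lo, f_hi = firing_rate(params, [lo, hi], duration_s)
    if not (f_lo <= target_f <= f_hi) or target_f <= 0:
        raise FrequencyRangeError(target_f, f_lo, f_hi)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = firing_rate(params, mid, duration_s)[0]
        if abs(f_mid - target_f) <= rel_tol * target_f:
            return mid
        if f_mid < target_f:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def calibrate_bank(
    freqs: np.ndarray,
    params: MorrisLecarParams,
    rel_tol: float = 0.005,
    duration_s: float = 4.0,
    n_curve: int = 25,
    max_rounds: int = 8,
) -> "MLBank":
    """Calibrate a whole bank of ML neurons to target frequencies at once.

    Seeds each neuron's bias by interpolating the inverse of a sampled f-I
    curve, then refines all neurons simultaneously with vectorized secant
    steps until every measured rate is within ``rel_tol`` of its target.
    """
    freqs = np.asarray(freqs, dtype=float)
    i_grid, rates = f_i_curve(params, n_points=n_curve, duration_s=duration_s)
    ok = rates > 0
    if ok.sum() < 2:
        raise CalibrationError("f-I curve has no oscillatory segment")
    i_ok, r_ok = i_grid[ok], rates[ok]
    if np.any(freqs < r_ok.min()) or np.any(freqs > r_ok.max()):
        raise FrequencyRangeError(
            float(freqs.min() if np.any(freqs < r_ok.min()) else freqs.max()),
            float(r_ok.min()),
            float(r_ok.max()),
        )
    # inverse interpolation I(f); r_ok is monotone on the oscillatory segment
    ib = np.interp(freqs, r_ok, i_ok)
    slope = np.gradient(i_ok, r_ok)  # dI/df along the curve
    local_slope = np.interp(freqs, r_ok, slope)

    for _ in range(max_rounds):
        measured = firing_rate(params, ib, duration_s)
        err = measured - freqs
        bad = np.abs(err) > rel_tol * freqs
        if not bad.any():
            break
        ib = ib - err * local_slope
        ib = np.clip(ib, i_grid[0], i_grid[-1])
    else:
        worst = float(np.max(np.abs(err) / freqs))
        raise CalibrationError(
            f"bank calibration did not converge (worst residual {worst:.2%})"
        )
    return MLBank(params=params, freqs=freqs, i_bias=ib, measured_rates=measured)


@dataclass
class MLBank:
    """A bank of ML neurons calibrated to target frequencies."""

    params: MorrisLecarParams
    freqs: np.ndarray
    i_bias: np.ndarray
    measured_rates: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_osc(self) -> int:
        return len(self.freqs)


def ml_states(
    bank: MLBank,
    t_grid_s: np.ndarray,
    amplitude: float = 1.0,
    store_dt_ms: float = 2.0,
) -> np.ndarray:
    """Normalized bank state matrix on a probe time grid.

    Integrates the calibrated bank over ``[0, max(t_grid)]``, then rescales
    each neuron's voltage affinely to ``[-1, 1]`` over the simulated window
    (times ``amplitude``) so ML voltages play the same role as the sine
    states in the coincidence readout.  Returns shape ``(n_osc, n_t)``.

    Raises :class:`CalibrationError` for a flat (non-oscillating) trace.
    """
    t_grid_s = np.asarray(t_grid_s, dtype=float)
    dur_ms = float(t_grid_s.max()) * 1e3
    stride = max(1, int(round(store_dt_ms / bank.params.dt_ms)))
    t_ms, V, _ = _integrate(bank.params, bank.i_bias, dur_ms, store_stride=stride)
    # flatness judged after the initial transient has decayed
    settled = V[V.shape[0] // 2 :]
    if np.any(np.ptp(settled, axis=0) < 1.0):  # < 1 mV excursion: no oscillation
        raise CalibrationError("flat voltage trace in bank; neuron not oscillating")
    out = np.empty((len(bank.freqs), len(t_grid_s)))
    for i in range(V.shape[1]):
        out[i] = np.interp(t_grid_s, t_ms * 1e-3, V[:, i])
    vmax = out.max(axis=1, keepdims=True)
    vmin = out.min(axis=1, keepdims=True)
    out = (2.0 * out - (vmax + vmin)) / (vmax - vmin)
    return amplitude * out


def with_dt(params: MorrisLecarParams, dt_ms: float) -> MorrisLecarParams:
    """Copy of ``params`` with a different integration step."""
    return replace(params, dt_ms=dt_ms)
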