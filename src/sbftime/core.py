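"""Reference memory and coincidence-detector readout.

The SBF circuit times an interval T in two phases.  During fixed-interval (FI)
training, the state of every input oscillator at the reinforcement time is
stored as a weight; over many FI trials, with the memorized criterion T_j
fluctuating from trial to trial, the reference memory becomes the normalized
trial average ``w_i = <cos(2 pi f_i T_j)>_j / norm`` with
``norm = max_i |<cos(2 pi f_i T_j)>_j|`` so that ``|w_i| <= 1``.  During a
probe trial the single coincidence-detector (output) neuron computes the dot
product of the stored weights with the current oscillator states.

Two kinds of parameter variability are supported, each as a multiplicative
``(1 + xi)`` factor with zero-mean ``xi`` of fractional SD sigma:

* criterion-time noise -- ``T_j = T (1 + xi_j)``, one draw per FI trial;
* frequency noise -- ``f_ij = f_i (1 + xi_ij)`` during probe trials, drawn
  either independently per (oscillator, trial) or shared by all oscillators
  within a trial (trial-to-trial clock-speed variability).

Averaging conventions
---------------------
The *signed* trial average (``probe_output``, ``encode_reference``) is the
quantity the closed forms in :mod:`sbftime.analytic` describe.  In the alpha
band its expected amplitude is damped by ``exp(-2 pi^2 f^2 T^2 sigma_T^2)``,
which is numerically zero once the criterion jitter exceeds one oscillation
period: the per-trial carriers decohere.  The observable trial statistic in
that regime is the *magnitude* of the match, estimated here as the RMS across
trials (``rms_output``); its expectation is the probability density of the
memorized criteria smoothed by the squared noiseless kernel, which is the
Gaussian whose width grows linearly with T.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np

from .exceptions import EncodingError, ValidationError

__all__ = [
    "NoiseSpec",
    "ReferenceMemory",
    "OutputTrace",
    "sample_multipliers",
    "encode_reference",
    "encode_reference_from_states",
    "probe_output",
    "rms_output",
    "rms_output_from_states",
    "default_time_grid",
]

_DISTRIBUTIONS = ("none", "gaussian", "uniform", "poisson")


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative noise: factors ``1 + xi`` with E[xi] = 0, SD[xi] = sigma.

    ``gaussian``: xi ~ Normal(0, sigma); ``uniform``: xi ~ U(-sqrt(3) sigma,
    +sqrt(3) sigma); ``poisson``: xi = (P(lambda) - lambda) sigma / sqrt(lambda)
    (zero-mean, SD sigma, discrete lattice made fine by a large lambda).
    """

    distribution: str = "none"
    sigma: float = 0.0
    seed: int | None = None
    poisson_lambda: float = 100.0

    def __post_init__(self) -> None:
        if self.distribution not in _DISTRIBUTIONS:
            raise ValidationError(
                f"unknown distribution {self.distribution!r}; "
                f"expected one of {_DISTRIBUTIONS}"
            )
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")
        if self.distribution == "none" and self.sigma != 0:
            raise ValidationError("distribution 'none' requires sigma = 0")
        if self.poisson_lambda <= 0:
            raise ValidationError("poisson_lambda must be > 0")

    @classmethod
    def none(cls) -> "NoiseSpec":
        return cls()


def _resolve_rng(
    rng: np.random.Generator | None, noise: NoiseSpec
) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(noise.seed)


def sample_multipliers(
    noise: NoiseSpec, n: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw ``n`` multiplicative factors ``1 + xi``; reproducible given a seed."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    if noise.distribution == "none":
        return np.ones(n)
    rng = _resolve_rng(rng, noise)
    s = noise.sigma
    if noise.distribution == "gaussian":
        xi = s * rng.standard_normal(n)
    elif noise.distribution == "uniform":
        half = np.sqrt(3.0) * s
        xi = rng.uniform(-half, half, n)
    else:  # poisson
        lam = noise.poisson_lambda
        xi = (rng.poisson(lam, n) - lam) * (s / np.sqrt(lam))
    return 1.0 + xi


@dataclass
class ReferenceMemory:
    """Normalized reference-memory weights encoding a criterion time."""

    weights: np.ndarray
    frequencies: np.ndarray
    criterion: float
    n_trials: int
    norm_constant: float
    criteria: np.ndarray | None = None  # sampled T_j, kept for audit

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.frequencies):
            raise ValidationError("weights and frequencies must have equal length")


@dataclass
class OutputTrace:
    """Coincidence-detector output sampled on a probe-trial time grid."""

    times: np.ndarray
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or len(self.times) != len(self.values):
            raise ValidationError("times and values must be 1-d and equally long")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError("time grid must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("trace values must be finite")

    def normalized(self) -> "OutputTrace":
        """Copy with values divided by the maximum absolute value."""
        peak = np.max(np.abs(self.values))
        if peak == 0:
            raise ValidationError("cannot normalize an all-zero trace")
        return OutputTrace(self.times, self.values / peak, dict(self.metadata))

    def restricted(self, t_lo: float, t_hi: float) -> "OutputTrace":
        m = (self.times >= t_lo) & (self.times <= t_hi)
        return OutputTrace(self.times[m], self.values[m], dict(self.metadata))


def default_time_grid(
    T: float, f_max: float, points_per_cycle: int = 20, span: float = 3.0
) -> np.ndarray:
    """Probe-trial grid on ``[0, span*T]`` resolving the fastest oscillation.

    Probe trials last about three times the criterion; the step is
    ``1 / (points_per_cycle * f_max)``.
    """
    dt = 1.0 / (points_per_cycle * f_max)
    return np.arange(0.0, span * T + dt / 2, dt)


def encode_reference(
    freqs: np.ndarray,
    T: float,
    n_trials: int = 1,
    noise: NoiseSpec = NoiseSpec(),
    rng: np.random.Generator | None = None,
    variant: Literal["signed", "positive"] = "signed",
    keep_criteria: bool = False,
) -> ReferenceMemory:
    """Encode the criterion time into normalized weights over FI trials.

    The unnormalized weight is ``u_i = mean_j cos(2 pi f_i T_j)`` with
    ``T_j = T (1 + xi_j)``; weights are ``u_i / max|u_i|`` so that
    ``max_i |w_i| = 1``.  The ``positive`` variant stores ``(1 + u_i) / 2``
    (states mapped onto [0, 1]) before normalization; signed and positive
    weights produce coincidence peaks at the same location.
    """
    if T < 0:
        raise ValidationError("criterion T must be >= 0")
    if n_trials < 1:
        raise ValidationError("n_trials must be >= 1")
    freqs = np.asarray(freqs, dtype=float)
    factors = sample_multipliers(noise, n_trials, rng)
    Tj = T * factors
    u = np.cos(2.0 * np.pi * np.outer(freqs, Tj)).mean(axis=1)
    if variant == "positive":
        u = 0.5 * (1.0 + u)
    norm = float(np.max(np.abs(u)))
    if norm == 0.0:
        raise EncodingError("degenerate encoding: all unnormalized weights zero")
    return ReferenceMemory(
        weights=u / norm,
        frequencies=freqs,
        criterion=T,
        n_trials=n_trials,
        norm_constant=norm,
        criteria=Tj if keep_criteria else None,
    )


def encode_reference_from_states(
    states_at: Callable[[np.ndarray], np.ndarray],
    freqs: np.ndarray,
    T: float,
    n_trials: int = 1,
    noise: NoiseSpec = NoiseSpec(),
    rng: np.random.Generator | None = None,
) -> ReferenceMemory:
    """Like :func:`encode_reference` but for arbitrary oscillator waveforms.

    ``states_at(t_array)`` must return the state matrix ``(n_osc, n_t)``; used
    for the Morris-Lecar bank, where states are interpolated voltage traces.
    """
    if T < 0:
        raise ValidationError("criterion T must be >= 0")
    factors = sample_multipliers(noise, n_trials, rng)
    Tj = T * factors
    u = states_at(Tj).mean(axis=1)
    norm = float(np.max(np.abs(u)))
    if norm == 0.0:
        raise EncodingError("degenerate encoding: all unnormalized weights zero")
    return ReferenceMemory(
        weights=u / norm,
        frequencies=np.asarray(freqs, dtype=float),
        criterion=T,
        n_trials=n_trials,
        norm_constant=norm,
    )


def _frequency_factors(
    noise: NoiseSpec,
    n_trials: int,
    n_osc: int,
    mode: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Multiplier matrix (n_trials, n_osc); shared mode broadcasts per trial."""
    if mode == "per_oscillator":
        return sample_multipliers(noise, n_trials * n_osc, rng).reshape(
            n_trials, n_osc
        )
    if mode == "shared":
        return np.repeat(
            sample_multipliers(noise, n_trials, rng)[:, None], n_osc, axis=1
        )
    raise ValidationError(f"unknown frequency-noise mode {mode!r}")


def probe_output(
    memory: ReferenceMemory,
    freqs: np.ndarray,
    amplitude: float,
    grid: np.ndarray,
    freq_noise: NoiseSpec = NoiseSpec(),
    n_probe_trials: int = 1,
    rng: np.random.Generator | None = None,
    mode: Literal["per_oscillator", "shared"] = "per_oscillator",
    average: Literal["mean", "rms"] = "mean",
    chunk: int = 64,
) -> OutputTrace:
    """Trial-averaged coincidence output on a probe-trial time grid.

    Without frequency noise this is the single deterministic trial
    ``out(t) = sum_i w_i a cos(2 pi f_i t)``.  With noise, frequency
    multipliers are drawn once per (oscillator, trial) -- or once per trial in
    ``shared`` mode -- held fixed within the trial, and the per-trial outputs
    are combined across trials by the signed mean (default) or RMS.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValidationError("empty probe time grid")
    freqs = np.asarray(freqs, dtype=float)
    w = memory.weights
    meta = {
        "criterion": memory.criterion,
        "amplitude": amplitude,
        "freq_noise": freq_noise.distribution,
        "sigma_f": freq_noise.sigma,
        "mode": mode,
        "average": average,
        "n_probe_trials": n_probe_trials,
    }
    if freq_noise.distribution == "none":
        out = w @ (amplitude * np.cos(2.0 * np.pi * np.outer(freqs, grid)))
        return OutputTrace(grid, out, meta | {"n_probe_trials": 1})

    if n_probe_trials < 1:
        raise ValidationError("n_probe_trials must be >= 1")
    rng = _resolve_rng(rng, freq_noise)
    acc = np.zeros(grid.shape)
    two_pi_t = 2.0 * np.pi * grid
    for start in range(0, n_probe_trials, chunk):
        k = min(chunk, n_probe_trials - start)
        fac = _frequency_factors(freq_noise, k, len(freqs), mode, rng)
        f_jit = fac * freqs  # (k, n_osc)
        # per-trial outputs: (k, n_t)
        per_trial = np.einsum(
            "i,kit->kt", w, np.cos(f_jit[:, :, None] * two_pi_t[None, None, :])
        )
        if average == "mean":
            acc += amplitude * per_trial.sum(axis=0)
        elif average == "rms":
            acc += (amplitude**2) * (per_trial**2).sum(axis=0)
        else:
            raise ValidationError(f"unknown average {average!r}")
    out = acc / n_probe_trials
    if average == "rms":
        out = np.sqrt(out)
    return OutputTrace(grid, out, meta)


def rms_output(
    freqs: np.ndarray,
    T: float,
    grid: np.ndarray,
    criterion_noise: NoiseSpec,
    n_trials: int = 1000,
    rng: np.random.Generator | None = None,
    amplitude: float = 1.0,
    chunk: int = 256,
) -> OutputTrace:
    """RMS across FI trials of the per-trial coincidence output.

    Trial j stores the oscillator states at its own criterion ``T_j`` and is
    probed without further noise; the traces are combined as
    ``sqrt(mean_j out_j(t)^2)``.  This is the magnitude statistic that remains
    observable when the signed trial average decoheres (see module docstring);
    its Gaussian width grows as ``sqrt(2) T sigma_T``.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValidationError("empty probe time grid")
    freqs = np.asarray(freqs, dtype=float)
    rng = _resolve_rng(rng, criterion_noise)
    Tj = T * sample_multipliers(criterion_noise, n_trials, rng)
    C = np.cos(2.0 * np.pi * np.outer(freqs, grid))  # (n_osc, n_t)
    acc = np.zeros(grid.shape)
    for start in range(0, n_trials, chunk):
        block = Tj[start : start + chunk]
        W = np.cos(2.0 * np.pi * np.outer(block, freqs))  # (k, n_osc)
        acc += ((W @ C) ** 2).sum(axis=0)
    out = amplitude * np.sqrt(acc / n_trials) / len(freqs)
    meta = {
        "criterion": T,
        "noise": criterion_noise.distribution,
        "sigma_T": criterion_noise.sigma,
        "n_trials": n_trials,
        "statistic": "rms",
    }
    return OutputTrace(grid, out, meta)


def rms_output_from_states(
    states_at: Callable[[np.ndarray], np.ndarray],
    T: float,
    grid: np.ndarray,
    criterion_noise: NoiseSpec,
    n_trials: int = 1000,
    rng: np.random.Generator | None = None,
    center: bool = True,
    chunk: int = 256,
) -> OutputTrace:
    """RMS coincidence output for arbitrary oscillator waveforms (ML bank).

    ``states_at(t_array) -> (n_osc, n_t)``.  With ``center=True`` each
    neuron's temporal mean over the probe window is subtracted from both the
    stored and the probe states, matching the zero-mean sine oscillators and
    removing the population-rate pedestal from the coincidence term.
    """
    grid = np.asarray(grid, dtype=float)
    rng = _resolve_rng(rng, criterion_noise)
    Tj = T * sample_multipliers(criterion_noise, n_trials, rng)
    S = states_at(grid)  # (n_osc, n_t)
    offset = S.mean(axis=1, keepdims=True) if center else 0.0
    S = S - offset
    Wall = states_at(Tj) - offset  # (n_osc, n_trials)
    acc = np.zeros(grid.shape)
    for start in range(0, n_trials, chunk):
        W = Wall[:, start : start + chunk].T  # (k, n_osc)
        acc += ((W @ S) ** 2).sum(axis=0)
    out = np.sqrt(acc / n_trials) / S.shape[0]
    meta = {
        "criterion": T,
        "noise": criterion_noise.distribution,
        "sigma_T": criterion_noise.sigma,
        "n_trials": n_trials,
        "statistic": "rms",
        "centered": center,
    }
    return OutputTrace(grid, out, meta)
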