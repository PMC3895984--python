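"""Reproducible experiment runners.

Ties the oscillator banks, the coincidence readout and the response metrics
into the four headline experiments:

* ``run_noiseless``      -- the noiseless circuit: output width independent of
  the criterion time (no scalar timing without noise);
* ``run_scalar_experiment`` -- criterion-time or frequency noise: Gaussian-fit
  width grows linearly with the criterion time (scalar timing from noise);
* ``run_fig5_sweep``     -- the analytic frequency-noise sweep: half-width
  ratio (skewness) and normalized half-height width as functions of sigma_f;
* ``generate_fixtures``  -- small deterministic artifacts for tests/demos.

Every stochastic run derives its generators from a single master seed through
``numpy.random.SeedSequence`` spawning, so repeated runs are bit-reproducible.

Averaging: criterion-noise runs use the RMS-across-trials statistic (see
:mod:`sbftime.core`); frequency-noise runs draw one clock-speed multiplier per
probe trial shared by all oscillators (trial-to-trial clock variability) and
also average by RMS, which is what leaves an observable long-tailed peak for
a finite frequency band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sbf_io
from .analytic import frequency_output_infinite, noiseless_width
from .bank import OscillatorBankSpec, make_frequencies
from .core import (
    NoiseSpec,
    OutputTrace,
    default_time_grid,
    encode_reference,
    probe_output,
    rms_output,
    rms_output_from_states,
)
from .exceptions import ValidationError
from .metrics import (
    GaussianFit,
    QuadraticFit,
    ScalarFit,
    fit_gaussian,
    half_width_points,
    scalar_regression,
    skew_quadratic_fit,
    upper_envelope,
    width_linear_fit,
)
from .ml import MorrisLecarParams, calibrate_bank, ml_states

__all__ = [
    "ExperimentConfig",
    "ExperimentReport",
    "run_noiseless",
    "run_scalar_experiment",
    "run_fig5_sweep",
    "generate_fixtures",
    "analysis_grid",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Bundled settings for one experiment run."""

    model: str = "sbf-sin"  # or "sbf-ml"
    bank: OscillatorBankSpec = OscillatorBankSpec(1000, 8.0, 12.0)
    criteria: tuple[float, ...] = (5.0, 10.0, 20.0, 30.0, 40.0, 50.0)
    noise_target: str = "none"  # none | criterion | frequency
    noise: NoiseSpec = NoiseSpec()
    n_fi_trials: int = 1000
    n_probe_trials: int = 1000
    n_grid: int = 500
    replicates: int = 1
    master_seed: int = 0
    ml_params: MorrisLecarParams = MorrisLecarParams()
    n_out: int = 1  # number of (identical) coincidence detectors
    # "equal": the analytic grid f_k = f_min + k df; "stratified": one
    # uniform draw per equal-width bin (uniformly distributed frequencies
    # without the commensurate spacing).  "auto" resolves to equal for
    # sbf-sin and stratified for sbf-ml, whose harmonic-rich waveforms turn
    # an equally spaced grid into strong fractional band revivals.
    freq_sampling: str = "auto"

    def __post_init__(self) -> None:
        if not self.criteria:
            raise ValidationError("criterion list must be non-empty")
        if any(T <= 0 for T in self.criteria):
            raise ValidationError("all criteria must be > 0")
        if self.model not in ("sbf-sin", "sbf-ml"):
            raise ValidationError(f"unknown model {self.model!r}")
        if self.noise_target not in ("none", "criterion", "frequency"):
            raise ValidationError(f"unknown noise target {self.noise_target!r}")
        if self.n_out < 1:
            raise ValidationError("n_out must be >= 1")
        if self.freq_sampling not in ("auto", "equal", "stratified"):
            raise ValidationError(f"unknown freq_sampling {self.freq_sampling!r}")

    def resolved_sampling(self) -> str:
        if self.freq_sampling != "auto":
            return self.freq_sampling
        return "stratified" if self.model == "sbf-ml" else "equal"

    def frequencies(self) -> np.ndarray:
        f = make_frequencies(self.bank)
        if self.resolved_sampling() == "stratified":
            jitter_rng = np.random.default_rng([self.master_seed, 0x5BF])
            f = f + jitter_rng.random(self.bank.n_osc) * self.bank.df
        return f


@dataclass
class ExperimentReport:
    """Per-(T, sigma, replicate) measurements plus the derived scalar fits."""

    table: pd.DataFrame
    fits: list[ScalarFit] = field(default_factory=list)
    skew_fit: QuadraticFit | None = None
    width_fit: ScalarFit | None = None
    metadata: dict = field(default_factory=dict)


def analysis_grid(T: float, n: int = 500, lo: float = 0.05, hi: float = 2.4):
    """Smooth-statistic grid on [lo*T, hi*T]; coarse on purpose.

    RMS/analytic traces are smooth on the scale of the output width, so a few
    hundred points suffice; the lower cut excludes the onset transient."""
    return np.linspace(lo * T, hi * T, n)


def _spawn(master_seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(master_seed).spawn(n)]


_ML_STATE_CACHE: dict = {}


def _ml_state_fn(config: ExperimentConfig, t_max: float):
    """Calibrate an ML bank and return an interpolating states callable.

    Calibration and the long bank integration are cached on (bank spec, ML
    params, horizon), so sweeps over noise levels reuse the same simulated
    states -- the noiseless bank dynamics do not depend on the noise.
    """
    sampling = config.resolved_sampling()
    seed_part = config.master_seed if sampling == "stratified" else None
    key = (config.bank, config.ml_params, round(t_max, 6), sampling, seed_part)
    if key in _ML_STATE_CACHE:
        return _ML_STATE_CACHE[key]
    freqs = config.frequencies()
    bank = calibrate_bank(freqs, config.ml_params)
    grid = np.linspace(0.0, t_max, max(2, int(t_max * 500)))  # 2 ms resolution
    states = ml_states(bank, grid, amplitude=config.bank.amplitude)

    def states_at(ts: np.ndarray) -> np.ndarray:
        ts = np.asarray(ts, dtype=float)
        out = np.empty((states.shape[0], ts.size))
        for i in range(states.shape[0]):
            out[i] = np.interp(ts, grid, states[i])
        return out

    _ML_STATE_CACHE[key] = (states_at, bank)
    return states_at, bank


def run_noiseless(config: ExperimentConfig) -> ExperimentReport:
    """Noiseless output widths across criteria.

    The envelope of the oscillatory output is extracted (analytic-signal
    magnitude) and its half-height width measured; for the sine bank the width
    is also compared with the closed-form envelope prediction.
    """
    if config.noise_target != "none":
        raise ValidationError("run_noiseless requires noise_target='none'")
    freqs = make_frequencies(config.bank)
    rows = []
    states_at = None
    if config.model == "sbf-ml":
        states_at, _ = _ml_state_fn(config, 3.0 * max(config.criteria))
    for T in config.criteria:
        grid = default_time_grid(T, config.bank.f_max)
        if config.model == "sbf-sin":
            memory = encode_reference(freqs, T)
            trace = probe_output(memory, freqs, config.bank.amplitude, grid)
        else:
            S = states_at(grid)
            Sc = S - S.mean(axis=1, keepdims=True)
            w = Sc[:, np.argmin(np.abs(grid - T))]
            w = w / np.max(np.abs(w))
            trace = OutputTrace(grid, w @ Sc)
        # window around the trained criterion: excludes the onset transient
        # and (for harmonic-rich ML banks) the commensurate-phase echo at 2T
        env = upper_envelope(trace, method="hilbert").restricted(0.25 * T, 1.75 * T)
        pc = half_width_points(env)
        gf = fit_gaussian(env)
        rows.append(
            {
                "T": T,
                "width": pc.fwhm,
                "sigma_env": gf.sigma,  # Gaussian fit of the envelope
                "t_peak": pc.t_peak,
                "predicted_width": noiseless_width(config.bank)
                if config.model == "sbf-sin"
                else np.nan,
                "seed": config.master_seed,
            }
        )
    table = pd.DataFrame(rows)
    spread = float(np.ptp(table["width"])) / float(np.mean(table["width"]))
    return ExperimentReport(
        table=table,
        metadata={
            "experiment": "noiseless",
            "model": config.model,
            "relative_width_spread": spread,
            "master_seed": config.master_seed,
        },
    )


def _one_noisy_trace(
    config: ExperimentConfig,
    T: float,
    rng: np.random.Generator,
    states_at=None,
) -> OutputTrace:
    grid = analysis_grid(T, config.n_grid)
    freqs = config.frequencies()
    if config.noise_target == "criterion":
        if config.model == "sbf-sin":
            return rms_output(
                freqs, T, grid, config.noise, config.n_fi_trials, rng,
                amplitude=config.bank.amplitude,
            )
        return rms_output_from_states(
            states_at, T, grid, config.noise, config.n_fi_trials, rng
        )
    # frequency noise: noiseless weights, shared clock-speed multiplier per
    # probe trial, RMS across trials
    if config.model == "sbf-sin":
        memory = encode_reference(freqs, T)
        return probe_output(
            memory, freqs, config.bank.amplitude, grid, config.noise,
            config.n_probe_trials, rng, mode="shared", average="rms",
        )
    # ML frequency noise: rescale the probe time axis per trial (equivalent
    # to co-modulating all bias currents through the inverse f-I map)
    S0 = states_at(grid)
    offset = S0.mean(axis=1)
    w = states_at(np.array([T]))[:, 0] - offset
    w = w / np.max(np.abs(w))
    from .core import sample_multipliers

    factors = sample_multipliers(config.noise, config.n_probe_trials, rng)
    acc = np.zeros(grid.shape)
    for fac in factors:
        acc += (w @ (states_at(fac * grid) - offset[:, None])) ** 2
    vals = np.sqrt(acc / len(factors)) / len(w)
    return OutputTrace(grid, vals, {"criterion": T, "model": "sbf-ml"})


def _smoothed(trace: OutputTrace, frac: float = 0.05) -> OutputTrace:
    """Hann-window moving average over ``frac`` of the grid length.

    Used before peak/half-width localization on Monte-Carlo traces, where a
    single noisy sample can otherwise masquerade as the peak; the Gaussian
    fit itself is least-squares and needs no smoothing.
    """
    n = max(3, int(len(trace.values) * frac) | 1)
    win = np.hanning(n + 2)[1:-1]
    win /= win.sum()
    pad = n // 2
    padded = np.pad(trace.values, pad, mode="edge")
    sm = np.convolve(padded, win, mode="valid")
    return OutputTrace(trace.times, sm[: len(trace.values)], dict(trace.metadata))


def _subtract_pedestal(trace: OutputTrace, q: float = 10.0) -> OutputTrace:
    """Remove the incoherent-variance floor from an RMS trace.

    The mean-square output is the coherent coincidence term plus a flat
    variance pedestal (noticeable for small banks); subtracting the lower
    percentile of the squared trace before taking the root recovers the
    coherent Gaussian-like shape.
    """
    ms = trace.values**2
    floor = np.percentile(ms, q)
    return OutputTrace(
        trace.times, np.sqrt(np.clip(ms - floor, 0.0, None)), dict(trace.metadata)
    )


def run_scalar_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Width-versus-criterion regressions under criterion or frequency noise.

    For each replicate and criterion T the trial-averaged (RMS) output --
    with its incoherent pedestal removed -- is fitted with a Gaussian
    (window at 10% of max); the fitted sigma is regressed on T.  Returns one
    :class:`ScalarFit` per replicate and the full measurement table.
    """
    if config.noise_target not in ("criterion", "frequency"):
        raise ValidationError("scalar experiment needs criterion or frequency noise")
    rngs = _spawn(config.master_seed, config.replicates * len(config.criteria))
    states_at = None
    if config.model == "sbf-ml":
        t_max = 2.5 * max(config.criteria)
        if config.noise_target == "frequency":
            # clock-speed multipliers stretch the probed time axis
            t_max = 2.4 * max(config.criteria) * (1.0 + 4.0 * config.noise.sigma)
        states_at, _ = _ml_state_fn(config, t_max)
    rows = []
    fits = []
    k = 0
    for rep in range(config.replicates):
        pairs = []
        for T in config.criteria:
            rng = rngs[k]
            k += 1
            try:
                trace = _subtract_pedestal(_one_noisy_trace(config, T, rng, states_at))
                pc = half_width_points(_smoothed(trace))
                if config.model == "sbf-sin":
                    # light smoothing (2% span) removes carrier-commensurate
                    # ripple (e.g. the Poisson criterion lattice) at a width
                    # bias well below 1%
                    gf = fit_gaussian(_smoothed(trace, frac=0.02))
                    width, t_peak, fit_r2 = gf.sigma, gf.mu, gf.r2
                else:
                    # half-height width is robust to the echo/plateau
                    # structure of small biophysical banks; 2.3548 converts
                    # FWHM to the Gaussian-equivalent sigma
                    width = pc.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
                    t_peak, fit_r2 = pc.t_peak, np.nan
            except Exception as exc:  # annotate failures with (T, sigma) context
                raise RuntimeError(
                    f"{exc} (T={T}, sigma={config.noise.sigma}, replicate={rep})"
                ) from exc
            rows.append(
                {
                    "replicate": rep,
                    "T": T,
                    "sigma": config.noise.sigma,
                    "width": width,
                    "t_peak": t_peak,
                    "fit_r2": fit_r2,
                    "skew_ratio": pc.skew_ratio,
                    "stream": k - 1,
                }
            )
            pairs.append((T, width))
        fits.append(scalar_regression(pairs))
    table = pd.DataFrame(rows)
    slopes = np.array([f.slope for f in fits])
    return ExperimentReport(
        table=table,
        fits=fits,
        metadata={
            "experiment": "scalar",
            "model": config.model,
            "noise_target": config.noise_target,
            "distribution": config.noise.distribution,
            "sigma": config.noise.sigma,
            "width_convention": "gaussian_fit_sigma"
            if config.model == "sbf-sin" else "fwhm_over_2.3548",
            "slope_mean": float(slopes.mean()),
            "slope_sd": float(slopes.std(ddof=1)) if len(slopes) > 1 else 0.0,
            "master_seed": config.master_seed,
        },
    )


def fig5_ratio_and_width(sigma_f: float, T: float = 10.0, n_grid: int = 400_000):
    """Half-width ratio and normalized half-height width of the unbounded-band
    frequency-noise closed form at one sigma_f."""
    t = np.linspace(1e-4 * T, 8.0 * T, n_grid)
    trace = frequency_output_infinite(T, sigma_f, t)
    pc = half_width_points(trace, normalize_time=True)
    return pc.skew_ratio, pc.fwhm


def run_fig5_sweep(
    sigmas: np.ndarray | None = None,
    T: float = 10.0,
    width_max_sigma: float = 0.5,
    n_grid: int = 400_000,
) -> ExperimentReport:
    """Analytic frequency-noise sweep: skewness quadratic and width line.

    Evaluates the unbounded-band closed form over a sigma_f grid in [0, 1],
    measures the half-height geometry in normalized time t/t_peak, fits the
    half-width ratio with a quadratic in sigma_f, and fits the half-height
    width with a line on sigma_f < ``width_max_sigma``.  At sigma_f = 0 the
    output is symmetric and the ratio is exactly 1 (set directly).
    """
    if sigmas is None:
        sigmas = np.linspace(0.0, 1.0, 101)
    sigmas = np.asarray(sigmas, dtype=float)
    if np.any(sigmas < 0) or np.any(sigmas > 1):
        raise ValidationError("sigma_f grid must lie within [0, 1]")
    rows = []
    for s in sigmas:
        if s == 0.0:
            rows.append({"sigma_f": 0.0, "skew_ratio": 1.0, "width_norm": np.nan})
            continue
        ratio, width = fig5_ratio_and_width(s, T, n_grid)
        rows.append({"sigma_f": s, "skew_ratio": ratio, "width_norm": width})
    table = pd.DataFrame(rows)
    skew_fit = skew_quadratic_fit(table["sigma_f"], table["skew_ratio"])
    wmask = (table["sigma_f"] > 0) & (table["sigma_f"] < width_max_sigma)
    width_fit = width_linear_fit(
        table.loc[wmask, "sigma_f"], table.loc[wmask, "width_norm"]
    )
    return ExperimentReport(
        table=table,
        skew_fit=skew_fit,
        width_fit=width_fit,
        metadata={"experiment": "fig5_sweep", "T": T},
    )


def generate_fixtures(out_dir: str | Path, seed: int = 0) -> list[Path]:
    """Write a small deterministic fixture set; byte-identical given a seed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = OscillatorBankSpec(n_osc=16, f_min=8.0, f_max=12.0)
    freqs = make_frequencies(spec)
    T = 2.0
    grid = default_time_grid(T, spec.f_max)

    rng_mem, rng_freq = _spawn(seed, 2)
    paths = []

    bank_path = out_dir / "bank.csv"
    pd.DataFrame({"oscillator_id": np.arange(spec.n_osc), "f_hz": freqs}).to_csv(
        bank_path, index=False, float_format="%.12g"
    )
    sbf_io.write_json(
        {"n_osc": spec.n_osc, "f_min": spec.f_min, "f_max": spec.f_max,
         "amplitude": spec.amplitude, "seed": seed},
        bank_path.with_suffix(".csv.meta.json"),
    )
    paths.append(bank_path)

    noise_T = NoiseSpec("gaussian", 0.1)
    memory = encode_reference(freqs, T, n_trials=200, noise=noise_T, rng=rng_mem)
    mem_path = out_dir / "memory.csv"
    sbf_io.write_memory(memory, mem_path)
    paths.append(mem_path)

    clean = probe_output(encode_reference(freqs, T), freqs, 1.0, grid)
    clean.metadata |= {"fixture": "noiseless", "seed": seed}
    sbf_io.write_trace(clean, out_dir / "trace_noiseless.csv")
    paths.append(out_dir / "trace_noiseless.csv")

    crit = rms_output(freqs, T, analysis_grid(T, 300), noise_T, n_trials=300,
                      rng=np.random.default_rng(seed + 1))
    crit.metadata |= {"fixture": "criterion_noise", "seed": seed}
    sbf_io.write_trace(crit, out_dir / "trace_criterion.csv")
    paths.append(out_dir / "trace_criterion.csv")

    fnoise = NoiseSpec("gaussian", 0.1)
    fmem = encode_reference(freqs, T)
    ftrace = probe_output(fmem, freqs, 1.0, analysis_grid(T, 300), fnoise,
                          n_probe_trials=200, rng=rng_freq, mode="shared",
                          average="rms")
    ftrace.metadata |= {"fixture": "frequency_noise", "seed": seed}
    sbf_io.write_trace(ftrace, out_dir / "trace_frequency.csv")
    paths.append(out_dir / "trace_frequency.csv")
    return paths
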