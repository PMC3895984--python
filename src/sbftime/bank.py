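"""Sine-wave oscillator banks.

The cortical input population of the striatal beat frequency (SBF) circuit is
modelled, in its simplest form, as a bank of phase oscillators whose membrane
potential is a pure cosine, ``v_i(t) = a * cos(2 pi f_i t)``.  All oscillators
are phase-aligned at stimulus onset (t = 0), mimicking the reset of cortical
oscillations at trial start.  Frequencies are equally spaced across a band
``[f_min, f_max)``; the default band in all experiments is the cortical alpha
band, 8-12 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError

__all__ = ["OscillatorBankSpec", "ALPHA_BAND", "make_frequencies", "sine_states"]


@dataclass(frozen=True)
class OscillatorBankSpec:
    """Specification of the input oscillator population.

    Parameters
    ----------
    n_osc
        Number of input oscillators (N_in).
    f_min, f_max
        Frequency band edges in Hz.  Oscillator k gets
        ``f_k = f_min + k * df`` with ``df = (f_max - f_min) / n_osc``,
        so the grid covers ``[f_min, f_max - df]``.
    amplitude
        Oscillation amplitude ``a`` (dimensionless membrane-potential units).
    """

    n_osc: int
    f_min: float
    f_max: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.n_osc < 1:
            raise ValidationError(f"n_osc must be >= 1, got {self.n_osc}")
        if not self.f_min > 0:
            raise ValidationError(f"f_min must be > 0, got {self.f_min}")
        if not self.f_max > self.f_min:
            raise ValidationError(
                f"f_max must exceed f_min, got ({self.f_min}, {self.f_max})"
            )
        if not self.amplitude > 0:
            raise ValidationError(f"amplitude must be > 0, got {self.amplitude}")

    @property
    def df(self) -> float:
        """Frequency spacing in Hz."""
        return (self.f_max - self.f_min) / self.n_osc

    def frequencies(self) -> np.ndarray:
        return make_frequencies(self)


#: The standard alpha-band bank used throughout: 1000 oscillators on 8-12 Hz.
ALPHA_BAND = OscillatorBankSpec(n_osc=1000, f_min=8.0, f_max=12.0)


def make_frequencies(spec: OscillatorBankSpec) -> np.ndarray:
    """Equally spaced oscillator frequencies ``f_k = f_min + k df``, k = 0..N-1.

    The grid is strictly increasing and lies entirely below ``f_max``.
    """
    k = np.arange(spec.n_osc)
    return spec.f_min + k * spec.df


def sine_states(
    freqs: np.ndarray, amplitude: float, t: float | np.ndarray
) -> np.ndarray:
    """Oscillator states ``a * cos(2 pi f_i t)``.

    For scalar ``t`` returns shape ``(n_osc,)``; for an array of times returns
    shape ``(n_osc, n_t)``.
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.isscalar(t) or np.ndim(t) == 0:
        return amplitude * np.cos(2.0 * np.pi * freqs * float(t))
    t = np.asarray(t, dtype=float)
    return amplitude * np.cos(2.0 * np.pi * np.outer(freqs, t))
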