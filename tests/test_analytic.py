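import numpy as np
import pytest

from sbftime import (
    NoiseSpec,
    OscillatorBankSpec,
    criterion_output_finite,
    criterion_output_infinite,
    encode_reference,
    frequency_output_finite,
    frequency_output_infinite,
    frequency_peak_time,
    make_frequencies,
    noiseless_envelope,
    noiseless_output,
    noiseless_width,
    predicted_peak,
    probe_output,
)
from sbftime.metrics import fit_gaussian, half_width_points, scalar_regression


class TestNoiselessForm:
    def test_envelope_peak_limit(self, alpha_small):
        """At t = T the Dirichlet-type envelope tends to N/2."""
        env = noiseless_envelope(alpha_small, 10.0, np.array([10.0]))
        assert env[0] == pytest.approx(alpha_small.n_osc / 2)

    def test_envelope_zeros(self, alpha_small):
        b0 = np.pi * (alpha_small.f_max - alpha_small.f_min)
        T = 10.0
        zeros = T + np.array([1, 2, -1, 5]) * np.pi / b0
        env = noiseless_envelope(alpha_small, T, zeros)
        assert np.max(np.abs(env)) < 1e-9 * alpha_small.n_osc

    def test_matches_brute_force_sum(self, alpha_small):
        f = make_frequencies(alpha_small)
        T = 3.0
        t = np.linspace(0.01, 3 * T, 3000)
        w = np.cos(2 * np.pi * f * T)
        brute = (w / np.max(np.abs(w))) @ np.cos(2 * np.pi * np.outer(f, t))
        ana = noiseless_output(alpha_small, T, t)
        assert np.max(np.abs(ana.values - brute)) / np.max(np.abs(brute)) < 1e-8


class TestNoiselessWidth:
    def test_independent_of_criterion(self, alpha_small):
        w10 = noiseless_width(alpha_small, 10.0)
        w30 = noiseless_width(alpha_small, 30.0)
        assert abs(w10 - w30) / w30 < 1e-6

    def test_inverse_band_scaling(self):
        """Doubling the band halves the width."""
        w1 = noiseless_width(OscillatorBankSpec(500, 8.0, 12.0))
        w2 = noiseless_width(OscillatorBankSpec(500, 8.0, 16.0))
        assert abs(w1 / w2 - 2.0) < 0.01

    def test_saturates_in_population_size(self):
        widths = [
            noiseless_width(OscillatorBankSpec(n, 8.0, 12.0))
            for n in (100, 1000, 10000)
        ]
        assert np.ptp(widths) / widths[-1] < 0.01


class TestCriterionNoiseForms:
    def test_infinite_band_accurate_symmetric_scalar(self):
        T, sig = 10.0, 0.1
        # grid symmetric about T so the even symmetry is testable exactly
        t = T + np.linspace(-0.9 * T, 0.9 * T, 6001)
        tr = criterion_output_infinite(T, sig, t)
        assert t[np.argmax(tr.values)] == pytest.approx(T, abs=t[1] - t[0])
        gf = fit_gaussian(tr)
        assert abs(gf.sigma - T * sig) / (T * sig) < 1e-3
        pc = half_width_points(tr)
        assert pc.skew_ratio == pytest.approx(1.0, abs=1e-6)

    def test_finite_band_wide_band_limit(self):
        T, sig = 2.0, 0.05
        t = np.linspace(0.01, 3 * T, 2000)
        wide = OscillatorBankSpec(1000, 1e-4, 400.0)
        a = criterion_output_finite(wide, T, sig, t).normalized()
        b = criterion_output_infinite(T, sig, t).normalized()
        assert np.max(np.abs(a.values - b.values)) < 1e-3

    def test_matches_monte_carlo_weights(self, alpha_small, rng):
        """The finite-band form is the large-trial limit of noisy encoding."""
        f = make_frequencies(OscillatorBankSpec(1000, 8.0, 12.0))
        spec = OscillatorBankSpec(1000, 8.0, 12.0)
        T, sig = 1.0, 0.02
        t = np.linspace(0.05, 3 * T, 1200)
        mem = encode_reference(f, T, 10**5, NoiseSpec("gaussian", sig), rng)
        mc = probe_output(mem, f, 1.0, t).normalized()
        ana = criterion_output_finite(spec, T, sig, t).normalized()
        assert np.max(np.abs(mc.values - ana.values)) < 0.02

    def test_width_scales_linearly_with_criterion(self):
        """Gaussian-fit sigma vs T: the scalar property of the closed form.

        The band must contain the damping support (~1/(2 pi T sigma_T) Hz)
        for the coherent output to keep its Gaussian shape, so the band
        reaches (near) zero here."""
        sig = 0.1
        spec = OscillatorBankSpec(1200, 0.01, 12.0)
        pairs = []
        for T in (5.0, 10.0, 20.0, 30.0):
            t = np.linspace(max(0.01, T - 6 * T * sig), T + 6 * T * sig, 3000)
            tr = criterion_output_finite(spec, T, sig, t)
            pairs.append((T, fit_gaussian(tr).sigma))
        fit = scalar_regression(pairs)
        assert fit.r2 > 0.999
        assert fit.slope == pytest.approx(sig, rel=0.15)


class TestFrequencyNoiseForms:
    def test_peak_formula_values(self):
        assert predicted_peak("frequency", 10.0, sigma=0.1).peak_time == pytest.approx(
            9.90099, abs=1e-4
        )
        assert predicted_peak("frequency", 30.0, sigma=0.2).peak_time == pytest.approx(
            30 / 1.04, abs=1e-9
        )
        assert predicted_peak("criterion", 7.0, sigma=0.3).peak_time == 7.0
        assert predicted_peak("frequency", 7.0, gamma=0.0).peak_time == 7.0

    def test_measured_peak_near_prediction(self):
        """Argmax of the long-tailed form is within a grid step of T/(1+s^2).

        The prediction holds to O(sigma_f^4 T), so it is exact at the
        resolution of a standard peak-localization grid (250 points over the
        probe span); the exact argmax formula is grid-independent."""
        T = 10.0
        t = np.linspace(0.01, 3 * T, 251)
        for sig in (0.1, 0.2, 0.3):
            tr = frequency_output_infinite(T, sig, t)
            t_peak = t[np.argmax(tr.values)]
            assert abs(t_peak - T / (1 + sig**2)) <= t[1] - t[0]
            assert abs(t_peak - frequency_peak_time(T, sig)) <= t[1] - t[0]
            # residual of the small-noise prediction is O(sigma^4 T)
            assert abs(frequency_peak_time(T, sig) - T / (1 + sig**2)) \
                <= 1.1 * T * sig**4

    def test_long_right_tail(self):
        T = 10.0
        t = np.linspace(0.01, 8 * T, 200_000)
        pc = half_width_points(frequency_output_infinite(T, 0.2, t))
        assert pc.tau2 > pc.tau1

    def test_skewness_increases_with_noise(self):
        T = 10.0
        t = np.linspace(0.01, 8 * T, 200_000)
        ratios = [
            half_width_points(frequency_output_infinite(T, s, t)).skew_ratio
            for s in (0.05, 0.1, 0.2, 0.3, 0.4, 0.5)
        ]
        assert np.all(np.diff(ratios) > 0)
        assert ratios[0] > 1.0

    def test_finite_band_wide_band_limit(self):
        T, sig = 5.0, 0.2
        t = np.linspace(0.05, 3 * T, 2000)
        wide = OscillatorBankSpec(4000, 1e-4, 400.0)
        a = frequency_output_finite(wide, T, sig, t).normalized()
        b = frequency_output_infinite(T, sig, t).normalized()
        assert np.max(np.abs(a.values - b.values)) < 1e-3

    def test_matches_monte_carlo_probe(self, rng):
        """Finite-band form equals the large-n probe average (alpha band).

        Regime chosen so the coherent expectation is resolvable:
        f * sigma_f * T ~ 0.2 cycles of phase spread."""
        spec = OscillatorBankSpec(400, 8.0, 12.0)
        f = make_frequencies(spec)
        T, sig = 1.0, 0.02
        t = np.linspace(0.05, 3 * T, 600)
        mem = encode_reference(f, T)
        mc = probe_output(mem, f, 1.0, t, NoiseSpec("gaussian", sig),
                          n_probe_trials=4000, rng=rng).normalized()
        ana = frequency_output_finite(spec, T, sig, t).normalized()
        assert np.max(np.abs(mc.values - ana.values)) < 0.05


class TestSymmetryDichotomy:
    def test_criterion_symmetric_frequency_skewed(self):
        T = 10.0
        t = np.linspace(0.01, 5 * T, 100_000)
        sym = half_width_points(criterion_output_infinite(T, 0.2, t))
        skew = half_width_points(frequency_output_infinite(T, 0.2, t))
        assert sym.skew_ratio == pytest.approx(1.0, abs=1e-4)
        assert skew.skew_ratio > 1.3
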