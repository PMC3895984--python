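import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sbftime import (
    NoiseSpec,
    OscillatorBankSpec,
    default_time_grid,
    encode_reference,
    make_frequencies,
    noiseless_output,
    probe_output,
    rms_output,
    sample_multipliers,
)
from sbftime.exceptions import ValidationError


class TestSampleMultipliers:
    def test_no_noise_is_exactly_one(self):
        assert np.all(sample_multipliers(NoiseSpec(), 100) == 1.0)

    def test_gaussian_moments_at_large_n(self, rng):
        m = sample_multipliers(NoiseSpec("gaussian", 0.1), 10**5, rng)
        assert 0.099 <= m.std() <= 0.101
        assert abs(m.mean() - 1.0) < 3 * 0.1 / np.sqrt(10**5)

    def test_uniform_support(self, rng):
        m = sample_multipliers(NoiseSpec("uniform", 0.1), 10**4, rng)
        half = np.sqrt(3) * 0.1
        assert np.all(m >= 1 - half) and np.all(m <= 1 + half)
        assert abs(m.std() - 0.1) < 3 * 0.1 / np.sqrt(10**4)

    def test_poisson_moments(self, rng):
        m = sample_multipliers(NoiseSpec("poisson", 0.2), 10**5, rng)
        assert abs(m.mean() - 1.0) < 3 * 0.2 / np.sqrt(10**5)
        assert abs(m.std() - 0.2) < 0.01

    def test_unknown_distribution_rejected(self):
        with pytest.raises(ValidationError):
            NoiseSpec("lognormal", 0.1)

    def test_reproducible_given_seed(self):
        a = sample_multipliers(NoiseSpec("gaussian", 0.1, seed=7), 100)
        b = sample_multipliers(NoiseSpec("gaussian", 0.1, seed=7), 100)
        np.testing.assert_array_equal(a, b)


class TestEncodeReference:
    def test_noiseless_single_trial(self, alpha_small):
        f = make_frequencies(alpha_small)
        mem = encode_reference(f, T=3.0)
        expected = np.cos(2 * np.pi * f * 3.0)
        np.testing.assert_allclose(
            mem.weights, expected / np.max(np.abs(expected)), atol=1e-12
        )
        assert np.max(np.abs(mem.weights)) == pytest.approx(1.0)

    def test_zero_criterion_gives_unit_weights(self, alpha_small):
        mem = encode_reference(make_frequencies(alpha_small), T=0.0)
        np.testing.assert_allclose(mem.weights, 1.0)

    def test_weight_bound_holds_under_noise(self, alpha_small, rng):
        mem = encode_reference(
            make_frequencies(alpha_small), 2.0, 500, NoiseSpec("gaussian", 0.1), rng
        )
        assert np.max(np.abs(mem.weights)) == pytest.approx(1.0)
        assert np.all(np.abs(mem.weights) <= 1.0)

    def test_gaussian_damping_closed_form(self, rng):
        """Mean weights converge to cos(2 pi f T) exp(-2 pi^2 f^2 T^2 s^2).

        Monte-Carlo oracle at n = 1e5 FI trials, in a regime where the
        damping factor is appreciable (f T sigma ~ 0.1)."""
        f = make_frequencies(OscillatorBankSpec(50, 8.0, 12.0))
        T, sig = 0.25, 0.05
        n = 10**5
        mem = encode_reference(f, T, n, NoiseSpec("gaussian", sig), rng)
        expected = np.cos(2 * np.pi * f * T) * np.exp(
            -2 * np.pi**2 * f**2 * T**2 * sig**2
        )
        expected /= np.max(np.abs(expected))
        # per-weight MC standard error is ~ 1/sqrt(2 n) before normalization
        assert np.max(np.abs(mem.weights - expected)) < 6.0 / np.sqrt(2 * n)


class TestProbeOutput:
    def test_noiseless_peak_at_criterion(self, alpha_small):
        f = make_frequencies(alpha_small)
        T = 3.0
        grid = default_time_grid(T, alpha_small.f_max)
        trace = probe_output(encode_reference(f, T), f, 1.0, grid)
        mask = grid > 0.2 * T
        assert grid[mask][np.argmax(trace.values[mask])] == pytest.approx(
            T, abs=grid[1] - grid[0]
        )

    def test_matches_noiseless_closed_form(self, alpha_small):
        f = make_frequencies(alpha_small)
        T = 3.0
        grid = default_time_grid(T, alpha_small.f_max)[1:]
        sim = probe_output(encode_reference(f, T), f, 1.0, grid)
        ana = noiseless_output(alpha_small, T, grid)
        scale = np.max(np.abs(ana.values))
        assert np.max(np.abs(sim.values - ana.values)) / scale < 1e-8

    def test_linearity_in_weights(self, alpha_small):
        f = make_frequencies(alpha_small)
        grid = np.linspace(0.1, 6.0, 500)
        mem = encode_reference(f, 2.0)
        base = probe_output(mem, f, 1.0, grid)
        mem.weights = 2.0 * mem.weights
        doubled = probe_output(mem, f, 1.0, grid)
        np.testing.assert_allclose(doubled.values, 2.0 * base.values, rtol=1e-12)

    def test_positive_weight_variant_same_peak(self, alpha_small):
        """Signed and positively defined weights peak at the same place."""
        f = make_frequencies(alpha_small)
        T = 3.0
        grid = default_time_grid(T, alpha_small.f_max)
        mask = grid > 0.2 * T
        peaks = []
        for variant in ("signed", "positive"):
            mem = encode_reference(f, T, variant=variant)
            tr = probe_output(mem, f, 1.0, grid)
            peaks.append(grid[mask][np.argmax(tr.values[mask])])
        assert abs(peaks[0] - peaks[1]) <= grid[1] - grid[0] + 1e-12

    def test_empty_grid_rejected(self, alpha_small):
        f = make_frequencies(alpha_small)
        with pytest.raises(ValidationError):
            probe_output(encode_reference(f, 2.0), f, 1.0, np.array([]))

    def test_monte_carlo_convergence_rate(self, rng):
        """Sup-norm distance to the exact expectation shrinks ~ n^(-1/2).

        Oracle: the exact per-oscillator expectation of the frequency-noise
        trace, cos(2 pi f t) damped by exp(-2 pi^2 f^2 sigma^2 t^2)."""
        spec = OscillatorBankSpec(100, 8.0, 12.0)
        f = make_frequencies(spec)
        T, sig = 1.0, 0.05
        grid = np.linspace(0.05, 2.5, 200)
        mem = encode_reference(f, T)
        damp = np.exp(-2 * np.pi**2 * np.outer(f**2, grid**2) * sig**2)
        exact = ((mem.weights[:, None] * damp) *
                 np.cos(2 * np.pi * np.outer(f, grid))).sum(axis=0)
        scale = np.max(np.abs(exact))
        dists = []
        for n in (100, 1000, 10000):
            tr = probe_output(mem, f, 1.0, grid, NoiseSpec("gaussian", sig),
                              n_probe_trials=n, rng=rng)
            dists.append(np.max(np.abs(tr.values - exact)) / scale)
        assert dists[1] < 0.62 * dists[0]
        assert dists[2] < 0.62 * dists[1]


class TestRmsOutput:
    def test_peak_and_width_under_criterion_noise(self, rng):
        """RMS trace peaks near T with Gaussian width ~ sqrt(2) T sigma."""
        from sbftime.metrics import fit_gaussian

        f = make_frequencies(OscillatorBankSpec(200, 8.0, 12.0))
        T, sig = 5.0, 0.1
        grid = np.linspace(0.25, 12.0, 400)
        tr = rms_output(f, T, grid, NoiseSpec("gaussian", sig), 400, rng)
        gf = fit_gaussian(tr)
        assert abs(gf.mu - T) < 0.2
        assert abs(gf.sigma - np.sqrt(2) * T * sig) / (np.sqrt(2) * T * sig) < 0.25


@given(seed=st.integers(0, 2**31 - 1))
@settings(max_examples=10, deadline=None)
def test_multiplier_mean_is_centred(seed):
    m = sample_multipliers(NoiseSpec("uniform", 0.3), 5000,
                           np.random.default_rng(seed))
    assert abs(m.mean() - 1.0) < 5 * 0.3 / np.sqrt(5000)
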