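"""EMD sifting, ensemble EMD, and the db4 wavelet baseline.

Brute-force and closed-form oracles: a three-point neighbour scan for
extrema, an independently solved natural-cubic-spline system for the
envelopes, and known tone separations for the decomposition itself.
"""

import numpy as np
import pytest

from eegmodes import SiftConfig, dwt_subbands, emd, eemd, envelope_mean, find_extrema
from eegmodes.decompose import (
    InsufficientExtremaError,
    _extend_mirrored,
    num_zero_crossings,
)


def brute_force_extrema(x):
    """Exhaustive three-point neighbour comparison (no plateaus)."""
    maxima, minima = [], []
    for i in range(1, len(x) - 1):
        if x[i] > x[i - 1] and x[i] > x[i + 1]:
            maxima.append(i)
        elif x[i] < x[i - 1] and x[i] < x[i + 1]:
            minima.append(i)
    return np.array(maxima), np.array(minima)


def natural_spline_eval(knots_x, knots_y, query):
    """Independent natural cubic spline: solve the tridiagonal system for
    the second derivatives directly, then evaluate piecewise."""
    x = np.asarray(knots_x, float)
    y = np.asarray(knots_y, float)
    n = len(x)
    h = np.diff(x)
    # interior equations: h[i-1] M[i-1] + 2(h[i-1]+h[i]) M[i] + h[i] M[i+1] = rhs
    a = np.zeros((n, n))
    rhs = np.zeros(n)
    a[0, 0] = a[-1, -1] = 1.0  # natural: M0 = Mn = 0
    for i in range(1, n - 1):
        a[i, i - 1] = h[i - 1]
        a[i, i] = 2 * (h[i - 1] + h[i])
        a[i, i + 1] = h[i]
        rhs[i] = 6 * ((y[i + 1] - y[i]) / h[i] - (y[i] - y[i - 1]) / h[i - 1])
    m = np.linalg.solve(a, rhs)
    out = np.empty(len(query))
    for j, q in enumerate(np.asarray(query, float)):
        i = np.clip(np.searchsorted(x, q) - 1, 0, n - 2)
        t = q - x[i]
        out[j] = (
            y[i]
            + t * ((y[i + 1] - y[i]) / h[i] - h[i] * (2 * m[i] + m[i + 1]) / 6)
            + t**2 * m[i] / 2
            + t**3 * (m[i + 1] - m[i]) / (6 * h[i])
        )
    return out


class TestFindExtrema:
    def test_single_period_sinusoid(self):
        t = np.linspace(0, 1, 200, endpoint=False)
        x = np.sin(2 * np.pi * t)
        mx, mn = find_extrema(x)
        assert len(mx) == 1 and len(mn) == 1
        assert abs(mx[0] - 50) <= 1 and abs(mn[0] - 150) <= 1

    def test_monotone_ramp_has_none(self):
        mx, mn = find_extrema(np.linspace(0, 1, 50))
        assert len(mx) == 0 and len(mn) == 0

    def test_matches_brute_force_on_random_series(self, rng):
        for _ in range(20):
            x = rng.standard_normal(50)
            mx, mn = find_extrema(x)
            bmx, bmn = brute_force_extrema(x)
            np.testing.assert_array_equal(mx, bmx)
            np.testing.assert_array_equal(mn, bmn)

    def test_plateau_midpoint(self):
        x = np.array([0.0, 1.0, 2.0, 2.0, 2.0, 1.0, 0.0, -1.0, 0.0])
        mx, mn = find_extrema(x)
        assert list(mx) == [3]  # midpoint of the flat top
        assert list(mn) == [7]

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            find_extrema(np.array([1.0, 2.0]))


class TestEnvelopeMean:
    def test_sinusoid_mean_near_zero(self):
        t = np.linspace(0, 6, 600, endpoint=False)
        x = np.sin(2 * np.pi * t)
        mx, mn = find_extrema(x)
        mean_env = envelope_mean(x, mx, mn)
        interior = slice(mx[0], mx[-1])
        assert np.max(np.abs(mean_env[interior])) < 0.05

    def test_translation_equivariance(self, rng):
        x = rng.standard_normal(120)
        mx, mn = find_extrema(x)
        base = envelope_mean(x, mx, mn)
        shifted = envelope_mean(x + 3.7, mx, mn)
        np.testing.assert_allclose(shifted, base + 3.7, atol=1e-10)

    def test_matches_independent_natural_spline(self, rng):
        x = rng.standard_normal(30)
        mx, mn = find_extrema(x)
        got = envelope_mean(x, mx, mn)
        grid = np.arange(len(x))
        envs = []
        for pos in (mx, mn):
            p, v = _extend_mirrored(pos, x[pos], len(x))
            envs.append(natural_spline_eval(p, v, grid))
        lo, hi = max(mx[0], mn[0]), min(mx[-1], mn[-1])
        np.testing.assert_allclose(
            got[lo:hi], 0.5 * (envs[0] + envs[1])[lo:hi], atol=1e-10
        )

    def test_too_few_extrema_signals_stop(self):
        x = np.linspace(0, 1, 50)
        with pytest.raises(InsufficientExtremaError):
            envelope_mean(x, np.array([10]), np.array([20, 30]))


class TestEMD:
    def test_pure_sinusoid_is_single_mode(self):
        t = np.arange(600) / 100.0
        x = np.sin(2 * np.pi * 5 * t)
        result = emd(x)
        rho = np.corrcoef(result.imfs[0], x)[0, 1]
        assert rho > 0.99
        assert np.linalg.norm(result.residue) < 0.01 * np.linalg.norm(x)

    def test_additivity_exact(self, rng):
        for _ in range(5):
            x = rng.standard_normal(1000)
            result = emd(x)
            err = np.linalg.norm(x - result.reconstruct()) / np.linalg.norm(x)
            assert err < 1e-8

    def test_two_tone_separation(self):
        t = np.arange(1000) / 100.0
        fast, slow = np.sin(2 * np.pi * 8 * t), np.sin(2 * np.pi * 0.5 * t)
        result = emd(fast + slow)
        assert np.corrcoef(result.imfs[0], fast)[0, 1] > 0.95
        assert np.corrcoef(result.imfs[1], slow)[0, 1] > 0.95

    def test_zero_crossing_count_decreases_with_imf_index(self):
        """IMF1 carries the fastest oscillations: zero-crossing counts
        strictly decrease down the IMF list on a seizure-like epoch."""
        from eegmodes import GeneratorConfig, generate_epoch

        epoch = generate_epoch("seizure", GeneratorConfig(seed=2, duration=20.0))
        result = emd(epoch.data[0])
        counts = [num_zero_crossings(imf) for imf in result.imfs]
        assert all(a > b for a, b in zip(counts, counts[1:]))

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            emd(np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError):
            emd(np.array([1.0, np.nan, 2.0, 3.0, 1.0]))

    def test_oscillation_property_on_random_signals(self, rng):
        satisfied = total = 0
        for _ in range(10):
            x = rng.standard_normal(1000)
            result = emd(x)
            for imf in result.imfs[:-1]:
                mx, mn = find_extrema(imf)
                total += 1
                satisfied += abs((len(mx) + len(mn)) - num_zero_crossings(imf)) <= 1
        assert satisfied / total >= 0.9


class TestEEMD:
    def test_degenerate_ensemble_equals_emd(self, rng):
        x = rng.standard_normal(400)
        config = SiftConfig(ensemble_size=1, noise_fraction=1e-12, seed=0)
        ensemble = eemd(x, config)
        plain = emd(x, config)
        assert len(ensemble) == len(plain)
        for a, b in zip(ensemble.imfs, plain.imfs):
            np.testing.assert_allclose(a, b, atol=1e-6)

    def test_determinism(self, rng):
        x = rng.standard_normal(300)
        config = SiftConfig(ensemble_size=5, seed=42)
        a, b = eemd(x, config), eemd(x, config)
        for ia, ib in zip(a.imfs, b.imfs):
            np.testing.assert_array_equal(ia, ib)
        np.testing.assert_array_equal(a.residue, b.residue)

    def test_averaging_is_linear(self, rng):
        """Mode count equals the max member count, and averaging two
        identical members reproduces the member."""
        x = rng.standard_normal(300)
        config = SiftConfig(ensemble_size=2, noise_fraction=1e-12, seed=1)
        ensemble = eemd(x, config)
        plain = emd(x, config)
        assert len(ensemble) == len(plain)
        for a, b in zip(ensemble.imfs, plain.imfs):
            np.testing.assert_allclose(a, b, atol=1e-6)


class TestDWT:
    def test_exactly_four_components(self, rng):
        sub = dwt_subbands(rng.standard_normal(512))
        names = [n for n, _ in sub.components()]
        assert names == ["A3", "D1", "D2", "D3"]

    def test_perfect_reconstruction(self, rng):
        x = rng.standard_normal(500)
        sub = dwt_subbands(x)
        np.testing.assert_allclose(
            sub.reconstruct(), x, rtol=0, atol=1e-8 * np.abs(x).max()
        )

    def test_impulse_energy_conservation(self):
        """Parseval for the orthonormal db4 transform, checked against the
        directly computed input energy of a unit impulse."""
        x = np.zeros(256)
        x[100] = 1.0
        sub = dwt_subbands(x)
        coeff_energy = sum(np.sum(c**2) for _, c in sub.components())
        assert abs(coeff_energy - 1.0) < 1e-8

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            dwt_subbands(np.ones(4))
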