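"""Morlet CWT, cross-wavelet transform, significance, phase filtering."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import locowave as lw
from oracles import morlet_cwt_direct

from conftest import make_spectrum, voices_off

RATE = 50.0


def _sine(freq, duration=100.0, rate=RATE, phase=0.0):
    t = np.arange(int(duration * rate)) / rate
    return np.sin(2 * np.pi * freq * t + phase)


complex_matrices = hnp.arrays(
    np.complex128, hnp.array_shapes(min_dims=2, max_dims=2, min_side=1, max_side=6),
    elements=st.complex_numbers(max_magnitude=1e6, allow_nan=False,
                                allow_infinity=False),
)


class TestCwt:
    def test_ridge_at_sinusoid_frequency(self, params):
        W = lw.cwt(_sine(0.5), RATE, params)
        ridge = W.freqs[np.argmax(np.abs(W.coeffs).mean(axis=1))]
        assert voices_off(ridge, 0.5) <= 1.0

    def test_zero_signal_zero_coefficients(self, params):
        W = lw.cwt(np.zeros(int(50 * RATE)), RATE, params)
        assert np.all(W.coeffs == 0)

    def test_short_record_rejected(self, params):
        with pytest.raises(ValueError, match="shorter"):
            lw.cwt(np.zeros(100), RATE, params)

    def test_matches_direct_convolution_oracle(self, rng):
        # n=256 at 50 Hz is 5.12 s; restrict the band so four periods fit
        params = lw.WaveletParams(fmin=1.0, fmax=5.0)
        x = rng.normal(size=256)
        x -= x.mean()
        W = lw.cwt(x, RATE, params)
        W_direct = morlet_cwt_direct(x, RATE, W.freqs, params.omega0)
        err = np.max(np.abs(W.coeffs - W_direct)) / np.max(np.abs(W_direct))
        assert err < 1e-6

    def test_white_noise_power_normalization(self, rng):
        # E|W|^2 must equal the signal variance at every scale (outside the
        # cone of influence); this is what the analytic significance
        # threshold assumes.  Averaged over realizations because low
        # frequencies have few independent coefficients per record.
        sigma = 2.5
        acc = None
        n_rep = 12
        for _ in range(n_rep):
            x = rng.normal(0, sigma, int(200 * RATE))
            W = lw.cwt(x, RATE)
            valid = W.outside_coi()
            pow_per_freq = np.array(
                [np.mean(np.abs(W.coeffs[i][valid[i]]) ** 2)
                 for i in range(0, W.freqs.size, 12)])  # one freq per octave
            acc = pow_per_freq if acc is None else acc + pow_per_freq
        np.testing.assert_allclose(acc / n_rep, sigma**2, rtol=0.15)


class TestXwt:
    def test_self_cross_has_zero_phase(self, params):
        W = lw.cwt(_sine(0.8), RATE, params)
        Wxx = lw.xwt(W, W)
        power = np.abs(Wxx.coeffs)
        np.testing.assert_allclose(Wxx.coeffs.imag[power > 0], 0, atol=1e-12)
        assert np.all(Wxx.coeffs.real >= 0)

    def test_half_period_delay_gives_180_degrees(self, params):
        x = _sine(0.5)
        y = _sine(0.5, phase=-np.pi)  # delayed by half a 2 s period
        Wxy = lw.xwt(lw.cwt(x, RATE, params), lw.cwt(y, RATE, params))
        i = np.argmin(np.abs(Wxy.freqs - 0.5))
        mid = slice(Wxy.times.size // 4, 3 * Wxy.times.size // 4)
        phases = np.degrees(np.angle(Wxy.coeffs[i, mid]))
        np.testing.assert_allclose(np.abs(phases), 180.0, atol=1.0)

    def test_zero_partner_gives_zero(self, params):
        W = lw.cwt(_sine(0.5), RATE, params)
        Z = W.replace(coeffs=np.zeros_like(W.coeffs))
        assert np.all(lw.xwt(W, Z).coeffs == 0)

    def test_axis_mismatch_rejected(self, params):
        W1 = lw.cwt(_sine(0.5, duration=60), RATE, params)
        W2 = lw.cwt(_sine(0.5, duration=80), RATE, params)
        with pytest.raises(ValueError):
            lw.xwt(W1, W2)

    def test_hermitian_symmetry(self, rng, params):
        Wx = lw.cwt(rng.normal(size=2500), RATE, params)
        Wy = lw.cwt(rng.normal(size=2500), RATE, params)
        np.testing.assert_allclose(lw.xwt(Wx, Wy).coeffs,
                                   np.conj(lw.xwt(Wy, Wx).coeffs), rtol=1e-12)


class TestNormalization:
    def test_joint_scaling_cancels(self, rng, params):
        x, y = rng.normal(size=(2, 3000))
        c = 3.7

        def normalized_xwt(a, b):
            s = lw.xwt(lw.cwt(a, RATE, params), lw.cwt(b, RATE, params))
            return lw.normalize_crossvariance(s, float(np.std(a)), float(np.std(b)))

        s1 = normalized_xwt(x, y)
        s2 = normalized_xwt(c * x, c * y)
        scale = np.max(np.abs(s1.coeffs))
        assert np.max(np.abs(s1.coeffs - s2.coeffs)) / scale < 1e-10
        assert s1.normalized

    def test_unit_sigmas_are_identity(self):
        spec = make_spectrum(np.eye(3) * (1 + 2j), ready=False)
        out = lw.normalize_crossvariance(spec, 1.0, 1.0)
        np.testing.assert_array_equal(out.coeffs, spec.coeffs)

    def test_zero_sigma_rejected(self):
        spec = make_spectrum(np.ones((2, 2)), ready=False)
        with pytest.raises(ValueError, match="degenerate|positive"):
            lw.normalize_crossvariance(spec, 0.0, 1.0)

    def test_double_normalization_rejected(self):
        spec = make_spectrum(np.ones((2, 2)), ready=False)
        out = lw.normalize_crossvariance(spec, 2.0, 3.0)
        with pytest.raises(ValueError, match="already"):
            lw.normalize_crossvariance(out, 2.0, 3.0)


class TestSignificance:
    def test_threshold_matches_chi_square_construction(self):
        # Z2(95%)/2 = 3.999/2 for the complex-wavelet white-noise background
        assert lw.white_noise_threshold(0.05) == pytest.approx(1.9995, abs=5e-4)

    def test_unnormalized_spectrum_rejected(self):
        spec = make_spectrum(np.ones((2, 2)), ready=False)
        with pytest.raises(ValueError, match="normalized"):
            lw.significance_mask(spec)

    def test_all_zero_spectrum_stays_empty(self, params):
        spec = make_spectrum(np.zeros((4, 8)), ready=False).replace(normalized=True)
        out = lw.significance_mask(spec, params)
        assert np.all(out.coeffs == 0) and not out.sig_mask.any()

    def test_common_rhythm_ridge_retained(self, params, rng):
        x = _sine(0.5) + 0.3 * rng.normal(size=5000)
        y = _sine(0.5, phase=-np.pi) + 0.3 * rng.normal(size=5000)
        s = lw.xwt(lw.cwt(x, RATE, params), lw.cwt(y, RATE, params))
        s = lw.significance_mask(
            lw.normalize_crossvariance(s, float(np.std(x)), float(np.std(y))), params)
        i = np.argmin(np.abs(s.freqs - 0.5))
        mid = slice(s.times.size // 4, 3 * s.times.size // 4)
        assert s.sig_mask[i, mid].mean() > 0.95

    def test_white_noise_retention_near_level(self):
        # small Monte-Carlo check; the full calibration runs in acceptance
        fr = lw.calibrate_significance(n_pairs=12, duration=100.0, seed=7)
        assert abs(fr.mean() - 0.05) < 0.015

    def test_coi_zero_policy_empties_edges(self, params, rng):
        p = lw.WaveletParams(coi_policy="zero")
        x, y = rng.normal(size=(2, 5000))
        s = lw.normalize_crossvariance(
            lw.xwt(lw.cwt(x, RATE, p), lw.cwt(y, RATE, p)),
            float(np.std(x)), float(np.std(y)))
        out = lw.significance_mask(s, p)
        assert not out.sig_mask[~out.outside_coi()].any()


class TestPhaseFilter:
    @pytest.mark.parametrize("angle_deg, kept", [
        (120.0, True),    # inclusive lower bound
        (240.0, True),    # inclusive upper bound
        (180.0, True),
        (0.0, False),
        (119.0, False),
        (241.0, False),
    ])
    def test_band_membership(self, angle_deg, kept, params):
        c = 2.0 * np.exp(1j * np.radians(angle_deg))
        out = lw.phase_filter(make_spectrum([[c]]), params)
        assert (out.coeffs[0, 0] != 0) == kept
        assert out.phase_filtered

    def test_all_at_180_is_identity(self, params):
        spec = make_spectrum(-np.ones((3, 5)) * 2.0)
        out = lw.phase_filter(spec, params)
        np.testing.assert_array_equal(out.coeffs, spec.coeffs)

    @given(complex_matrices)
    def test_idempotent(self, coeffs):
        spec = make_spectrum(coeffs, ready=False)
        once = lw.phase_filter(spec)
        twice = lw.phase_filter(once)
        np.testing.assert_array_equal(once.coeffs, twice.coeffs)

    @given(complex_matrices, st.floats(0.0, 360.0), st.floats(1.0, 179.0))
    def test_survivors_lie_in_band(self, coeffs, center, halfwidth):
        p = lw.WaveletParams(phase_center=center, phase_halfwidth=halfwidth)
        out = lw.phase_filter(make_spectrum(coeffs, ready=False), p)
        nz = out.coeffs[out.coeffs != 0]
        if nz.size:
            off = np.degrees(np.angle(nz * np.exp(-1j * np.radians(center))))
            assert np.all(np.abs(off) <= halfwidth + 1e-6)


class TestSummaries:
    def test_global_power_flat_spectrum(self):
        spec = make_spectrum(np.full((5, 10), 2.0 + 0j))
        _, power, _ = lw.global_power_spectrum(spec)
        np.testing.assert_allclose(power, 1.0)

    def test_global_power_single_bin_delta(self):
        coeffs = np.zeros((5, 10), complex)
        coeffs[3, 4] = 1j
        spec = make_spectrum(coeffs, freqs=np.geomspace(0.1, 1.6, 5))
        freqs, power, peak = lw.global_power_spectrum(spec)
        assert peak == pytest.approx(freqs[3])
        assert power[3] == 1.0 and np.sum(power) == 1.0

    def test_global_power_all_zero_flagged(self):
        _, _, peak = lw.global_power_spectrum(make_spectrum(np.zeros((3, 3))))
        assert np.isnan(peak)

    def test_phase_distribution_mean_at_180(self):
        spec = make_spectrum(-np.ones((2, 4)) * 3.0)
        _, _, mean_angle, rlen = lw.phase_distribution(spec)
        assert mean_angle == pytest.approx(180.0)
        assert rlen == pytest.approx(1.0)

    def test_antipodal_bins_cancel(self):
        coeffs = np.array([[2j, -2j]])  # 90 and 270 degrees, equal power
        _, _, _, rlen = lw.phase_distribution(make_spectrum(coeffs))
        assert rlen == pytest.approx(0.0, abs=1e-12)

    def test_empty_distribution_flagged(self):
        _, hist, mean_angle, _ = lw.phase_distribution(make_spectrum(np.zeros((2, 2))))
        assert np.isnan(mean_angle) and np.all(hist == 0)

    def test_ridge_constant_rhythm(self, params, rng):
        x = _sine(1.0) + 0.2 * rng.normal(size=5000)
        y = -_sine(1.0) + 0.2 * rng.normal(size=5000)
        s = lw.normalize_crossvariance(
            lw.xwt(lw.cwt(x, RATE, params), lw.cwt(y, RATE, params)),
            float(np.std(x)), float(np.std(y)))
        s = lw.phase_filter(lw.significance_mask(s, params), params)
        times, freq = lw.frequency_ridge(s)
        mid = (times > 10) & (times < 90)
        assert np.all(voices_off(freq[mid], 1.0) <= 1.0)

    def test_ridge_all_zero_is_all_gap(self):
        _, freq = lw.frequency_ridge(make_spectrum(np.zeros((3, 6))))
        assert np.all(np.isnan(freq))
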