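import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from powdercone import compute_Q, fit_circle, layer_std, spectrum, unwrap
from powdercone.spectrum import DeviationProfile, default_band

from conftest import cosine_contour


def profile_from_e(e, R=10.0):
    e = np.asarray(e, dtype=float)
    e = e - e.mean()
    M = len(e)
    theta = 2 * np.pi * np.arange(M) / M
    return DeviationProfile(layer_index=0, theta=theta, r=R - e, e=e, R=R)


class TestCircleFit:
    def test_four_axis_points(self):
        fit = fit_circle([(1, 0), (-1, 0), (0, 1), (0, -1)])
        assert fit.center == pytest.approx((0.0, 0.0), abs=1e-12)
        assert fit.R == pytest.approx(1.0, abs=1e-12)

    def test_exact_circle_recovered(self):
        theta = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        pts = np.column_stack([3 + 7 * np.cos(theta), -2 + 7 * np.sin(theta)])
        fit = fit_circle(pts)
        assert fit.center == pytest.approx((3.0, -2.0), abs=1e-9)
        assert fit.R == pytest.approx(7.0, abs=1e-9)
        assert fit.rms_residual < 1e-9

    def test_square_corners(self):
        fit = fit_circle([(1, 1), (-1, 1), (-1, -1), (1, -1)])
        assert fit.center == pytest.approx((0.0, 0.0), abs=1e-12)
        assert fit.R == pytest.approx(np.sqrt(2), abs=1e-12)

    def test_collinear_points_rejected(self):
        with pytest.raises(ValueError):
            fit_circle([(0, 0), (1, 1), (2, 2), (3, 3)])
        with pytest.raises(ValueError):
            fit_circle([(0, 0), (1, 1)])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        cx=st.floats(-50, 50),
        cy=st.floats(-50, 50),
        R=st.floats(0.1, 100),
        n=st.integers(5, 60),
    )
    def test_recovers_any_noiseless_circle(self, cx, cy, R, n):
        theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
        pts = np.column_stack([cx + R * np.cos(theta), cy + R * np.sin(theta)])
        fit = fit_circle(pts)
        assert np.hypot(fit.center[0] - cx, fit.center[1] - cy) < 1e-6 * max(1, R)
        assert abs(fit.R - R) < 1e-6 * max(1, R)


class TestUnwrap:
    def test_exact_circle_gives_zero_deviation(self):
        contour = cosine_contour(R=10.0, amp=0.0)
        fit = fit_circle(contour.points)
        profile = unwrap(contour, fit, M=128)
        assert np.max(np.abs(profile.e)) < 1e-9

    def test_cosine_contour_oracle(self):
        # r(theta) = 10 + 0.5 cos(4 theta)  =>  e(theta) = -0.5 cos(4 theta)
        contour = cosine_contour(R=10.0, amp=0.5, harmonic=4, n=720)
        fit = fit_circle(contour.points)
        profile = unwrap(contour, fit, M=512)
        assert np.max(np.abs(profile.e + 0.5 * np.cos(4 * profile.theta))) < 1e-3
        assert abs(np.mean(profile.e)) < 1e-9

    def test_non_power_of_two_grid_rejected(self):
        contour = cosine_contour()
        fit = fit_circle(contour.points)
        with pytest.raises(ValueError):
            unwrap(contour, fit, M=100)
        with pytest.raises(ValueError):
            unwrap(contour, fit, M=8)

    def test_profile_arrays_consistent(self):
        contour = cosine_contour(amp=0.3, harmonic=6)
        fit = fit_circle(contour.points)
        p = unwrap(contour, fit, M=256)
        assert len(p.theta) == len(p.r) == len(p.e) == 256
        assert p.perimeter == pytest.approx(2 * np.pi * fit.R)
        assert np.allclose(p.s, p.theta * fit.R)


class TestSpectrum:
    def test_zero_signal_zero_magnitudes(self):
        spec = spectrum(profile_from_e(np.zeros(128)))
        assert np.all(spec.mag == 0)

    def test_pure_cosine_single_bin(self):
        M = 512
        theta = 2 * np.pi * np.arange(M) / M
        spec = spectrum(profile_from_e(np.cos(8 * theta)))
        assert spec.mag[7] == pytest.approx(M / 2, rel=1e-12)  # k = 8
        others = np.delete(spec.mag, 7)
        assert np.max(others) < 1e-9

    def test_linearity_of_magnitudes(self):
        rng = np.random.default_rng(0)
        e = rng.normal(size=256)
        m1 = spectrum(profile_from_e(e)).mag
        m2 = spectrum(profile_from_e(2 * e)).mag
        assert np.allclose(m2, 2 * m1)

    def test_wavelength_axis(self):
        spec = spectrum(profile_from_e(np.zeros(64), R=5.0))
        assert np.all(np.diff(spec.lam) < 0)
        assert np.allclose(spec.beta, 1.0 / spec.lam)
        assert spec.lam[0] == pytest.approx(2 * np.pi * 5.0 / 1)

    def test_fft_matches_direct_dft(self):
        # independent O(M^2) DFT oracle
        rng = np.random.default_rng(42)
        M = 512
        e = rng.normal(scale=0.5, size=M)
        e -= e.mean()
        spec = spectrum(profile_from_e(e))
        j = np.arange(M)
        direct = np.array(
            [abs(np.sum(e * np.exp(-2j * np.pi * k * j / M))) for k in range(1, M // 2 + 1)]
        )
        assert np.max(np.abs(spec.mag - direct)) < 1e-8

    def test_parseval_ties_spectrum_to_variance(self):
        rng = np.random.default_rng(3)
        M = 256
        e = rng.normal(size=M)
        e -= e.mean()
        F = np.fft.rfft(e)
        spec = spectrum(profile_from_e(e))
        total = abs(F[0]) ** 2 + 2 * np.sum(spec.mag[:-1] ** 2) + spec.mag[-1] ** 2
        assert total == pytest.approx(M * np.sum(e**2), rel=1e-12)


class TestQ:
    def test_zero_spectrum_zero_Q(self):
        spec = spectrum(profile_from_e(np.zeros(128)))
        assert compute_Q(spec) == 0.0

    def test_trapezoid_against_brute_force(self):
        M = 512
        theta = 2 * np.pi * np.arange(M) / M
        spec = spectrum(profile_from_e(np.cos(8 * theta)))
        lam_min, lam_max = default_band(spec)
        # independent brute-force trapezoid over the lambda grid
        mask = (spec.lam >= lam_min) & (spec.lam <= lam_max)
        lam = spec.lam[mask][::-1]
        mag = spec.mag[mask][::-1]
        expected = sum(
            0.5 * (mag[i] + mag[i + 1]) * (lam[i + 1] - lam[i]) for i in range(len(lam) - 1)
        )
        assert compute_Q(spec) == pytest.approx(expected, rel=1e-12)

    def test_Q_linear_in_signal(self):
        rng = np.random.default_rng(1)
        e = rng.normal(size=256)
        q1 = compute_Q(spectrum(profile_from_e(e)))
        q2 = compute_Q(spectrum(profile_from_e(2 * e)))
        assert q2 == pytest.approx(2 * q1, rel=1e-12)

    def test_band_validation(self):
        spec = spectrum(profile_from_e(np.zeros(64)))
        with pytest.raises(ValueError):
            compute_Q(spec, 5.0, 2.0)
        with pytest.raises(ValueError):
            compute_Q(spec, 1e-6, 2e-6)  # below all wavelengths


class TestLayerStd:
    def test_zero_for_flat_profile(self):
        assert layer_std(profile_from_e(np.zeros(64))) == 0.0

    def test_cosine_closed_form(self):
        theta = 2 * np.pi * np.arange(256) / 256
        assert layer_std(profile_from_e(np.cos(theta))) == pytest.approx(
            1 / np.sqrt(2), rel=1e-12
        )

    def test_invariant_to_dc_offset(self):
        rng = np.random.default_rng(2)
        e = rng.normal(size=128)
        assert layer_std(profile_from_e(e)) == pytest.approx(
            layer_std(profile_from_e(e + 5.0)), rel=1e-12
        )
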