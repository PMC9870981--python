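"""Width-at-fractional-height analysis of wall-stain profiles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gcxquant import (
    GcxiConfig,
    IntensityProfile,
    analyze_profile,
    artery_gcxi,
    smooth_profile,
)
from gcxquant.exceptions import (
    NoCrossingError,
    NoInflectionError,
    NoPeakError,
    UnusableArteryError,
)
from gcxquant.scene import GAUSSIAN_WIDTH_FACTOR

from conftest import NO_SMOOTHING, gaussian_profile, raised_cosine_profile


class TestSmoothing:
    def test_window_one_is_identity(self):
        prof = gaussian_profile(step=0.5)
        out = smooth_profile(prof, GcxiConfig(smoothing_window=1))
        np.testing.assert_array_equal(out.intensities, prof.intensities)

    def test_polynomial_reproduced_exactly(self):
        x = np.linspace(-5, 5, 101)
        y = 2.0 + 3.0 * x - 0.5 * x**2 + 0.1 * x**3
        prof = IntensityProfile(positions=x, intensities=y)
        out = smooth_profile(prof, GcxiConfig(smoothing_window=9, smoothing_polyorder=3))
        np.testing.assert_allclose(out.intensities[4:-4], y[4:-4], rtol=1e-9)

    def test_constant_profile_unchanged(self):
        x = np.linspace(0, 10, 51)
        prof = IntensityProfile(positions=x, intensities=np.full(51, 4.2))
        out = smooth_profile(prof, GcxiConfig())
        np.testing.assert_allclose(out.intensities, 4.2)

    def test_window_longer_than_profile_rejected(self):
        x = np.linspace(0, 1, 5)
        prof = IntensityProfile(positions=x, intensities=np.zeros(5))
        with pytest.raises(ValueError):
            smooth_profile(prof, GcxiConfig(smoothing_window=7))


class TestAnalyzeProfile:
    def test_gaussian_ridge_landmarks(self):
        # analytic oracle: inflections at +-sigma, c = a e^{-1/2},
        # b = a (0.6 + 0.4 e^{-1/2}), d = 2 sigma sqrt(-2 ln(0.6 + 0.4 e^{-1/2}))
        res = analyze_profile(gaussian_profile(sigma=10.0, amplitude=100.0), NO_SMOOTHING)
        assert res.a_value == pytest.approx(100.0, rel=1e-6)
        assert res.infl_left[0] == pytest.approx(-10.0, abs=0.02)
        assert res.infl_right[0] == pytest.approx(10.0, abs=0.02)
        assert res.c_value == pytest.approx(60.653, abs=0.01)
        assert res.b_level == pytest.approx(84.261, abs=0.01)
        assert res.d_px == pytest.approx(11.705, rel=0.005)

    def test_raised_cosine_ridge_landmarks(self):
        # analytic oracle: inflections at +-w/2, c = a/2, b = 0.8 a,
        # d = (2w/pi) arccos(0.6)
        res = analyze_profile(raised_cosine_profile(w=20.0, amplitude=100.0), NO_SMOOTHING)
        assert res.infl_left[0] == pytest.approx(-10.0, abs=0.02)
        assert res.infl_right[0] == pytest.approx(10.0, abs=0.02)
        assert res.c_value == pytest.approx(50.0, abs=0.05)
        assert res.b_level == pytest.approx(80.0, abs=0.05)
        assert res.d_px == pytest.approx(11.807, rel=0.005)

    def test_landmark_ordering_invariants(self):
        res = analyze_profile(gaussian_profile(background=12.0), NO_SMOOTHING)
        assert res.infl_left[0] < res.a_position < res.infl_right[0]
        assert res.c_value < res.b_level < res.a_value
        assert res.cross_left < res.a_position < res.cross_right
        assert res.d_px > 0

    @given(alpha=st.floats(0.1, 50.0), beta=st.floats(-100.0, 100.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_affine_intensity_invariance(self, alpha, beta):
        prof = gaussian_profile(sigma=8.0, amplitude=40.0, step=0.2)
        base = analyze_profile(prof, NO_SMOOTHING).d_px
        scaled = IntensityProfile(positions=prof.positions,
                                  intensities=alpha * prof.intensities + beta)
        assert analyze_profile(scaled, NO_SMOOTHING).d_px == pytest.approx(base, rel=1e-9)

    def test_spatial_equivariance(self):
        prof = gaussian_profile(sigma=5.0, step=0.05)
        base = analyze_profile(prof, NO_SMOOTHING).d_px
        for s in (0.5, 2.0, 3.0):
            stretched = IntensityProfile(positions=s * prof.positions,
                                         intensities=prof.intensities)
            assert analyze_profile(stretched, NO_SMOOTHING).d_px == pytest.approx(
                s * base, rel=1e-9
            )

    def test_reflection_symmetry(self):
        rng = np.random.default_rng(4)
        x = np.arange(-40, 40.001, 0.2)
        y = 80 * np.exp(-(x**2) / 72) + 10 + rng.normal(0, 0.5, size=x.size)
        prof = IntensityProfile(positions=x, intensities=y)
        mirrored = IntensityProfile(positions=x, intensities=y[::-1])
        cfg = GcxiConfig()  # smoothing on: noisy profile
        assert analyze_profile(mirrored, cfg).d_px == pytest.approx(
            analyze_profile(prof, cfg).d_px, rel=1e-9
        )

    def test_convergence_to_analytic_width_with_fine_sampling(self):
        for sigma in (5.0, 10.0, 20.0):
            res = analyze_profile(gaussian_profile(sigma=sigma, step=0.1), NO_SMOOTHING)
            assert res.d_px == pytest.approx(GAUSSIAN_WIDTH_FACTOR * sigma, rel=0.005)

    def test_flat_profile_raises_no_peak(self):
        x = np.linspace(0, 10, 51)
        prof = IntensityProfile(positions=x, intensities=np.full(51, 3.0))
        with pytest.raises(NoPeakError):
            analyze_profile(prof, NO_SMOOTHING)

    def test_monotone_profile_raises_no_peak(self):
        x = np.linspace(0, 10, 51)
        prof = IntensityProfile(positions=x, intensities=x.copy())
        with pytest.raises(NoPeakError):
            analyze_profile(prof, NO_SMOOTHING)

    def test_missing_inflection_raises(self):
        # concave parabola has no second-derivative sign change
        x = np.linspace(-5, 5, 101)
        prof = IntensityProfile(positions=x, intensities=100 - x**2)
        with pytest.raises(NoInflectionError):
            analyze_profile(prof, NO_SMOOTHING)

    def test_uncrossed_threshold_raises(self):
        # truncate the profile so tightly that b_level is never reached on
        # the right: gaussian plus a plateau shoulder that stays above b
        x = np.arange(-30, 30.001, 0.1)
        y = 100 * np.exp(-(x**2) / 50)
        y[x > 1.0] = np.maximum(y[x > 1.0], 95.0)
        prof = IntensityProfile(positions=x, intensities=y)
        with pytest.raises(NoCrossingError):
            analyze_profile(prof, NO_SMOOTHING)

    def test_prominence_gate(self):
        prof = gaussian_profile(sigma=5.0, amplitude=2.0, background=50.0, step=0.2)
        with pytest.raises(NoPeakError):
            analyze_profile(prof, GcxiConfig(smoothing_window=1, min_peak_prominence=5.0))

    def test_multiple_crossings_take_nearest_the_peak(self):
        # two Gaussian ridges: distal structure must not widen the measurement
        x = np.arange(-60, 60.001, 0.1)
        y = 100 * np.exp(-(x**2) / 200) + 95 * np.exp(-((x - 45) ** 2) / 18)
        prof = IntensityProfile(positions=x, intensities=y)
        res = analyze_profile(prof, NO_SMOOTHING)
        assert res.cross_right < 30.0


class TestArteryAggregation:
    def test_mean_of_three_line_widths(self):
        analyses = [
            analyze_profile(gaussian_profile(sigma=s, step=0.1), NO_SMOOTHING)
            for s in (3.0, 4.0, 5.0)
        ]
        art = artery_gcxi(analyses, artery_id="a1", diameter_class=40)
        assert art.gcxi_um == pytest.approx(
            sum(a.d_um for a in analyses) / 3, rel=1e-12
        )

    def test_equal_widths_average_to_themselves(self):
        a = analyze_profile(gaussian_profile(sigma=10.0, step=0.1), NO_SMOOTHING)
        art = artery_gcxi([a, a, a])
        assert art.gcxi_um == pytest.approx(a.d_um, rel=1e-12)
        assert art.gcxi_um == pytest.approx(11.705, rel=0.005)

    def test_fewer_than_three_lines_flagged_unusable(self):
        a = analyze_profile(gaussian_profile(step=0.1), NO_SMOOTHING)
        with pytest.raises(UnusableArteryError):
            artery_gcxi([a, a], artery_id="bad")


def test_config_validation():
    with pytest.raises(ValueError):
        GcxiConfig(upper_fraction=1.5)
    with pytest.raises(ValueError):
        GcxiConfig(smoothing_window=4)
    with pytest.raises(ValueError):
        GcxiConfig(smoothing_window=3, smoothing_polyorder=3)
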