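"""Profiles, autocorrelation, spacing/amplitude and group statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mps_scope import RenderedImage, periodicity
from mps_scope.errors import (
    ParameterError,
    PeakNotFoundError,
    TraceOutsideImageError,
    UndefinedStatisticError,
)
from mps_scope.periodicity import (
    AutocorrCurve,
    IntensityProfile,
    Polyline,
    amplitude,
    autocorrelate,
    average_curves,
    compare_groups,
    extract_profile,
    fit_spacing,
    measure_intensity,
)


def brute_force_autocorr(values):
    """O(N^2) biased normalized autocorrelation, straight from the formula."""
    v = np.asarray(values, dtype=float)
    vc = v - v.mean()
    denom = np.sum(vc**2)
    n = len(v)
    return np.array(
        [sum(vc[i] * vc[i + k] for i in range(n - k)) / denom for k in range(n)]
    )


def cosine_profile(period_nm=192.0, n_periods=20, step=16.0, phase=0.0):
    n = int(round(n_periods * period_nm / step))
    pos = step * np.arange(n)
    return IntensityProfile(pos, np.cos(2 * np.pi * pos / period_nm + phase))


def stripe_image(period_nm=185.0, px=16.0, shape=(64, 256)):
    cols = px * np.arange(shape[1])
    img = np.tile(1.0 + np.cos(2 * np.pi * cols / period_nm), (shape[0], 1))
    return RenderedImage(pixels=img, pixel_size=px, origin=(0.0, 0.0))


# ---------------------------------------------------------------------------
# extract_profile


class TestExtractProfile:
    def test_axis_aligned_stripes(self):
        img = stripe_image()
        trace = Polyline(np.array([[0.0, 512.0], [16.0 * 255, 512.0]]),
                         band_width=64.0)
        prof = extract_profile(img, trace)
        expected = 1.0 + np.cos(2 * np.pi * prof.positions / 185.0)
        np.testing.assert_allclose(prof.values, expected, atol=1e-9)

    def test_constant_image_gives_constant_profile(self):
        img = RenderedImage(np.full((32, 32), 3.5), pixel_size=16.0)
        trace = Polyline(np.array([[50.0, 250.0], [450.0, 250.0]]), band_width=96)
        prof = extract_profile(img, trace)
        np.testing.assert_allclose(prof.values, 3.5)

    def test_rotation_equivariance(self):
        # the same cosine pattern, axis-aligned vs rotated 45 degrees,
        # sampled along a matching trace, yields the same profile
        px, period = 8.0, 160.0
        n = 360
        coords = px * np.arange(n)
        gx, gy = np.meshgrid(coords, coords)
        th = np.deg2rad(45.0)
        u = np.array([np.cos(th), np.sin(th)])
        img_rot = RenderedImage(
            1.0 + np.cos(2 * np.pi * (gx * u[0] + gy * u[1]) / period),
            pixel_size=px,
        )
        start, length = np.array([400.0, 400.0]), 1600.0
        trace_rot = Polyline(np.array([start, start + length * u]), band_width=0)
        prof_rot = extract_profile(img_rot, trace_rot)

        img_ax = stripe_image(period_nm=period, px=px, shape=(64, n))
        s0 = float(start @ u)
        trace_ax = Polyline(np.array([[s0, 256.0], [s0 + length, 256.0]]))
        prof_ax = extract_profile(img_ax, trace_ax)

        m = min(len(prof_rot), len(prof_ax))
        np.testing.assert_allclose(
            prof_rot.values[:m], prof_ax.values[:m], atol=0.02
        )

    def test_trace_outside_image_names_vertex(self):
        img = stripe_image()
        trace = Polyline(np.array([[0.0, 512.0], [1e6, 512.0]]))
        with pytest.raises(TraceOutsideImageError, match="vertex"):
            extract_profile(img, trace)


# ---------------------------------------------------------------------------
# autocorrelate


class TestAutocorrelate:
    def test_matches_bruteforce_definition(self, rng):
        for n in (24, 100, 333):
            prof = IntensityProfile(16.0 * np.arange(n), rng.normal(size=n))
            curve = autocorrelate(prof)
            np.testing.assert_allclose(
                curve.values, brute_force_autocorr(prof.values),
                rtol=1e-10, atol=1e-12,
            )
            assert curve.values[0] == pytest.approx(1.0)
            assert np.all(np.abs(curve.values) <= 1 + 1e-12)

    def test_cosine_first_peak_at_period(self):
        curve = autocorrelate(cosine_profile(period_nm=192.0))
        peak_lag = curve.lags[
            1 + np.argmax(curve.values[1:len(curve.values) // 2])
        ]
        assert peak_lag == pytest.approx(192.0, abs=8.0)
        assert np.interp(96.0, curve.lags, curve.values) < 0

    def test_white_noise_has_no_structure(self):
        # Monte-Carlo null: the seed-averaged curve stays within 3/sqrt(N)
        n, n_seeds = 512, 20
        curves = []
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            prof = IntensityProfile(16.0 * np.arange(n), r.normal(size=n))
            curves.append(autocorrelate(prof))
        mean_curve = average_curves(curves)
        assert np.max(np.abs(mean_curve.values[1:n // 2])) < 3 / np.sqrt(n)

    def test_zero_variance_raises(self):
        prof = IntensityProfile(16.0 * np.arange(30), np.full(30, 2.0))
        with pytest.raises(UndefinedStatisticError):
            autocorrelate(prof)

    def test_short_profile_rejected(self):
        prof = IntensityProfile(16.0 * np.arange(10), np.random.rand(10))
        with pytest.raises(ParameterError):
            autocorrelate(prof)

    @settings(derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(24, 256))
    def test_biased_estimator_bounded(self, seed, n):
        r = np.random.default_rng(seed)
        prof = IntensityProfile(16.0 * np.arange(n), r.normal(size=n))
        curve = autocorrelate(prof)
        assert curve.values[0] == pytest.approx(1.0)
        assert np.all(np.abs(curve.values) <= 1 + 1e-12)


# ---------------------------------------------------------------------------
# averaging, fitting, amplitude


class TestAverageAndFit:
    def test_average_single_and_identical(self):
        c = autocorrelate(cosine_profile())
        np.testing.assert_array_equal(average_curves([c]).values, c.values)
        avg = average_curves([c, c])
        np.testing.assert_allclose(avg.values, c.values)
        assert avg.n == 2

    def test_average_equals_elementwise_mean(self, rng):
        curves = [
            autocorrelate(IntensityProfile(16.0 * np.arange(64),
                                           rng.normal(size=64)))
            for _ in range(5)
        ]
        avg = average_curves(curves)
        brute = np.mean([c.values for c in curves], axis=0)
        np.testing.assert_allclose(avg.values, brute, rtol=1e-12)

    def test_mismatched_grids_rejected(self):
        a = autocorrelate(cosine_profile(step=16.0))
        b = autocorrelate(cosine_profile(step=20.0))
        with pytest.raises(ParameterError):
            average_curves([a, b])

    def test_average_then_fit_idempotent(self):
        c = autocorrelate(cosine_profile(period_nm=185.0))
        s_one, _ = fit_spacing(c)
        s_avg, _ = fit_spacing(average_curves([c] * 4))
        assert s_avg == pytest.approx(s_one, abs=1e-9)

    @pytest.mark.parametrize("period", [185.0, 192.0])
    def test_cosine_spacing_recovered(self, period):
        curve = autocorrelate(cosine_profile(period_nm=period))
        s, err = fit_spacing(curve)
        assert s == pytest.approx(period, abs=2.0)
        assert err >= 0

    def test_gaussian_and_quadratic_models_agree(self):
        curve = autocorrelate(cosine_profile(period_nm=188.0))
        s_g, _ = fit_spacing(curve, model="gaussian")
        s_q, _ = fit_spacing(curve, model="quadratic")
        assert abs(s_g - s_q) < 2.0

    def test_monotone_decay_has_no_peak(self):
        lags = 16.0 * np.arange(40)
        curve = AutocorrCurve(lags, np.exp(-lags / 150.0))
        with pytest.raises(PeakNotFoundError):
            fit_spacing(curve)

    def test_tie_breaks_toward_smaller_lag(self):
        lags = 16.0 * np.arange(40)
        vals = np.zeros(40)
        vals[0] = 1.0
        vals[9] = vals[15] = 0.5  # equal maxima at 144 and 240 nm
        s, _ = fit_spacing(AutocorrCurve(lags, vals), model="quadratic",
                           fit_halfwidth=32.0)
        assert s < 192.0

    def test_amplitude_of_192_cosine_approaches_two(self):
        curve = autocorrelate(cosine_profile(period_nm=192.0, n_periods=50))
        assert amplitude(curve) == pytest.approx(2.0, abs=0.1)
        assert amplitude(curve) <= 2.0

    def test_amplitude_null_on_noise(self):
        n, amps = 512, []
        for seed in range(50):
            r = np.random.default_rng(seed)
            prof = IntensityProfile(16.0 * np.arange(n),
                                    5.0 + r.normal(size=n))
            amps.append(amplitude(autocorrelate(prof)))
        assert abs(np.mean(amps)) < 3 / np.sqrt(n)

    def test_amplitude_lags_exact_on_16nm_grid(self):
        curve = autocorrelate(cosine_profile(period_nm=192.0))
        assert 96.0 in curve.lags and 192.0 in curve.lags
        i96 = int(np.where(curve.lags == 96.0)[0][0])
        i192 = int(np.where(curve.lags == 192.0)[0][0])
        assert amplitude(curve) == pytest.approx(
            curve.values[i192] - curve.values[i96], abs=1e-12
        )

    def test_amplitude_needs_192nm_range(self):
        curve = AutocorrCurve(16.0 * np.arange(10), np.linspace(1, 0, 10))
        with pytest.raises(ParameterError):
            amplitude(curve)


# ---------------------------------------------------------------------------
# intensity measurement


class TestMeasureIntensity:
    def test_uniform_image_measures_zero(self):
        img = RenderedImage(np.full((64, 64), 7.0), pixel_size=16.0)
        trace = Polyline(np.array([[100.0, 200.0], [900.0, 200.0]]), band_width=64)
        bg = Polyline(np.array([[100.0, 800.0], [900.0, 800.0]]), band_width=64)
        assert measure_intensity(img, trace, bg) == pytest.approx(0.0)

    def test_stripe_on_zero_background(self):
        img = RenderedImage(np.zeros((64, 64)), pixel_size=16.0)
        img.pixels[10:14, :] = 5.0
        trace = Polyline(np.array([[100.0, 16.0 * 12], [900.0, 16.0 * 12]]))
        bg = Polyline(np.array([[100.0, 800.0], [900.0, 800.0]]))
        assert measure_intensity(img, trace, bg) == pytest.approx(5.0)

    def test_overlapping_regions_warn(self):
        img = RenderedImage(np.ones((64, 64)), pixel_size=16.0)
        trace = Polyline(np.array([[100.0, 200.0], [900.0, 200.0]]), band_width=64)
        with pytest.warns(UserWarning, match="overlap"):
            measure_intensity(img, trace, trace)


# ---------------------------------------------------------------------------
# group statistics


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        g = list(range(10))
        comp = compare_groups({"a": g, "b": g}, design="two_group")
        assert comp.p_omnibus > 0.9
        assert comp.pairwise["code"].iloc[0] == "ns"

    def test_separated_groups_highly_significant(self):
        comp = compare_groups(
            {"a": range(1, 11), "b": range(101, 111)}, design="two_group"
        )
        assert comp.p_omnibus < 0.001
        assert comp.pairwise["code"].iloc[0] == "***"

    def test_mann_whitney_u_equals_pairwise_win_count(self, rng):
        a = rng.normal(0, 1, 5)
        b = rng.normal(0.5, 1, 5)
        comp = compare_groups({"a": a, "b": b}, design="two_group")
        brute = sum(
            1.0 if ai > bi else (0.5 if ai == bi else 0.0)
            for ai in a for bi in b
        )
        assert comp.pairwise["statistic"].iloc[0] == pytest.approx(brute)

    def test_multi_group_dunn_detects_outlier_group(self, rng):
        groups = {
            "ctrl": rng.normal(185, 3, 20),
            "same": rng.normal(185, 3, 20),
            "shifted": rng.normal(230, 3, 20),
        }
        comp = compare_groups(groups, design="multi_group")
        assert comp.p_omnibus < 0.001
        pw = comp.pairwise.set_index(["group_a", "group_b"])
        assert pw.loc[("ctrl", "shifted"), "p_adj"] < 0.001
        assert pw.loc[("ctrl", "same"), "p_adj"] > 0.05

    def test_parametric_switch_runs_tukey(self, rng):
        groups = {k: rng.normal(m, 1, 10) for k, m in
                  [("a", 0.0), ("b", 0.2), ("c", 5.0)]}
        comp = compare_groups(groups, design="multi_group", parametric=True)
        assert "Tukey" in comp.test_name
        assert comp.p_omnibus < 0.001

    def test_sem_definition(self):
        comp = compare_groups({"a": [10, 12, 14], "b": [1, 2, 3]},
                              design="two_group")
        assert comp.means[0] == pytest.approx(12.0)
        assert comp.sems[0] == pytest.approx(2.0 / np.sqrt(3))

    def test_small_group_rejected(self):
        with pytest.raises(ParameterError):
            compare_groups({"a": [1, 2], "b": [1, 2, 3]}, design="two_group")
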