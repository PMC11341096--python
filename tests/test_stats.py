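"""Pixelwise statistics: closed forms, fit equivalence, flat fields."""

import numpy as np
import pytest

import fpmkit as fk
from fpmkit.stats import (
    compute_pixel_maps,
    fit_pixel_sinusoid,
    flat_field_correct,
    register_custom_statistic,
    unregister_custom_statistic,
)

from conftest import forward_pixel


def stack_from_pixel(values, pixel_size=1.0):
    """A 2x2 stack where every pixel has the given 4-angle response."""
    v = np.asarray(values, dtype=float)
    return fk.FPMStack(np.tile(v[:, None, None], (1, 2, 2)), pixel_size=pixel_size)


class TestComputePixelMaps:
    def test_fully_modulated_pixel(self):
        maps = compute_pixel_maps(stack_from_pixel([2, 1, 0, 1]))
        assert maps.S0[0, 0] == 2
        assert maps.S1[0, 0] == 2
        assert maps.S2[0, 0] == 0
        assert maps.order[0, 0] == pytest.approx(1.0)
        assert maps.azimuth[0, 0] == pytest.approx(0.0)

    def test_unpolarized_pixel_flagged(self):
        maps = compute_pixel_maps(stack_from_pixel([1, 1, 1, 1]))
        assert maps.S0[0, 0] == 2
        assert maps.order[0, 0] == pytest.approx(0.0)
        assert np.isnan(maps.azimuth[0, 0])

    def test_dark_pixel_order_undefined(self):
        maps = compute_pixel_maps(stack_from_pixel([0, 0, 0, 0]))
        assert np.isnan(maps.order[0, 0])
        assert np.isnan(maps.azimuth[0, 0])

    def test_forward_model_recovery(self):
        """A pixel sampled from I = 10(1 + 0.5 cos 2(w - 30 deg)) yields
        p = 0.5, alpha = 30 deg to machine precision."""
        omega = np.deg2rad([0, 45, 90, 135])
        intensities = 10.0 * (1 + 0.5 * np.cos(2 * (omega - np.deg2rad(30.0))))
        maps = compute_pixel_maps(stack_from_pixel(intensities))
        assert maps.order[0, 0] == pytest.approx(0.5, abs=1e-12)
        assert np.degrees(maps.azimuth[0, 0]) == pytest.approx(30.0, abs=1e-10)

    def test_scale_invariance(self, rng):
        images = rng.uniform(1, 100, size=(4, 8, 8))
        maps1 = compute_pixel_maps(fk.FPMStack(images))
        maps2 = compute_pixel_maps(fk.FPMStack(images * 7.3))
        np.testing.assert_allclose(maps2.order, maps1.order, rtol=1e-12)
        np.testing.assert_allclose(maps2.azimuth, maps1.azimuth, rtol=1e-12)

    def test_noiseless_recovery_random_fields(self, rng):
        """Forward-model stacks invert exactly at every signal pixel."""
        h = w = 16
        p_true = rng.uniform(0, 1, (h, w))
        alpha_true = rng.uniform(0, 180, (h, w))
        amp = rng.uniform(1, 50, (h, w))
        scene = fk.SyntheticScene(
            truth_order=p_true, truth_azimuth_deg=alpha_true, amplitude=amp,
            background=0.0,
        )
        maps = compute_pixel_maps(fk.render_stack(scene))
        np.testing.assert_allclose(maps.order, p_true, atol=1e-12)
        defined = np.isfinite(maps.azimuth) & (p_true > 1e-9)
        recovered = np.degrees(maps.azimuth[defined]) % 180.0
        delta = np.abs(recovered - alpha_true[defined]) % 180.0
        np.testing.assert_allclose(np.minimum(delta, 180 - delta), 0.0, atol=1e-8)


class TestSinusoidFit:
    def test_exact_sinusoid(self):
        fit = fit_pixel_sinusoid([2, 1, 0, 1])
        assert fit.offset == pytest.approx(1.0)
        assert fit.amplitude == pytest.approx(1.0)
        assert fit.phase == pytest.approx(0.0)
        assert fit.rss == pytest.approx(0.0, abs=1e-20)

    def test_constant_response_degenerate_phase(self):
        fit = fit_pixel_sinusoid([1, 1, 1, 1])
        assert fit.offset == pytest.approx(1.0)
        assert fit.amplitude == pytest.approx(0.0, abs=1e-12)
        assert fit.phase == 0.0
        assert fit.rss == pytest.approx(0.0, abs=1e-20)

    def test_matches_closed_form(self, rng):
        """For the 4 equally spaced angles the least-squares fit equals
        a = S0/2, b = sqrt(S1^2+S2^2)/2, phi = alpha."""
        for _ in range(200):
            y = rng.uniform(0, 100, 4)
            fit = fit_pixel_sinusoid(y)
            s0 = y.sum() / 2
            s1, s2 = y[0] - y[2], y[1] - y[3]
            assert fit.offset == pytest.approx(s0 / 2, abs=1e-10)
            assert fit.amplitude == pytest.approx(np.hypot(s1, s2) / 2, abs=1e-10)
            if fit.amplitude > 1e-9:
                expected_phase = (0.5 * np.arctan2(s2, s1) + np.pi / 2) % np.pi - np.pi / 2
                assert fit.phase == pytest.approx(expected_phase, abs=1e-10)

    def test_is_global_minimum_by_grid_search(self, rng):
        """No (a, b, phi) on a fine phase grid beats the fit's RSS."""
        omega = np.deg2rad([0, 45, 90, 135])
        for _ in range(10):
            y = rng.uniform(0, 10, 4)
            fit = fit_pixel_sinusoid(y)
            best = np.inf
            for phi in np.deg2rad(np.arange(-90, 90, 0.5)):
                design = np.column_stack([np.ones(4), np.cos(2 * (omega - phi))])
                coef, *_ = np.linalg.lstsq(design, y, rcond=None)
                rss = float(np.sum((y - design @ coef) ** 2))
                best = min(best, rss)
            assert fit.rss <= best + 1e-9


class TestFlatField:
    def test_uniform_flat_is_identity(self, rng):
        images = rng.uniform(1, 10, (4, 6, 6))
        stack = fk.FPMStack(images)
        flat = fk.FlatFieldStack(np.ones((4, 6, 6)))
        out = flat_field_correct(stack, [flat])
        np.testing.assert_array_equal(out.images, stack.images)

    def test_constant_flat_is_identity(self, rng):
        images = rng.uniform(1, 10, (4, 6, 6))
        stack = fk.FPMStack(images)
        flat = fk.FlatFieldStack(np.full((4, 6, 6), 3.7))
        out = flat_field_correct(stack, [flat])
        np.testing.assert_allclose(out.images, stack.images, rtol=1e-12)

    def test_gradient_flat_matches_direct_quotient(self):
        """Linear-gradient flat on a uniform image equals the elementwise
        quotient computed independently."""
        h, w = 5, 8
        gradient = 1.0 + np.tile(np.linspace(0, 1, w), (h, 1))
        flat = fk.FlatFieldStack(np.tile(gradient, (4, 1, 1)))
        stack = fk.FPMStack(np.full((4, h, w), 10.0))
        out = flat_field_correct(stack, [flat])
        expected = 10.0 / (gradient / gradient.mean())
        for k in range(4):
            np.testing.assert_allclose(out.images[k], expected, rtol=1e-12)

    def test_multiple_flats_are_averaged(self, rng):
        images = rng.uniform(1, 10, (4, 4, 4))
        stack = fk.FPMStack(images)
        f1 = fk.FlatFieldStack(np.full((4, 4, 4), 2.0))
        f2 = fk.FlatFieldStack(np.full((4, 4, 4), 4.0))
        out = flat_field_correct(stack, [f1, f2])
        np.testing.assert_allclose(out.images, stack.images, rtol=1e-12)

    def test_dimension_mismatch_rejected(self):
        stack = fk.FPMStack(np.ones((4, 4, 4)))
        flat = fk.FlatFieldStack(np.ones((4, 5, 5)))
        with pytest.raises(fk.StackFormatError):
            flat_field_correct(stack, [flat])


class TestCustomStatistics:
    def test_total_intensity_statistic(self, rng):
        register_custom_statistic("total", lambda i0, i45, i90, i135: i0 + i45 + i90 + i135)
        try:
            maps = compute_pixel_maps(fk.FPMStack(rng.uniform(0, 5, (4, 4, 4))))
            np.testing.assert_allclose(maps.custom["total"], 2 * maps.S0, rtol=1e-12)
        finally:
            unregister_custom_statistic("total")

    def test_duplicate_name_rejected(self):
        register_custom_statistic("dup_stat", lambda *a: a[0])
        try:
            with pytest.raises(ValueError):
                register_custom_statistic("dup_stat", lambda *a: a[1])
        finally:
            unregister_custom_statistic("dup_stat")

    def test_custom_statistic_flows_into_object_means(self, puncta_scene):
        """A registered p^2 statistic's per-object mean equals the mean of
        the squared order map over the object pixels."""
        register_custom_statistic("psq", lambda i0, i45, i90, i135: (
            (np.hypot(i0 - i90, i45 - i135) / ((i0 + i45 + i90 + i135) / 2)) ** 2
        ))
        try:
            stack = fk.render_stack(puncta_scene)
            maps = compute_pixel_maps(stack)
            seg = fk.segment_puncta(maps.S0)
            objs = fk.extract_features(seg, maps, stack, compute_midlines=False)
            assert len(objs) > 0
            for obj in objs[:5]:
                mask = seg.labels == obj.id
                expected = np.nanmean(maps.order[mask] ** 2)
                assert obj.custom_means["psq"] == pytest.approx(expected, rel=1e-9)
        finally:
            unregister_custom_statistic("psq")

    def test_constant_statistic_mean_is_one(self, puncta_scene):
        register_custom_statistic("one", lambda i0, i45, i90, i135: np.ones_like(i0))
        try:
            stack = fk.render_stack(puncta_scene)
            maps = compute_pixel_maps(stack)
            seg = fk.segment_puncta(maps.S0)
            objs = fk.extract_features(seg, maps, stack, compute_midlines=False)
            assert all(o.custom_means["one"] == pytest.approx(1.0) for o in objs)
        finally:
            unregister_custom_statistic("one")


def test_forward_pixel_helper_consistency():
    """The test helper and the package forward model agree."""
    vals = forward_pixel(10.0, 0.5, 30.0)
    scene = fk.SyntheticScene(
        truth_order=np.array([[0.5]]),
        truth_azimuth_deg=np.array([[30.0]]),
        amplitude=np.array([[10.0]]),
        background=0.0,
    )
    stack = fk.render_stack(scene)
    np.testing.assert_allclose(stack.images[:, 0, 0], vals, rtol=1e-12)
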