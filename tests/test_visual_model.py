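"""Receptor contrasts, acuity blur and the RNL filter."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fringecam.visual_model import (
    EPS_CATCH,
    ConeCatchImage,
    RNLParams,
    ViewerModel,
    acuity_blur,
    acuity_sigma_px,
    delta_s_chromatic,
    delta_s_lum,
    rnl_filter,
    to_cone_catch,
)

catches = st.floats(min_value=1e-3, max_value=1e3)


def chromatic_oracle(qa, qb, e1=0.05, e2=0.07071, e3=0.1657):
    """Scalar re-derivation of the trichromatic receptor-noise distance."""
    f1, f2, f3 = (math.log(a / b) for a, b in zip(qa, qb))
    num = e3**2 * (f1 - f2) ** 2 + e2**2 * (f1 - f3) ** 2 + e1**2 * (f2 - f3) ** 2
    den = (e1 * e2) ** 2 + (e1 * e3) ** 2 + (e2 * e3) ** 2
    return math.sqrt(num / den)


class TestDeltaS:
    def test_luminance_closed_forms(self):
        assert delta_s_lum(0.4, 0.4) == 0.0
        assert delta_s_lum(math.e, 1.0, 0.1) == pytest.approx(10.0, abs=1e-9)
        assert delta_s_lum(0.70, 0.25, 0.1) == pytest.approx(
            abs(math.log(0.70 / 0.25)) / 0.1, abs=1e-9
        )

    @given(qa=catches, qb=catches, c=st.floats(min_value=1e-2, max_value=1e2))
    def test_luminance_symmetry_and_scale_invariance(self, qa, qb, c):
        d = delta_s_lum(qa, qb)
        assert d >= 0
        assert d == pytest.approx(delta_s_lum(qb, qa), rel=1e-12)
        assert d == pytest.approx(delta_s_lum(c * qa, c * qb), rel=1e-9, abs=1e-9)

    def test_nonpositive_catch_rejected(self):
        with pytest.raises(ValueError):
            delta_s_lum(0.0, 1.0)
        with pytest.raises(ValueError):
            delta_s_chromatic([0.1, -0.1, 0.1], [0.1, 0.1, 0.1])

    def test_chromatic_zero_cases(self):
        q = [0.3, 0.5, 0.2]
        assert delta_s_chromatic(q, q) == 0.0
        scaled = [3 * v for v in q]
        assert delta_s_chromatic(scaled, q) == pytest.approx(0.0, abs=1e-12)

    @given(
        q1=catches, q2=catches, q3=catches, p1=catches, p2=catches, p3=catches
    )
    def test_chromatic_matches_scalar_oracle(self, q1, q2, q3, p1, p2, p3):
        qa, qb = [q1, q2, q3], [p1, p2, p3]
        assert delta_s_chromatic(qa, qb) == pytest.approx(
            chromatic_oracle(qa, qb), rel=1e-9, abs=1e-9
        )

    def test_chromatic_single_channel_shift(self):
        qb = [1.0, 1.0, 1.0]
        qa = [math.exp(0.1), 1.0, 1.0]  # Δf = (0.1, 0, 0)
        assert delta_s_chromatic(qa, qb) == pytest.approx(
            chromatic_oracle(qa, qb), abs=1e-9
        )


class TestViewerModel:
    def test_mra_defaults_to_inverse_acuity(self):
        v = ViewerModel(acuity_cpd=72.0)
        assert v.mra_deg == pytest.approx(1 / 72)
        # the printed rounded MRA is accepted (product within 1e-4)
        ViewerModel(acuity_cpd=72.0, mra_deg=0.01389)

    def test_inconsistent_mra_rejected(self):
        with pytest.raises(ValueError):
            ViewerModel(acuity_cpd=72.0, mra_deg=0.02)

    @pytest.mark.parametrize("field", ["weber_lw", "weber_mw", "weber_sw", "weber_lum"])
    def test_positive_weber_required(self, field):
        with pytest.raises(ValueError):
            ViewerModel(**{field: 0.0})


class TestAcuityBlur:
    def test_sigma_from_viewing_geometry(self):
        # 1300 mm viewing distance, MRA 1/72 deg, 11.8 px/mm
        footprint = 1300 * math.tan(math.radians(1 / 72)) * 11.8
        assert footprint == pytest.approx(3.72, abs=0.01)
        assert acuity_sigma_px(ViewerModel(), 11.8, sigma_factor=0.5) == pytest.approx(
            footprint / 2, rel=1e-9
        )
        assert acuity_sigma_px(ViewerModel(), 11.8) == pytest.approx(
            footprint, rel=1e-9
        )

    def test_sigma_inverse_in_acuity(self):
        s72 = acuity_sigma_px(ViewerModel(acuity_cpd=72), 11.8)
        s10 = acuity_sigma_px(ViewerModel(acuity_cpd=10), 11.8)
        assert s10 / s72 == pytest.approx(7.2, rel=1e-6)

    def test_uniform_image_unchanged(self):
        img = np.full((64, 64), 0.4)
        out = acuity_blur(img, ViewerModel(), 11.8)
        assert np.allclose(out, 0.4, atol=1e-12)

    def test_mean_preserved_on_scene(self):
        from fringecam.synthetic_scenes import ScenarioSpec, render_object_scene

        spec = ScenarioSpec(
            appendage_count=16,
            object_radius_px=60,
            appendage_length_px=15,
            object_circumference_px=377,
        )
        img = render_object_scene(spec, canvas_side=220)
        out = acuity_blur(img, ViewerModel(), 11.8)
        assert abs(out.mean() - img.mean()) < 1e-6

    def test_subpixel_blur_is_identity(self):
        img = np.linspace(0.1, 0.9, 100).reshape(10, 10)
        # 72 cpd at a very coarse image scale: sigma below pixel scale
        out = acuity_blur(img, ViewerModel(), px_per_mm=0.05)
        assert np.array_equal(out, img)


class TestConeCatch:
    def test_grayscale_maps_identically(self):
        img = np.array([[0.2, 0.6]])
        cc = to_cone_catch(img)
        assert np.array_equal(cc.lum, img)
        assert np.array_equal(cc.lw, cc.sw)

    def test_equal_rgb_matches_grayscale(self):
        rgb = np.full((2, 2, 3), 0.3)
        cc = to_cone_catch(rgb)
        assert np.allclose(cc.lum, 0.3)

    def test_zero_clamped_to_floor(self):
        cc = to_cone_catch(np.array([[0.0, 0.5]]))
        assert cc.lw[0, 0] == EPS_CATCH

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            to_cone_catch(np.array([[-0.1, 0.5]]))

    def test_display_linearization(self):
        cc = to_cone_catch(np.array([[0.5]]), gamma_mode="srgb22")
        assert cc.lum[0, 0] == pytest.approx(0.5**2.2)


class TestRNLFilter:
    def test_uniform_image_is_fixed_point(self):
        img = np.full((32, 32), 0.5)
        out = rnl_filter(img)
        assert np.allclose(out, 0.5, atol=1e-14)

    def test_suprathreshold_step_preserved(self):
        # two-level step with ΔS ≈ 10: no mixing across the boundary
        img = np.full((64, 64), 0.25)
        img[:, 32:] = 0.70
        out = rnl_filter(img)
        assert np.allclose(out[:, :32], 0.25, atol=1e-6)
        assert np.allclose(out[:, 32:], 0.70, atol=1e-6)

    def test_subthreshold_noise_variance_reduced(self, rng):
        base = 0.5
        noise = rng.uniform(-0.01, 0.01, (48, 48))  # per-pixel ΔS < 1
        img = base + noise
        out = rnl_filter(img)
        assert out.var() < img.var()

    def test_output_within_input_range(self, rng):
        img = rng.uniform(0.2, 0.8, (40, 40))
        out = rnl_filter(img)
        assert out.min() >= img.min() - 1e-12
        assert out.max() <= img.max() + 1e-12

    def test_achromatic_cone_catch_matches_gray_path(self, rng):
        arr = rng.uniform(0.3, 0.6, (24, 24))
        gray = rnl_filter(arr)
        cc = rnl_filter(ConeCatchImage(lw=arr, mw=arr.copy(), sw=arr.copy()))
        assert np.allclose(cc.lw, gray, atol=1e-12)

    def test_chromatic_path_stays_in_range(self, rng):
        lw = rng.uniform(0.3, 0.5, (20, 20))
        mw = rng.uniform(0.2, 0.4, (20, 20))
        sw = rng.uniform(0.1, 0.3, (20, 20))
        out = rnl_filter(ConeCatchImage(lw=lw, mw=mw, sw=sw))
        for before, after in ((lw, out.lw), (mw, out.mw), (sw, out.sw)):
            assert after.min() >= before.min() - 1e-12
            assert after.max() <= before.max() + 1e-12

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            RNLParams(radius_px=2.0, falloff_px=3.0)
        with pytest.raises(ValueError):
            RNLParams(iterations=-1)


def test_full_chain_localizes_outline_gradient(basic_zero):
    """Blur + filter on the zero-appendage scene leaves a thin high-gradient
    ring at the object radius (mean radius within ±3 px of 470)."""
    gy, gx = np.gradient(basic_zero.lum)
    g = np.hypot(gy, gx)
    k = 3000
    thr = np.partition(g[basic_zero.band], -k)[-k]
    sel = (g >= thr) & basic_zero.band
    yy, xx = np.indices(g.shape)
    ctr = (g.shape[0] - 1) / 2
    radii = np.hypot(yy - ctr, xx - ctr)[sel]
    assert abs(radii.mean() - 470) <= 3.0
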