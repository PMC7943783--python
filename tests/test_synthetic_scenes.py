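"""Scene rendering: geometry, compositing, grids, fixtures."""

import numpy as np
import pytest

from fringecam.synthetic_scenes import (
    COUNT_STAGES,
    ScenarioSpec,
    appendage_mask,
    length_fraction_pattern,
    place_appendages,
    raster_hash,
    render_background,
    render_object_scene,
    scenario_grid,
    scene_masks,
    synth_chick_scene,
)


def small_spec(**kwargs):
    """Reduced geometry for cheap rendering tests."""
    defaults = dict(
        object_radius_px=60.0,
        object_circumference_px=377.0,
        appendage_length_px=15.0,
        appendage_thickness_px=4.0,
    )
    defaults.update(kwargs)
    return ScenarioSpec(**defaults)


class TestRenderObjectScene:
    def test_two_tone_without_appendages(self):
        img = render_object_scene(small_spec(appendage_count=0), canvas_side=220)
        assert set(np.unique(img)) == {0.25, 0.70}

    def test_disc_boundary_length_consistent_with_circumference(self):
        from skimage.measure import perimeter_crofton

        outline, _ = scene_masks(ScenarioSpec())
        measured = perimeter_crofton(outline, directions=4)
        assert measured == pytest.approx(2 * np.pi * 470, rel=0.015)

    def test_full_ring_fills_annulus_at_object_level(self):
        spec = small_spec(appendage_count="full")
        img = render_object_scene(spec, canvas_side=220)
        yy, xx = np.indices(img.shape)
        r = np.hypot(yy - 109.5, xx - 109.5)
        ring = (r > 60) & (r <= 75)
        assert np.all(img[ring] == 0.70)

    def test_histogram_support_on_uniform_background(self):
        spec = small_spec(appendage_count=16, transparency=0.25)
        img = render_object_scene(spec, canvas_side=220)
        composite = 0.75 * 0.70 + 0.25 * 0.25
        assert set(np.unique(img)) == {0.25, composite, 0.70}

    def test_canvas_too_small_rejected(self):
        with pytest.raises(ValueError, match="canvas"):
            render_object_scene(small_spec(), canvas_side=100)

    def test_capacity_error_beyond_one_per_pixel(self):
        with pytest.raises(ValueError, match="capacity"):
            render_object_scene(small_spec(appendage_count=1000), canvas_side=220)

    def test_rendering_is_deterministic(self):
        spec = small_spec(appendage_count=32, length_profile=((0.5, 0.5),))
        a = render_object_scene(spec, canvas_side=220)
        b = render_object_scene(spec, canvas_side=220)
        assert raster_hash(a) == raster_hash(b)


class TestPlaceAppendages:
    def test_angular_spacing(self):
        spec = small_spec(appendage_count=32)
        mask = appendage_mask((220, 220), (109.5, 109.5), spec)
        # sample a circle through the appendage zone and count arcs
        theta = np.linspace(0, 2 * np.pi, 7200, endpoint=False)
        rr = 67.0
        ys = np.round(109.5 + rr * np.sin(theta)).astype(int)
        xs = np.round(109.5 + rr * np.cos(theta)).astype(int)
        on = mask[ys, xs].astype(int)
        runs = np.sum((on[1:] == 1) & (on[:-1] == 0)) + (on[0] and not on[-1])
        assert runs == 32  # 360/32 = 11.25 degrees apart

    def test_alpha_compositing_closed_form(self):
        spec = small_spec(appendage_count=8, transparency=0.5)
        base = np.full((220, 220), 0.25)
        out = place_appendages(base, spec)
        mask = appendage_mask((220, 220), (109.5, 109.5), spec)
        assert np.allclose(out[mask], 0.5 * 0.70 + 0.5 * 0.25, atol=1e-12)
        assert np.all(out[~mask] == 0.25)

    def test_coverage_monotone_in_count_and_full(self):
        annulus = None
        prev = -1.0
        for count in (0, 8, 16, 32, 64, "full"):
            spec = small_spec(appendage_count=count)
            mask = appendage_mask((220, 220), (109.5, 109.5), spec)
            if annulus is None:
                yy, xx = np.indices(mask.shape)
                r = np.hypot(yy - 109.5, xx - 109.5)
                annulus = (r > 60) & (r <= 75)
            cov = mask[annulus].mean()
            assert cov >= prev
            prev = cov
        assert prev == 1.0

    def test_overlapping_counts_render_idempotently(self):
        # denser than the tiling capacity: mask saturates to the annulus
        spec = small_spec(appendage_count=96)  # full capacity is 94
        img = render_object_scene(spec, canvas_side=220)
        full = render_object_scene(small_spec(appendage_count="full"), 220)
        assert np.array_equal(img, full)

    def test_length_profile_shortens_alternate_appendages(self):
        spec = small_spec(appendage_count=16, length_profile=((0.5, 0.5),))
        mask = appendage_mask((220, 220), (109.5, 109.5), spec)
        yy, xx = np.indices(mask.shape)
        r = np.hypot(yy - 109.5, xx - 109.5)
        outer = mask & (r > 60 + 0.5 * 15 + 2)
        theta = np.mod(np.arctan2(yy - 109.5, xx - 109.5), 2 * np.pi)[outer]
        k = np.rint(theta / (2 * np.pi / 16)).astype(int) % 16
        # only full-length appendages reach the outer half of the zone
        assert set(k) == set(range(1, 16, 2))


class TestLengthPattern:
    def test_half_at_half_length_interleaves(self):
        assert list(length_fraction_pattern(((0.5, 0.5),))) == [0.5, 1.0]

    def test_mixed_profile_composition(self):
        pattern = length_fraction_pattern(((0.5, 0.25), (0.25, 0.5)))
        assert len(pattern) == 4
        assert sorted(pattern) == [0.25, 0.25, 0.5, 1.0]

    def test_empty_profile_full_length(self):
        assert list(length_fraction_pattern(())) == [1.0]


class TestBackgrounds:
    def test_uniform_zero_variance(self):
        bg = render_background("uniform", (50, 50), 0.25)
        assert bg.var() == 0.0

    def test_chessboard_period(self):
        bg = render_background("chessboard", (1400, 1400), 0.25, 0.70, 346)
        assert bg[0, 0] == 0.25
        assert bg[0, 346] == 0.70
        assert np.array_equal(bg[:, 0], bg[:, 692])  # two squares per period

    def test_small_squares_have_more_boundaries(self):
        # boundary density per unit length scales as 1/square_px (346/86 ≈ 4x)
        width = 100 * 346
        big = render_background("chessboard", (2, width), 0.25, 0.70, 346)
        small = render_background("chessboard", (2, width), 0.25, 0.70, 86)
        boundaries_big = np.sum(np.diff(big[0]) != 0)
        boundaries_small = np.sum(np.diff(small[0]) != 0)
        assert boundaries_small / boundaries_big == pytest.approx(346 / 86, rel=0.05)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            render_background("stripes", (10, 10), 0.5)


class TestScenarioGrid:
    def test_basic_counts(self):
        specs = scenario_grid("basic")
        assert [s.appendage_count for s in specs] == list(COUNT_STAGES)

    def test_family_levels(self):
        assert {s.appendage_thickness_px for s in scenario_grid("thickness")} == {
            8.0,
            12.0,
        }
        assert {s.transparency for s in scenario_grid("transparency")} == {0.25, 0.5}
        assert {s.acuity_cpd for s in scenario_grid("acuity")} == {30.0, 10.0}
        assert {s.square_px for s in scenario_grid("background")} == {346.0, 86.0}

    def test_full_count_derivation(self):
        assert ScenarioSpec(appendage_count="full").full_count == 737
        assert ScenarioSpec(appendage_thickness_px=8.0).full_count == 368

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            scenario_grid("texture")

    def test_specs_serializable(self):
        from fringecam.synthetic_scenes import spec_records
        import json

        records = spec_records(scenario_grid("length"))
        assert len(records) == 14
        json.dumps(records)  # round-trippable to a config file

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec(transparency=1.5)
        with pytest.raises(ValueError):
            ScenarioSpec(object_level=0.5, background_level=0.5)
        with pytest.raises(ValueError):
            ScenarioSpec(length_profile=((0.7, 0.5), (0.6, 0.25)))
        with pytest.raises(ValueError):
            ScenarioSpec(background="chessboard")


class TestChickFixture:
    def test_same_seed_identical_rasters(self):
        a = synth_chick_scene(7, size=192)
        b = synth_chick_scene(7, size=192)
        assert raster_hash(a.subject_with_fringe) == raster_hash(b.subject_with_fringe)
        assert raster_hash(a.shadow_mask) == raster_hash(b.shadow_mask)

    def test_zero_fringe_effect_gives_identical_pair(self):
        fix = synth_chick_scene(3, fringe_effect=0.0, size=192)
        assert np.array_equal(fix.subject_with_fringe, fix.subject_without_fringe)

    def test_pair_differs_only_outside_outline(self):
        fix = synth_chick_scene(3, fringe_effect=1.0, size=192)
        diff = fix.subject_with_fringe != fix.subject_without_fringe
        assert diff.any()
        assert not np.any(diff & fix.outline_mask)
        assert not np.any(diff & ~fix.feather_boundary_mask)

    def test_outline_within_feather_boundary(self):
        fix = synth_chick_scene(11, size=192)
        assert not np.any(fix.outline_mask & ~fix.feather_boundary_mask)
        assert fix.feather_boundary_mask.sum() > fix.outline_mask.sum()

    def test_shadow_covers_requested_band_fraction(self):
        from fringecam.pipeline import fixture_band
        from fringecam.roi import apply_shadow_exclusion

        fix = synth_chick_scene(5, shadow_fraction=0.28, size=256)
        band = fixture_band(fix)
        _, retained = apply_shadow_exclusion(band, fix.shadow_mask)
        assert retained == pytest.approx(0.72, abs=0.01)

    def test_exposure_noise_decorrelates_pair(self):
        fix = synth_chick_scene(3, fringe_effect=0.0, size=128, exposure_noise=0.01)
        diff = fix.subject_with_fringe - fix.subject_without_fringe
        assert np.abs(diff).mean() > 0.005
        assert fix.subject_with_fringe.min() > 0

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            synth_chick_scene(0, fringe_effect=-1.0)
        with pytest.raises(ValueError):
            synth_chick_scene(0, shadow_fraction=1.0)
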