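"""Shared fixtures: the expensive full-scale observer chains run once."""

from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import settings

from fringecam.hei_stats import hei_threshold_from_reference
from fringecam.leia import leia_stack, postprocess_stack
from fringecam.pipeline import RunConfig, measure_edge_values, run_experiment1
from fringecam.roi import contour_band
from fringecam.synthetic_scenes import (
    ScenarioSpec,
    render_object_scene,
    scene_masks,
)
from fringecam.visual_model import RNLParams, ViewerModel

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def basic_zero():
    """Zero-appendage reference scene pushed through the full observer chain."""
    spec = ScenarioSpec(scenario_id="basic-0", appendage_count=0)
    img = render_object_scene(spec)
    outline, feather = scene_masks(spec)
    band = contour_band(outline, feather, 30)
    values, lum = measure_edge_values(
        img, band, ViewerModel(), RNLParams(), spec.px_per_mm
    )
    stack = postprocess_stack(leia_stack(lum, band))
    return SimpleNamespace(
        spec=spec,
        image=img,
        lum=lum,
        band=band,
        outline=outline,
        feather=feather,
        stack=stack,
        values=values,
    )


@pytest.fixture(scope="session")
def reference_hei(basic_zero):
    """HEI pixel fraction q determined once from the reference scene."""
    return hei_threshold_from_reference(basic_zero.values, mode="fraction")


@pytest.fixture(scope="session")
def exp1_curves(reference_hei):
    """Mean-HEI curves for the basic and thickness families (full scale)."""
    results, summary, _ = run_experiment1(
        RunConfig(),
        families=("basic", "thickness"),
        reference_hei=reference_hei,
    )
    return results, summary


@pytest.fixture(scope="session")
def low_acuity_mean_hei(reference_hei):
    """Mean HEI of the 256-appendage scene for a 10 cpd (canid-like) viewer."""
    from fringecam.hei_stats import mean_hei

    spec = ScenarioSpec(
        scenario_id="5b-256",
        family="acuity",
        variant="5b",
        appendage_count=256,
        acuity_cpd=10.0,
    )
    img = render_object_scene(spec)
    outline, feather = scene_masks(spec)
    band = contour_band(outline, feather, 30)
    values, _ = measure_edge_values(
        img, band, ViewerModel(acuity_cpd=10.0), RNLParams(), spec.px_per_mm
    )
    return mean_hei(values, reference_hei).mean_hei


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
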