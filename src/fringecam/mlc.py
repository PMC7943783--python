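"""Mean Luminance Comparison (MLC).

Tests whether the appendage zone forms a luminance *transition zone*: its
mean luminance should lie between the object's and the background's, ideally
at their midpoint.  For a uniform scene with opaque appendages covering a
fraction α of the annulus the appendage-region mean follows the affine law
``α·object + (1−α)·background``, so the midpoint optimum is reached at 50 %
coverage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .roi import ROISet
from .synthetic_scenes import ScenarioSpec, length_fraction_pattern


@dataclass
class MLCResult:
    mean_object: float
    mean_appendage: float
    mean_background: float
    midpoint: float
    transition_score: float
    is_intermediate: bool


def region_means(lum: np.ndarray, regions: ROISet) -> MLCResult:
    """Mean luminance of the object / appendage / background regions.

    ``transition_score`` is the distance of the appendage-region mean from the
    object/background midpoint (0 is the optimum); ``is_intermediate`` flags
    an appendage mean strictly between the other two.
    """
    lum = np.asarray(lum, dtype=np.float64)
    means = {}
    for name in ("object_region", "appendage_region", "background_region"):
        mask = getattr(regions, name)
        if mask is None or not mask.any():
            raise ValueError(f"empty region: {name}")
        means[name] = float(lum[mask].mean())
    mo, ma, mb = (
        means["object_region"],
        means["appendage_region"],
        means["background_region"],
    )
    midpoint = (mo + mb) / 2.0
    return MLCResult(
        mean_object=mo,
        mean_appendage=ma,
        mean_background=mb,
        midpoint=midpoint,
        transition_score=abs(ma - midpoint),
        is_intermediate=min(mo, mb) < ma < max(mo, mb),
    )


def annulus_area(spec: ScenarioSpec) -> float:
    """Analytic area of the appendage annulus π(R² − r²)."""
    r = spec.object_radius_px
    return math.pi * ((r + spec.appendage_length_px) ** 2 - r**2)


def coverage_fraction(spec: ScenarioSpec) -> float:
    """Analytic effective coverage of the appendage annulus.

    ``count · thickness · mean_length / annulus_area`` capped at 1, with
    transparency scaling effective coverage by ``1 − transparency``.  At
    count "full" the annulus is completely filled, so the (opaque-equivalent)
    coverage is ``1 − transparency`` exactly.
    """
    if spec.appendage_count == "full":
        return 1.0 - spec.transparency
    mean_len = spec.appendage_length_px * float(
        length_fraction_pattern(spec.length_profile).mean()
    )
    covered = spec.resolved_count * spec.appendage_thickness_px * mean_len
    return min(1.0, covered / annulus_area(spec)) * (1.0 - spec.transparency)


def count_for_coverage(spec: ScenarioSpec, target: float = 0.5) -> float:
    """Appendage count at which the effective coverage reaches ``target``."""
    mean_len = spec.appendage_length_px * float(
        length_fraction_pattern(spec.length_profile).mean()
    )
    per_appendage = spec.appendage_thickness_px * mean_len * (1.0 - spec.transparency)
    return target * annulus_area(spec) / per_appendage
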