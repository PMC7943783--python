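"""Regions of interest: contour band, rectangle ROI, region partitions, shadow.

Masks are pixel-centre binary arrays (bool).  Radial pads use the exact
Euclidean distance transform, i.e. a disc structuring element, which matches
the annular geometry of the appendage zone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt


@dataclass
class ROISet:
    """Named binary masks sharing one coordinate frame."""

    contour_band: np.ndarray | None = None
    object_region: np.ndarray | None = None
    appendage_region: np.ndarray | None = None
    background_region: np.ndarray | None = None
    shadow: np.ndarray | None = None
    retained_fraction: float | None = None

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in (
            "contour_band",
            "object_region",
            "appendage_region",
            "background_region",
            "shadow",
        ):
            mask = getattr(self, name)
            if mask is not None:
                rows.append({"region": name, "area_px": int(mask.sum())})
        df = pd.DataFrame(rows)
        if self.retained_fraction is not None:
            df.attrs["retained_fraction"] = self.retained_fraction
        return df


def dilate_disc(mask: np.ndarray, pad_px: float) -> np.ndarray:
    """Dilate a binary mask by a disc of radius ``pad_px`` (exact EDT)."""
    mask = np.asarray(mask, dtype=bool)
    if pad_px <= 0:
        return mask.copy()
    return distance_transform_edt(~mask) <= pad_px


def erode_disc(mask: np.ndarray, pad_px: float) -> np.ndarray:
    """Erode a binary mask by a disc of radius ``pad_px`` (exact EDT)."""
    mask = np.asarray(mask, dtype=bool)
    if pad_px <= 0:
        return mask.copy()
    return distance_transform_edt(mask) > pad_px


def contour_band(
    outline: np.ndarray, feather_boundary: np.ndarray, pad_px: float = 30
) -> np.ndarray:
    """Band from ``pad_px`` inside the outline to ``pad_px`` outside the
    feather boundary.

    For the circular-object geometry (outline radius 470, feather boundary
    588, pad 30) this is the annulus r ∈ [440, 618] — a 178 px wide band.
    """
    outline = np.asarray(outline, dtype=bool)
    feather_boundary = np.asarray(feather_boundary, dtype=bool)
    if np.any(outline & ~feather_boundary):
        raise ValueError("outline must lie within the feather-boundary footprint")
    inner = erode_disc(outline, pad_px)
    if pad_px > 0 and not inner.any():
        raise ValueError("erosion emptied the object; pad_px too large")
    return dilate_disc(feather_boundary, pad_px) & ~inner


def rect_roi(
    shape: tuple[int, int], center: tuple[float, float], side_px: int = 1500
) -> np.ndarray:
    """Axis-aligned square mask of ``side_px`` centred on ``center`` (row, col)."""
    h, w = shape
    cy, cx = center
    r0 = int(round(cy - side_px / 2))
    c0 = int(round(cx - side_px / 2))
    r1, c1 = r0 + side_px, c0 + side_px
    if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
        raise ValueError("rectangle ROI does not fit the canvas")
    mask = np.zeros(shape, dtype=bool)
    mask[r0:r1, c0:c1] = True
    return mask


def mlc_regions(outline: np.ndarray, feather_boundary: np.ndarray) -> ROISet:
    """Partition the canvas into object / appendage / background regions.

    object = inside the outline; appendage = feather boundary minus outline;
    background = everything outside the feather boundary.
    """
    outline = np.asarray(outline, dtype=bool)
    feather_boundary = np.asarray(feather_boundary, dtype=bool)
    if np.any(outline & ~feather_boundary):
        raise ValueError("outline must lie within the feather-boundary footprint")
    return ROISet(
        object_region=outline.copy(),
        appendage_region=feather_boundary & ~outline,
        background_region=~feather_boundary,
    )


def apply_shadow_exclusion(
    band: np.ndarray, shadow: np.ndarray
) -> tuple[np.ndarray, float]:
    """Remove shadowed positions from an analysis band.

    Returns the retained mask and the retained fraction
    ``|band \\ shadow| / |band|``; an entirely shadowed band is an error.
    """
    band = np.asarray(band, dtype=bool)
    shadow = np.asarray(shadow, dtype=bool)
    if band.shape != shadow.shape:
        raise ValueError("masks must be aligned")
    total = int(band.sum())
    if total == 0:
        raise ValueError("empty band")
    retained = band & ~shadow
    frac = retained.sum() / total
    if frac == 0:
        raise ValueError("shadow covers the entire band")
    return retained, float(frac)
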