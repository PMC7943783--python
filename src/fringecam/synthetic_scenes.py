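"""Procedural scenes: circular objects with protruding appendages, and
seeded chick-like photograph fixtures.

The artificial-object experiment renders a uniformly light grey disc
(radius 470 px, printed circumference 2950 px, 11.8 px/mm) on a darker
background and adds object-coloured appendages — thin radial line segments of
118 px length — at regular angular intervals, doubling their number stepwise
(0, 32, 64, ..., 512) up to a "full" ring in which the appendage annulus is
completely filled.  Scenario families vary appendage thickness, transparency,
length heterogeneity, background complexity (chessboard) and viewer acuity.

Rendering uses hard pixel assignment (no anti-aliasing) so every scene is
bit-reproducible from its spec.  The two grey levels are not dictated by the
geometry; the defaults (object 0.70, background 0.25) give strongly
supra-threshold edges (ΔS ≈ 10.3 at Weber fraction 0.1) and are configurable.

The chick-scene fixture emulates paired field photographs: a patterned oval
subject on a mottled substrate, rendered once with and once without a fringe
of thin protruding strokes, plus outline / feather-boundary / shadow masks
and a black-backdrop reference crop.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter

from .roi import contour_band

#: Appendage-count stages of the scenario grid.
COUNT_STAGES = (0, 32, 64, 128, 256, 512, "full")

FAMILIES = ("basic", "thickness", "transparency", "length", "background", "acuity")


@dataclass(frozen=True)
class ScenarioSpec:
    """Full geometric/compositing recipe for one artificial-object image."""

    scenario_id: str = "basic-0"
    family: str = "basic"
    variant: str = "basic"
    object_radius_px: float = 470.0
    object_circumference_px: float = 2950.0
    appendage_length_px: float = 118.0
    appendage_thickness_px: float = 4.0
    appendage_count: int | str = 0
    transparency: float = 0.0
    length_profile: tuple[tuple[float, float], ...] = ()
    background: str = "uniform"
    square_px: float | None = None
    px_per_mm: float = 11.8
    object_level: float = 0.70
    background_level: float = 0.25
    acuity_cpd: float = 72.0

    def __post_init__(self) -> None:
        if min(self.object_radius_px, self.appendage_length_px) <= 0:
            raise ValueError("radius and lengths must be > 0")
        if self.appendage_thickness_px <= 0:
            raise ValueError("thickness must be > 0")
        if not 0.0 <= self.transparency <= 1.0:
            raise ValueError("transparency must lie in [0, 1]")
        if not (0 < self.object_level <= 1 and 0 < self.background_level <= 1):
            raise ValueError("grey levels must lie in (0, 1]")
        if self.background == "uniform" and self.object_level == self.background_level:
            raise ValueError("object and background levels must differ")
        if self.background == "chessboard" and not (self.square_px or 0) > 0:
            raise ValueError("chessboard background needs square_px > 0")
        if sum(f for f, _ in self.length_profile) > 1 + 1e-12:
            raise ValueError("length_profile appendage fractions must sum to <= 1")
        if isinstance(self.appendage_count, str) and self.appendage_count != "full":
            raise ValueError("appendage_count must be an integer or 'full'")
        if isinstance(self.appendage_count, int) and self.appendage_count < 0:
            raise ValueError("appendage_count must be >= 0")

    @property
    def full_count(self) -> int:
        """Count at which appendages tile the inner circle completely."""
        return int(self.object_circumference_px // self.appendage_thickness_px)

    @property
    def max_count(self) -> int:
        """Hard capacity: one appendage per pixel of circumference.

        Denser-than-full counts are legal (thick appendages overlap, as in
        the thickness scenarios) and render idempotently; beyond one
        appendage per circumference pixel the request is degenerate.
        """
        return int(self.object_circumference_px)

    @property
    def resolved_count(self) -> int:
        return self.full_count if self.appendage_count == "full" else self.appendage_count

    @property
    def outer_radius_px(self) -> float:
        return self.object_radius_px + self.appendage_length_px

    def default_canvas_side(self) -> int:
        return int(2 * (self.outer_radius_px + 200))


def length_fraction_pattern(
    profile: tuple[tuple[float, float], ...], max_cycle: int = 1024
) -> np.ndarray:
    """Deterministic interleaved cycle of per-appendage length fractions.

    ``profile`` lists (appendage_fraction, length_fraction) groups; appendages
    not covered by the profile keep full length.  Groups are spread as evenly
    as possible around one cycle (largest-deficit scheduling), e.g. a profile
    of half the appendages at 50 % length yields the cycle (0.5, 1.0): every
    second appendage shortened.
    """
    if not profile:
        return np.ones(1)
    fracs = [f for f, _ in profile]
    m = next(
        (
            m
            for m in range(1, max_cycle + 1)
            if all(abs(f * m - round(f * m)) < 1e-9 for f in fracs)
        ),
        max_cycle,
    )
    counts = [round(f * m) for f in fracs]
    lengths = [lf for _, lf in profile]
    counts.append(m - sum(counts))  # remainder keeps full length
    lengths.append(1.0)
    assigned = [0] * len(counts)
    pattern = np.empty(m)
    for k in range(m):
        deficits = [c * (k + 1) / m - a for c, a in zip(counts, assigned)]
        g = int(np.argmax(deficits))
        pattern[k] = lengths[g]
        assigned[g] += 1
    return pattern


def render_background(
    kind: str,
    shape: tuple[int, int],
    level_a: float,
    level_b: float | None = None,
    square_px: float | None = None,
) -> np.ndarray:
    """Uniform or chessboard background raster.

    The chessboard alternates ``level_a``/``level_b`` squares of side
    ``square_px`` anchored at the canvas origin (the (0, 0) square carries
    ``level_a``).
    """
    if kind == "uniform":
        return np.full(shape, float(level_a))
    if kind == "chessboard":
        if not (square_px or 0) > 0:
            raise ValueError("square_px must be > 0 for a chessboard")
        if level_b is None:
            raise ValueError("chessboard needs two levels")
        yy, xx = np.indices(shape)
        parity = (yy // int(square_px) + xx // int(square_px)) % 2
        return np.where(parity == 0, float(level_a), float(level_b))
    raise ValueError(f"unknown background kind {kind!r}")


def _polar(shape: tuple[int, int], center: tuple[float, float]):
    yy, xx = np.indices(shape, dtype=np.float64)
    dy = yy - center[0]
    dx = xx - center[1]
    r = np.hypot(dy, dx)
    theta = np.mod(np.arctan2(dy, dx), 2 * np.pi)
    return r, theta


def appendage_mask(
    shape: tuple[int, int], center: tuple[float, float], spec: ScenarioSpec
) -> np.ndarray:
    """Union pixel mask of all appendages (outside the object disc).

    Discrete counts are radial rectangles of the spec thickness, equally
    spaced in angle, extending from the object radius outward by their
    (profile-scaled) length.  At count "full" the ring is completely filled:
    the mask is the whole appendage annulus.
    """
    n = spec.resolved_count
    if n == 0:
        return np.zeros(shape, dtype=bool)
    r, theta = _polar(shape, center)
    r0 = spec.object_radius_px
    if spec.appendage_count == "full" or (
        not spec.length_profile and n >= spec.full_count
    ):
        return (r > r0) & (r <= r0 + spec.appendage_length_px)
    dtheta = 2 * np.pi / n
    k = np.rint(theta / dtheta).astype(np.int64) % n
    delta = theta - np.rint(theta / dtheta) * dtheta
    pattern = length_fraction_pattern(spec.length_profile)
    lengths = spec.appendage_length_px * pattern[k % pattern.size]
    perp = r * np.abs(np.sin(delta))
    axial = r * np.cos(delta)
    return (
        (r > r0)
        & (perp <= spec.appendage_thickness_px / 2)
        & (axial >= r0)
        & (axial <= r0 + lengths)
    )


def place_appendages(
    base: np.ndarray, spec: ScenarioSpec, center: tuple[float, float] | None = None
) -> np.ndarray:
    """Composite the appendage layer over ``base``.

    Appendage pixels are alpha-composited with ``alpha = 1 − transparency``
    over whatever lies beneath; the mask is a set union, so overlapping
    appendages are drawn idempotently (no double compositing).
    """
    if isinstance(spec.appendage_count, int) and spec.appendage_count > spec.max_count:
        raise ValueError(
            f"appendage_count {spec.appendage_count} exceeds capacity "
            f"{spec.max_count}"
        )
    if center is None:
        center = ((base.shape[0] - 1) / 2, (base.shape[1] - 1) / 2)
    mask = appendage_mask(base.shape, center, spec)
    alpha = 1.0 - spec.transparency
    out = base.copy()
    out[mask] = alpha * spec.object_level + (1 - alpha) * base[mask]
    return out


def render_object_scene(
    spec: ScenarioSpec, canvas_side: int | None = None
) -> np.ndarray:
    """Render a full artificial-object scene (background, disc, appendages).

    The default square canvas side is ``2 × (radius + appendage length +
    200 px)``, large enough for the feather-boundary circle plus a 30 px pad
    and (at the reference geometry) the 1500 px rectangle ROI.
    """
    side = canvas_side if canvas_side is not None else spec.default_canvas_side()
    if side < 2 * (spec.outer_radius_px + 30):
        raise ValueError(
            "canvas too small: must contain the feather-boundary circle plus a "
            "30 px pad"
        )
    if isinstance(spec.appendage_count, int) and spec.appendage_count > spec.max_count:
        raise ValueError(
            f"appendage_count {spec.appendage_count} exceeds capacity "
            f"{spec.max_count}"
        )
    shape = (side, side)
    img = render_background(
        spec.background,
        shape,
        spec.background_level,
        spec.object_level,
        spec.square_px,
    )
    center = ((side - 1) / 2, (side - 1) / 2)
    r, _ = _polar(shape, center)
    img[r <= spec.object_radius_px] = spec.object_level
    return place_appendages(img, spec, center)


def scene_masks(
    spec: ScenarioSpec, canvas_side: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(outline, feather_boundary) disc masks matching the rendered scene."""
    side = canvas_side if canvas_side is not None else spec.default_canvas_side()
    center = ((side - 1) / 2, (side - 1) / 2)
    r, _ = _polar((side, side), center)
    return r <= spec.object_radius_px, r <= spec.outer_radius_px


def scenario_grid(family: str) -> list[ScenarioSpec]:
    """The full factorial of one scenario family: 7 count stages × levels.

    Families: ``basic`` (thin opaque appendages, uniform background, 72 cpd),
    ``thickness`` (8 / 12 px), ``transparency`` (25 % / 50 %), ``length``
    (half at 50 % length; half at 25 % + quarter at 50 %), ``background``
    (chessboard 346 / 86 px squares) and ``acuity`` (30 / 10 cpd).
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown scenario family {family!r}")
    variants: list[tuple[str, dict]] = []
    if family == "basic":
        variants = [("basic", {})]
    elif family == "thickness":
        variants = [
            ("1a", {"appendage_thickness_px": 8.0}),
            ("1b", {"appendage_thickness_px": 12.0}),
        ]
    elif family == "transparency":
        variants = [("2a", {"transparency": 0.25}), ("2b", {"transparency": 0.5})]
    elif family == "length":
        variants = [
            ("3a", {"length_profile": ((0.5, 0.5),)}),
            ("3b", {"length_profile": ((0.5, 0.25), (0.25, 0.5))}),
        ]
    elif family == "background":
        variants = [
            ("4a", {"background": "chessboard", "square_px": 346.0}),
            ("4b", {"background": "chessboard", "square_px": 86.0}),
        ]
    elif family == "acuity":
        variants = [("5a", {"acuity_cpd": 30.0}), ("5b", {"acuity_cpd": 10.0})]
    specs = []
    for variant, kwargs in variants:
        for count in COUNT_STAGES:
            specs.append(
                ScenarioSpec(
                    scenario_id=f"{variant}-{count}",
                    family=family,
                    variant=variant,
                    appendage_count=count,
                    **kwargs,
                )
            )
    return specs


def spec_records(specs: list[ScenarioSpec]) -> list[dict]:
    """Serializable records (one per spec) for a config file."""
    out = []
    for s in specs:
        rec = {k: getattr(s, k) for k in s.__dataclass_fields__}
        rec["length_profile"] = [list(p) for p in s.length_profile]
        out.append(rec)
    return out


def raster_hash(img: np.ndarray) -> str:
    """SHA1 of the exact raster bytes (determinism checks)."""
    return hashlib.sha1(np.ascontiguousarray(img).tobytes()).hexdigest()


# ---------------------------------------------------------------------------
# Chick-photograph fixtures
# ---------------------------------------------------------------------------


@dataclass
class SceneFixture:
    """One synthetic paired-photograph subject.

    ``subject_with_fringe`` / ``subject_without_fringe`` differ only in the
    fringe-stroke pixels (unless independent exposure noise is requested);
    ``reference_image`` is the fringeless subject cropped onto a uniform
    near-black backdrop, used to determine the per-subject HEI threshold.
    """

    seed: int
    fringe_effect: float
    shadow_fraction: float
    background_image: np.ndarray
    subject_with_fringe: np.ndarray
    subject_without_fringe: np.ndarray
    reference_image: np.ndarray
    outline_mask: np.ndarray
    feather_boundary_mask: np.ndarray
    shadow_mask: np.ndarray
    fringe_len_px: float
    px_per_mm: float = 11.8


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")
    f -= f.min()
    peak = f.max()
    return f / peak if peak > 0 else f


def _sector_shadow(
    band: np.ndarray, center, start_angle: float, fraction: float
) -> np.ndarray:
    """Contiguous angular sector of the band covering ≈ ``fraction`` of it."""
    if fraction <= 0:
        return np.zeros_like(band)
    _, theta = _polar(band.shape, center)
    rel = np.mod(theta - start_angle, 2 * np.pi)
    total = band.sum()
    lo, hi = 0.0, 2 * np.pi
    for _ in range(40):  # bisect the sector width
        mid = (lo + hi) / 2
        if (band & (rel <= mid)).sum() / total < fraction:
            lo = mid
        else:
            hi = mid
    return band & (rel <= (lo + hi) / 2)


def synth_chick_scene(
    seed: int,
    fringe_effect: float = 1.0,
    shadow_fraction: float = 0.28,
    size: int = 320,
    exposure_noise: float = 0.0,
    black_level: float = 0.02,
) -> SceneFixture:
    """Generate one seeded paired-photograph fixture.

    A patterned bright oval subject sits on a darker mottled substrate
    (band-limited noise quantized into three luminance patches).  The
    with-fringe rendering adds thin strokes of heterogeneous length
    protruding orthogonally beyond the outline, coloured like the adjacent
    plumage; ``fringe_effect`` scales stroke density (0 → no strokes, the
    with/without rasters are then identical).  ``exposure_noise`` > 0 adds
    independent seeded sensor noise to the two exposures, emulating separate
    photographs.  The shadow mask covers a contiguous arc of the contour
    band with area fraction ≈ ``shadow_fraction``.
    """
    if fringe_effect < 0:
        raise ValueError("fringe_effect must be >= 0")
    if not 0 <= shadow_fraction < 1:
        raise ValueError("shadow_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    shape = (size, size)

    # Mottled substrate: smooth random field quantized into 3 patches.
    field = _smooth_field(rng, shape, size / 32)
    qs = np.quantile(field, [1 / 3, 2 / 3])
    bg = np.select([field < qs[0], field < qs[1]], [0.14, 0.22], 0.32)

    # Oval subject with internal patterning.
    cy = cx = (size - 1) / 2
    a, b = 0.21 * size, 0.15 * size
    phi = rng.uniform(0, np.pi)
    yy, xx = np.indices(shape, dtype=np.float64)
    u = (yy - cy) * math.cos(phi) + (xx - cx) * math.sin(phi)
    v = -(yy - cy) * math.sin(phi) + (xx - cx) * math.cos(phi)
    outline = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    pattern = 0.45 + 0.35 * _smooth_field(rng, shape, size / 40)
    without = np.where(outline, pattern, bg)

    fringe_len = max(6.0, 0.05 * size)
    dist_out = distance_transform_edt(~outline)
    feather = outline | (dist_out <= fringe_len)

    # Fringe strokes: radial 1 px lines from the outline outward.
    with_img = without.copy()
    perimeter = math.pi * (3 * (a + b) - math.sqrt((3 * a + b) * (a + 3 * b)))
    n_strokes = int(round(fringe_effect * perimeter / 2.0))
    if n_strokes > 0:
        from skimage.draw import line as draw_line

        ts = np.sort(rng.uniform(0, 2 * np.pi, n_strokes))
        lens = rng.uniform(0.35, 1.0, n_strokes) * fringe_len
        for t, ln in zip(ts, lens):
            # boundary point of the rotated ellipse and its outward normal
            pu, pv = a * math.cos(t), b * math.sin(t)
            nu, nv = math.cos(t) / a, math.sin(t) / b
            norm = math.hypot(nu, nv)
            nu, nv = nu / norm, nv / norm
            by = cy + pu * math.cos(phi) - pv * math.sin(phi)
            bx = cx + pu * math.sin(phi) + pv * math.cos(phi)
            ny = nu * math.cos(phi) - nv * math.sin(phi)
            nx = nu * math.sin(phi) + nv * math.cos(phi)
            ey, ex = by + ny * ln, bx + nx * ln
            rr, cc = draw_line(
                int(round(by)), int(round(bx)), int(round(ey)), int(round(ex))
            )
            keep = (rr >= 0) & (rr < size) & (cc >= 0) & (cc < size)
            rr, cc = rr[keep], cc[keep]
            colour = pattern[
                min(size - 1, max(0, int(round(by)))),
                min(size - 1, max(0, int(round(bx)))),
            ]
            sel = ~outline[rr, cc] & feather[rr, cc]
            with_img[rr[sel], cc[sel]] = colour

    reference = np.where(outline, without, black_level)

    band = contour_band(outline, feather, pad_px=max(4, round(0.03 * size)))
    shadow = _sector_shadow(band, (cy, cx), rng.uniform(0, 2 * np.pi), shadow_fraction)

    if exposure_noise > 0:
        with_img = with_img + rng.normal(0.0, exposure_noise, shape)
        without = without + rng.normal(0.0, exposure_noise, shape)
        lo = 1.0 / 65536.0
        with_img = np.clip(with_img, lo, 1.0)
        without = np.clip(without, lo, 1.0)

    return SceneFixture(
        seed=seed,
        fringe_effect=fringe_effect,
        shadow_fraction=shadow_fraction,
        background_image=bg,
        subject_with_fringe=with_img,
        subject_without_fringe=without,
        reference_image=reference,
        outline_mask=outline,
        feather_boundary_mask=feather,
        shadow_mask=shadow,
        fringe_len_px=fringe_len,
    )
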