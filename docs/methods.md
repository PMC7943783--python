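# Methods

This note documents the models, conventions and calibrations behind
`fringecam`, in the order the pipeline applies them.

## Scene generation

**Artificial objects.** The reference object is a disc of radius 470 px
(printed circumference 2950 px at 11.8 px/mm, i.e. a 39.8 mm-radius object)
drawn at `object_level` on a background at `background_level`. Appendages
are radial line segments of length 118 px, thickness 4 px (variants 8 and
12 px), placed at equal angular intervals starting at the disc edge,
composited with `alpha = 1 − transparency` over whatever lies beneath.
Appendage counts follow the doubling series 0, 32, 64, 128, 256, 512 up to
"full", the count at which segments tile the inner circle
(⌊circumference/thickness⌋: 737 at 4 px). At "full" — and for any denser
count — the appendage ring is rendered as the completely filled annulus:
radial rectangles necessarily splay apart at the outer radius, and the
filled-ring reading is the only one consistent with a "completely filled"
extended outline and with coverage reaching 1. Counts above the tiling
capacity (the 8/12 px variants at 256–512) simply overlap and are drawn
idempotently from a union mask. Rendering uses hard pixel-centre assignment,
no anti-aliasing, so every scene is a pure function of its spec
(bit-reproducible, and uniform-background scenes have exactly the two or
three predicted grey values).

Length heterogeneity (e.g. half the appendages at 50 % length) is assigned
deterministically by interleaving shortened and full appendages as evenly as
possible around the circle (largest-deficit scheduling) rather than by
random draw, so a spec always renders the same image.

**Grey levels.** The defaults `object_level = 0.70`,
`background_level = 0.25` give a strongly supra-threshold outline
(ΔS = |ln 2.8|/0.1 ≈ 10.3) between a light grey object and dark grey
background. Both are configurable; absolute edge-intensity values scale with
this choice, the curve shapes do not (checked at contrast ratios 2.8
and 4.4).

**Canvas.** Square, side `2 × (radius + appendage length + 200 px)` =
1576 px for the reference geometry, which accommodates the feather-boundary
circle plus the 30 px band pad and the 1500 px rectangle region.

**Chessboard backgrounds** reuse the two grey levels, with square sides
346 px or 86 px anchored at the canvas origin.

## Viewer model and acuity blur

A viewer is specified by Weber fractions (defaults: human
0.05/0.07071/0.1657 for lw/mw/sw, 0.1 for luminance), spatial acuity in
cycles per degree (72 human, 30 corvid, 10 canid), and a viewing distance
(1300 mm). The minimum resolvable angle is `MRA = 1/cpd` degrees; its
footprint on the scene is `distance · tan(MRA)`, 3.72 px at the reference
scale.

Acuity is modelled as a Gaussian blur. Published acuity-control
implementations do not document the constant linking σ to the MRA footprint,
so it is a single exposed parameter (`sigma_factor`). The default, σ = one
full MRA footprint, was *identified* rather than assumed: over a scan of
σ/footprint ∈ [0.5, 1.25] (jointly with the LEIA sampling scale, below),
it is the convention under which the full pipeline reproduces the known
qualitative behaviour of outline diffusion — appendages lower the
high-edge-intensity statistic monotonically to a minimum at an intermediate
count (256 for 4 px appendages) before dense rings re-solidify the
silhouette, low-acuity viewers see far weaker outlines, and the
zero-appendage modal share lands near 1.6 % of the contour band. Halving the
constant (σ = footprint/2) inverts the first of these: thin blurred lines
then retain enough concentrated contrast to *raise* the statistic. Blur
below 0.3 px is skipped with a logged notice.

## RNL filter

The filter is iterative ΔS-gated smoothing: each pixel is replaced by the
weighted mean of itself (weight 1) and every neighbour within 5 px whose
contrast to it — max of luminance and chromatic ΔS — is below 1 ΔS
(one just-noticeable difference); spatial weights fall linearly to zero
between radius − falloff (2 px) and the radius. Five iterations, as in the
published parameterization. Sub-threshold detail (noise, imperceptible
texture) is averaged away while discriminable edges never mix: a
supra-threshold step is a fixed point, outputs stay within the per-channel
input range, and uniform images are unchanged. The inner loop is compiled
with numba; an achromatic fast path covers the grayscale pipeline.

One consequence of the threshold gate is worth stating: a blur ramp whose
interior pixels all differ from *both* flanking levels by more than 1 ΔS is
itself a fixed point, so the filter sharpens blurred edges from their tails
inward but cannot collapse them into perfect steps. See "Known limitations".

## LEIA

For every in-ROI pixel and each of four orientations (horizontal, vertical,
two diagonals), ΔS is measured between the two neighbours straddling the
focal position at ±`offset` pixels (optionally means of short segments).
The default offset is 4 px — the observer's resolution scale (≈ the MRA
footprint and the filter radius at the reference geometry) — so an extended
boundary registers its full amplitude even after acuity blur, whereas a line
thinner than the blur kernel registers only its attenuated one. This choice
resolves an ambiguity in the published description of the analysis (the
finest reading, single neighbours at ±1 px, is available as `offset=1`) and
was identified jointly with the blur constant, as above.

Post-processing follows the published protocol: natural-log transform of
each slice; values of exactly 0 are "no measurement" markers (outside the
ROI, or at borders where a neighbour is missing) and never enter analysis
sets; negative logs — edges weaker than 1 JND, artefacts of no-edge areas —
are clamped to 0 and *retained*; the collapsed map is the parallel maximum
over the four slices. Note the deliberate conflation inherited from the
protocol: an in-ROI position whose measured ΔS is genuinely 0 (bit-identical
flat neighbourhood) is indistinguishable from "no edge" and enters the
analysis set as a clamped 0 via its measured-but-sub-JND orientations; the
analysis set is the full measured ROI, which is what makes modal *shares*
comparable across images.

## Regions of interest

Masks are pixel-centre booleans; radial pads use exact Euclidean distance
transforms (disc structuring elements). The contour band runs from the
outline eroded by 30 px to the feather boundary dilated by 30 px — the
annulus r ∈ [440, 618], a 178 px band, for the reference circle. The
enlarged region is a 1500 × 1500 px rectangle centred on the object. For
the mean-luminance comparison the canvas partitions into object (inside the
outline), appendage (outline to feather boundary) and background (the rest).
Shadowed areas are removed from the band before analysis and the retained
fraction is reported; an entirely shadowed band is an error.

## HEI threshold and mean

Edge-intensity distributions of whole bands are dominated by a point mass at
0 (no-edge positions) plus a continuum and a distinct high mode from the
outline. The threshold procedure fits a Gaussian KDE (Silverman bandwidth,
configurable) to the *positive* values, locates local maxima, and takes the
antimode — the lowest density point between the two largest modes, using the
midpoint of the minimal plateau when the valley is numerically flat. A
unimodal or degenerate sample raises an explicit "no HEI mode" error, never
a silent default. Two usage modes:

- **fraction** (artificial-object protocol): `q` = share of *all* reference
  values above the antimode, determined once from the zero-appendage
  reference (q = 0.0198 under defaults) and reused for every scenario image;
  each image reports the mean of its top ⌈q·n⌉ values (ties at the cut
  resolved by stable positional order).
- **value** (paired-photograph protocol, default there): the antimode itself
  is the threshold, determined per subject from the subject's crop on a
  uniform near-black backdrop; each image reports the mean of values above
  it. Fraction mode is selectable for both.

The paired comparison is a standard two-sided paired t-test on
(without − with) mean-HEI differences with a 95 % t-interval; degenerate
inputs (fewer than 3 pairs, zero-variance differences) are errors.

## Mean luminance comparison

Region means are taken on the same blurred-and-filtered luminance image LEIA
sees, keeping the two detectability mechanisms on one observer stage. For
uniform scenes the appendage-region mean obeys the affine law
`α·object + (1−α)·background` with α the effective coverage
(pixel coverage × (1 − transparency)); the transition optimum (midpoint
luminance) is reached at α = 0.5, which for the reference geometry solves to
≈ 416 appendages — between the 256 and 512 stages. `coverage_fraction` is
the analytic counterpart `count·thickness·mean_length/annulus area`, capped
at 1, with "full" exactly 1 by construction.

## Synthetic paired-photograph fixtures

Each seeded fixture emulates one field subject: a mottled substrate
(band-limited Gaussian field quantized into three luminance patches,
0.14/0.22/0.32), a brighter patterned oval subject (smooth field mapped to
0.45–0.80, random orientation), and a fringe of ~1 px strokes of
heterogeneous length (0.35–1 × the fringe depth, 5 % of the canvas)
protruding outward from the outline, coloured like the adjacent plumage;
`fringe_effect` scales stroke density and 0 disables the fringe entirely
(with/without rasters are then identical). Masks: the outline ellipse, the
feather boundary (outline dilated by the fringe depth), and a contiguous
angular shadow sector sized by bisection to a requested fraction of the
contour band (default 0.28, i.e. 72 % retained). The reference crop places
the fringeless subject on a uniform 0.02 backdrop (photographic black, not
numerical zero). An optional `exposure_noise` adds independent seeded
Gaussian sensor noise to the two exposures, emulating separate photographs;
it defaults to 0 and is switched on for null calibration, where the paired
test's type-I error over 200 replicates is 7 % at α = 5 % (15 subjects,
192 px fixtures, 1 % noise).

What the fixtures do *not* emulate: real plumage texture statistics, depth
of field, illumination gradients, UV reflectance, or manual mask
imprecision. Passing fixture tests therefore demonstrates that the
*protocol* behaves correctly (direction and significance of the fringe
effect, calibrated null), not that any particular field effect size is
recovered; reproducing a field study's printed statistics requires its
original photographs, for which the photograph-directory entry point
(`run_experiment2_photos`) is provided.

## Problem sizes and determinism

Default problem sizes are the reference geometry (1576 px canvases) for the
artificial-object experiment — the full 42-image grid runs in ≈ 4 minutes on
one CPU — and 320 px fixtures (192 px for the 200-replicate null
calibration) for the paired experiment. All randomness flows through
`numpy.random.SeedSequence` children of a single seed; rendering is
seed-free and bit-reproducible, and identical configurations produce
identical output tables (a config hash and the seed are recorded in every
row).

## Known limitations

- **Thickness ordering at high counts.** With 8 px appendages the mean-HEI
  minimum falls at 256 rather than 128 (the 12 px variant does show 128).
  Under the threshold-gated mean filter the partially merged 8 px/256 ring
  (outer-radius coverage 0.56) yields a boundary weaker than the count-128
  outline/line mixture for every blur width explored; an ordering with the
  minimum already at 128 evidently requires a filter with stronger edge
  reconstruction than the ΔS-gate admits (see the filter note above).
- **Very low acuity saturates.** At 10 cpd (σ ≈ 27 px) the 256-appendage
  scene retains no supra-JND edges at all: the mean HEI is exactly 0 rather
  than a small positive value. The qualitative ordering (10 cpd ≪ 72 cpd)
  holds.
- **Value-mode thresholds need a bimodal reference.** Subjects whose
  black-backdrop crop lacks a distinct high mode (possible for weakly
  patterned synthetic subjects at small sizes) are skipped with a logged
  reason rather than given a silent default.
- The cone-catch stage treats synthetic scenes as linear and applies a fixed
  2.2-exponent inverse to photographs; camera-specific calibration is out of
  scope.
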