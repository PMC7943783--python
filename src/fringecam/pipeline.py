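"""End-to-end experiment orchestration.

Experiment 1 renders the artificial-object scenario grid, pushes every image
through the observer chain (cone catch → acuity blur → RNL filter), runs LEIA
on the contour band (or the 1500 px rectangle), and summarizes the mean edge
intensity of the HEI pixels together with the mean-luminance-comparison
fields, one row per image.  The HEI pixel fraction is determined once, from
the zero-appendage reference image, and reused for every scenario image.

Experiment 2 runs the paired with/without-fringe protocol on subjects — either
seeded synthetic fixtures or user-supplied photographs plus masks — with a
per-subject HEI threshold determined from the subject's black-backdrop
reference crop, shadow-excluded contour bands, and a two-sided paired t-test
across subjects.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import hei_stats, imgio, mlc, roi
from .hei_stats import HEIResult, PairedComparison
from .leia import leia_stack, postprocess_stack
from .synthetic_scenes import (
    FAMILIES,
    ScenarioSpec,
    SceneFixture,
    scenario_grid,
    scene_masks,
    render_object_scene,
    synth_chick_scene,
)
from .visual_model import RNLParams, ViewerModel, acuity_blur, rnl_filter, to_cone_catch

logger = logging.getLogger(__name__)

EPS = 1.0 / 65536.0


@dataclass
class RunConfig:
    """Declarative run configuration (CLI / YAML surface)."""

    experiment: str = "exp1"
    families: tuple[str, ...] = FAMILIES
    seed: int = 0
    output_dir: str | None = None
    enlarged_roi: bool = False
    hei_mode: str = "value"
    n_subjects: int = 15
    fringe_effect: float = 1.0
    shadow_fraction: float = 0.28
    fixture_size: int = 320
    exposure_noise: float = 0.0
    subjects_dir: str | None = None
    gamma_mode: str = "srgb22"
    px_per_mm: float = 11.8
    keep_intermediates: bool = False
    sigma_factor: float | None = None
    viewer: dict = field(default_factory=dict)
    rnl: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "families" in data:
            data["families"] = tuple(data["families"])
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def observer_luminance(
    image: np.ndarray,
    viewer: ViewerModel,
    rnl: RNLParams,
    px_per_mm: float,
    gamma_mode: str = "linear",
    sigma_factor: float | None = None,
) -> np.ndarray:
    """Full observer chain on one image, returning the filtered luminance."""
    catch = to_cone_catch(image, gamma_mode)
    lum = acuity_blur(catch.lum, viewer, px_per_mm, sigma_factor)
    return rnl_filter(lum, rnl, viewer)


def measure_edge_values(
    image: np.ndarray,
    roi_mask: np.ndarray,
    viewer: ViewerModel,
    rnl: RNLParams,
    px_per_mm: float,
    gamma_mode: str = "linear",
    sigma_factor: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Observer chain + LEIA on a ROI; returns (analysis values, filtered lum)."""
    lum = observer_luminance(image, viewer, rnl, px_per_mm, gamma_mode, sigma_factor)
    stack = postprocess_stack(leia_stack(lum, roi_mask, viewer.weber_lum))
    return stack.analysis_values(), lum


# ---------------------------------------------------------------------------
# Experiment 1
# ---------------------------------------------------------------------------


def _scene_roi(spec: ScenarioSpec, enlarged: bool, pad_px: float = 30.0):
    outline, feather = scene_masks(spec)
    if enlarged:
        side = spec.default_canvas_side()
        center = ((side - 1) / 2, (side - 1) / 2)
        return roi.rect_roi(outline.shape, center, 1500), outline, feather
    return roi.contour_band(outline, feather, pad_px), outline, feather


def _process_scenario(
    spec: ScenarioSpec,
    rnl_params: RNLParams,
    enlarged: bool,
    viewer_base: ViewerModel,
    sigma_factor: float | None = None,
):
    viewer = ViewerModel(
        weber_lw=viewer_base.weber_lw,
        weber_mw=viewer_base.weber_mw,
        weber_sw=viewer_base.weber_sw,
        weber_lum=viewer_base.weber_lum,
        acuity_cpd=spec.acuity_cpd,
        viewing_distance_mm=viewer_base.viewing_distance_mm,
    )
    img = render_object_scene(spec)
    band, outline, feather = _scene_roi(spec, enlarged)
    values, lum = measure_edge_values(
        img, band, viewer, rnl_params, spec.px_per_mm, sigma_factor=sigma_factor
    )
    regions = roi.mlc_regions(outline, feather)
    mlc_res = mlc.region_means(lum, regions)
    return values, lum, mlc_res


def run_experiment1(
    config: RunConfig | None = None,
    families: tuple[str, ...] | None = None,
    rnl_params: RNLParams | None = None,
    viewer: ViewerModel | None = None,
    enlarged_roi: bool = False,
    reference_hei: HEIResult | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, HEIResult]:
    """Run the artificial-object experiment.

    Returns (per-image results table, per-family argmin summary, the
    reference HEI threshold).  The HEI pixel fraction q comes from the
    zero-appendage basic image unless ``reference_hei`` is supplied.
    Per-image failures are logged and skipped, not fatal.
    """
    config = config or RunConfig()
    families = families or config.families
    rnl_params = rnl_params or RNLParams(**config.rnl)
    viewer = viewer or ViewerModel(**config.viewer)
    enlarged = enlarged_roi or config.enlarged_roi

    if reference_hei is None:
        ref_spec = ScenarioSpec(scenario_id="basic-0", appendage_count=0)
        ref_values, _, _ = _process_scenario(
            ref_spec, rnl_params, enlarged, viewer, config.sigma_factor
        )
        reference_hei = hei_stats.hei_threshold_from_reference(
            ref_values, mode="fraction"
        )
    chash = config.config_hash()

    rows = []
    for family in families:
        for spec in scenario_grid(family):
            try:
                values, lum, mlc_res = _process_scenario(
                    spec, rnl_params, enlarged, viewer, config.sigma_factor
                )
                res = hei_stats.mean_hei(values, reference_hei)
            except Exception:
                logger.exception("scenario %s failed; skipping", spec.scenario_id)
                continue
            rows.append(
                {
                    "scenario": spec.scenario_id,
                    "family": spec.family,
                    "variant": spec.variant,
                    "count": spec.appendage_count,
                    "count_n": spec.resolved_count,
                    "acuity_cpd": spec.acuity_cpd,
                    "q": reference_hei.q,
                    "mean_hei": res.mean_hei,
                    "n_hei_pixels": res.n_pixels,
                    "n_analysis_pixels": res.n_total,
                    "coverage_fraction": mlc.coverage_fraction(spec),
                    "mean_object": mlc_res.mean_object,
                    "mean_appendage": mlc_res.mean_appendage,
                    "mean_background": mlc_res.mean_background,
                    "mlc_transition_score": mlc_res.transition_score,
                    "mlc_is_intermediate": mlc_res.is_intermediate,
                    "seed": config.seed,
                    "config_hash": chash,
                }
            )
    results = pd.DataFrame(rows)
    summary = hei_stats.scenario_curve(results) if len(results) else pd.DataFrame()
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        results.to_csv(out / "experiment1_results.csv", index=False)
        summary.to_csv(out / "experiment1_summary.csv", index=False)
    return results, summary, reference_hei


# ---------------------------------------------------------------------------
# Experiment 2
# ---------------------------------------------------------------------------


def fixture_band(fix: SceneFixture) -> np.ndarray:
    """Contour band of a fixture (outline −pad to feather boundary +pad)."""
    pad = max(4, round(0.03 * fix.outline_mask.shape[0]))
    return roi.contour_band(fix.outline_mask, fix.feather_boundary_mask, pad)


def subject_seeds(seed: int, n_subjects: int) -> np.ndarray:
    """Stable per-subject seeds derived from one master seed."""
    return np.random.SeedSequence(seed).generate_state(n_subjects) % (2**31)


def _measure_subject(
    with_img,
    without_img,
    reference_img,
    band,
    shadow,
    hei_mode: str,
    viewer: ViewerModel,
    rnl_params: RNLParams,
    px_per_mm: float,
    gamma_mode: str = "linear",
):
    ref_values, _ = measure_edge_values(
        reference_img, band, viewer, rnl_params, px_per_mm, gamma_mode
    )
    hei = hei_stats.hei_threshold_from_reference(ref_values, mode=hei_mode)
    retained_band, retained = roi.apply_shadow_exclusion(band, shadow)
    vals_with, _ = measure_edge_values(
        with_img, retained_band, viewer, rnl_params, px_per_mm, gamma_mode
    )
    vals_without, _ = measure_edge_values(
        without_img, retained_band, viewer, rnl_params, px_per_mm, gamma_mode
    )
    res_with = hei_stats.mean_hei(vals_with, hei)
    res_without = hei_stats.mean_hei(vals_without, hei)
    return res_with, res_without, hei, retained


def run_experiment2(
    config: RunConfig | None = None,
    n_subjects: int | None = None,
    seed: int | None = None,
    fringe_effect: float | None = None,
    shadow_fraction: float | None = None,
    size: int | None = None,
    exposure_noise: float | None = None,
    hei_mode: str | None = None,
    viewer: ViewerModel | None = None,
    rnl_params: RNLParams | None = None,
) -> tuple[PairedComparison, pd.DataFrame]:
    """Paired with/without-fringe comparison on seeded synthetic subjects."""
    config = config or RunConfig(experiment="exp2")
    n_subjects = n_subjects if n_subjects is not None else config.n_subjects
    seed = seed if seed is not None else config.seed
    fringe_effect = (
        fringe_effect if fringe_effect is not None else config.fringe_effect
    )
    shadow_fraction = (
        shadow_fraction if shadow_fraction is not None else config.shadow_fraction
    )
    size = size if size is not None else config.fixture_size
    exposure_noise = (
        exposure_noise if exposure_noise is not None else config.exposure_noise
    )
    hei_mode = hei_mode or config.hei_mode
    viewer = viewer or ViewerModel(**config.viewer)
    rnl_params = rnl_params or RNLParams(**config.rnl)

    rows, with_means, without_means, ids = [], [], [], []
    for i, sseed in enumerate(subject_seeds(seed, n_subjects)):
        fix = synth_chick_scene(
            int(sseed),
            fringe_effect=fringe_effect,
            shadow_fraction=shadow_fraction,
            size=size,
            exposure_noise=exposure_noise,
        )
        band = fixture_band(fix)
        try:
            res_w, res_wo, hei, retained = _measure_subject(
                fix.subject_with_fringe,
                fix.subject_without_fringe,
                fix.reference_image,
                band,
                fix.shadow_mask,
                hei_mode,
                viewer,
                rnl_params,
                fix.px_per_mm,
            )
        except Exception:
            logger.exception("subject %d (seed %d) failed; skipping", i, sseed)
            continue
        ids.append(i)
        with_means.append(res_w.mean_hei)
        without_means.append(res_wo.mean_hei)
        rows.append(
            {
                "subject": i,
                "subject_seed": int(sseed),
                "mean_hei_with": res_w.mean_hei,
                "mean_hei_without": res_wo.mean_hei,
                "hei_threshold": hei.threshold_value,
                "hei_q": hei.q,
                "retained_fraction": retained,
                "seed": seed,
                "config_hash": config.config_hash(),
            }
        )
    comparison = hei_stats.paired_comparison(with_means, without_means, ids)
    table = pd.DataFrame(rows)
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "experiment2_subjects.csv", index=False)
    return comparison, table


def run_experiment2_photos(
    subjects_dir,
    hei_mode: str = "value",
    gamma_mode: str = "srgb22",
    viewer: ViewerModel | None = None,
    rnl_params: RNLParams | None = None,
    px_per_mm: float = 11.8,
    band_pad_px: float = 30.0,
) -> tuple[PairedComparison, pd.DataFrame]:
    """Paired comparison on user-supplied photographs.

    ``subjects_dir`` holds, per subject id, ``<id>_with.<ext>``,
    ``<id>_without.<ext>`` and ``<id>_reference.<ext>`` rasters (PNG/TIFF/
    JPEG) plus ``<id>_outline.png`` and ``<id>_feather.png`` masks and an
    optional ``<id>_shadow.png``.  Subjects with missing files are skipped
    with a logged reason.
    """
    viewer = viewer or ViewerModel()
    rnl_params = rnl_params or RNLParams()
    root = Path(subjects_dir)
    subject_ids = sorted(
        {p.name.rsplit("_with", 1)[0] for p in root.glob("*_with.*")}
    )
    rows, with_means, without_means, ids = [], [], [], []
    for sid in subject_ids:
        try:
            def find(tag):
                hits = sorted(root.glob(f"{sid}_{tag}.*"))
                if not hits:
                    raise FileNotFoundError(f"{sid}: missing {tag} image")
                return hits[0]

            with_img = _to_gray(imgio.read_image(find("with")))
            without_img = _to_gray(imgio.read_image(find("without")))
            reference_img = _to_gray(imgio.read_image(find("reference")))
            outline = imgio.read_mask(find("outline"))
            feather = imgio.read_mask(find("feather"))
            shadow_files = sorted(root.glob(f"{sid}_shadow.*"))
            shadow = (
                imgio.read_mask(shadow_files[0])
                if shadow_files
                else np.zeros_like(outline)
            )
            band = roi.contour_band(outline, feather, band_pad_px)
            res_w, res_wo, hei, retained = _measure_subject(
                np.maximum(with_img, EPS),
                np.maximum(without_img, EPS),
                np.maximum(reference_img, EPS),
                band,
                shadow,
                hei_mode,
                viewer,
                rnl_params,
                px_per_mm,
                gamma_mode,
            )
        except Exception as exc:
            logger.warning("subject %s skipped: %s", sid, exc)
            continue
        ids.append(sid)
        with_means.append(res_w.mean_hei)
        without_means.append(res_wo.mean_hei)
        rows.append(
            {
                "subject": sid,
                "mean_hei_with": res_w.mean_hei,
                "mean_hei_without": res_wo.mean_hei,
                "hei_threshold": hei.threshold_value,
                "hei_q": hei.q,
                "retained_fraction": retained,
            }
        )
    comparison = hei_stats.paired_comparison(with_means, without_means, ids)
    return comparison, pd.DataFrame(rows)


def _to_gray(img: np.ndarray) -> np.ndarray:
    return img.mean(axis=2) if img.ndim == 3 else img


def null_rejection_rate(
    n_replicates: int = 200,
    n_subjects: int = 15,
    seed: int = 0,
    size: int = 192,
    exposure_noise: float = 0.01,
    alpha: float = 0.05,
    hei_mode: str = "value",
    viewer: ViewerModel | None = None,
    rnl_params: RNLParams | None = None,
) -> tuple[float, np.ndarray]:
    """Type-I-error calibration of the paired protocol under no fringe effect.

    The same ``n_subjects`` fringeless subjects are re-photographed with
    independent exposure noise in every replicate; per-subject HEI thresholds
    come from the (noise-free) reference crops, computed once.  Returns the
    rejection fraction at ``alpha`` and the replicate p-values.
    """
    viewer = viewer or ViewerModel()
    rnl_params = rnl_params or RNLParams()
    subjects = []
    for sseed in subject_seeds(seed, n_subjects):
        fix = synth_chick_scene(
            int(sseed), fringe_effect=0.0, shadow_fraction=0.28, size=size
        )
        band = fixture_band(fix)
        ref_values, _ = measure_edge_values(
            fix.reference_image, band, viewer, rnl_params, fix.px_per_mm
        )
        hei = hei_stats.hei_threshold_from_reference(ref_values, mode=hei_mode)
        retained_band, _ = roi.apply_shadow_exclusion(band, fix.shadow_mask)
        subjects.append((fix, retained_band, hei))

    rng = np.random.default_rng(np.random.SeedSequence([seed, 987654321]))
    pvals = np.empty(n_replicates)
    for r in range(n_replicates):
        with_means, without_means = [], []
        for fix, retained_band, hei in subjects:
            base = fix.subject_without_fringe  # no fringe: both exposures match
            means = []
            for _ in range(2):
                noisy = np.clip(
                    base + rng.normal(0.0, exposure_noise, base.shape), EPS, 1.0
                )
                vals, _ = measure_edge_values(
                    noisy, retained_band, viewer, rnl_params, fix.px_per_mm
                )
                means.append(hei_stats.mean_hei(vals, hei).mean_hei)
            with_means.append(means[0])
            without_means.append(means[1])
        pvals[r] = hei_stats.paired_comparison(with_means, without_means).p
    return float(np.mean(pvals < alpha)), pvals
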