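"""High-edge-intensity (HEI) pixel statistics and the paired comparison.

The per-pixel edge intensities of a scene are multimodal: most of the
analysis region carries little or no edge signal while outline pixels form a
distinct high-intensity mode.  The HEI threshold is read off a reference
image as the antimode — the density minimum separating the high-intensity
mode from the rest of the distribution — estimated by a Gaussian kernel
density fit.  The threshold is used either as a pixel *fraction* q (share of
reference values above the antimode; each analysis image then contributes the
mean of its top ⌈q·n⌉ values) or as an absolute edge-intensity *value*
(mean of values above it).  Paired with/without measurements are compared
with a two-sided paired t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats


class NoHeiModeError(ValueError):
    """The edge-intensity distribution has no distinct high-intensity mode."""


@dataclass
class HEIResult:
    """Threshold definition plus (once filled) the mean HEI statistic."""

    mode: str  # "fraction" | "value"
    q: float
    threshold_value: float
    mean_hei: float | None = None
    n_pixels: int | None = None
    n_total: int | None = None


@dataclass
class PairedComparison:
    """Per-subject with/without mean-HEI pairs and the paired-test summary."""

    subject_ids: list
    mean_hei_with: np.ndarray
    mean_hei_without: np.ndarray
    t: float
    df: int
    p: float
    mean_diff: float
    ci95: tuple[float, float]

    @property
    def n_lower_with(self) -> int:
        """Subjects whose with-fringe mean HEI is the lower of the pair."""
        return int(np.sum(self.mean_hei_with < self.mean_hei_without))

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": self.subject_ids,
                "mean_hei_with": self.mean_hei_with,
                "mean_hei_without": self.mean_hei_without,
                "diff_without_minus_with": self.mean_hei_without - self.mean_hei_with,
            }
        )


def density_profile(
    values: np.ndarray, grid_size: int = 1024, bw_method="silverman"
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-KDE density of an edge-intensity sample on a regular grid."""
    v = np.asarray(values, dtype=np.float64).ravel()
    kde = stats.gaussian_kde(v, bw_method=bw_method)
    h = math.sqrt(float(kde.covariance[0, 0]))
    grid = np.linspace(v.min() - 3 * h, v.max() + 3 * h, grid_size)
    return grid, kde(grid)


def _local_maxima(density: np.ndarray) -> np.ndarray:
    """Indices of strict-or-plateau local maxima of a 1-D density curve."""
    idx = []
    n = density.size
    i = 1
    while i < n - 1:
        if density[i] > density[i - 1]:
            j = i
            while j < n - 1 and density[j + 1] == density[j]:
                j += 1
            if j == n - 1 or density[j + 1] < density[j]:
                idx.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return np.asarray(idx, dtype=int)


def hei_threshold_from_reference(
    values,
    mode: str = "fraction",
    bw_method="silverman",
    grid_size: int = 1024,
    min_n: int = 1000,
) -> HEIResult:
    """Determine the HEI threshold from a reference edge-intensity sample.

    Finds the antimode (lowest-density point between the two largest modes of
    the KDE; the midpoint of the minimal plateau when the density is flat
    between well-separated modes).  Values of exactly 0 are the clamped
    "no edge" floor, not edge-intensity modes, so the density is estimated on
    the positive values; ``q`` is nevertheless the share of *all* reference
    values above the antimode, and ``threshold_value`` is the antimode
    itself.  A unimodal or degenerate sample raises :class:`NoHeiModeError`
    — never a silent default.
    """
    if mode not in ("fraction", "value"):
        raise ValueError("mode must be 'fraction' or 'value'")
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size < min_n:
        raise ValueError(f"need at least {min_n} reference values, got {v.size}")
    pos = v[v > 0]
    if pos.size < 2 or np.ptp(pos) == 0:
        raise NoHeiModeError("degenerate reference values: no HEI mode")
    grid, density = density_profile(pos, grid_size=grid_size, bw_method=bw_method)
    maxima = _local_maxima(density)
    if maxima.size < 2:
        raise NoHeiModeError("unimodal edge-intensity distribution: no HEI mode")
    top_two = maxima[np.argsort(density[maxima])[-2:]]
    lo_idx, hi_idx = int(top_two.min()), int(top_two.max())
    segment = density[lo_idx : hi_idx + 1]
    dmin = segment.min()
    # Midpoint of the contiguous minimal-density plateau containing the argmin
    # (the density can be numerically flat between well-separated modes).
    tol = dmin * 1e-9 + 1e-300
    low = segment <= dmin + tol
    arg = int(np.argmin(segment))
    left = arg
    while left > 0 and low[left - 1]:
        left -= 1
    right = arg
    while right < segment.size - 1 and low[right + 1]:
        right += 1
    antimode = float(grid[lo_idx + (left + right) // 2])
    q = float(np.mean(v > antimode))
    if not 0 < q < 1:
        raise NoHeiModeError("antimode does not separate a high-intensity mode")
    return HEIResult(mode=mode, q=q, threshold_value=antimode)


def mean_hei(values, hei: HEIResult) -> HEIResult:
    """Mean edge intensity of the HEI pixels of one analysis image.

    Fraction mode: mean of the top ``⌈q·n⌉`` values, ties at the cut resolved
    by stable (positional) order.  Value mode: mean of values strictly above
    the threshold.  Returns a filled copy of ``hei``.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0:
        raise ValueError("empty value set")
    if hei.mode == "fraction":
        if hei.q * v.size < 1:
            raise ValueError("q*n < 1: no HEI pixels at this fraction")
        k = math.ceil(hei.q * v.size)
        order = np.argsort(-v, kind="stable")[:k]
        sel = v[order]
    else:
        sel = v[v > hei.threshold_value]
        if sel.size == 0:
            raise ValueError("no values above the HEI threshold")
    return replace(
        hei, mean_hei=float(sel.mean()), n_pixels=int(sel.size), n_total=int(v.size)
    )


def paired_comparison(
    mean_hei_with, mean_hei_without, subject_ids=None
) -> PairedComparison:
    """Two-sided paired t-test on (without − with) mean-HEI differences."""
    w = np.asarray(mean_hei_with, dtype=np.float64)
    wo = np.asarray(mean_hei_without, dtype=np.float64)
    if w.shape != wo.shape or w.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D sequences")
    n = w.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    diffs = wo - w
    sd = diffs.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences: paired t-test undefined")
    res = stats.ttest_rel(wo, w)
    df = n - 1
    mean_diff = float(diffs.mean())
    half = stats.t.ppf(0.975, df) * sd / math.sqrt(n)
    if subject_ids is None:
        subject_ids = list(range(n))
    return PairedComparison(
        subject_ids=list(subject_ids),
        mean_hei_with=w,
        mean_hei_without=wo,
        t=float(res.statistic),
        df=df,
        p=float(res.pvalue),
        mean_diff=mean_diff,
        ci95=(mean_diff - half, mean_diff + half),
    )


def scenario_curve(results: pd.DataFrame) -> pd.DataFrame:
    """Per-family/variant argmin of the mean-HEI curve over appendage counts.

    ``results`` needs columns family, variant, count, count_n (numeric count
    for ordering) and mean_hei; returns one row per (family, variant) with the
    count at which mean HEI is lowest.
    """
    rows = []
    for (family, variant), grp in results.groupby(["family", "variant"], sort=False):
        grp = grp.sort_values("count_n")
        best = grp.loc[grp["mean_hei"].idxmin()]
        rows.append(
            {
                "family": family,
                "variant": variant,
                "argmin_count": best["count"],
                "argmin_count_n": best["count_n"],
                "min_mean_hei": best["mean_hei"],
            }
        )
    return pd.DataFrame(rows)
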