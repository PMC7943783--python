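"""Numba inner loops for the RNL ranked filter."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def rnl_gray(q, dys, dxs, ws, iterations, thresh, weber_lum):
    h, w = q.shape
    cur = q.copy()
    inv_weber = 1.0 / weber_lum
    for _ in range(iterations):
        lg = np.log(cur)
        out = np.empty_like(cur)
        for i in range(h):
            for j in range(w):
                lf = lg[i, j]
                acc = cur[i, j]
                wsum = 1.0
                for k in range(dys.size):
                    ii = i + dys[k]
                    jj = j + dxs[k]
                    if 0 <= ii < h and 0 <= jj < w:
                        ds = abs(lf - lg[ii, jj]) * inv_weber
                        if ds < thresh:
                            acc += ws[k] * cur[ii, jj]
                            wsum += ws[k]
                out[i, j] = acc / wsum
        cur = out
    return cur


@njit(cache=True)
def rnl_color(
    lw, mw, sw, dys, dxs, ws, iterations, thresh, weber_lum, e_lw, e_mw, e_sw
):
    h, w = lw.shape
    c1 = lw.copy()
    c2 = mw.copy()
    c3 = sw.copy()
    inv_weber = 1.0 / weber_lum
    den = (e_lw * e_mw) ** 2 + (e_lw * e_sw) ** 2 + (e_mw * e_sw) ** 2
    for _ in range(iterations):
        l1 = np.log(c1)
        l2 = np.log(c2)
        l3 = np.log(c3)
        llum = np.log((c1 + c2) / 2.0)
        o1 = np.empty_like(c1)
        o2 = np.empty_like(c2)
        o3 = np.empty_like(c3)
        for i in range(h):
            for j in range(w):
                a1 = c1[i, j]
                a2 = c2[i, j]
                a3 = c3[i, j]
                wsum = 1.0
                for k in range(dys.size):
                    ii = i + dys[k]
                    jj = j + dxs[k]
                    if 0 <= ii < h and 0 <= jj < w:
                        ds_lum = abs(llum[i, j] - llum[ii, jj]) * inv_weber
                        d1 = l1[i, j] - l1[ii, jj]
                        d2 = l2[i, j] - l2[ii, jj]
                        d3 = l3[i, j] - l3[ii, jj]
                        num = (
                            e_sw**2 * (d1 - d2) ** 2
                            + e_mw**2 * (d1 - d3) ** 2
                            + e_lw**2 * (d2 - d3) ** 2
                        )
                        ds_chrom = np.sqrt(num / den)
                        if max(ds_lum, ds_chrom) < thresh:
                            a1 += ws[k] * c1[ii, jj]
                            a2 += ws[k] * c2[ii, jj]
                            a3 += ws[k] * c3[ii, jj]
                            wsum += ws[k]
                o1[i, j] = a1 / wsum
                o2[i, j] = a2 / wsum
                o3[i, j] = a3 / wsum
        c1, c2, c3 = o1, o2, o3
    return c1, c2, c3
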