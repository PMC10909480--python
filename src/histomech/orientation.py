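"""Local collagen-fibre orientation of the stromal phase.

The stroma is tiled into non-overlapping square sub-regions, each much
smaller than the characteristic stromal length scale, and a dominant
axial direction per sub-region is estimated with the classical gradient
structure tensor of the (smoothed) stroma indicator.  Fibres run along
stromal channels, i.e. along edges of the indicator, which is the
eigenvector of the *smaller* structure-tensor eigenvalue.  Coherence
(lmax - lmin)/(lmax + lmin) in [0, 1] measures how directed the window
is.  Windows with too little stroma inherit the orientation of the
nearest valid window, so every stromal finite element can be assigned a
fibre direction.
"""
from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import LabelImage, OrientationMap, STROMA, wrap_axial_deg

MIN_STROMA_FRACTION = 0.25


def local_orientation_map(label: LabelImage, window_px: int = 32,
                          sigma_px: float = 2.0) -> OrientationMap:
    """Structure-tensor orientation map on non-overlapping windows.

    Per window the 2x2 structure tensor of the smoothed stroma indicator
    is accumulated over stromal pixels; the axial orientation along
    edges/channels and a [0, 1] coherence are stored at every pixel of
    the window (nan outside stroma).
    """
    if window_px < 4:
        raise ValueError("window_px must be >= 4")
    stroma = label.phase_mask(STROMA)
    if not stroma.any():
        raise ValueError("no stromal pixels: orientation undefined")

    ind = ndimage.gaussian_filter(stroma.astype(float), sigma_px,
                                  mode="nearest")
    gy, gx = np.gradient(ind)  # axis 0 is y (row 0 at the bottom)
    Jxx, Jxy, Jyy = gx * gx, gx * gy, gy * gy

    ny, nx = stroma.shape
    # the smoothed indicator is unreliable where the filter support
    # leaves the raster; keep a border band out of the statistics
    margin = int(np.ceil(3 * sigma_px)) + 1
    accum = np.zeros_like(stroma)
    if ny > 2 * margin and nx > 2 * margin:
        accum[margin:ny - margin, margin:nx - margin] = True
        accum &= stroma
    else:
        accum = stroma
    nwy = (ny + window_px - 1) // window_px
    nwx = (nx + window_px - 1) // window_px
    win_angle = np.full((nwy, nwx), np.nan)
    win_coh = np.zeros((nwy, nwx))
    valid = np.zeros((nwy, nwx), dtype=bool)

    for wi in range(nwy):
        for wj in range(nwx):
            sl = (slice(wi * window_px, min((wi + 1) * window_px, ny)),
                  slice(wj * window_px, min((wj + 1) * window_px, nx)))
            m = accum[sl]
            if m.sum() < MIN_STROMA_FRACTION * window_px**2:
                continue
            jxx = Jxx[sl][m].sum()
            jxy = Jxy[sl][m].sum()
            jyy = Jyy[sl][m].sum()
            tr = jxx + jyy
            disc = np.sqrt((jxx - jyy) ** 2 + 4 * jxy**2)
            coh = 0.0 if tr <= 0 else disc / tr
            # dominant gradient direction; edges run perpendicular to it
            grad_angle = 0.5 * np.degrees(np.arctan2(2 * jxy, jxx - jyy))
            win_angle[wi, wj] = wrap_axial_deg(grad_angle + 90.0)
            win_coh[wi, wj] = min(coh, 1.0)
            valid[wi, wj] = True

    if not valid.any():
        raise ValueError("no window reaches the minimum stromal fraction")

    # stroma-poor windows copy the nearest valid window (row-major ties)
    if not valid.all():
        vi, vj = np.nonzero(valid)
        ii, jj = np.meshgrid(np.arange(nwy), np.arange(nwx), indexing="ij")
        d2 = (ii.ravel()[:, None] - vi[None, :]) ** 2 \
            + (jj.ravel()[:, None] - vj[None, :]) ** 2
        nearest = np.argmin(d2, axis=1)  # argmin takes first (row-major) tie
        win_angle = win_angle[vi[nearest], vj[nearest]].reshape(nwy, nwx)
        win_coh = win_coh[vi[nearest], vj[nearest]].reshape(nwy, nwx)

    angle = np.repeat(np.repeat(win_angle, window_px, axis=0),
                      window_px, axis=1)[:ny, :nx]
    coh = np.repeat(np.repeat(win_coh, window_px, axis=0),
                    window_px, axis=1)[:ny, :nx]
    angle = np.where(stroma, angle, np.nan)
    coh = np.where(stroma, coh, 0.0)
    return OrientationMap(angle, coh, window_px=window_px,
                         pixel_size_um=label.pixel_size_um)


def element_orientation(omap: OrientationMap, x_um: float, y_um: float) -> float:
    """Fibre angle at a physical point; nan for non-stromal queries."""
    j = int(np.floor(x_um / omap.pixel_size_um))
    i = int(np.floor(y_um / omap.pixel_size_um))
    ny, nx = omap.shape
    if not (0 <= i < ny and 0 <= j < nx):
        raise ValueError(
            f"query point ({x_um}, {y_um}) um lies outside the raster")
    return float(omap.angle_deg[i, j])
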