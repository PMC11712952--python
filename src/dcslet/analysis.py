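"""Beamlet and plan analysis: filters, profiles, histograms, plan metrics.

Reduces voxel maps to the quantities of interest: the depth of the Bragg
peak, planar dose-weighted LET_d, LET_d in the lateral penumbra at the 10 %
dose level, cumulative dose- / LET- / dose-difference-volume histograms, and
the summary table of plan metrics (all doses normalized to the physical
target D95).

All filters are mask-aware: voxels that carry NaN (statistically masked
LET) are ignored by the neighborhoods rather than polluting them, and edges
use shrunken neighborhoods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage


def median_filter(volume: np.ndarray, span: int = 1) -> np.ndarray:
    """Median filter with a ``span``-voxel cubic neighborhood (default 3x3x3).

    NaN voxels are excluded from every neighborhood; edge voxels use the
    shrunken neighborhood that fits inside the volume.  A voxel whose whole
    neighborhood is NaN stays NaN.
    """
    if volume.ndim != 3:
        raise ValueError("median_filter expects a 3D volume")
    v = np.pad(volume.astype(np.float32), span, constant_values=np.nan)
    shifts = []
    rng = range(-span, span + 1)
    for dx in rng:
        for dy in rng:
            for dz in rng:
                shifts.append(v[span + dx: v.shape[0] - span + dx,
                               span + dy: v.shape[1] - span + dy,
                               span + dz: v.shape[2] - span + dz])
    stack = np.stack(shifts, axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        out = np.nanmedian(stack, axis=0)
    return out.astype(volume.dtype, copy=False)


def gaussian_smooth(volume: np.ndarray, sigma: float = 0.5) -> np.ndarray:
    """Separable Gaussian smoothing, sigma in voxels, kernel truncated at 4 sigma.

    NaN-aware: finite values are smoothed with a renormalized kernel
    (normalized convolution); NaN voxels remain NaN.
    """
    finite = np.isfinite(volume)
    filled = np.where(finite, volume, 0.0)
    num = ndimage.gaussian_filter(filled, sigma, truncate=4.0, mode="constant")
    den = ndimage.gaussian_filter(finite.astype(float), sigma, truncate=4.0,
                                  mode="constant")
    with np.errstate(invalid="ignore"):
        out = num / den
    out[~finite] = np.nan
    return out


def find_bragg_peak(depth_cm: np.ndarray, values: np.ndarray) -> float:
    """Depth of the curve maximum with parabolic refinement (cm).

    Requires an interior maximum; a monotone curve raises.
    """
    depth_cm = np.asarray(depth_cm, float)
    values = np.asarray(values, float)
    i = int(np.argmax(values))
    if i == 0 or i == len(values) - 1:
        raise ValueError("depth curve has no interior maximum")
    y0, y1, y2 = values[i - 1], values[i], values[i + 1]
    denom = y0 - 2.0 * y1 + y2
    delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    return float(depth_cm[i] + delta * (depth_cm[1] - depth_cm[0]))


def planar_dose_weighted_letd(dose_map: np.ndarray, letd_map: np.ndarray,
                              grid, z_cm: float) -> float:
    """Dose-weighted mean LET_d over the lateral plane at depth z (keV/um).

    Sums LET_d * dose over the plane's unmasked voxels, normalized by the
    summed dose.
    """
    k = int(np.floor((z_cm - grid.origin[2]) / grid.spacing[2]))
    if not 0 <= k < grid.dims[2]:
        raise ValueError("plane outside grid")
    d = dose_map[:, :, k]
    l = letd_map[:, :, k]
    ok = np.isfinite(l) & (d > 0)
    if d[ok].sum() <= 0:
        raise ValueError("zero-dose plane")
    return float(np.sum(l[ok] * d[ok]) / np.sum(d[ok]))


def penumbra_letd_at_10pct(positions_cm: np.ndarray, dose_profile: np.ndarray,
                           letd_profile: np.ndarray, level: float = 0.1):
    """LET_d at the lateral positions where dose falls to 10 % of the profile peak.

    Returns (left, right): the LET_d linearly interpolated at the outermost
    crossing of ``level * max(dose)`` on each side of the peak.  Raises when
    a side never crosses the level inside the profile.
    """
    x = np.asarray(positions_cm, float)
    d = np.asarray(dose_profile, float)
    l = np.asarray(letd_profile, float)
    if d.max() <= 0:
        raise ValueError("profile peak must be positive")
    thr = level * d.max()
    ipk = int(np.argmax(d))

    def crossing(side):
        idx = range(ipk, 0, -1) if side == "left" else range(ipk, len(d) - 1)
        stepd = -1 if side == "left" else 1
        found = None
        for i in idx:
            j = i + stepd
            if (d[i] - thr) * (d[j] - thr) <= 0 and d[i] != d[j]:
                t = (thr - d[i]) / (d[j] - d[i])
                found = (i, j, t)  # keep last -> outermost crossing
        if found is None:
            raise ValueError(f"no {level:.0%} crossing on the {side} side")
        i, j, t = found
        li, lj = l[i], l[j]
        if not np.isfinite(li):
            li = lj
        if not np.isfinite(lj):
            lj = li
        return float(li + t * (lj - li))

    return crossing("left"), crossing("right")


@dataclass(frozen=True)
class HistogramCurve:
    """Cumulative volume histogram: fraction of ROI volume >= each edge."""

    bin_edges: np.ndarray
    volume_fraction: np.ndarray

    def value_at_volume(self, fraction: float) -> float:
        """Smallest threshold received by at least ``fraction`` of the volume."""
        return float(np.interp(fraction, self.volume_fraction[::-1],
                               self.bin_edges[::-1]))


def volume_histogram(volume: np.ndarray, roi_mask: np.ndarray,
                     bin_edges: np.ndarray | None = None,
                     kind: str = "dose") -> HistogramCurve:
    """Cumulative volume-fraction-at-or-above curve for an ROI.

    ``kind`` labels the axis (dose, letd or difference); for ``difference``
    pass the (RBE-weighted minus physical) map directly.
    """
    if not np.any(roi_mask):
        raise ValueError("empty ROI")
    vals = np.asarray(volume)[roi_mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("ROI contains no defined voxels")
    if bin_edges is None:
        lo = min(0.0, vals.min())
        hi = vals.max() * 1.001 + 1e-12
        bin_edges = np.linspace(lo, hi, 512)
    frac = np.array([(vals >= e).mean() for e in bin_edges])
    return HistogramCurve(np.asarray(bin_edges, float), frac)


def dose_percentile(volume: np.ndarray, roi_mask: np.ndarray, q: float) -> float:
    """D_q: the value received by at least q of the ROI volume (q in (0,1))."""
    vals = np.asarray(volume)[roi_mask]
    vals = vals[np.isfinite(vals)]
    return float(np.percentile(vals, 100.0 * (1.0 - q)))


def volume_at_least(volume: np.ndarray, threshold: float,
                    voxel_volume_cm3: float,
                    roi_mask: np.ndarray | None = None) -> float:
    """Absolute volume (cm^3) receiving at least ``threshold``."""
    arr = np.asarray(volume)
    sel = arr >= threshold
    if roi_mask is not None:
        sel &= roi_mask
    return float(np.count_nonzero(sel) * voxel_volume_cm3)


def plan_metrics(dose_map: np.ndarray, rbe_dose_map: np.ndarray,
                 letd_map: np.ndarray, rois: dict, prescription: float,
                 voxel_volume_cm3: float) -> pd.DataFrame:
    """Summary metric table for one plan, physical and RBE-weighted.

    Doses are normalized to the physical target D95; rows: target D95,
    normal-tissue ring median doses, body mean, skin max, half-prescription
    volume V50 (cm^3), and the target LET_d upper quartile (keV/um, physical
    column only).
    """
    d95_phys = dose_percentile(dose_map, rois["target"], 0.95)
    rows = []

    def add(metric, phys_val, rbe_val):
        rows.append({"metric": metric, "physical": phys_val,
                     "rbe_weighted": rbe_val})

    norm = d95_phys
    add("target_D95", dose_percentile(dose_map, rois["target"], 0.95) / norm,
        dose_percentile(rbe_dose_map, rois["target"], 0.95) / norm)
    for ring in ("ring_5mm", "ring_10mm", "ring_20mm"):
        if ring in rois and np.any(rois[ring]):
            add(f"{ring}_median",
                float(np.median(dose_map[rois[ring]])) / norm,
                float(np.median(rbe_dose_map[rois[ring]])) / norm)
    if "body" in rois:
        add("body_mean", float(dose_map[rois["body"]].mean()) / norm,
            float(rbe_dose_map[rois["body"]].mean()) / norm)
    if "skin" in rois:
        add("skin_max", float(dose_map[rois["skin"]].max()) / norm,
            float(rbe_dose_map[rois["skin"]].max()) / norm)
    add("V50_cm3",
        volume_at_least(dose_map, 0.5 * prescription, voxel_volume_cm3),
        volume_at_least(rbe_dose_map, 0.5 * prescription, voxel_volume_cm3))
    tl = letd_map[rois["target"]]
    tl = tl[np.isfinite(tl)]
    add("target_letd_upper_quartile", float(np.percentile(tl, 75.0)), np.nan)
    return pd.DataFrame(rows)
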