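"""Per-voxel LET scorers and planar spectral tallies.

Each transport step contributes three accumulators to every voxel its
segment traverses: the energy transfer ``sum_e`` (MeV), the path length
``sum_l`` (cm) and the squared-energy-per-path term ``sum_e2_over_l``
(MeV^2/cm).  The track-averaged and dose-averaged LET of a voxel are then

    LET_t = sum_e / sum_l            LET_d = sum_e2_over_l / sum_e

converted to keV/um.  Steps crossing voxel faces are split exactly at the
faces, sub-step j receiving eps_j = eps * l_j / l, so merging runs and
splitting steps are both exact (accumulator addition commutes with the
conversions).

Zero-length point deposits (cutoff kills, lumped nuclear deposits, local
electron deposits) are kept in a separate dose-only accumulator
``sum_e_point``: a pathless energy lump inside the LET_d denominator would
break the Cauchy-Schwarz ordering LET_d >= LET_t that the track tallies
guarantee.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from dcslet.materials import let_in_water, E_MIN, E_MAX

MEV_PER_CM_TO_KEV_PER_UM = 0.1
GY_PER_MEV_PER_G = 1.602176634e-10

#: Relative-dose threshold below which a voxel's LET is masked as noise.
DOSE_MASK_REL = 1e-4

SPECTRUM_BIN = 0.1  # MeV for energy, keV/um for LET_t


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned voxel lattice: half-open voxels [o + i*s, o + (i+1)*s)."""

    origin: tuple    # cm, (x, y, z)
    spacing: tuple   # cm
    dims: tuple      # voxel counts

    def __post_init__(self):
        o = tuple(float(v) for v in self.origin)
        s = tuple(float(v) for v in self.spacing)
        d = tuple(int(v) for v in self.dims)
        if any(v <= 0 for v in s):
            raise ValueError("spacing must be positive")
        if any(v < 1 for v in d):
            raise ValueError("dims must be >= 1")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "spacing", s)
        object.__setattr__(self, "dims", d)

    @property
    def voxel_volume(self) -> float:
        return self.spacing[0] * self.spacing[1] * self.spacing[2]

    @property
    def upper(self) -> tuple:
        return tuple(self.origin[a] + self.dims[a] * self.spacing[a] for a in range(3))

    def z_centers(self) -> np.ndarray:
        return self.origin[2] + (np.arange(self.dims[2]) + 0.5) * self.spacing[2]

    def index_of(self, point) -> tuple:
        return tuple(int(np.floor((point[a] - self.origin[a]) / self.spacing[a]))
                     for a in range(3))


@dataclass
class ScoreMaps:
    """Voxelized (sum_e, sum_l, sum_e2_over_l) accumulators plus history count."""

    grid: VoxelGrid
    sum_e: np.ndarray = None          # MeV, track steps only
    sum_l: np.ndarray = None          # cm
    sum_e2_over_l: np.ndarray = None  # MeV^2/cm
    sum_e_point: np.ndarray = None    # MeV, zero-length deposits (dose only)
    histories: int = 0

    def __post_init__(self):
        for name in ("sum_e", "sum_l", "sum_e2_over_l", "sum_e_point"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(self.grid.dims, dtype=np.float64))
            elif getattr(self, name).shape != tuple(self.grid.dims):
                raise ValueError(f"{name} shape does not match grid dims")

    def merge(self, other: "ScoreMaps") -> "ScoreMaps":
        """Accumulator addition; exact, so conversions commute with merging."""
        if other.grid != self.grid:
            raise ValueError("grid mismatch")
        return ScoreMaps(self.grid,
                         self.sum_e + other.sum_e,
                         self.sum_l + other.sum_l,
                         self.sum_e2_over_l + other.sum_e2_over_l,
                         self.sum_e_point + other.sum_e_point,
                         self.histories + other.histories)


def _segment_voxel_lengths(grid: VoxelGrid, p0, p1):
    """Split the segment p0->p1 at voxel faces.

    Returns (indices, lengths): the flat voxel index and path length of every
    traversed sub-segment inside the grid.  Portions outside the grid are
    dropped (the transport loop clips at the phantom boundary anyway).
    """
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    d = p1 - p0
    seg_len = float(np.linalg.norm(d))
    if seg_len == 0.0:
        return np.empty(0, np.intp), np.empty(0, float)
    lo = np.asarray(grid.origin)
    hi = np.asarray(grid.upper)
    # slab clip to the grid box
    t0, t1 = 0.0, 1.0
    for a in range(3):
        if d[a] == 0.0:
            if p0[a] < lo[a] or p0[a] >= hi[a]:
                return np.empty(0, np.intp), np.empty(0, float)
        else:
            ta = (lo[a] - p0[a]) / d[a]
            tb = (hi[a] - p0[a]) / d[a]
            ta, tb = min(ta, tb), max(ta, tb)
            t0, t1 = max(t0, ta), min(t1, tb)
    if t1 <= t0:
        return np.empty(0, np.intp), np.empty(0, float)
    # all face crossings strictly inside (t0, t1)
    ts = [t0, t1]
    sp = np.asarray(grid.spacing)
    for a in range(3):
        if d[a] != 0.0:
            xa, xb = p0[a] + t0 * d[a], p0[a] + t1 * d[a]
            ia = np.floor((min(xa, xb) - lo[a]) / sp[a])
            ib = np.floor((max(xa, xb) - lo[a]) / sp[a])
            planes = lo[a] + np.arange(ia + 1, ib + 1) * sp[a]
            ts.extend(((planes - p0[a]) / d[a]).tolist())
    ts = np.unique(np.clip(ts, t0, t1))
    mids = p0[None, :] + 0.5 * (ts[:-1] + ts[1:])[:, None] * d[None, :]
    lengths = np.diff(ts) * seg_len
    keep = lengths > 0
    mids, lengths = mids[keep], lengths[keep]
    idx = np.floor((mids - lo[None, :]) / sp[None, :]).astype(np.intp)
    idx = np.clip(idx, 0, np.asarray(grid.dims) - 1)
    flat = np.ravel_multi_index((idx[:, 0], idx[:, 1], idx[:, 2]), grid.dims)
    return flat, lengths


def score_step(maps: ScoreMaps, p0, p1, eps: float, l: float) -> None:
    """Tally one transport step with energy transfer eps (MeV) over path l (cm).

    The segment is split at voxel faces; sub-step j in voxel v adds
    (eps*l_j/l, l_j, eps^2*l_j/l^2) to v's accumulators.
    """
    if l <= 0:
        raise ValueError("score_step requires l > 0; use score_point for point deposits")
    flat, lengths = _segment_voxel_lengths(maps.grid, p0, p1)
    if flat.size == 0:
        return
    frac = lengths / l
    np.add.at(maps.sum_e.ravel(), flat, eps * frac)
    np.add.at(maps.sum_l.ravel(), flat, lengths)
    np.add.at(maps.sum_e2_over_l.ravel(), flat, eps**2 * frac / l)


def score_point(maps: ScoreMaps, p, eps: float) -> None:
    """Tally a zero-length deposit: dose only, excluded from the LET sums.

    Keeping these out of ``sum_e`` as well preserves the Cauchy-Schwarz
    ordering LET_d >= LET_t, which a pathless energy lump in the LET_d
    denominator would destroy.
    """
    i, j, k = maps.grid.index_of(p)
    if 0 <= i < maps.grid.dims[0] and 0 <= j < maps.grid.dims[1] \
            and 0 <= k < maps.grid.dims[2]:
        maps.sum_e_point[i, j, k] += eps


def _dose_mask(maps: ScoreMaps, rel: float):
    total = maps.sum_e + maps.sum_e_point
    return (total > rel * total.max()) & (maps.sum_l > 0) & (maps.sum_e > 0)


def lett_map(maps: ScoreMaps, dose_mask_rel: float = DOSE_MASK_REL) -> np.ndarray:
    """Track-averaged LET per voxel, keV/um; statistically empty voxels are NaN."""
    ok = _dose_mask(maps, dose_mask_rel)
    out = np.full(maps.grid.dims, np.nan)
    out[ok] = maps.sum_e[ok] / maps.sum_l[ok] * MEV_PER_CM_TO_KEV_PER_UM
    return out


def letd_map(maps: ScoreMaps, dose_mask_rel: float = DOSE_MASK_REL) -> np.ndarray:
    """Dose-averaged LET per voxel, keV/um; masked voxels are NaN."""
    ok = _dose_mask(maps, dose_mask_rel)
    out = np.full(maps.grid.dims, np.nan)
    out[ok] = maps.sum_e2_over_l[ok] / maps.sum_e[ok] * MEV_PER_CM_TO_KEV_PER_UM
    return out


def dose_map(maps: ScoreMaps, density: float = 1.0, in_gray: bool = False) -> np.ndarray:
    """Energy deposit per voxel mass: MeV/g by default, Gy with in_gray=True.

    Includes both track-step and zero-length point deposits."""
    mass = density * maps.grid.voxel_volume
    out = (maps.sum_e + maps.sum_e_point) / mass
    return out * GY_PER_MEV_PER_G if in_gray else out


@dataclass
class PlaneSpectrum:
    """Energy and track-LET histograms of particles crossing a z plane.

    Fixed 0.1 MeV / 0.1 keV/um bins; bin b covers [b*0.1, (b+1)*0.1).
    """

    z_plane: float
    energy_hist: np.ndarray = field(
        default_factory=lambda: np.zeros(int(E_MAX / SPECTRUM_BIN), float))
    lett_hist: np.ndarray = field(
        default_factory=lambda: np.zeros(1200, float))

    @property
    def energy_bin_edges(self) -> np.ndarray:
        return np.arange(self.energy_hist.size + 1) * SPECTRUM_BIN

    @property
    def lett_bin_edges(self) -> np.ndarray:
        return np.arange(self.lett_hist.size + 1) * SPECTRUM_BIN

    def total(self) -> float:
        return float(self.energy_hist.sum())


def record_plane_crossing(spectrum: PlaneSpectrum, E, weight=None) -> None:
    """Tally plane crossings of kinetic energy E (MeV, scalar or array).

    The LET axis uses the unrestricted proton LET in water at E, clipped to
    the stopping-table window for the lookup.
    """
    E = np.atleast_1d(np.asarray(E, float))
    if np.any(E <= 0):
        raise ValueError("crossing energies must be positive")
    w = np.ones_like(E) if weight is None else np.atleast_1d(np.asarray(weight, float))
    eb = np.minimum((E / SPECTRUM_BIN).astype(np.intp), spectrum.energy_hist.size - 1)
    np.add.at(spectrum.energy_hist, eb, w)
    lett = let_in_water(np.clip(E, E_MIN, E_MAX))
    lb = np.minimum((np.asarray(lett) / SPECTRUM_BIN).astype(np.intp),
                    spectrum.lett_hist.size - 1)
    np.add.at(spectrum.lett_hist, lb, w)
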