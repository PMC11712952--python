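"""Spot layout, weight optimization and composite recombination of plans.

A plan covers a target (rectangular prism or inverted pyramid) inside the
plan phantom with energy layers at a fixed energy spacing and spots on a
square lattice.  Collimation strategies:

``none``
    uncollimated beamlets everywhere;
``fixed_field``
    one static aperture at the lateral target boundary, shared by all
    energy layers (the rectangular-target strategy);
``per_layer_target_width``
    the aperture tracks each layer's lateral target cross-section (the
    energy-specific strategy used for the pyramidal target).

Nonnegative spot weights minimize a quadratic target-conformity objective
with a normal-tissue penalty, and the optimized plan is renormalized so the
target D95 equals the prescription, so collimated and uncollimated plans
are compared at equal coverage.  The composite LET_d is recombined from the
weighted accumulator sums (energy transfer and squared-transfer-per-path),
not from averaging per-beamlet LET_d maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from dcslet.scoring import VoxelGrid, ScoreMaps
from dcslet.surrogate import (SurrogateParams, params_for_energy,
                              make_surrogate_scoremaps, surrogate_depth_dose,
                              surrogate_letd, _lateral_profile, LETT_PER_LETD)
from dcslet.materials import water, csda_range, energy_at_range

#: Default plan grid: 12.2 x 12.2 cm lateral, 10 cm deep, 2 mm voxels.  The
#: lateral origin is chosen so the +-2.5 cm target boundary lies on voxel
#: faces: an aperture through a voxel *center* would leave that rim voxel
#: permanently half-covered.
DEFAULT_PLAN_GRID = VoxelGrid(origin=(-6.1, -6.1, 0.0),
                              spacing=(0.2, 0.2, 0.2), dims=(61, 61, 50))


@dataclass(frozen=True)
class PlanSpec:
    """Planning directives: target shape, prescription and lattice spacing."""

    target: str = "cube"             # "cube" or "pyramid"
    prescription: float = 25.0       # Gy
    energy_spacing: float = 4.0      # MeV
    spot_spacing: float = 0.25       # cm
    collimation_strategy: str = "none"  # none | fixed_field | per_layer_target_width
    #: aperture expansion beyond the layer target width, cm, applied by the
    #: per-layer strategy only: the expanding aperture tracks the target
    #: boundary plus this margin so deeper, narrower layers do not starve
    #: the cone-shell voxels of their entrance dose.  The fixed-field
    #: aperture sits exactly at the target boundary.
    aperture_margin: float = 0.4
    # geometry of the targets, cm (centered laterally)
    cube_half_x: float = 2.5
    cube_half_y: float = 2.5
    # shallow placement (distal face at the 90 MeV Bragg-peak anchor): the
    # spot size grows rapidly at low energy, which is the regime in which
    # energy-specific trimmer collimation is clinically motivated
    z_top: float = 2.4
    z_bottom: float = 6.4
    pyramid_apex_half: float = 0.25  # 5 mm square face at the shallow end

    def __post_init__(self):
        if self.prescription <= 0:
            raise ValueError("prescription must be positive")
        if self.energy_spacing <= 0 or self.spot_spacing <= 0:
            raise ValueError("spacings must be positive")
        if self.target not in ("cube", "pyramid"):
            raise ValueError("target must be 'cube' or 'pyramid'")
        if self.collimation_strategy not in ("none", "fixed_field",
                                             "per_layer_target_width"):
            raise ValueError("unknown collimation strategy")

    def half_width_at(self, z: float) -> float:
        """Lateral half-width of the target cross-section at depth z (cm).

        The inverted pyramid carries its 5 x 5 cm base at the shallow face
        and tapers to the 5 mm apex at the deep face, so the per-layer
        aperture *expands* over the distal-to-proximal delivery order.
        """
        if self.target == "cube":
            return self.cube_half_x
        t = np.clip((z - self.z_top) / (self.z_bottom - self.z_top), 0.0, 1.0)
        return self.cube_half_x + t * (self.pyramid_apex_half
                                       - self.cube_half_x)


@dataclass(frozen=True)
class BeamletSpec:
    energy: float
    spot_x: float
    spot_y: float
    edge_x_lo: float | None = None
    edge_x_hi: float | None = None
    edge_y_lo: float | None = None
    edge_y_hi: float | None = None


@dataclass
class ROISet:
    """Voxel masks on the plan grid."""

    target: np.ndarray
    ring_5mm: np.ndarray
    ring_10mm: np.ndarray
    ring_20mm: np.ndarray
    skin: np.ndarray
    body: np.ndarray

    def as_dict(self) -> dict:
        return {"target": self.target, "ring_5mm": self.ring_5mm,
                "ring_10mm": self.ring_10mm, "ring_20mm": self.ring_20mm,
                "skin": self.skin, "body": self.body}


@dataclass
class Plan:
    spec: PlanSpec
    grid: VoxelGrid
    beamlets: list
    weights: np.ndarray
    rois: ROISet

    def __post_init__(self):
        if len(self.weights) != len(self.beamlets):
            raise ValueError("one weight per beamlet required")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")


def target_mask(spec: PlanSpec, grid: VoxelGrid) -> np.ndarray:
    xs = grid.origin[0] + (np.arange(grid.dims[0]) + 0.5) * grid.spacing[0]
    ys = grid.origin[1] + (np.arange(grid.dims[1]) + 0.5) * grid.spacing[1]
    zs = grid.z_centers()
    hw = np.array([spec.half_width_at(z) for z in zs])
    inz = (zs >= spec.z_top) & (zs <= spec.z_bottom)
    m = (np.abs(xs[:, None, None]) <= hw[None, None, :]) \
        & (np.abs(ys[None, :, None]) <= hw[None, None, :]) \
        & inz[None, None, :]
    return m


def build_rois(spec: PlanSpec, grid: VoxelGrid) -> ROISet:
    """Target plus 5/10/20 mm distance-transform ring shells, skin and body."""
    tgt = target_mask(spec, grid)
    dist = ndimage.distance_transform_edt(~tgt, sampling=grid.spacing)
    rings = []
    prev = 0.0
    for r in (0.5, 1.0, 2.0):
        rings.append((dist > prev) & (dist <= r))
        prev = r
    zs = grid.z_centers()
    skin = np.zeros(grid.dims, bool)
    skin[:, :, zs <= 0.5] = True
    body = np.ones(grid.dims, bool)
    return ROISet(tgt, rings[0], rings[1], rings[2], skin & ~tgt, body)


def _layer_energies(spec: PlanSpec) -> list:
    """Energy layers whose peak depths span the target depth extent."""
    from dcslet.surrogate import _BP_PER_CSDA
    e0 = float(energy_at_range(water, spec.z_bottom / _BP_PER_CSDA))
    # distal margin of half a layer spacing so the last target voxels sit on
    # the distal layer's peak rather than its falloff (mirrors the proximal
    # half-step margin)
    spacing_cm = (csda_range(water, e0)
                  - csda_range(water, e0 - spec.energy_spacing)) * _BP_PER_CSDA
    e = float(energy_at_range(
        water, (spec.z_bottom + 0.5 * spacing_cm) / _BP_PER_CSDA))
    energies = []
    while e > 10.0:
        energies.append(e)
        if params_for_energy(e).range < spec.z_top:
            break  # one layer proximal of the target face closes coverage
        e -= spec.energy_spacing
    return energies


def spot_layout(spec: PlanSpec, grid: VoxelGrid = DEFAULT_PLAN_GRID) -> list:
    """Beamlet specs: energy layers, spot lattice, per-strategy collimation.

    Spots cover each layer's lateral target cross-section plus a one-spot
    margin; apertures are absolute edge positions (cm).
    """
    if spec.z_bottom >= grid.upper[2]:
        raise ValueError("target deeper than the plan phantom")
    beamlets = []
    for bundle in _bundles(spec, grid):
        beamlets.extend(bundle.beamlet_specs())
    return beamlets


class _LayerBundle:
    """Separable evaluation cache for one energy layer.

    All spots of a layer share the depth-dose curve, the depth-LET curve and
    the aperture edges, and the lateral profile factorizes per axis, so the
    layer's composite maps reduce to small einsum contractions over the
    per-axis profile banks.
    """

    def __init__(self, spec: PlanSpec, energy: float, spots: np.ndarray,
                 edges, grid: VoxelGrid):
        self.energy = energy
        self.spots = spots          # 1D lattice coordinates (shared by x and y)
        self.edges = edges
        self.grid = grid
        self.params = params_for_energy(
            energy, edge_x_lo=edges[0], edge_x_hi=edges[1],
            edge_y_lo=edges[2], edge_y_hi=edges[3])
        self._banks = None

    def _ensure_banks(self):
        if self._banks is not None:
            return
        p, grid, edges = self.params, self.grid, self.edges
        xs = grid.origin[0] + (np.arange(grid.dims[0]) + 0.5) * grid.spacing[0]
        ys = grid.origin[1] + (np.arange(grid.dims[1]) + 0.5) * grid.spacing[1]
        zs = grid.z_centers()
        self.dz = surrogate_depth_dose(p, zs)
        self.letd_depth = surrogate_letd(p, zs)
        # profile banks: (n_spots, nz, nx)
        self.gx = np.stack([
            np.stack([_lateral_profile(replace(p, spot_x=s), xs, z, "x")
                      for z in zs]) for s in self.spots]).astype(np.float32)
        self.gy = np.stack([
            np.stack([_lateral_profile(replace(p, spot_y=s), ys, z, "y")
                      for z in zs]) for s in self.spots]).astype(np.float32)
        # LET_d edge-ridge factors per axis (pure functions of x or y)
        ps = p.penumbra_sigma
        self.rx = np.zeros_like(xs)
        self.ry = np.zeros_like(ys)
        for e in (edges[0], edges[1]):
            if e is not None:
                self.rx += np.exp(-0.5 * ((xs - e) / ps) ** 2)
        for e in (edges[2], edges[3]):
            if e is not None:
                self.ry += np.exp(-0.5 * ((ys - e) / ps) ** 2)
        self._banks = True

    @property
    def n_beamlets(self) -> int:
        return len(self.spots) ** 2

    def beamlet_specs(self) -> list:
        return [BeamletSpec(self.energy, float(sx), float(sy), *self.edges)
                for sx in self.spots for sy in self.spots]

    def influence(self, sel_flat: np.ndarray) -> np.ndarray:
        """(n_beamlets, n_sel) dose influence at the selected flat voxels."""
        self._ensure_banks()
        xv, yv, zv = np.unravel_index(sel_flat, self.grid.dims)
        gxv = self.gx[:, zv, xv]             # (ns, nsel)
        gyv = self.gy[:, zv, yv]
        dzv = self.dz[zv].astype(np.float32)
        out = (gxv[:, None, :] * (gyv * dzv[None, :])[None, :, :])
        return out.reshape(self.n_beamlets, sel_flat.size)

    def composite(self, w: np.ndarray, with_letd: bool = False):
        """Weighted dose (and optionally sum_e2_over_l) maps of the layer."""
        self._ensure_banks()
        W = np.asarray(w, np.float32).reshape(len(self.spots), len(self.spots))
        t = np.einsum("izx,ij->jzx", self.gx, W)
        fl = np.einsum("jzx,jzy->zxy", t, self.gy)
        dose = (self.dz[:, None, None] * fl).transpose(1, 2, 0)
        if not with_letd:
            return dose
        ridge = (1.0 + self.params.edge_letd_boost
                 * np.minimum(self.rx[None, :, None]
                              + self.ry[None, None, :], 1.5))
        e2l = (self.letd_depth[:, None, None] / 0.1) * ridge * \
            (self.dz[:, None, None] * fl)
        return dose, e2l.transpose(1, 2, 0)


def _bundles(spec: PlanSpec, grid: VoxelGrid) -> list:
    out = []
    for e in _layer_energies(spec):
        p = params_for_energy(e)
        hw_layer = spec.half_width_at(min(p.range, spec.z_bottom))
        n_half = int(np.ceil(hw_layer / spec.spot_spacing)) + 1
        spots = np.arange(-n_half, n_half + 1) * spec.spot_spacing
        if spec.collimation_strategy == "none":
            edges = (None, None, None, None)
        elif spec.collimation_strategy == "fixed_field":
            a = spec.cube_half_x
            edges = (-a, a, -a, a)
        else:
            a = hw_layer + spec.aperture_margin
            edges = (-a, a, -a, a)
        out.append(_LayerBundle(spec, e, spots, edges, grid))
    return out


def beamlet_params(b: BeamletSpec, **overrides) -> SurrogateParams:
    return params_for_energy(b.energy, spot_x=b.spot_x, spot_y=b.spot_y,
                             edge_x_lo=b.edge_x_lo, edge_x_hi=b.edge_x_hi,
                             edge_y_lo=b.edge_y_lo, edge_y_hi=b.edge_y_hi,
                             **overrides)


def beamlet_dose(b: BeamletSpec, grid: VoxelGrid) -> np.ndarray:
    """Relative dose array of one surrogate beamlet on the plan grid."""
    p = beamlet_params(b)
    xs = grid.origin[0] + (np.arange(grid.dims[0]) + 0.5) * grid.spacing[0]
    ys = grid.origin[1] + (np.arange(grid.dims[1]) + 0.5) * grid.spacing[1]
    zs = grid.z_centers()
    dz = surrogate_depth_dose(p, zs)
    gx = np.stack([_lateral_profile(p, xs, z, "x") for z in zs])
    gy = np.stack([_lateral_profile(p, ys, z, "y") for z in zs])
    return np.einsum("z,zx,zy->xyz", dz, gx, gy).astype(np.float32)


def influence_matrix(bundles: list, voxel_sel: np.ndarray) -> np.ndarray:
    """Dose-influence matrix (n_beamlets x n_selected_voxels), float32.

    ``voxel_sel`` is either a boolean mask on the grid or an array of flat
    voxel indices.
    """
    voxel_sel = np.asarray(voxel_sel)
    if voxel_sel.dtype == bool:
        sel = np.flatnonzero(voxel_sel.ravel())
    else:
        sel = voxel_sel.ravel()
    return np.concatenate([b.influence(sel) for b in bundles], axis=0)


def optimize_weights(influence: np.ndarray, target_sel: np.ndarray,
                     prescription: float, normal_penalty: float = 0.05,
                     max_iter: int = 400, tol: float = 1e-6) -> np.ndarray:
    """Nonnegative weights minimizing the conformity + normal-dose objective.

    minimize  sum_target (D - p)^2 + lambda * sum_normal D^2,  w >= 0,
    by accelerated projected gradient, stopping at ``tol`` relative
    objective change.  Columns of ``influence`` are voxels; ``target_sel``
    flags the target columns.  Raises if part of the target receives no
    influence from any beamlet.
    """
    A = influence
    nt = target_sel
    if not np.any(nt):
        raise ValueError("empty target")
    cover = np.asarray(A[:, nt].sum(axis=0))
    if np.any(cover <= 0):
        raise ValueError(
            f"{int((cover <= 0).sum())} target voxels receive no beamlet "
            "influence; layout cannot cover the target")
    dt = A.dtype
    p = np.where(nt, prescription, 0.0).astype(dt)
    lam = np.where(nt, 1.0, normal_penalty).astype(dt)
    # Jacobi preconditioning: scale each beamlet by its column norm in the
    # lam metric, which near-equalizes the Hessian diagonal and makes the
    # rim/edge modes converge at the same rate as the bulk
    s = 1.0 / np.sqrt(np.maximum((A * A) @ lam, 1e-20)).astype(dt)
    u = np.full(A.shape[0], prescription / max(np.mean(cover), 1e-12),
                dtype=dt) / s

    def matvec_T(uv):
        return A.T @ (s * uv)

    def matvec(Dv):
        return s * (A @ (lam * Dv))

    # Lipschitz estimate via power iteration on the preconditioned operator
    v = np.random.default_rng(0).standard_normal(A.shape[0]).astype(dt)
    for _ in range(12):
        v = matvec(matvec_T(v))
        v /= np.linalg.norm(v)
    L = float(v @ matvec(matvec_T(v))) * 1.05
    step = 1.0 / L
    y = u.copy()
    t_acc = 1.0
    prev_obj = np.inf
    for it in range(max_iter):
        grad = matvec(matvec_T(y) - p)
        u_new = np.maximum(y - step * grad, 0.0)
        # keep momentum scalars as python floats: a numpy float64 scalar
        # would silently upcast the float32 iterates (and the matvecs)
        t_new = 0.5 * (1.0 + float(np.sqrt(1.0 + 4.0 * t_acc ** 2)))
        y = u_new + float((t_acc - 1.0) / t_new) * (u_new - u)
        u, t_acc = u_new, t_new
        if it % 20 == 0:
            D = matvec_T(u)
            obj = float(np.sum(lam * (D - p) ** 2))
            if abs(prev_obj - obj) <= tol * max(obj, 1e-30):
                break
            prev_obj = obj
    return s * u


def make_plan(spec: PlanSpec, grid: VoxelGrid = DEFAULT_PLAN_GRID,
              normal_penalty: float = 0.05) -> Plan:
    """Lay out, optimize and D95-normalize a plan on surrogate beamlets."""
    from dcslet.analysis import dose_percentile
    bundles = _bundles(spec, grid)
    beamlets = [b for bundle in bundles for b in bundle.beamlet_specs()]
    rois = build_rois(spec, grid)
    # optimize on a strided sample of the target and normal-tissue shells;
    # the beamlet sigma (4-6 mm) far exceeds the sample pitch, so the
    # objective is unchanged at desk scale
    t_idx = np.flatnonzero(rois.target.ravel())[::3]
    n_idx = np.flatnonzero((rois.ring_5mm | rois.ring_10mm
                            | rois.ring_20mm).ravel())[::5]
    sel_idx = np.concatenate([t_idx, n_idx])
    A = influence_matrix(bundles, sel_idx)
    tsel = np.zeros(sel_idx.size, bool)
    tsel[:t_idx.size] = True
    w = optimize_weights(A, tsel, spec.prescription,
                         normal_penalty=normal_penalty)
    plan = Plan(spec, grid, beamlets, w, rois)
    plan._bundles = bundles
    dose = composite_dose(plan)
    d95 = dose_percentile(dose, rois.target, 0.95)
    plan.weights = w * (spec.prescription / d95)
    return plan


def _plan_bundles(plan: Plan) -> list:
    bundles = getattr(plan, "_bundles", None)
    if bundles is None:
        bundles = _bundles(plan.spec, plan.grid)
        plan._bundles = bundles
    return bundles


def _layer_slices(bundles: list):
    off = 0
    for b in bundles:
        yield b, slice(off, off + b.n_beamlets)
        off += b.n_beamlets


def composite_dose(plan: Plan) -> np.ndarray:
    """Weighted-superposition physical dose map of the plan."""
    out = np.zeros(plan.grid.dims, np.float64)
    for bundle, sl in _layer_slices(_plan_bundles(plan)):
        out += bundle.composite(plan.weights[sl])
    return out


def composite_maps(plan: Plan, dose_mask_rel: float = 1e-4):
    """Composite dose and LET_d maps from the weighted accumulator sums.

    The composite LET_d is the ratio of the weighted squared-energy-transfer
    sum to the weighted energy-transfer sum, per voxel -- not an average of
    per-beamlet LET_d values.
    """
    sum_e = np.zeros(plan.grid.dims, np.float64)
    sum_e2l = np.zeros(plan.grid.dims, np.float64)
    for bundle, sl in _layer_slices(_plan_bundles(plan)):
        d, e2l = bundle.composite(plan.weights[sl], with_letd=True)
        sum_e += d
        sum_e2l += e2l
    dose = sum_e  # uniform voxel mass: relative dose == sum_e
    letd = np.full(plan.grid.dims, np.nan)
    ok = sum_e > dose_mask_rel * sum_e.max()
    letd[ok] = sum_e2l[ok] / sum_e[ok] * 0.1
    return dose, letd


def plan_manifest(plan: Plan) -> pd.DataFrame:
    rows = []
    for i, (b, w) in enumerate(zip(plan.beamlets, plan.weights)):
        rows.append({"beamlet": i, "energy_MeV": b.energy, "x_cm": b.spot_x,
                     "y_cm": b.spot_y, "edge_x_lo": b.edge_x_lo,
                     "edge_x_hi": b.edge_x_hi, "edge_y_lo": b.edge_y_lo,
                     "edge_y_hi": b.edge_y_hi, "weight": w})
    return pd.DataFrame(rows)
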