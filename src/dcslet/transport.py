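"""Condensed-history proton transport through the collimated beamline.

A class-II-lite scheme: deterministic mean energy loss from the stopping
tables, Gaussian (Bohr) straggling, Highland multiple Coulomb scattering,
and a lumped nuclear-interaction surrogate in water.  Delta rays are not
transported (their energy is deposited on the proton step), the air gaps are
treated as vacuum, and protons below the 0.5 MeV cutoff deposit their
residual energy locally.

The batch loop itself is compiled (see ``_kernels``); this module holds the
configuration, the single-step reference implementation used by the tests,
and the result containers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from dcslet import _kernels
from dcslet.beamline import (CollimationConfig, SourceModel, SPECTRAL_PLANE_Z,
                             sample_primaries)
from dcslet.materials import (MaterialSpec, water, nickel, mass_stopping_power,
                              E_MIN)
from dcslet.particles import ParticleBatch
from dcslet.scoring import ScoreMaps, VoxelGrid, PlaneSpectrum, record_plane_crossing

#: Default beamlet scoring grid: 10 x 10 x 20 cm water phantom, 1 mm voxels.
DEFAULT_BEAMLET_GRID = VoxelGrid(origin=(-5.0, -5.0, 0.0),
                                 spacing=(0.1, 0.1, 0.1),
                                 dims=(100, 100, 200))


@dataclass(frozen=True)
class TransportConfig:
    """Transport-loop controls.

    ``nuclear_rate`` is the surrogate nonelastic interaction probability per
    cm of water at high energy (default 1 %/cm); ``nuclear_local_fraction``
    is the fraction of the interacting proton's energy lumped as local dose.
    """

    max_step_water: float = 0.05   # cm
    max_step_nickel: float = 0.02  # cm
    energy_cutoff: float = 0.5     # MeV
    nuclear_on: bool = True
    nuclear_rate: float = 0.01         # 1/cm
    nuclear_local_fraction: float = 0.6
    straggling_on: bool = True
    scattering_on: bool = True

    def __post_init__(self):
        if self.max_step_water <= 0 or self.max_step_nickel <= 0:
            raise ValueError("max steps must be positive")
        if self.energy_cutoff < E_MIN:
            raise ValueError("cutoff below stopping-table minimum")


@dataclass
class TransportResult:
    """Outputs of one transported batch."""

    score_maps: ScoreMaps | None
    plane_records: pd.DataFrame     # columns energy, x, y, weight, origin_tag
    spectrum: PlaneSpectrum
    energy_sinks: np.ndarray        # [phantom, collimator, escaped, binding] MeV
    hist_initial: np.ndarray
    hist_accounted: np.ndarray

    @property
    def max_conservation_error(self) -> float:
        """Worst per-history relative energy-bookkeeping error."""
        return float(np.max(np.abs(self.hist_accounted - self.hist_initial)
                            / self.hist_initial))


def highland_theta0(E: float, path_gcm2: float, X0_gcm2: float) -> float:
    """Highland multiple-scattering angle (radians); 0 for zero path."""
    if path_gcm2 < 0:
        raise ValueError("path must be nonnegative")
    return _kernels._highland_theta0(E, path_gcm2, X0_gcm2)


def bohr_sigma(E: float, material: MaterialSpec, ds: float) -> float:
    """Bohr energy-loss straggling sigma (MeV) over a path ds (cm)."""
    return _kernels._bohr_sigma(E, material.Z_over_A, material.density, ds)


def step(position, direction, energy, medium: MaterialSpec, ds: float,
         rng: np.random.Generator, config: TransportConfig = TransportConfig()):
    """Single condensed-history step (reference implementation for tests).

    Returns (new_position, new_direction, new_energy, eps, l, alive).
    """
    if ds <= 0:
        raise ValueError("step length must be positive")
    position = np.asarray(position, float)
    direction = np.asarray(direction, float)
    E = float(energy)
    cutoff = config.energy_cutoff
    # exact CSDA energy update via the range tables
    from dcslet.materials import csda_range, energy_at_range
    r_now = csda_range(medium, E)
    r_cut = csda_range(medium, cutoff)
    if r_now - r_cut <= ds:
        l = r_now - r_cut
        return position + direction * l, direction, 0.0, E, max(l, 1e-9), False
    eps = E - energy_at_range(medium, r_now - ds)
    if config.straggling_on:
        eps += bohr_sigma(E, medium, ds) * rng.standard_normal()
        eps = float(np.clip(eps, 0.0, E))
    E -= eps
    new_dir = direction
    if config.scattering_on:
        th0 = highland_theta0(E, medium.density * ds, medium.radiation_length)
        if th0 > 0:
            e1 = np.array([-direction[1], direction[0], 0.0])
            if np.linalg.norm(e1) < 1e-6:
                e1 = np.array([1.0, 0.0, 0.0])
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(direction, e1)
            new_dir = direction + th0 * rng.standard_normal() * e1 \
                + th0 * rng.standard_normal() * e2
            new_dir /= np.linalg.norm(new_dir)
    alive = E >= cutoff
    return position + direction * ds, new_dir, E, eps, ds, alive


def _material_tables():
    log_e = np.log(water.energies)
    return (log_e, np.log(water.stopping_powers), np.log(nickel.stopping_powers),
            water.energies,
            water._cum_range / water.density, nickel._cum_range / nickel.density)


def transport(batch: ParticleBatch,
              collimation: CollimationConfig,
              score_maps: ScoreMaps | None = None,
              plane_z: float = SPECTRAL_PLANE_Z,
              config: TransportConfig = TransportConfig(),
              seed: int = 0) -> TransportResult:
    """Transport a batch through the blades into the phantom.

    When ``score_maps`` is given, every water step is tallied into its grid
    and the phantom occupies exactly the grid box; otherwise no phantom is
    modeled and the world ends just beyond the spectral plane (fast
    spectra-only mode).  Per-history random streams derive from ``seed``, so
    identical seeds give identical results regardless of batch splitting.
    """
    n = len(batch)
    if score_maps is not None:
        g = score_maps.grid
        ph_lo = np.asarray(g.origin)
        ph_hi = np.asarray(g.upper)
        score_on = True
        sum_e, sum_l, sum_e2l = (score_maps.sum_e, score_maps.sum_l,
                                 score_maps.sum_e2_over_l)
        sum_e_pt = score_maps.sum_e_point
        gox, goy, goz = g.origin
        gsx, gsy, gsz = g.spacing
        gnx, gny, gnz = g.dims
    else:
        ph_lo = np.zeros(3)
        ph_hi = np.zeros(3)
        score_on = False
        sum_e = sum_l = sum_e2l = sum_e_pt = np.zeros((1, 1, 1))
        gox = goy = goz = 0.0
        gsx = gsy = gsz = 1.0
        gnx = gny = gnz = 1

    cap = 4 * n
    rec_E = np.empty(cap)
    rec_x = np.empty(cap)
    rec_y = np.empty(cap)
    rec_tag = np.empty(cap, np.int64)
    hist_initial = np.empty(n)
    hist_accounted = np.empty(n)
    sinks = np.zeros(4)
    tables = _material_tables()

    n_rec = _kernels.run_batch(
        np.ascontiguousarray(batch.position[:, 0]),
        np.ascontiguousarray(batch.position[:, 1]),
        np.ascontiguousarray(batch.position[:, 2]),
        np.ascontiguousarray(batch.direction[:, 0]),
        np.ascontiguousarray(batch.direction[:, 1]),
        np.ascontiguousarray(batch.direction[:, 2]),
        np.ascontiguousarray(batch.kinetic_energy),
        np.ascontiguousarray(batch.origin_tag),
        int(seed) % 2147483647,
        collimation.as_array(),
        *tables,
        water.density, nickel.density, water.Z_over_A, nickel.Z_over_A,
        water.radiation_length, nickel.radiation_length,
        config.max_step_water, config.max_step_nickel, config.energy_cutoff,
        config.nuclear_on, config.nuclear_rate, config.nuclear_local_fraction,
        config.straggling_on, config.scattering_on,
        ph_lo, ph_hi,
        score_on, gox, goy, goz, gsx, gsy, gsz, gnx, gny, gnz,
        sum_e, sum_l, sum_e2l, sum_e_pt,
        plane_z, rec_E, rec_x, rec_y, rec_tag,
        hist_initial, hist_accounted, sinks)

    if score_maps is not None:
        score_maps.histories += n
    records = pd.DataFrame({"energy": rec_E[:n_rec], "x": rec_x[:n_rec],
                            "y": rec_y[:n_rec],
                            "weight": np.ones(n_rec),
                            "origin_tag": rec_tag[:n_rec]})
    spectrum = PlaneSpectrum(z_plane=plane_z)
    if n_rec:
        record_plane_crossing(spectrum, rec_E[:n_rec])
    return TransportResult(score_maps, records, spectrum, sinks,
                           hist_initial, hist_accounted)


def simulate_beamlet(energy: float,
                     scenario: str = "uncollimated",
                     offset: float = 0.0,
                     n: int = 100_000,
                     seed: int = 0,
                     grid: VoxelGrid | None = DEFAULT_BEAMLET_GRID,
                     config: TransportConfig = TransportConfig(),
                     source: SourceModel | None = None) -> TransportResult:
    """Sample and transport one beamlet; the standard single-beamlet run.

    Pass ``grid=None`` for a fast spectra-only run (no phantom transport).
    """
    from dcslet.beamline import build_collimation
    src = source if source is not None else SourceModel.for_energy(energy)
    rng = np.random.default_rng(seed)
    batch = sample_primaries(src, n, rng)
    maps = ScoreMaps(grid) if grid is not None else None
    return transport(batch, build_collimation(scenario, offset),
                     score_maps=maps, config=config, seed=seed)


def integral_depth_dose(maps: ScoreMaps) -> pd.DataFrame:
    """Laterally integrated energy deposit per depth slab (the IDD)."""
    e = (maps.sum_e + maps.sum_e_point).sum(axis=(0, 1))
    return pd.DataFrame({"z_cm": maps.grid.z_centers(), "energy_MeV": e})
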