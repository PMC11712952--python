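"""Proton phase-space container shared by the source and the transport loop."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

ORIGIN_PRIMARY = 0
ORIGIN_COLLIMATOR_SCATTER = 1
ORIGIN_NUCLEAR_SECONDARY = 2

ORIGIN_NAMES = {ORIGIN_PRIMARY: "primary",
                ORIGIN_COLLIMATOR_SCATTER: "collimator_scatter",
                ORIGIN_NUCLEAR_SECONDARY: "nuclear_secondary"}


@dataclass
class ParticleBatch:
    """Structure-of-arrays proton batch.

    ``position`` (n, 3) cm; ``direction`` (n, 3) unit vectors;
    ``kinetic_energy`` (n,) MeV; ``weight`` (n,) > 0; ``origin_tag`` (n,)
    int codes (see module constants); ``alive`` (n,) bool.
    """

    position: np.ndarray
    direction: np.ndarray
    kinetic_energy: np.ndarray
    weight: np.ndarray = None
    origin_tag: np.ndarray = None
    alive: np.ndarray = None

    def __post_init__(self):
        n = self.kinetic_energy.shape[0]
        if self.weight is None:
            self.weight = np.ones(n)
        if self.origin_tag is None:
            self.origin_tag = np.full(n, ORIGIN_PRIMARY, dtype=np.int64)
        if self.alive is None:
            self.alive = np.ones(n, dtype=bool)
        norms = np.linalg.norm(self.direction, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("directions must be unit vectors")
        if np.any(self.kinetic_energy < 0):
            raise ValueError("kinetic energies must be nonnegative")
        if np.any(self.weight <= 0):
            raise ValueError("weights must be positive")

    def __len__(self) -> int:
        return self.kinetic_energy.shape[0]
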