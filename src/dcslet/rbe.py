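"""McNamara phenomenological proton RBE model.

RBE is modeled as a function of the physical dose D, the dose-averaged LET
and the tissue's photon linear-quadratic ratio (alpha/beta)_x:

    RBE_max = p0 + p1 * LET_d / (a/b)_x
    RBE_min = p2 + p3 * sqrt((a/b)_x) * LET_d
    RBE = (1 / 2D) * [ sqrt((a/b)_x^2 + 4 D (a/b)_x RBE_max
                            + 4 D^2 RBE_min^2) - (a/b)_x ]

with the D -> 0 limit equal to RBE_max.  The published fit coefficients are
the defaults below; an (alpha/beta)_x of 3.49 Gy is assumed for the plan
analyses.  D is the per-voxel dose of the full delivered plan (no
fractionation model).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class RBEParams:
    p0: float = 0.99064
    p1: float = 0.35605
    p2: float = 1.1012
    p3: float = -0.0038703
    alpha_beta_x: float = 3.49  # Gy

    def __post_init__(self):
        if self.alpha_beta_x <= 0:
            raise ValueError("(alpha/beta)_x must be positive")

    def rbe_max(self, letd):
        return self.p0 + self.p1 * np.asarray(letd, float) / self.alpha_beta_x

    def rbe_min(self, letd):
        return self.p2 + self.p3 * np.sqrt(self.alpha_beta_x) \
            * np.asarray(letd, float)


def rbe(D, letd, params: RBEParams = RBEParams()):
    """RBE at physical dose D (Gy) and dose-averaged LET (keV/um).

    Scalar or array inputs (broadcast); D = 0 returns the RBE_max limit.
    NaN LET (masked voxels) propagates to NaN.
    """
    D = np.asarray(D, float)
    letd = np.asarray(letd, float)
    if np.any(D < 0):
        raise ValueError("dose must be nonnegative")
    if np.any(letd[np.isfinite(letd)] < 0):
        raise ValueError("LET_d must be nonnegative")
    ab = params.alpha_beta_x
    rmax = params.rbe_max(letd)
    rmin = params.rbe_min(letd)
    with np.errstate(divide="ignore", invalid="ignore"):
        full = (np.sqrt(ab**2 + 4.0 * D * ab * rmax + 4.0 * D**2 * rmin**2)
                - ab) / (2.0 * D)
    out = np.where(D > 0, full, rmax)
    return float(out) if out.ndim == 0 else out


def rbe_weighted_dose(dose_map, letd_map, params: RBEParams = RBEParams()):
    """Voxelwise RBE-weighted dose D * RBE(D, LET_d); masked voxels stay NaN."""
    dose_map = np.asarray(dose_map, float)
    letd_map = np.asarray(letd_map, float)
    if dose_map.shape != letd_map.shape:
        raise ValueError("dose and LET_d maps must share one grid")
    return dose_map * rbe(dose_map, letd_map, params)
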