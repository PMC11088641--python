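"""Greyscale -> density -> modulus material mapping and binning.

Apparent density follows the linear CT calibration
``rho_app = 0.001029 * GV + 0.114259`` (g/cm^3) and Young's modulus the
power law ``E = 6850 * rho_app^1.49`` (MPa).  Elements are partitioned into
a small number of material sets (default 10) by equal-width greyscale
binning; each bin's representative greyscale is the mean of its member
elements, so total stiffness is approximately preserved.  Poisson's ratio
is 0.3 for every bin.

Note: at the top of the nominal greyscale range (GV = 4095) the calibration
yields rho_app ~ 4.33 g/cm^3, beyond physiological bone density.  The
mapping is applied as calibrated; ``MaterialTable.supra_physiological``
flags bins with rho_app > 2.2 g/cm^3 instead of clamping them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DENSITY_INTERCEPT",
    "DENSITY_SLOPE",
    "MODULUS_COEFF",
    "MODULUS_EXPONENT",
    "POISSON_RATIO",
    "MaterialTable",
    "bin_materials",
    "density_to_modulus",
    "gv_to_density",
]

DENSITY_SLOPE = 0.001029  # (g/cm^3) per greyscale unit
DENSITY_INTERCEPT = 0.114259  # g/cm^3
MODULUS_COEFF = 6850.0  # MPa at rho_app = 1 g/cm^3
MODULUS_EXPONENT = 1.49
POISSON_RATIO = 0.3

# 1 g/cm^3 = 1e-9 tonne/mm^3 (mm-N-MPa-tonne unit system)
GCM3_TO_TONNE_MM3 = 1.0e-9

_SUPRA_PHYSIOLOGICAL_RHO = 2.2  # g/cm^3, above compact cortical bone


def gv_to_density(gv):
    """Apparent density (g/cm^3) from CT greyscale. Raises on negative GV."""
    gv = np.asarray(gv, dtype=float)
    if np.any(~np.isfinite(gv)) or np.any(gv < 0):
        raise ValueError("greyscale values must be finite and non-negative")
    rho = DENSITY_SLOPE * gv + DENSITY_INTERCEPT
    return rho if rho.ndim else float(rho)


def density_to_modulus(rho):
    """Young's modulus (MPa) from apparent density (g/cm^3)."""
    rho = np.asarray(rho, dtype=float)
    if np.any(~np.isfinite(rho)) or np.any(rho < 0):
        raise ValueError("density must be finite and non-negative")
    e = MODULUS_COEFF * rho**MODULUS_EXPONENT
    return e if e.ndim else float(e)


@dataclass
class MaterialTable:
    """Binned material sets and the element -> bin assignment."""

    density: np.ndarray  # (B,) g/cm^3
    youngs_modulus: np.ndarray  # (B,) MPa
    poisson: np.ndarray  # (B,)
    element_bin: np.ndarray  # (M,) int
    gv_edges: np.ndarray  # (B, 2) greyscale interval of each bin
    supra_physiological: np.ndarray = field(
        default_factory=lambda: np.array([], bool)
    )

    @property
    def n_bins(self) -> int:
        return self.density.shape[0]

    def element_modulus(self) -> np.ndarray:
        return self.youngs_modulus[self.element_bin]

    def element_density(self) -> np.ndarray:
        """Per-element apparent density, g/cm^3."""
        return self.density[self.element_bin]

    def element_mass_density(self) -> np.ndarray:
        """Per-element mass density in tonne/mm^3 (for the mass matrix)."""
        return self.element_density() * GCM3_TO_TONNE_MM3

    def validate(self) -> None:
        if np.any(self.density <= 0) or np.any(self.youngs_modulus <= 0):
            raise ValueError("bin density and modulus must be positive")
        if not np.all(self.poisson == POISSON_RATIO):
            raise ValueError("Poisson's ratio must be 0.3 for every bin")
        if np.any(np.diff(self.density) <= 0) or np.any(
            np.diff(self.youngs_modulus) <= 0
        ):
            raise ValueError("bins must be strictly increasing in rho and E")
        if self.element_bin.min() < 0 or self.element_bin.max() >= self.n_bins:
            raise ValueError("element_bin out of range")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": np.arange(self.n_bins),
                "gv_low": self.gv_edges[:, 0],
                "gv_high": self.gv_edges[:, 1],
                "density_g_cm3": self.density,
                "youngs_modulus_mpa": self.youngs_modulus,
                "poisson": self.poisson,
                "supra_physiological": self.supra_physiological,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def bin_materials(model_or_gv, n_bins: int = 10) -> MaterialTable:
    """Partition elements into equal-width greyscale bins and map properties.

    Accepts a :class:`~femurbench.model.FemurModel` or a raw per-element
    greyscale array.  Empty bins are dropped; each populated bin's
    representative greyscale is the mean over its member elements.
    """
    gv = np.asarray(getattr(model_or_gv, "element_gv", model_or_gv), float)
    if gv.size == 0:
        raise ValueError("element greyscale field is empty")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    lo, hi = float(gv.min()), float(gv.max())
    if hi <= lo:  # degenerate constant field -> single bin
        edges = np.array([lo, lo + 1.0])
        idx = np.zeros(gv.shape, int)
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
        idx = np.clip(np.searchsorted(edges, gv, side="right") - 1, 0, n_bins - 1)
    populated = np.unique(idx)
    remap = -np.ones(idx.max() + 1, int)
    remap[populated] = np.arange(populated.size)
    element_bin = remap[idx]
    rep_gv = np.array([gv[idx == b].mean() for b in populated])
    order = np.argsort(rep_gv)
    rep_gv = rep_gv[order]
    inv = np.empty_like(order)
    inv[order] = np.arange(order.size)
    element_bin = inv[element_bin]
    rho = gv_to_density(rep_gv)
    table = MaterialTable(
        density=np.atleast_1d(rho),
        youngs_modulus=np.atleast_1d(density_to_modulus(rho)),
        poisson=np.full(populated.size, POISSON_RATIO),
        element_bin=element_bin,
        gv_edges=np.stack(
            [edges[populated[order]], edges[populated[order] + 1]], axis=1
        ),
        supra_physiological=np.atleast_1d(rho) > _SUPRA_PHYSIOLOGICAL_RHO,
    )
    table.validate()
    return table
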