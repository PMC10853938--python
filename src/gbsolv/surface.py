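"""Atomic van der Waals surface areas and volumes by spherical-cap overlap.

Each atom is a sphere of van der Waals radius R_I.  For every overlapping
neighbor J the spherical cap of atom I buried inside atom J is subtracted
from I's free-sphere surface and volume.  With the crossing plane at signed
offset

    a = (r_IJ^2 + R_I^2 - R_J^2) / (2 r_IJ)

from atom I's center, the buried cap has height h = R_I - a (clamped to
[0, 2 R_I]), area dS = 2 pi R_I h and volume dV = pi h^2 (3 R_I - h) / 3.

The pairwise subtraction is exact for two-sphere overlap; with multiple
mutual overlap it over-subtracts, so per-atom results are clamped at zero.
That bias is acceptable here: the areas and volumes feed a learned
regression, not an energy functional.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .molecule import Molecule, load_radii


def cap_geometry(R_I: float, R_J: float, r_IJ: float) -> tuple[float, float, float]:
    """Crossing-plane offset and buried-cap area/volume of atom I inside J.

    Returns (a, dS, dV); dS = dV = 0 for non-overlapping spheres, and the
    full sphere of I when it is entirely contained in J.
    """
    if R_I <= 0 or R_J <= 0:
        raise ValueError("radii must be positive")
    if r_IJ <= 0:
        raise ValueError("center distance must be positive")
    a = (r_IJ * r_IJ + R_I * R_I - R_J * R_J) / (2.0 * r_IJ)
    h = min(max(R_I - a, 0.0), 2.0 * R_I)
    if r_IJ >= R_I + R_J:  # no overlap (h may be >0 only through rounding)
        h = 0.0
    if r_IJ + R_I <= R_J:  # I fully inside J
        h = 2.0 * R_I
    dS = 2.0 * np.pi * R_I * h
    dV = np.pi * h * h * (3.0 * R_I - h) / 3.0
    return a, dS, dV


def _pair_caps(mol: Molecule, radii: dict[str, float], bonded_only: bool,
               cn_cutoff: float) -> tuple[np.ndarray, np.ndarray]:
    """Total buried cap area and volume per atom, summed over neighbors."""
    n = mol.n_atoms
    R = np.array([radii[s] for s in mol.symbols])
    d = mol.distance_matrix()
    dS = np.zeros(n)
    dV = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if bonded_only and d[i, j] > cn_cutoff * (R[i] + R[j]) / 2.0:
                continue
            if d[i, j] >= R[i] + R[j]:
                continue
            _, s_ij, v_ij = cap_geometry(R[i], R[j], d[i, j])
            dS[i] += s_ij
            dV[i] += v_ij
    return dS, dV


def atomic_surfaces(
    mol: Molecule,
    radii: dict[str, float] | None = None,
    bonded_only: bool = False,
    cn_cutoff: float = 0.8,
) -> np.ndarray:
    """Exposed surface area per atom (A^2), clamped at zero.

    "Adjacent" means sphere-overlapping (r_IJ < R_I + R_J) by default; the
    ``bonded_only`` flag restricts the subtraction to short contacts for
    sensitivity checks.
    """
    radii = radii if radii is not None else load_radii()
    R = np.array([radii[s] for s in mol.symbols])
    dS, _ = _pair_caps(mol, radii, bonded_only, cn_cutoff)
    return np.maximum(4.0 * np.pi * R * R - dS, 0.0)


def atomic_volumes(
    mol: Molecule,
    radii: dict[str, float] | None = None,
    bonded_only: bool = False,
    cn_cutoff: float = 0.8,
) -> np.ndarray:
    """Retained volume per atom (A^3), clamped at zero."""
    radii = radii if radii is not None else load_radii()
    R = np.array([radii[s] for s in mol.symbols])
    _, dV = _pair_caps(mol, radii, bonded_only, cn_cutoff)
    return np.maximum(4.0 / 3.0 * np.pi * R**3 - dV, 0.0)


@dataclass(frozen=True)
class SurfaceVolumeResult:
    """Per-atom exposed areas/volumes and their molecular totals."""

    S: np.ndarray  # A^2 per atom
    V: np.ndarray  # A^3 per atom

    @property
    def S_tot(self) -> float:
        return float(self.S.sum())

    @property
    def V_tot(self) -> float:
        return float(self.V.sum())


def surface_volume(
    mol: Molecule, radii: dict[str, float] | None = None
) -> SurfaceVolumeResult:
    """Convenience: areas and volumes in one pass."""
    radii = radii if radii is not None else load_radii()
    return SurfaceVolumeResult(
        S=atomic_surfaces(mol, radii), V=atomic_volumes(mol, radii)
    )
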