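"""Generalized-Born energy terms and the raw descriptor vector.

The electrostatic descriptors are element-grouped generalized-Born terms
built from EE charges, unmodified van der Waals radii, and the Still pair
function

    f_IJ = sqrt(r_IJ^2 + R_I R_J exp(-r_IJ^2 / (c R_I R_J))),  c = 4.

Self terms (per element L):   E1(L) = -(k/2)(1 - 1/eps) sum_{I in L} Q_I^2 / R_I
Pair terms (per element pair): E2(L1,L2) = -k (1 - 1/eps) sum_{I<J} Q_I Q_J / f_IJ
with k = 332.06 kcal*A/(mol*e^2), so a single ion reproduces the Born
spherical-ion solvation energy.  The sign convention (negative = stabilizing)
is fixed by the single constant COULOMB_KCAL; the downstream network absorbs
any global sign.

The raw descriptor vector is, in order: number of atoms, total charge,
molecular volume V_tot, total surface S_tot, nine element surface sums S_L,
nine self terms E1(L), the retained pair terms E2 (36 by default), and --
for nonaqueous solvents -- the solvent dielectric constant, boiling point,
and heavy-atom count (58 or 61 entries with the default pair list).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .charges import ChargeSolution
from .molecule import Molecule, SolventDescriptor, _data_path, load_radii
from .surface import SurfaceVolumeResult

#: Coulomb constant, kcal*A/(mol*e^2).
COULOMB_KCAL = 332.06

#: The nine elements resolved in the element-grouped features, fixed order.
FEATURE_ELEMENTS = ("H", "C", "N", "O", "F", "S", "Cl", "Br", "I")


def pair_function(r_ij, R_I, R_J, c: float = 4.0):
    """Still generalized-Born pair function f_IJ (Angstrom); vectorized."""
    R_I = np.asarray(R_I, dtype=float)
    R_J = np.asarray(R_J, dtype=float)
    if np.any(R_I <= 0) or np.any(R_J <= 0):
        raise ValueError("radii must be positive")
    r = np.asarray(r_ij, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance must be non-negative")
    rr = R_I * R_J
    return np.sqrt(r * r + rr * np.exp(-(r * r) / (c * rr)))


def _canonical_pair(a: str, b: str) -> tuple[str, str]:
    ia, ib = FEATURE_ELEMENTS.index(a), FEATURE_ELEMENTS.index(b)
    return (a, b) if ia <= ib else (b, a)


def load_pair_list(path=None) -> tuple[tuple[str, str], ...]:
    """Ordered element pairs retained for the pair-energy features."""
    p = Path(path) if path else _data_path("pair_list.txt")
    pairs = []
    for line in p.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        a, b = line.split("-")
        pairs.append(_canonical_pair(a, b))
    return tuple(pairs)


def all_pairs() -> tuple[tuple[str, str], ...]:
    """All 45 unordered pairs of the nine feature elements, canonical order."""
    out = []
    for i, a in enumerate(FEATURE_ELEMENTS):
        for b in FEATURE_ELEMENTS[i:]:
            out.append((a, b))
    return tuple(out)


@dataclass(frozen=True)
class FeatureSchema:
    """Layout of the raw descriptor vector."""

    aqueous: bool = True
    pair_list: tuple[tuple[str, str], ...] = field(default_factory=load_pair_list)

    def __post_init__(self):
        valid = set(all_pairs())
        for p in self.pair_list:
            if p not in valid:
                raise ValueError(f"pair {p} is not a canonical element pair")

    @property
    def raw_dim(self) -> int:
        n = 4 + len(FEATURE_ELEMENTS) * 2 + len(self.pair_list)
        return n if self.aqueous else n + 3

    def feature_names(self) -> list[str]:
        names = ["n_atoms", "Q_tot", "V_tot", "S_tot"]
        names += [f"S_{L}" for L in FEATURE_ELEMENTS]
        names += [f"E1_{L}" for L in FEATURE_ELEMENTS]
        names += [f"E2_{a}_{b}" for a, b in self.pair_list]
        if not self.aqueous:
            names += ["solvent_epsilon", "solvent_bp", "solvent_heavy_atoms"]
        return names


def default_schema(aqueous: bool = True) -> FeatureSchema:
    return FeatureSchema(aqueous=aqueous)


def dielectric_factor(epsilon: float) -> float:
    if epsilon <= 1:
        raise ValueError("dielectric constant must exceed 1")
    return 1.0 - 1.0 / epsilon


def born_self_terms(
    charges: ChargeSolution,
    mol: Molecule,
    radii: dict[str, float] | None = None,
    epsilon: float = 78.36,
) -> dict[str, float]:
    """Element-grouped Born self terms E1(L) in kcal/mol.

    Elements outside the nine-element feature set (Si, P) carry charge but
    contribute to no element-resolved term; absent elements map to 0.
    """
    radii = radii if radii is not None else load_radii()
    pref = -0.5 * COULOMB_KCAL * dielectric_factor(epsilon)
    out = {L: 0.0 for L in FEATURE_ELEMENTS}
    for sym, q in zip(mol.symbols, charges.charges):
        if sym in out:
            out[sym] += pref * q * q / radii[sym]
    return out


def born_pair_terms(
    charges: ChargeSolution,
    mol: Molecule,
    radii: dict[str, float] | None = None,
    epsilon: float = 78.36,
    schema: FeatureSchema | None = None,
) -> dict[tuple[str, str], float]:
    """Element-pair-grouped Born terms E2(L1,L2) in kcal/mol.

    Sums run over unordered atom pairs I<J; only pairs in the schema's
    pair list are returned.
    """
    radii = radii if radii is not None else load_radii()
    schema = schema or default_schema()
    pref = -COULOMB_KCAL * dielectric_factor(epsilon)
    out = {p: 0.0 for p in schema.pair_list}
    q = charges.charges
    d = mol.distance_matrix()
    for i in range(mol.n_atoms):
        si = mol.symbols[i]
        if si not in FEATURE_ELEMENTS:
            continue
        for j in range(i + 1, mol.n_atoms):
            sj = mol.symbols[j]
            if sj not in FEATURE_ELEMENTS:
                continue
            key = _canonical_pair(si, sj)
            if key not in out:
                continue
            f = pair_function(d[i, j], radii[si], radii[sj])
            out[key] += pref * q[i] * q[j] / f
    return out


def gb_electrostatic_energy(
    charges: ChargeSolution,
    mol: Molecule,
    radii: dict[str, float] | None = None,
    epsilon: float = 78.36,
) -> float:
    """Total generalized-Born electrostatic solvation energy (kcal/mol).

    Sum of all self terms and all 45 pair terms; used by the ionic
    dielectric-extrapolation augmentation.
    """
    schema = FeatureSchema(aqueous=True, pair_list=all_pairs())
    e1 = born_self_terms(charges, mol, radii, epsilon)
    e2 = born_pair_terms(charges, mol, radii, epsilon, schema)
    return float(sum(e1.values()) + sum(e2.values()))


def assemble_features(
    mol: Molecule,
    charges: ChargeSolution,
    surfvol: SurfaceVolumeResult,
    epsilon: float,
    solvent: SolventDescriptor | None = None,
    schema: FeatureSchema | None = None,
    radii: dict[str, float] | None = None,
) -> np.ndarray:
    """Assemble the ordered raw descriptor vector."""
    schema = schema or default_schema()
    if not schema.aqueous and solvent is None:
        raise ValueError("nonaqueous feature layout requires a solvent descriptor")
    radii = radii if radii is not None else load_radii()
    s_L = {L: 0.0 for L in FEATURE_ELEMENTS}
    for sym, s in zip(mol.symbols, surfvol.S):
        if sym in s_L:
            s_L[sym] += float(s)
    e1 = born_self_terms(charges, mol, radii, epsilon)
    e2 = born_pair_terms(charges, mol, radii, epsilon, schema)
    vec = [float(mol.n_atoms), float(mol.total_charge), surfvol.V_tot, surfvol.S_tot]
    vec += [s_L[L] for L in FEATURE_ELEMENTS]
    vec += [e1[L] for L in FEATURE_ELEMENTS]
    vec += [e2[p] for p in schema.pair_list]
    if not schema.aqueous:
        vec += [solvent.epsilon, solvent.boiling_point, float(solvent.heavy_atoms)]
    out = np.array(vec, dtype=float)
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite feature encountered")
    return out


def featurize(
    mol: Molecule,
    solvent: SolventDescriptor,
    schema: FeatureSchema | None = None,
    params=None,
    radii: dict[str, float] | None = None,
) -> np.ndarray:
    """Full geometry-to-descriptor pipeline for one molecule in one solvent."""
    from .charges import solve_charges
    from .surface import surface_volume

    schema = schema or default_schema(aqueous=solvent.is_water)
    radii = radii if radii is not None else load_radii()
    sol = solve_charges(mol, params=params)
    sv = surface_volume(mol, radii)
    return assemble_features(
        mol, sol, sv, solvent.epsilon,
        solvent=None if schema.aqueous else solvent,
        schema=schema, radii=radii,
    )
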