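"""Molecular geometries, radii tables, coordination numbers, solvents.

The only physical input to the solvation model is a molecular geometry
(Cartesian coordinates in Angstrom), element symbols, and the total solute
charge.  XYZ files carry the charge as a ``charge=<int>`` token in the
comment line, since the XYZ format has no standard charge field.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import UnknownSolventError, UnsupportedElementError, XYZParseError

#: Elements with electronegativity-equalization parameters.
SUPPORTED_ELEMENTS = ("H", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Br", "I")


def _data_path(name: str) -> Path:
    return Path(str(resources.files("gbsolv").joinpath("data", name)))


def _read_table(path: Path) -> dict[str, list[str]]:
    """Parse a whitespace-delimited key/value text table, skipping comments."""
    out: dict[str, list[str]] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        out[parts[0]] = parts[1:]
    return out


@dataclass(frozen=True)
class Molecule:
    """A solute: element symbols, Cartesian coordinates (A), total charge (e)."""

    symbols: tuple[str, ...]
    coords: np.ndarray
    total_charge: int = 0

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "symbols", tuple(self.symbols))
        if len(self.symbols) < 1:
            raise ValueError("a molecule needs at least one atom")
        if coords.shape[0] != len(self.symbols):
            raise ValueError("symbols and coordinates disagree in length")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        for s in self.symbols:
            if s not in SUPPORTED_ELEMENTS:
                raise UnsupportedElementError(s)

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    def distance_matrix(self) -> np.ndarray:
        d = self.coords[:, None, :] - self.coords[None, :, :]
        return np.sqrt((d * d).sum(axis=-1))


# --------------------------------------------------------------------------
# XYZ input/output

_CHARGE_RE = re.compile(r"charge\s*=\s*([+-]?\d+)", re.IGNORECASE)


def read_xyz(path) -> Molecule:
    """Read an XYZ file; total charge from a ``charge=<int>`` comment token."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise XYZParseError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise XYZParseError(f"{path}: malformed atom-count line {lines[0]!r}") from exc
    if len(lines) < n + 2:
        raise XYZParseError(f"{path}: expected {n} atom rows, file too short")
    comment = lines[1] if len(lines) > 1 else ""
    m = _CHARGE_RE.search(comment)
    charge = int(m.group(1)) if m else 0
    symbols, coords = [], []
    for i, line in enumerate(lines[2 : 2 + n]):
        parts = line.split()
        if len(parts) < 4:
            raise XYZParseError(f"{path}: malformed atom row {i + 1}: {line!r}")
        sym = parts[0].capitalize() if len(parts[0]) > 1 else parts[0].upper()
        if sym not in SUPPORTED_ELEMENTS:
            raise UnsupportedElementError(parts[0], f"{path} row {i + 1}")
        symbols.append(sym)
        try:
            coords.append([float(x) for x in parts[1:4]])
        except ValueError as exc:
            raise XYZParseError(f"{path}: bad coordinates in row {i + 1}") from exc
    return Molecule(tuple(symbols), np.array(coords), charge)


def write_xyz(mol: Molecule, path, comment: str = "") -> None:
    """Write an XYZ file, embedding the total charge in the comment line."""
    out = [str(mol.n_atoms), f"charge={mol.total_charge} {comment}".rstrip()]
    for s, (x, y, z) in zip(mol.symbols, mol.coords):
        out.append(f"{s:<2s} {x:18.10f} {y:18.10f} {z:18.10f}")
    Path(path).write_text("\n".join(out) + "\n")


# --------------------------------------------------------------------------
# Radii tables


def load_radii(path=None) -> dict[str, float]:
    """van der Waals radii (Bondi set by default), element -> Angstrom."""
    p = Path(path) if path else _data_path("bondi_radii.txt")
    table = {k: float(v[0]) for k, v in _read_table(p).items()}
    for el, r in table.items():
        if r <= 0:
            raise ValueError(f"non-positive radius for {el}")
    return table


def load_covalent_radii(path=None) -> dict[str, float]:
    p = Path(path) if path else _data_path("covalent_radii.txt")
    return {k: float(v[0]) for k, v in _read_table(p).items()}


def lookup_radius(symbol: str, table: dict[str, float] | None = None) -> float:
    table = table if table is not None else load_radii()
    try:
        return table[symbol]
    except KeyError:
        raise UnsupportedElementError(symbol, "no tabulated radius") from None


# --------------------------------------------------------------------------
# Coordination numbers


def coordination_numbers(
    mol: Molecule,
    radii: dict[str, float] | None = None,
    tolerance: float = 1.2,
) -> np.ndarray:
    """Geometric coordination numbers by a covalent-radius-sum cutoff.

    Atom J counts as bonded to I when r_IJ <= tolerance * (r_cov(I) + r_cov(J)).
    Returns raw neighbor counts; mapping onto the coordination-number ranges
    of the charge-parameter table happens at parameter resolution.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    radii = radii if radii is not None else load_covalent_radii()
    rc = np.array([radii[s] for s in mol.symbols])
    d = mol.distance_matrix()
    cutoff = tolerance * (rc[:, None] + rc[None, :])
    bonded = (d <= cutoff) & ~np.eye(mol.n_atoms, dtype=bool)
    return bonded.sum(axis=1).astype(int)


# --------------------------------------------------------------------------
# Solvent registry


@dataclass(frozen=True)
class SolventDescriptor:
    """Three-number solvent description: dielectric, boiling point, size."""

    name: str
    epsilon: float
    boiling_point: float  # deg C
    heavy_atoms: int

    def __post_init__(self):
        if self.epsilon <= 1:
            raise ValueError("dielectric constant must exceed 1")
        if self.heavy_atoms < 1:
            raise ValueError("heavy-atom count must be at least 1")

    @property
    def is_water(self) -> bool:
        return self.name.lower() == "water"


def load_solvents(path=None) -> dict[str, SolventDescriptor]:
    """Load the solvent registry; keys are lower-cased names."""
    p = Path(path) if path else _data_path("solvents.txt")
    out: dict[str, SolventDescriptor] = {}
    for line in p.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.rsplit(None, 3)
        if len(parts) != 4:
            raise ValueError(f"malformed solvent row: {line!r}")
        name = parts[0]
        out[name.lower()] = SolventDescriptor(
            name=name,
            epsilon=float(parts[1]),
            boiling_point=float(parts[2]),
            heavy_atoms=int(parts[3]),
        )
    return out


def save_solvents(registry: dict[str, SolventDescriptor], path) -> None:
    rows = ["# name  epsilon  bp  heavy_atoms"]
    for s in registry.values():
        rows.append(f"{s.name}  {s.epsilon}  {s.boiling_point}  {s.heavy_atoms}")
    Path(path).write_text("\n".join(rows) + "\n")


def lookup_solvent(
    name: str, table: dict[str, SolventDescriptor] | None = None
) -> SolventDescriptor:
    table = table if table is not None else load_solvents()
    try:
        return table[name.lower()]
    except KeyError:
        raise UnknownSolventError(name, [s.name for s in table.values()]) from None
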