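"""Electronegativity-equalization (EE) atomic charges.

Charges follow from the condition that every atom's effective
electronegativity is equal at the solution.  With per-atom intrinsic
electronegativity A_I and hardness B_I (both dependent on element and
coordination number) and a distance-dependent coupling Y_IJ, the charges
solve the (N+1)x(N+1) linear system

    2 B_I Q_I + sum_{J != I} Y_IJ Q_J - chi = -A_I      (one row per atom)
    sum_I Q_I = Q_tot                                   (constraint row)

where chi is the equalized electronegativity.  The diagonal carries the
conventional factor of two from the quadratic charge-energy expansion
(E ~ A Q + B Q^2); the factor is pinned by a unit test.

The coupling is a screened Coulomb interaction with two global screening
lengths kappa and kappa2 (Angstrom),

    Y_IJ = 1 / sqrt(r_IJ^2 + kappa*kappa2 * exp(-r_IJ^2 / (kappa*kappa2)))

which is symmetric, strictly positive, strictly decreasing in r_IJ, finite
at contact (Y -> (kappa*kappa2)^(-1/2) as r -> 0), and asymptotically
Coulombic (r*Y -> 1).  A and B are kept in their as-tabulated units with
distances in Angstrom, so Y carries units of 1/Angstrom and no separate
Coulomb constant enters the system.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize

from .errors import SingularSystemError, UnsupportedElementError
from .molecule import Molecule, _data_path, coordination_numbers

#: Diagonal convention of the equalization rows (2*B_I).
HARDNESS_DIAGONAL_FACTOR = 2.0

#: Condition number beyond which the system is reported singular.
_COND_LIMIT = 1e12


def _parse_cn_spec(spec: str) -> frozenset[int] | None:
    """Parse a coordination-number column: '4', '2,3', '1-3', or '*' (any)."""
    if spec == "*":
        return None
    cns: set[int] = set()
    for tok in spec.split(","):
        if "-" in tok:
            lo, hi = tok.split("-")
            cns.update(range(int(lo), int(hi) + 1))
        else:
            cns.add(int(tok))
    return frozenset(cns)


def _format_cn_spec(cns: frozenset[int] | None) -> str:
    if cns is None:
        return "*"
    return ",".join(str(c) for c in sorted(cns))


@dataclass(frozen=True)
class EEEntry:
    element: str
    cns: frozenset[int] | None  # None = any coordination number
    A: float
    B: float


@dataclass
class EEParameterSet:
    """Per-(element, CN-range) electronegativity/hardness parameters."""

    entries: tuple[EEEntry, ...]
    kappa: float
    kappa2: float

    def __post_init__(self):
        if self.kappa <= 0 or self.kappa2 <= 0:
            raise ValueError("screening lengths must be positive")
        for e in self.entries:
            if e.B <= 0:
                raise ValueError(f"hardness must be positive ({e.element})")

    def resolve(self, element: str, cn: int) -> EEEntry:
        """Entry for (element, CN); CNs outside any listed range map to the
        nearest listed range (an isolated atom lands on the lowest row)."""
        rows = [e for e in self.entries if e.element == element]
        if not rows:
            raise UnsupportedElementError(element, "no EE parameters")
        wildcard = [e for e in rows if e.cns is None]
        if wildcard:
            return wildcard[0]
        exact = [e for e in rows if cn in e.cns]
        if exact:
            return exact[0]
        # clamp to nearest listed CN (ties -> lower CN)
        best = min(rows, key=lambda e: (min(abs(cn - c) for c in e.cns), min(e.cns)))
        return best

    # -- serialization (plain-text table mirroring the parameter columns) --

    @classmethod
    def from_file(cls, path=None) -> "EEParameterSet":
        p = Path(path) if path else _data_path("ee_params.txt")
        entries, kappa, kappa2 = [], None, None
        for line in p.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if parts[0] == "kappa":
                kappa = float(parts[1])
            elif parts[0] == "kappa2":
                kappa2 = float(parts[1])
            else:
                el, cn_spec, a, b = parts
                entries.append(EEEntry(el, _parse_cn_spec(cn_spec), float(a), float(b)))
        if kappa is None or kappa2 is None:
            raise ValueError(f"{p}: missing kappa/kappa2 rows")
        return cls(tuple(entries), kappa, kappa2)

    def to_file(self, path) -> None:
        rows = ["# element  cn  A  B"]
        for e in self.entries:
            rows.append(f"{e.element:<4s} {_format_cn_spec(e.cns):<5s} {e.A:.6f} {e.B:.6f}")
        rows.append(f"kappa  {self.kappa:.6f}")
        rows.append(f"kappa2 {self.kappa2:.6f}")
        Path(path).write_text("\n".join(rows) + "\n")


_DEFAULT_PARAMS: EEParameterSet | None = None


def default_parameters() -> EEParameterSet:
    global _DEFAULT_PARAMS
    if _DEFAULT_PARAMS is None:
        _DEFAULT_PARAMS = EEParameterSet.from_file()
    return _DEFAULT_PARAMS


# --------------------------------------------------------------------------
# Coupling and linear solve


def offdiag_coupling(r_ij, kappa: float, kappa2: float):
    """Screened-Coulomb coupling Y_IJ (1/Angstrom); vectorized in r_ij."""
    r = np.asarray(r_ij, dtype=float)
    if np.any(r <= 0):
        raise ValueError("interatomic distance must be positive")
    p = kappa * kappa2
    return 1.0 / np.sqrt(r * r + p * np.exp(-(r * r) / p))


@dataclass(frozen=True)
class ChargeSolution:
    """EE charges (e) and the equalized electronegativity chi."""

    charges: np.ndarray
    chi: float


def build_system(
    mol: Molecule, cn: np.ndarray, params: EEParameterSet
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the (N+1)x(N+1) equalization matrix and right-hand side."""
    n = mol.n_atoms
    A = np.zeros(n)
    M = np.zeros((n + 1, n + 1))
    for i, (sym, c) in enumerate(zip(mol.symbols, cn)):
        entry = params.resolve(sym, int(c))
        A[i] = entry.A
        M[i, i] = HARDNESS_DIAGONAL_FACTOR * entry.B
    if n > 1:
        d = mol.distance_matrix()
        iu = np.triu_indices(n, k=1)
        y = offdiag_coupling(d[iu], params.kappa, params.kappa2)
        M[iu] = y
        M[(iu[1], iu[0])] = y
    M[:n, n] = -1.0  # -chi column
    M[n, :n] = 1.0  # total-charge constraint row
    rhs = np.concatenate([-A, [float(mol.total_charge)]])
    return M, rhs


def solve_charges(
    mol: Molecule,
    cn: np.ndarray | None = None,
    params: EEParameterSet | None = None,
) -> ChargeSolution:
    """Solve the EE linear system; total charge is conserved exactly."""
    params = params or default_parameters()
    if cn is None:
        cn = coordination_numbers(mol)
    M, rhs = build_system(mol, np.asarray(cn), params)
    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        raise SingularSystemError(cond)
    x = np.linalg.solve(M, rhs)
    q = x[:-1]
    # project out solver round-off in the conservation constraint
    q = q + (mol.total_charge - q.sum()) / mol.n_atoms
    return ChargeSolution(charges=q, chi=float(x[-1]))


# --------------------------------------------------------------------------
# Parameter refitting (derivative-free simplex)


def _collect_free_entries(
    params: EEParameterSet, training
) -> list[EEEntry]:
    """Entries actually exercised by the training molecules, in table order."""
    used: set = set()
    for mol, cn, _targets in training:
        for sym, c in zip(mol.symbols, cn):
            used.add(id(params.resolve(sym, int(c))))
    return [e for e in params.entries if id(e) in used]


def _charge_rmse(params: EEParameterSet, training) -> float:
    sq, count = 0.0, 0
    for mol, cn, targets in training:
        sol = solve_charges(mol, cn, params)
        sq += float(np.sum((sol.charges - np.asarray(targets)) ** 2))
        count += mol.n_atoms
    return np.sqrt(sq / count)


def fit_parameters(
    training,
    initial: EEParameterSet | None = None,
    max_iter: int = 20000,
    fit_screening: bool = True,
    tol: float = 1e-10,
) -> tuple[EEParameterSet, float]:
    """Refit (A, B) rows -- and optionally kappa, kappa2 -- against target
    charges by Nelder-Mead simplex, minimizing the per-atom charge RMSE.

    ``training`` is a list of (Molecule, coordination numbers, target charges);
    every molecule's targets must sum to its total charge.  Only parameter
    rows exercised by the training molecules are varied.  All atoms are
    weighted equally.  Returns (fitted parameters, final RMSE in e).
    """
    params = initial or default_parameters()
    for mol, _cn, targets in training:
        if abs(float(np.sum(targets)) - mol.total_charge) > 1e-6:
            raise ValueError("target charges must sum to the molecular charge")
    free = _collect_free_entries(params, training)
    if not free:
        raise ValueError("no parameter rows exercised by the training set")

    def pack(ps: EEParameterSet) -> np.ndarray:
        x = []
        lookup = {(e.element, e.cns): e for e in ps.entries}
        for e in free:
            cur = lookup[(e.element, e.cns)]
            x.extend([cur.A, cur.B])
        if fit_screening:
            x.extend([ps.kappa, ps.kappa2])
        return np.array(x)

    def unpack(x: np.ndarray) -> EEParameterSet:
        repl = {}
        for k, e in enumerate(free):
            repl[(e.element, e.cns)] = (x[2 * k], x[2 * k + 1])
        entries = tuple(
            EEEntry(e.element, e.cns, *repl[(e.element, e.cns)])
            if (e.element, e.cns) in repl
            else e
            for e in params.entries
        )
        if fit_screening:
            kap, kap2 = x[-2], x[-1]
        else:
            kap, kap2 = params.kappa, params.kappa2
        return EEParameterSet(entries, kap, kap2)

    def objective(x: np.ndarray) -> float:
        # barrier against non-physical hardness / screening lengths
        bs = x[1 : 2 * len(free) : 2]
        tail = x[2 * len(free) :]
        if np.any(bs <= 1e-3) or (fit_screening and np.any(tail <= 1e-3)):
            return 1e3
        try:
            return _charge_rmse(unpack(x), training)
        except SingularSystemError:
            return 1e3

    x0 = pack(params)
    res = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={
            "maxiter": max_iter,
            "maxfev": max_iter,
            "xatol": 1e-8,
            "fatol": tol,
            "adaptive": True,
        },
    )
    if not res.success:
        warnings.warn(
            f"simplex fit did not converge in {max_iter} iterations; "
            f"returning best point (RMSE {res.fun:.3e} e)",
            stacklevel=2,
        )
    fitted = unpack(res.x)
    return fitted, float(res.fun)


class EEChargeModel:
    """Estimator-style wrapper: refit EE parameters, then predict charges.

    Parameters
    ----------
    initial : EEParameterSet, optional
        Starting point for the simplex fit (bundled table by default).
    fit_screening : bool
        Whether kappa/kappa2 are varied jointly with the A/B rows.
    max_iter : int
        Simplex iteration budget.
    """

    def __init__(self, initial: EEParameterSet | None = None,
                 fit_screening: bool = True, max_iter: int = 20000):
        self.initial = initial
        self.fit_screening = fit_screening
        self.max_iter = max_iter

    def get_params(self, deep: bool = True) -> dict:
        return {
            "initial": self.initial,
            "fit_screening": self.fit_screening,
            "max_iter": self.max_iter,
        }

    def set_params(self, **kw) -> "EEChargeModel":
        for k, v in kw.items():
            setattr(self, k, v)
        return self

    def fit(self, training) -> "EEChargeModel":
        self.params_, self.rmse_ = fit_parameters(
            training,
            initial=self.initial,
            max_iter=self.max_iter,
            fit_screening=self.fit_screening,
        )
        return self

    def predict(self, mol: Molecule, cn: np.ndarray | None = None) -> np.ndarray:
        params = getattr(self, "params_", None) or self.initial or default_parameters()
        return solve_charges(mol, cn, params).charges
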