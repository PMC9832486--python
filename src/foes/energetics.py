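"""Residue-pair nonbonded interaction-energy matrices.

The built-in model is a deliberately simple heavy-atom surrogate for a full
MM/GBSA decomposition: Lennard-Jones (Lorentz-Berthelot combining, 10 A
cutoff) plus Coulomb electrostatics screened by a distance-dependent
dielectric eps(r) = 4r, a standard implicit-solvent shortcut. Downstream
analysis consumes any symmetric matrix, so externally computed per-residue
decompositions can be imported from CSV/TSV instead.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structure_io import Residue, Structure

logger = logging.getLogger(__name__)

COULOMB_CONSTANT = 332.06  # kcal*A/(mol*e^2)


class MatrixFormatError(ValueError):
    """Raised for malformed matrix files or label mismatches."""


class DegenerateGeometryError(ValueError):
    """Two atoms coincide; the pair energy is undefined."""


# Lennard-Jones parameters per element (Amber-like): epsilon kcal/mol, sigma A.
DEFAULT_LJ = {
    "C": (0.086, 3.40),
    "N": (0.170, 3.25),
    "O": (0.210, 2.96),
    "S": (0.250, 3.56),
    "P": (0.200, 3.74),
}
FALLBACK_LJ = (0.10, 3.40)

# Approximate Amber-like heavy-atom partial charges. Backbone is shared by
# all residues; side chains list only atoms that depart appreciably from
# neutral carbon. Hydrogens are not modelled (heavy-atom surrogate), so
# polar-group charges are net-group values rather than per-H splits.
_BACKBONE_CHARGES = {"N": -0.42, "CA": 0.03, "C": 0.60, "O": -0.57}

_SIDECHAIN_CHARGES = {
    "SER": {"OG": -0.40},
    "THR": {"OG1": -0.40},
    "CYS": {"SG": -0.20},
    "MET": {"SD": -0.10},
    "ASN": {"CG": 0.55, "OD1": -0.55, "ND2": -0.45},
    "GLN": {"CD": 0.55, "OE1": -0.55, "NE2": -0.45},
    "TYR": {"OH": -0.40},
    "TRP": {"NE1": -0.30},
    "HIS": {"ND1": -0.35, "NE2": -0.35},
    # Charged side chains carry the net formal charge on the terminal group.
    "ASP": {"CG": 0.60, "OD1": -0.80, "OD2": -0.80},
    "GLU": {"CD": 0.60, "OE1": -0.80, "OE2": -0.80},
    "LYS": {"NZ": 0.70, "CE": 0.30},
    "ARG": {"CZ": 0.60, "NH1": 0.20, "NH2": 0.20, "NE": 0.0},
}


def default_charge_table() -> dict[tuple[str, str], float]:
    """Per-(residue name, atom name) partial charges for the 20 amino acids."""
    table: dict[tuple[str, str], float] = {}
    residues = set(_SIDECHAIN_CHARGES) | {
        "ALA", "GLY", "VAL", "LEU", "ILE", "PRO", "PHE",
    }
    for res in residues:
        for atom, q in _BACKBONE_CHARGES.items():
            table[(res, atom)] = q
        for atom, q in _SIDECHAIN_CHARGES.get(res, {}).items():
            table[(res, atom)] = q
    return table


@dataclass
class EnergyParams:
    """Parameters of the built-in pair-energy surrogate."""

    charges: dict[tuple[str, str], float] = field(default_factory=default_charge_table)
    lj: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_LJ))
    lj_cutoff: float = 10.0
    dielectric_slope: float = 4.0  # eps(r) = dielectric_slope * r
    default_charge: float = 0.0
    exclude_adjacent: bool = False
    lj_enabled: bool = True

    def __post_init__(self):
        if self.lj_cutoff <= 0:
            raise ValueError("lj_cutoff must be positive")
        for elem, (eps, sigma) in self.lj.items():
            if eps < 0 or sigma <= 0:
                raise ValueError(f"invalid LJ parameters for element {elem}")

    @classmethod
    def from_json(cls, path: str | Path) -> "EnergyParams":
        """Load overrides from a JSON file on top of the defaults."""
        with open(path) as fh:
            raw = json.load(fh)
        params = cls()
        if "lj_cutoff" in raw:
            params.lj_cutoff = float(raw["lj_cutoff"])
        if "dielectric_slope" in raw:
            params.dielectric_slope = float(raw["dielectric_slope"])
        if "exclude_adjacent" in raw:
            params.exclude_adjacent = bool(raw["exclude_adjacent"])
        if "lj_enabled" in raw:
            params.lj_enabled = bool(raw["lj_enabled"])
        for key, q in raw.get("charges", {}).items():
            res, atom = key.split(":")
            params.charges[(res, atom)] = float(q)
        for elem, pair in raw.get("lj", {}).items():
            params.lj[elem] = (float(pair[0]), float(pair[1]))
        return params


@dataclass
class InteractionMatrix:
    """N x N symmetric residue-pair energy matrix (kcal/mol)."""

    values: np.ndarray
    labels: list[str]
    provenance: str = "builtin"  # builtin | imported

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if values.shape != (n, n):
            raise MatrixFormatError(
                f"matrix shape {values.shape} does not match {n} labels"
            )
        if not np.all(np.isfinite(values)):
            raise MatrixFormatError("matrix contains non-finite entries")
        if not np.array_equal(values, values.T):
            raise MatrixFormatError("matrix is not symmetric")
        if np.any(np.diag(values) != 0.0):
            raise MatrixFormatError("diagonal entries must be zero")
        self.values = values

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)


def _residue_arrays(residue: Residue, params: EnergyParams):
    """Heavy-atom coordinates, charges, and LJ parameters for one residue."""
    coords, charges, eps, sigma = [], [], [], []
    for atom in residue.atoms:
        if atom.element == "H":
            continue
        coords.append(atom.coord)
        charges.append(
            params.charges.get((residue.name, atom.name), params.default_charge)
        )
        e, s = params.lj.get(atom.element, FALLBACK_LJ)
        eps.append(e)
        sigma.append(s)
    return (
        np.asarray(coords),
        np.asarray(charges),
        np.asarray(eps),
        np.asarray(sigma),
    )


def pair_energy(
    res_i: Residue, res_j: Residue, params: EnergyParams | None = None
) -> float:
    """Nonbonded interaction energy between two residues (kcal/mol).

    Sum over heavy-atom pairs of LJ (within the cutoff) plus screened Coulomb
    q_i q_j * 332.06 / (4r * r); symmetric in its arguments.
    """
    if params is None:
        params = EnergyParams()
    ci, qi, ei, si = _residue_arrays(res_i, params)
    cj, qj, ej, sj = _residue_arrays(res_j, params)
    if ci.size == 0 or cj.size == 0:
        return 0.0
    r = cdist(ci, cj)
    if np.any(r == 0.0):
        raise DegenerateGeometryError(
            f"coincident atoms between residues {res_i.label} and {res_j.label}"
        )
    qq = np.outer(qi, qj)
    coulomb = COULOMB_CONSTANT * qq / (params.dielectric_slope * r * r)
    total = float(coulomb.sum())
    if params.lj_enabled:
        eps = np.sqrt(np.outer(ei, ej))  # Lorentz-Berthelot
        sigma = 0.5 * (si[:, None] + sj[None, :])
        mask = r <= params.lj_cutoff
        sr6 = (sigma[mask] / r[mask]) ** 6
        total += float(np.sum(4.0 * eps[mask] * (sr6 * sr6 - sr6)))
    return total


def energy_matrix(
    structure: Structure, params: EnergyParams | None = None
) -> InteractionMatrix:
    """Built-in N x N interaction matrix over all residue pairs."""
    if params is None:
        params = EnergyParams()
    n = len(structure)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if params.exclude_adjacent and _adjacent(
                structure.residues[i], structure.residues[j]
            ):
                continue
            try:
                e = pair_energy(structure.residues[i], structure.residues[j], params)
            except DegenerateGeometryError as exc:
                raise DegenerateGeometryError(
                    f"{exc} (matrix indices {i}, {j})"
                ) from exc
            values[i, j] = values[j, i] = e
    return InteractionMatrix(
        values=values, labels=structure.labels(), provenance="builtin"
    )


def _adjacent(a: Residue, b: Residue) -> bool:
    return a.chain_id == b.chain_id and abs(a.number - b.number) == 1 and not (
        a.icode or b.icode
    )


def read_energy_matrix(
    path: str | Path,
    structure: Structure | None = None,
    asymmetry_tol: float = 1e-6,
) -> InteractionMatrix:
    """Import an externally computed residue-pair matrix from CSV/TSV.

    Row/column labels (``chain:resnum``) must match; when a structure is
    supplied the matrix is reordered to the structure's residue order. The
    matrix is symmetrized as (M + M^T)/2, with a warning if the asymmetry
    exceeds ``asymmetry_tol``.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    frame = pd.read_csv(path, sep=sep, index_col=0)
    if frame.shape[0] != frame.shape[1]:
        raise MatrixFormatError(
            f"matrix in {path} is not square: shape {frame.shape}"
        )
    rows = [str(r) for r in frame.index]
    cols = [str(c) for c in frame.columns]
    if rows != cols:
        if sorted(rows) != sorted(cols):
            raise MatrixFormatError("row and column labels differ")
        frame = frame.loc[rows, rows]

    if structure is not None:
        wanted = structure.labels()
        missing = set(wanted) - set(rows)
        if missing:
            raise MatrixFormatError(
                f"labels missing from matrix file: {sorted(missing)[:5]} ..."
                if len(missing) > 5
                else f"labels missing from matrix file: {sorted(missing)}"
            )
        frame = frame.loc[wanted, wanted]
        labels = wanted
    else:
        labels = [str(r) for r in frame.index]

    values = frame.to_numpy(dtype=float)
    asym = float(np.max(np.abs(values - values.T))) if values.size else 0.0
    if asym > asymmetry_tol:
        logger.warning(
            "matrix %s asymmetric (max |M_ij - M_ji| = %.3g); symmetrizing",
            path,
            asym,
        )
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 0.0)
    return InteractionMatrix(values=values, labels=labels, provenance="imported")
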