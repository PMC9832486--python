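"""Protein structure parsing, representative atoms, and selection export.

Structures are held as a flat list of residues; residue order is stable and
defines the matrix-index <-> residue mapping used by every downstream stage.
PDB reading and writing go through biotite's ``AtomArray``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

import biotite.structure as bst
import biotite.structure.io.pdb as bpdb

logger = logging.getLogger(__name__)

#: Three-letter codes treated as protein residues.
PROTEIN_RESIDUES = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR
    TRP TYR VAL MSE HID HIE HIP ASH GLH LYN CYX""".split()
)

#: Common monosaccharide codes treated as glycan residues (C1 representative).
GLYCAN_RESIDUES = frozenset(
    "NAG NDG MAN BMA GAL GLA GLC BGC FUC FUL SIA XYS RIB A2G NGA".split()
)

_SOLVENT = frozenset("HOH WAT DOD SOL NA CL K MG CA ZN SO4 PO4 GOL EDO".split())


class StructureError(ValueError):
    """Raised for unreadable files, empty selections, or missing atoms."""


class MissingAtomError(StructureError):
    """A residue lacks every usable representative atom."""


@dataclass(frozen=True)
class Atom:
    """A heavy (or hydrogen) atom with Cartesian coordinates in Angstrom."""

    name: str
    element: str
    coord: np.ndarray
    occupancy: float | None = None
    bfactor: float | None = None

    def __post_init__(self):
        coord = np.asarray(self.coord, dtype=float)
        if coord.shape != (3,) or not np.all(np.isfinite(coord)):
            raise StructureError(f"atom {self.name}: coord must be a finite 3-vector")
        if not self.element:
            raise StructureError(f"atom {self.name}: element must be non-empty")
        object.__setattr__(self, "coord", coord)


@dataclass
class Residue:
    """One residue identified by author numbering (chain, number, icode)."""

    chain_id: str
    number: int
    name: str
    atoms: list[Atom]
    icode: str = ""
    kind: str = "protein"  # protein | glycan | other

    def __post_init__(self):
        if not self.atoms:
            raise StructureError(f"residue {self.key} has no atoms")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.icode)

    @property
    def label(self) -> str:
        """Compact text id, e.g. ``A:42`` or ``A:42A``."""
        return f"{self.chain_id}:{self.number}{self.icode}"

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Structure:
    """An ordered residue list; order defines 0-based matrix indices."""

    id: str
    residues: list[Residue]
    source: str = "synthetic"

    def __post_init__(self):
        if len(self.residues) < 2:
            raise StructureError("a structure needs at least 2 residues")
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise StructureError("duplicate (chain, number, icode) residue keys")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def index_map(self) -> dict[tuple[str, int, str], int]:
        """Residue key -> 0-based contiguous matrix index."""
        return {r.key: i for i, r in enumerate(self.residues)}

    def labels(self) -> list[str]:
        return [r.label for r in self.residues]

    def representative_coords(self) -> np.ndarray:
        """(N, 3) array of representative-atom coordinates."""
        return np.array([representative_coord(r) for r in self.residues])

    def heavy_coords(self) -> np.ndarray:
        """All heavy-atom coordinates of the structure, stacked."""
        return np.concatenate(
            [[a.coord for a in r.atoms if a.element != "H"] for r in self.residues]
        )


def classify_residue(res_name: str) -> str:
    if res_name in PROTEIN_RESIDUES:
        return "protein"
    if res_name in GLYCAN_RESIDUES:
        return "glycan"
    return "other"


def representative_coord(residue: Residue) -> np.ndarray:
    """Representative-atom coordinate used for contacts and windows.

    Protein residues use C-beta; glycine (which has none) uses C-alpha, and a
    non-glycine residue with a truncated side chain falls back to C-alpha with
    a warning. Glycan residues use the anomeric C1 carbon.
    """
    if residue.kind == "glycan":
        c1 = residue.atom("C1")
        if c1 is not None:
            return c1.coord
        raise MissingAtomError(f"glycan residue {residue.label} has no C1 atom")
    cb = residue.atom("CB")
    if cb is not None:
        return cb.coord
    ca = residue.atom("CA")
    if ca is not None:
        if residue.name != "GLY":
            logger.warning(
                "residue %s (%s) has no CB; falling back to CA",
                residue.label,
                residue.name,
            )
        return ca.coord
    raise MissingAtomError(
        f"residue {residue.label} ({residue.name}) has neither CB nor CA"
    )


def _select_altloc(atom_array: bst.AtomArray) -> bst.AtomArray:
    # biotite's get_structure(altloc="occupancy") already keeps the
    # highest-occupancy conformer (first on ties); nothing left to do here.
    return atom_array


def load_structure(
    path: str | Path,
    model_index: int = 0,
    chain_filter: Iterable[str] | None = None,
    keep_other: bool = False,
    structure_id: str | None = None,
) -> Structure:
    """Read one model of a PDB file into a :class:`Structure`.

    Waters, ions, detergents and other non-protein, non-glycan HETATM records
    are dropped unless ``keep_other`` is set. Alternate locations keep the
    highest-occupancy conformer. ``model_index`` is 0-based (multi-model NMR
    files default to the first model).
    """
    path = Path(path)
    try:
        pdb_file = bpdb.PDBFile.read(str(path))
        n_models = pdb_file.get_model_count()
        if not 0 <= model_index < n_models:
            raise StructureError(
                f"model_index {model_index} out of range (file has {n_models})"
            )
        atoms = pdb_file.get_structure(
            model=model_index + 1,
            altloc="occupancy",
            extra_fields=["occupancy", "b_factor"],
        )
    except StructureError:
        raise
    except Exception as exc:  # biotite raises various parse errors
        raise StructureError(f"cannot parse PDB file {path}: {exc}") from exc

    atoms = _select_altloc(atoms)
    if chain_filter is not None:
        wanted = set(chain_filter)
        atoms = atoms[np.isin(atoms.chain_id, sorted(wanted))]

    residues: list[Residue] = []
    for start, stop in zip(*_residue_slices(atoms)):
        sub = atoms[start:stop]
        name = str(sub.res_name[0])
        kind = classify_residue(name)
        if kind == "other" and (not keep_other or name in _SOLVENT):
            continue
        res_atoms = [
            Atom(
                name=str(sub.atom_name[k]),
                element=str(sub.element[k]) or "X",
                coord=sub.coord[k],
                occupancy=float(sub.occupancy[k]),
                bfactor=float(sub.b_factor[k]),
            )
            for k in range(len(sub))
        ]
        residues.append(
            Residue(
                chain_id=str(sub.chain_id[0]),
                number=int(sub.res_id[0]),
                icode=str(sub.ins_code[0]).strip(),
                name=name,
                atoms=res_atoms,
                kind=kind,
            )
        )
    if len(residues) < 2:
        raise StructureError(f"no usable residues left after filtering {path}")
    return Structure(
        id=structure_id or path.stem, residues=residues, source=str(path)
    )


def _residue_slices(atoms: bst.AtomArray) -> tuple[np.ndarray, np.ndarray]:
    starts = bst.get_residue_starts(atoms)
    stops = np.append(starts[1:], len(atoms))
    return starts, stops


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a :class:`Structure` back out as a PDB file."""
    n_atoms = sum(len(r.atoms) for r in structure.residues)
    arr = bst.AtomArray(n_atoms)
    arr.add_annotation("occupancy", float)
    arr.add_annotation("b_factor", float)
    k = 0
    for res in structure.residues:
        for atom in res.atoms:
            arr.chain_id[k] = res.chain_id
            arr.res_id[k] = res.number
            arr.ins_code[k] = res.icode
            arr.res_name[k] = res.name
            arr.atom_name[k] = atom.name
            arr.element[k] = atom.element
            arr.coord[k] = atom.coord
            arr.hetero[k] = res.kind == "other"
            arr.occupancy[k] = atom.occupancy if atom.occupancy is not None else 1.0
            arr.b_factor[k] = atom.bfactor if atom.bfactor is not None else 0.0
            k += 1
    pdb_file = bpdb.PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(str(path))


def selection_to_json(residues: Sequence[Residue]) -> str:
    """Export a residue selection as a JSON list of identity records."""
    records = [
        {"chain": r.chain_id, "number": r.number, "icode": r.icode, "name": r.name}
        for r in residues
    ]
    return json.dumps(records, indent=2)


def selection_to_text(residues: Sequence[Residue]) -> str:
    """Flat one-line selection string, e.g. ``A:12 A:13 A:20A``."""
    return " ".join(r.label for r in residues)
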