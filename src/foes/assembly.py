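"""Combine retained fragment poses into candidate hit molecules.

Fragments that docked into a common coordinate frame are fused in the
simplest way possible: a direct bond, or a bridge of one or two sp3 methylene
carbons placed by linear interpolation between the two attachment atoms. The
Bcl-style strategy first builds two-fragment cores from anchor poses and then
grows them by adding one to three further fragments. Hits are raw: no
minimization, no stereo assignment; steric clashes are counted and reported,
not fatal.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from rdkit import Chem

from .docking import FragmentPose

logger = logging.getLogger(__name__)

CLASH_DISTANCE = 2.0  # A, heavy-atom pairs from different fragments


class AssemblyError(ValueError):
    pass


@dataclass(frozen=True)
class AttachmentSite:
    """A hydrogen-bearing heavy atom where a new bond can be formed."""

    atom_index: int
    n_hydrogens: int
    direction: np.ndarray  # outward unit vector

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(d)
        if not np.isclose(norm, 1.0, atol=1e-6):
            raise AssemblyError("site direction must be a unit vector")
        object.__setattr__(self, "direction", d)


@dataclass(frozen=True)
class LinkerSpec:
    """A 0/1/2-methylene bridge with its geometric feasibility window."""

    n_methylenes: int
    distance_min: float
    distance_max: float
    max_angle_deg: float = 45.0
    ideal_distance: float | None = None

    def __post_init__(self):
        if self.n_methylenes not in (0, 1, 2):
            raise AssemblyError("n_methylenes must be 0, 1, or 2")
        if not self.distance_min < self.distance_max:
            raise AssemblyError("need distance_min < distance_max")
        if self.ideal_distance is None:
            object.__setattr__(
                self, "ideal_distance", 0.5 * (self.distance_min + self.distance_max)
            )

    def feasible_distance(self, d: float) -> bool:
        return self.distance_min <= d <= self.distance_max


#: Default linker menu: windows centered near ideal C-C chain geometry
#: (1.54 A per bond, tetrahedral angles).
DEFAULT_LINKERS = (
    LinkerSpec(0, 0.8, 2.2),
    LinkerSpec(1, 2.0, 3.2),
    LinkerSpec(2, 3.0, 4.6),
)


@dataclass
class CandidateHit:
    """An assembled multi-fragment molecule with provenance."""

    mol: Chem.Mol  # carries one conformer
    fragment_ids: tuple
    window_ids: tuple
    linker_methylenes: tuple  # one entry per join, in assembly order
    fragment_heavy_atoms: int  # sum over source fragments
    clash_count: int = 0
    valid: bool = True
    score: float | None = None  # filled by the final rescoring stage

    @property
    def smiles(self) -> str:
        return Chem.MolToSmiles(Chem.Mol(self.mol))

    @property
    def n_fragments(self) -> int:
        return len(self.fragment_ids)

    @property
    def heavy_atom_count(self) -> int:
        return self.mol.GetNumHeavyAtoms()

    @property
    def coords(self) -> np.ndarray:
        return np.asarray(self.mol.GetConformer().GetPositions(), dtype=float)


def attachment_sites(obj) -> list[AttachmentSite]:
    """Sites of a pose or hit: one per hydrogen-bearing heavy atom.

    The outward direction points from the heavy atom away from the molecule's
    centroid (hydrogens are implicit throughout). Ordered by atom index.
    """
    mol = obj.mol if hasattr(obj, "mol") else obj
    coords = np.asarray(mol.GetConformer().GetPositions(), dtype=float)
    centroid = coords.mean(axis=0)
    sites = []
    for atom in mol.GetAtoms():
        n_h = atom.GetTotalNumHs()
        if n_h < 1:
            continue
        vec = coords[atom.GetIdx()] - centroid
        norm = np.linalg.norm(vec)
        direction = vec / norm if norm > 1e-6 else np.array([1.0, 0.0, 0.0])
        sites.append(
            AttachmentSite(
                atom_index=atom.GetIdx(), n_hydrogens=n_h, direction=direction
            )
        )
    return sites


def _angle_ok(direction: np.ndarray, bond_vec: np.ndarray, max_deg: float) -> bool:
    norm = np.linalg.norm(bond_vec)
    if norm < 1e-9:
        return False
    cosang = float(np.clip(direction @ (bond_vec / norm), -1.0, 1.0))
    return math.degrees(math.acos(cosang)) <= max_deg


def _consume_hydrogen(atom: Chem.Atom) -> None:
    if atom.GetNumExplicitHs() > 0:
        atom.SetNumExplicitHs(atom.GetNumExplicitHs() - 1)
    # else: implicit H count re-derives from valence after sanitization


def _origins(mol: Chem.Mol, default: str) -> list[str]:
    out = []
    for atom in mol.GetAtoms():
        out.append(
            atom.GetProp("frag_origin") if atom.HasProp("frag_origin") else default
        )
    return out


def count_clashes(mol: Chem.Mol, origins: list[str] | None = None) -> int:
    """Heavy-atom pairs from different source fragments closer than 2 A.

    Directly bonded pairs (the deliberately created junctions) are excluded.
    """
    if origins is None:
        origins = _origins(mol, "0")
    coords = np.asarray(mol.GetConformer().GetPositions(), dtype=float)
    if len(coords) < 2:
        return 0
    dist = squareform(pdist(coords))
    clashes = 0
    for i in range(len(coords)):
        for j in range(i + 1, len(coords)):
            if origins[i] == origins[j]:
                continue
            if mol.GetBondBetweenAtoms(i, j) is not None:
                continue
            if dist[i, j] < CLASH_DISTANCE:
                clashes += 1
    return clashes


def _tag_origin(mol: Chem.Mol, tag: str) -> Chem.Mol:
    mol = Chem.Mol(mol)
    for atom in mol.GetAtoms():
        if not atom.HasProp("frag_origin"):
            atom.SetProp("frag_origin", tag)
    return mol


def _join_mols(
    mol_a: Chem.Mol,
    mol_b: Chem.Mol,
    site_a: AttachmentSite,
    site_b: AttachmentSite,
    linker: LinkerSpec,
) -> Chem.Mol | None:
    """Fuse two placed molecules through the given sites and linker.

    Returns the sanitized combined molecule or None if sanitization fails.
    """
    combo = Chem.RWMol(Chem.CombineMols(mol_a, mol_b))
    offset = mol_a.GetNumAtoms()
    ia, ib = site_a.atom_index, site_b.atom_index + offset
    _consume_hydrogen(combo.GetAtomWithIdx(ia))
    _consume_hydrogen(combo.GetAtomWithIdx(ib))

    conf = combo.GetConformer()
    pa = np.array(conf.GetAtomPosition(ia))
    pb = np.array(conf.GetAtomPosition(ib))
    chain = [ia]
    for k in range(1, linker.n_methylenes + 1):
        carbon = Chem.Atom(6)
        carbon.SetProp("frag_origin", "linker")
        new_idx = combo.AddAtom(carbon)
        pos = pa + (k / (linker.n_methylenes + 1)) * (pb - pa)
        conf.SetAtomPosition(new_idx, pos.tolist())
        chain.append(new_idx)
    chain.append(ib)
    for u, v in zip(chain, chain[1:]):
        combo.AddBond(u, v, Chem.BondType.SINGLE)

    mol = combo.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # pragma: no cover - defensive
        logger.debug("join rejected at sanitization: %s", exc)
        return None
    return mol


def _as_joinable(obj):
    """(tagged mol, fragment_ids, window_ids, linker_ns, fragment_heavy)."""
    if isinstance(obj, CandidateHit):
        return (
            Chem.Mol(obj.mol),
            obj.fragment_ids,
            obj.window_ids,
            obj.linker_methylenes,
            obj.fragment_heavy_atoms,
        )
    if isinstance(obj, FragmentPose):
        mol = _tag_origin(obj.mol, f"{obj.fragment_id}@{obj.window_id}")
        return (
            mol,
            (obj.fragment_id,),
            (obj.window_id,),
            (),
            mol.GetNumHeavyAtoms(),
        )
    raise AssemblyError(f"cannot join object of type {type(obj).__name__}")


def join_pair(
    pose_a, pose_b, linkers: tuple[LinkerSpec, ...] = DEFAULT_LINKERS
) -> list[CandidateHit]:
    """All feasible joinings of two placed fragments (or hit + fragment).

    For every attachment-site pair and linker whose distance window contains
    the inter-site distance and whose direction/angle test passes, one hydrogen
    is removed per site, the methylene chain (if any) is interpolated along
    the inter-site vector, and the pieces are bonded. Hits are sorted by
    (clash count, |distance - ideal|).
    """
    mol_a, frags_a, wins_a, links_a, heavy_a = _as_joinable(pose_a)
    mol_b, frags_b, wins_b, links_b, heavy_b = _as_joinable(pose_b)
    coords_a = np.asarray(mol_a.GetConformer().GetPositions(), dtype=float)
    coords_b = np.asarray(mol_b.GetConformer().GetPositions(), dtype=float)

    scored: list[tuple[int, float, CandidateHit]] = []
    for site_a in attachment_sites(mol_a):
        for site_b in attachment_sites(mol_b):
            pa = coords_a[site_a.atom_index]
            pb = coords_b[site_b.atom_index]
            vec = pb - pa
            d = float(np.linalg.norm(vec))
            for linker in linkers:
                if not linker.feasible_distance(d):
                    continue
                if not _angle_ok(site_a.direction, vec, linker.max_angle_deg):
                    continue
                if not _angle_ok(site_b.direction, -vec, linker.max_angle_deg):
                    continue
                mol = _join_mols(mol_a, mol_b, site_a, site_b, linker)
                if mol is None:
                    continue
                clashes = count_clashes(mol)
                hit = CandidateHit(
                    mol=mol,
                    fragment_ids=frags_a + frags_b,
                    window_ids=wins_a + wins_b,
                    linker_methylenes=links_a + links_b + (linker.n_methylenes,),
                    fragment_heavy_atoms=heavy_a + heavy_b,
                    clash_count=clashes,
                )
                strain = abs(d - linker.ideal_distance)
                scored.append((clashes, strain, hit))
    scored.sort(key=lambda t: (t[0], t[1]))
    return [hit for _, _, hit in scored]


def build_cores(
    anchor_poses: list[FragmentPose],
    linkers: tuple[LinkerSpec, ...] = DEFAULT_LINKERS,
) -> list[CandidateHit]:
    """All pairwise joins among anchor poses, deduplicated by canonical graph."""
    if len(anchor_poses) < 2:
        raise AssemblyError("core building needs at least 2 anchor poses")
    cores: list[CandidateHit] = []
    seen: set[str] = set()
    for pose_a, pose_b in itertools.combinations(anchor_poses, 2):
        for hit in join_pair(pose_a, pose_b, linkers):
            key = hit.smiles
            if key in seen:
                continue
            seen.add(key)
            cores.append(hit)
    return cores


def grow_core(
    core: CandidateHit,
    poses: list[FragmentPose],
    linkers: tuple[LinkerSpec, ...] = DEFAULT_LINKERS,
    max_additions: int = 3,
) -> list[CandidateHit]:
    """Breadth-first growth of a core by 1..max_additions extra fragments.

    At each step every remaining pose (one use per pose object) is joined to
    the current hit through the normal join semantics; all intermediate hits
    are emitted, provenance recording the addition order.
    """
    if not 1 <= max_additions <= 3:
        raise AssemblyError("max_additions must be between 1 and 3")
    results: list[CandidateHit] = []
    frontier: list[tuple[CandidateHit, frozenset]] = [(core, frozenset())]
    for _ in range(max_additions):
        next_frontier = []
        for hit, used in frontier:
            for k, pose in enumerate(poses):
                if k in used:
                    continue
                for grown in join_pair(hit, pose, linkers):
                    results.append(grown)
                    next_frontier.append((grown, used | {k}))
        frontier = next_frontier
        if not frontier:
            break
    return results


@dataclass
class ValidityReport:
    valid: bool
    connected: bool
    valence_ok: bool
    clash_count: int
    problems: list[str] = field(default_factory=list)


def validate_hit(hit: CandidateHit) -> ValidityReport:
    """Check valence compliance, connectivity, and recount clashes."""
    problems: list[str] = []
    mol = Chem.Mol(hit.mol)
    valence_ok = True
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:
        valence_ok = False
        problems.append(str(exc))
    connected = len(Chem.GetMolFrags(hit.mol)) == 1
    if not connected:
        problems.append("molecular graph is disconnected")
    clash_count = count_clashes(hit.mol)
    valid = valence_ok and connected
    hit.valid = valid
    hit.clash_count = clash_count
    return ValidityReport(
        valid=valid,
        connected=connected,
        valence_ok=valence_ok,
        clash_count=clash_count,
        problems=problems,
    )


def write_hits_sdf(hits: list[CandidateHit], path) -> None:
    """Write hits as 3D SDF with provenance in SD tags."""
    writer = Chem.SDWriter(str(path))
    try:
        for i, hit in enumerate(hits, start=1):
            mol = Chem.Mol(hit.mol)
            mol.SetProp("_Name", f"hit{i}")
            mol.SetProp("fragment_ids", ",".join(hit.fragment_ids))
            mol.SetProp("window_ids", ",".join(hit.window_ids))
            mol.SetProp(
                "linker_methylenes", ",".join(map(str, hit.linker_methylenes))
            )
            mol.SetProp("clash_count", str(hit.clash_count))
            if hit.score is not None:
                mol.SetProp("score", repr(hit.score))
            writer.write(mol)
    finally:
        writer.close()
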