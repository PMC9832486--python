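"""Pluggable fragment-placement stage.

Provides a deterministic naive rigid-body sampler with a softened
steric/electrostatic/H-bond scorer for desk-scale runs, an SDF importer for
poses docked by external engines, and the retention/filtering policies
(generate -> keep -> best pose; score cutoff or percentile; required
contacts). The built-in scorer and an external engine's scores live on
different scales: absolute cutoffs (e.g. -3.5) are meaningful only for
imported scores, while built-in scores are filtered by percentile rank
within their own sampling distribution.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from rdkit import Chem
from rdkit.Chem import AllChem

from .energetics import COULOMB_CONSTANT, DEFAULT_LJ, FALLBACK_LJ, EnergyParams
from .structure_io import Structure
from .windows import DockingBox

logger = logging.getLogger(__name__)

HBOND_DISTANCE = 3.5  # A, donor/acceptor heavy-atom pair
HBOND_WEIGHT = -1.0  # kcal/mol-ish bonus per donor-acceptor contact
STERIC_FLOOR = 1.2  # A, distance clamp that softens the LJ core


class LibraryError(ValueError):
    """No valid fragment records could be read."""


class ImportError_(ValueError):
    """No usable pose records could be read."""


@dataclass
class Fragment:
    """A small molecule as a heavy-atom RDKit graph plus canonical SMILES."""

    id: str
    mol: Chem.Mol
    smiles: str

    @classmethod
    def from_smiles(cls, smiles: str, frag_id: str) -> "Fragment":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise LibraryError(f"cannot parse SMILES {smiles!r}")
        if len(Chem.GetMolFrags(mol)) != 1:
            raise LibraryError(f"fragment {frag_id} is not a connected graph")
        return cls(id=frag_id, mol=mol, smiles=Chem.MolToSmiles(mol))

    @property
    def heavy_atom_count(self) -> int:
        return self.mol.GetNumHeavyAtoms()

    def embed(self, seed: int = 0) -> Chem.Mol:
        """Single seeded ETKDG conformer, heavy atoms only."""
        molh = Chem.AddHs(Chem.Mol(self.mol))
        params = AllChem.ETKDGv3()
        params.randomSeed = int(seed) & 0x7FFFFFFF
        if AllChem.EmbedMolecule(molh, params) != 0:
            # fall back to unconstrained random coords for pathological cases
            params.useRandomCoords = True
            if AllChem.EmbedMolecule(molh, params) != 0:
                raise LibraryError(f"cannot embed fragment {self.id}")
        return Chem.RemoveHs(molh)


@dataclass
class FragmentPose:
    """A placed fragment: heavy-atom coordinates plus a score (lower=better)."""

    fragment_id: str
    mol: Chem.Mol  # carries one conformer with the pose coordinates
    score: float
    window_id: str = ""
    engine: str = "builtin"  # builtin | imported
    score_percentile: float | None = None  # rank within the sampling run

    def __post_init__(self):
        if self.mol.GetNumConformers() != 1:
            raise ValueError("pose molecule must carry exactly one conformer")
        if not np.isfinite(self.score):
            raise ValueError("pose score must be finite")

    @property
    def coords(self) -> np.ndarray:
        return np.asarray(self.mol.GetConformer().GetPositions(), dtype=float)


@dataclass
class DockingPolicy:
    """Pose generation/retention policy."""

    n_generated: int = 10_000
    n_kept_intermediate: int = 1_000
    n_final_per_fragment: int = 1
    score_cutoff: float | None = None
    percentile_cutoff: float | None = 20.0  # best 20% of builtin scores
    required_contact_residues: frozenset | None = None
    contact_distance: float = 4.5
    seed: int = 0

    def __post_init__(self):
        if not (
            1 <= self.n_final_per_fragment
            <= self.n_kept_intermediate
            <= self.n_generated
        ):
            raise ValueError("need n_final <= n_kept <= n_generated, all >= 1")


def load_fragment_library(path: str | Path) -> list[Fragment]:
    """Read fragments from a SMILES (.smi/.smiles/.txt) or SDF file.

    Invalid records are skipped with a logged reason; duplicate ids are
    suffixed deterministically (``_2``, ``_3``, ...).
    """
    path = Path(path)
    fragments: list[Fragment] = []
    seen: dict[str, int] = {}

    def _add(mol: Chem.Mol | None, raw_id: str, record: str):
        if mol is None:
            logger.warning("skipping unparsable fragment record %s", record)
            return
        try:
            frag = Fragment.from_smiles(Chem.MolToSmiles(mol), frag_id=raw_id)
        except LibraryError as exc:
            logger.warning("skipping fragment %s: %s", raw_id, exc)
            return
        seen[raw_id] = seen.get(raw_id, 0) + 1
        if seen[raw_id] > 1:
            frag.id = f"{raw_id}_{seen[raw_id]}"
        fragments.append(frag)

    if path.suffix.lower() == ".sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
        for i, mol in enumerate(supplier):
            raw_id = (
                mol.GetProp("_Name")
                if mol is not None and mol.HasProp("_Name") and mol.GetProp("_Name")
                else f"frag{i + 1}"
            )
            _add(mol, raw_id, f"#{i + 1}")
    else:
        with open(path) as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                raw_id = parts[1] if len(parts) > 1 else f"frag{i + 1}"
                _add(Chem.MolFromSmiles(parts[0]), raw_id, f"line {i + 1}")
    if not fragments:
        raise LibraryError(f"no valid fragment records in {path}")
    return fragments


def _run_seed(seed: int, fragment_id: str, window_id: str) -> int:
    """Stable per-(fragment, window) seed so results are order-independent."""
    return zlib.crc32(f"{seed}:{fragment_id}:{window_id}".encode()) & 0x7FFFFFFF


def _protein_context(
    structure: Structure, box: DockingBox, params: EnergyParams, margin: float = 12.0
):
    """Heavy atoms (coords, charges, LJ) of residues near the docking box."""
    coords, charges, eps, sigma, is_polar = [], [], [], [], []
    for res in structure.residues:
        for atom in res.atoms:
            if atom.element == "H":
                continue
            coords.append(atom.coord)
            charges.append(
                params.charges.get((res.name, atom.name), params.default_charge)
            )
            e, s = params.lj.get(atom.element, FALLBACK_LJ)
            eps.append(e)
            sigma.append(s)
            is_polar.append(atom.element in ("N", "O"))
    coords = np.asarray(coords)
    near = np.all(
        np.abs(coords - box.center) <= box.half_extents + margin, axis=1
    )
    return (
        coords[near],
        np.asarray(charges)[near],
        np.asarray(eps)[near],
        np.asarray(sigma)[near],
        np.asarray(is_polar)[near],
    )


def _fragment_arrays(mol: Chem.Mol, params: EnergyParams):
    """Gasteiger charges, LJ parameters, and polarity flags per heavy atom."""
    molc = Chem.Mol(mol)
    AllChem.ComputeGasteigerCharges(molc)
    charges, eps, sigma, is_polar = [], [], [], []
    for atom in molc.GetAtoms():
        q = atom.GetDoubleProp("_GasteigerCharge")
        charges.append(q if np.isfinite(q) else 0.0)
        e, s = params.lj.get(atom.GetSymbol(), FALLBACK_LJ)
        eps.append(e)
        sigma.append(s)
        is_polar.append(atom.GetSymbol() in ("N", "O"))
    return (
        np.asarray(charges),
        np.asarray(eps),
        np.asarray(sigma),
        np.asarray(is_polar),
    )


def score_coords(
    frag_coords: np.ndarray,
    frag_arrays,
    prot_context,
    params: EnergyParams,
) -> float:
    """Built-in pose score: softened LJ + screened Coulomb + H-bond bonus."""
    q_f, eps_f, sig_f, pol_f = frag_arrays
    p_coords, q_p, eps_p, sig_p, pol_p = prot_context
    if len(p_coords) == 0:
        return 0.0
    r = cdist(np.atleast_2d(frag_coords), p_coords)
    r_soft = np.maximum(r, STERIC_FLOOR)
    eps = np.sqrt(np.outer(eps_f, eps_p))
    sigma = 0.5 * (sig_f[:, None] + sig_p[None, :])
    sr6 = (sigma / r_soft) ** 6
    lj = np.sum(4.0 * eps * (sr6 * sr6 - sr6) * (r <= params.lj_cutoff))
    coulomb = np.sum(
        COULOMB_CONSTANT
        * np.outer(q_f, q_p)
        / (params.dielectric_slope * r_soft * r_soft)
    )
    hbonds = np.sum(np.outer(pol_f, pol_p) & (r <= HBOND_DISTANCE))
    return float(lj + coulomb + HBOND_WEIGHT * hbonds)


def score_pose_mol(
    mol: Chem.Mol,
    box: DockingBox,
    structure: Structure,
    params: EnergyParams | None = None,
) -> float:
    """Score an already-placed molecule's conformer with the built-in function."""
    if params is None:
        params = EnergyParams()
    context = _protein_context(structure, box, params)
    arrays = _fragment_arrays(mol, params)
    coords = np.asarray(mol.GetConformer().GetPositions(), dtype=float)
    return score_coords(coords, arrays, context, params)


def dock_fragment(
    fragment: Fragment,
    box: DockingBox,
    structure: Structure,
    policy: DockingPolicy | None = None,
    window_id: str = "",
    params: EnergyParams | None = None,
) -> list[FragmentPose]:
    """Naive rigid-body docking of one fragment into one box.

    Samples ``n_generated`` placements (uniform translation of the fragment
    centroid within the box, uniform random rotation), scores each, keeps the
    best ``n_kept_intermediate`` and returns the best ``n_final_per_fragment``
    poses. Deterministic for a fixed (seed, fragment, window) triple and
    independent of call order across fragments/windows.
    """
    if policy is None:
        policy = DockingPolicy()
    if params is None:
        params = EnergyParams()
    run_seed = _run_seed(policy.seed, fragment.id, window_id)
    rng = np.random.default_rng(run_seed)

    conf_mol = fragment.embed(seed=run_seed)
    base = np.asarray(conf_mol.GetConformer().GetPositions(), dtype=float)
    base = base - base.mean(axis=0)

    context = _protein_context(structure, box, params)
    if len(context[0]) == 0:
        logger.warning(
            "docking box for window %r has no protein atom nearby; "
            "poses will score 0",
            window_id,
        )
    arrays = _fragment_arrays(conf_mol, params)

    n = policy.n_generated
    quats = rng.normal(size=(n, 4))
    quats /= np.linalg.norm(quats, axis=1, keepdims=True)
    rotations = Rotation.from_quat(quats)  # uniform over SO(3)
    translations = box.center + rng.uniform(-1.0, 1.0, size=(n, 3)) * box.half_extents

    scores = np.empty(n)
    placed = np.empty((n,) + base.shape)
    chunk = 512
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        for k in range(start, stop):
            coords = rotations[k].apply(base) + translations[k]
            placed[k] = coords
            scores[k] = score_coords(coords, arrays, context, params)

    order = np.argsort(scores, kind="stable")
    kept = order[: policy.n_kept_intermediate]
    final = kept[: policy.n_final_per_fragment]

    poses = []
    for k in final:
        mol = Chem.Mol(conf_mol)
        conf = mol.GetConformer()
        for a in range(mol.GetNumAtoms()):
            conf.SetAtomPosition(a, placed[k][a].tolist())
        percentile = 100.0 * (np.searchsorted(scores[order], scores[k], "right")) / n
        poses.append(
            FragmentPose(
                fragment_id=fragment.id,
                mol=mol,
                score=float(scores[k]),
                window_id=window_id,
                engine="builtin",
                score_percentile=float(percentile),
            )
        )
    return poses


def import_poses(
    path: str | Path, score_tag: str = "score", window_id: str = ""
) -> list[FragmentPose]:
    """Read externally docked poses from an SDF file carrying a score tag.

    Records missing coordinates or the score tag are skipped with a warning.
    """
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
    poses = []
    skipped = 0
    for i, mol in enumerate(supplier):
        if mol is None or mol.GetNumConformers() == 0:
            skipped += 1
            logger.warning("pose record %d unreadable; skipped", i + 1)
            continue
        if not mol.HasProp(score_tag):
            skipped += 1
            logger.warning("pose record %d missing tag %r; skipped", i + 1, score_tag)
            continue
        try:
            score = float(mol.GetProp(score_tag))
        except ValueError:
            skipped += 1
            logger.warning("pose record %d has non-numeric score; skipped", i + 1)
            continue
        frag_id = (
            mol.GetProp("_Name")
            if mol.HasProp("_Name") and mol.GetProp("_Name")
            else f"imported{i + 1}"
        )
        poses.append(
            FragmentPose(
                fragment_id=frag_id,
                mol=mol,
                score=score,
                window_id=window_id,
                engine="imported",
            )
        )
    if not poses:
        raise ImportError_(f"no usable pose records in {path} ({skipped} skipped)")
    return poses


def write_poses(poses: list[FragmentPose], path: str | Path, score_tag: str = "score"):
    """Write poses to SDF with the score as an SD tag."""
    writer = Chem.SDWriter(str(path))
    try:
        for pose in poses:
            mol = Chem.Mol(pose.mol)
            mol.SetProp("_Name", pose.fragment_id)
            mol.SetProp(score_tag, repr(pose.score))
            mol.SetProp("window_id", pose.window_id)
            mol.SetProp("engine", pose.engine)
            writer.write(mol)
    finally:
        writer.close()


def filter_poses(
    poses: list[FragmentPose],
    policy: DockingPolicy,
    structure: Structure | None = None,
) -> list[FragmentPose]:
    """Apply the retention filters; idempotent.

    Imported poses are kept iff score <= ``score_cutoff`` (when set); builtin
    poses iff their stored sampling percentile <= ``percentile_cutoff`` (when
    set; the absolute cutoff does not transfer to the builtin score scale).
    When ``required_contact_residues`` is set, a pose also needs at least one
    heavy atom within ``contact_distance`` of any heavy atom of a required
    residue.
    """
    contact_coords = None
    if policy.required_contact_residues and structure is not None:
        wanted = set(policy.required_contact_residues)
        pts = [
            a.coord
            for r in structure.residues
            if r.label in wanted
            for a in r.atoms
            if a.element != "H"
        ]
        contact_coords = np.asarray(pts) if pts else None

    kept = []
    for pose in poses:
        if pose.engine == "imported":
            if policy.score_cutoff is not None and pose.score > policy.score_cutoff:
                continue
        else:
            if (
                policy.percentile_cutoff is not None
                and pose.score_percentile is not None
                and pose.score_percentile > policy.percentile_cutoff
            ):
                continue
        if contact_coords is not None:
            dmin = cdist(pose.coords, contact_coords).min()
            if dmin > policy.contact_distance:
                continue
        kept.append(pose)
    return kept
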