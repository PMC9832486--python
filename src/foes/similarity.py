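"""Atom-pair fingerprints and Tanimoto similarity ranking.

Every unordered heavy-atom pair becomes a (type_i, type_j, distance) feature;
atom types combine element, heavy-atom degree, an aromatic/pi flag, and
formal charge. Distances are either topological (shortest bond path) or
geometric (binned Cartesian distance). Features are hashed to 64-bit ids and
stored sparsely, so collisions are negligible at fragment and hit sizes.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from rdkit import Chem

logger = logging.getLogger(__name__)


class FingerprintError(ValueError):
    pass


@dataclass(frozen=True)
class AtomPairParams:
    """Typing scheme and distance handling for atom-pair fingerprints."""

    distance_mode: str = "topological"  # topological | geometric
    bin_width: float = 1.0  # A, geometric mode
    max_distance: float = 20.0  # A, geometric cap
    hash_bits: int = 64
    count_based: bool = False

    def __post_init__(self):
        if self.distance_mode not in ("topological", "geometric"):
            raise FingerprintError("distance_mode must be topological or geometric")
        if self.bin_width <= 0:
            raise FingerprintError("bin_width must be positive")


@dataclass
class Fingerprint:
    """Sparse multiset of hashed atom-pair features."""

    features: Counter
    params: AtomPairParams

    @property
    def feature_set(self) -> frozenset:
        return frozenset(self.features)

    def __len__(self) -> int:
        return len(self.features)


def atom_type(atom: Chem.Atom) -> tuple:
    """(element, heavy-degree, pi flag, formal charge) atom type.

    The pi flag is set for aromatic atoms or atoms in any multiple bond,
    approximating a hybridization-aware typing scheme.
    """
    pi = atom.GetIsAromatic() or any(
        b.GetBondType() in (Chem.BondType.DOUBLE, Chem.BondType.TRIPLE)
        for b in atom.GetBonds()
    )
    return (atom.GetSymbol(), atom.GetDegree(), pi, atom.GetFormalCharge())


def _hash_feature(feature: tuple, bits: int) -> int:
    digest = hashlib.blake2b(repr(feature).encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") % (1 << bits)


def atom_pair_fingerprint(
    mol: Chem.Mol, params: AtomPairParams | None = None
) -> Fingerprint:
    """Atom-pair fingerprint over all unordered heavy-atom pairs.

    Each pair contributes (min(type), max(type), distance bucket). Invariant
    to atom input ordering. Geometric mode needs a conformer.
    """
    if params is None:
        params = AtomPairParams()
    heavy = [a for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    if params.distance_mode == "geometric":
        if mol.GetNumConformers() == 0:
            raise FingerprintError("geometric mode requires 3D coordinates")
        coords = np.asarray(mol.GetConformer().GetPositions(), dtype=float)
        dist = squareform(pdist(coords)) if len(coords) > 1 else np.zeros((1, 1))
    else:
        dist = Chem.GetDistanceMatrix(mol)

    features: Counter = Counter()
    for a_pos, atom_a in enumerate(heavy):
        for atom_b in heavy[a_pos + 1 :]:
            i, j = atom_a.GetIdx(), atom_b.GetIdx()
            if params.distance_mode == "geometric":
                d = min(dist[i, j], params.max_distance)
                bucket = int(d / params.bin_width)
            else:
                bucket = int(dist[i, j])
            ta, tb = sorted([atom_type(atom_a), atom_type(atom_b)])
            features[_hash_feature((ta, tb, bucket), params.hash_bits)] += 1
    return Fingerprint(features=features, params=params)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |A & B| / |A | B| over the feature sets.

    Binary by default; the count-based variant uses min/max of counts. Two
    empty fingerprints score 0 with a warning.
    """
    if a.params != b.params:
        raise FingerprintError("fingerprints were built with different parameters")
    if not a.features and not b.features:
        warnings.warn("Tanimoto of two empty fingerprints defined as 0", stacklevel=2)
        return 0.0
    if a.params.count_based:
        keys = set(a.features) | set(b.features)
        inter = sum(min(a.features[k], b.features[k]) for k in keys)
        union = sum(max(a.features[k], b.features[k]) for k in keys)
    else:
        sa, sb = a.feature_set, b.feature_set
        inter = len(sa & sb)
        union = len(sa | sb)
    return inter / union if union else 0.0


@dataclass
class SimilarityRecord:
    hit_id: str
    reference_id: str
    tanimoto: float
    docking_score: float | None
    rank: int

    def __post_init__(self):
        if not 0.0 <= self.tanimoto <= 1.0:
            raise FingerprintError("tanimoto must lie in [0, 1]")


def load_references(path: str | Path) -> list[tuple[str, Chem.Mol]]:
    """Read reference ligands from a SMILES or SDF file."""
    path = Path(path)
    refs: list[tuple[str, Chem.Mol]] = []
    if path.suffix.lower() == ".sdf":
        for i, mol in enumerate(Chem.SDMolSupplier(str(path), removeHs=True)):
            if mol is None:
                logger.warning("skipping unreadable reference record %d", i + 1)
                continue
            name = (
                mol.GetProp("_Name")
                if mol.HasProp("_Name") and mol.GetProp("_Name")
                else f"ref{i + 1}"
            )
            refs.append((name, mol))
    else:
        with open(path) as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                mol = Chem.MolFromSmiles(parts[0])
                if mol is None:
                    logger.warning("skipping unparsable reference line %d", i + 1)
                    continue
                name = parts[1] if len(parts) > 1 else f"ref{i + 1}"
                refs.append((name, mol))
    if not refs:
        raise FingerprintError(f"no usable reference molecules in {path}")
    return refs


def similarity_table(
    hits,
    references: list[tuple[str, Chem.Mol]],
    params: AtomPairParams | None = None,
    top_k: int = 30,
) -> tuple[list[SimilarityRecord], pd.DataFrame]:
    """Rank hits by docking score and annotate the best Tanimoto per hit.

    Each hit is compared against every reference; the maximum Tanimoto (and
    the reference achieving it) is recorded. The table is sorted by docking
    score ascending (best first; hits without scores sort last by similarity
    descending). Returns the top_k records plus the full table.
    """
    if params is None:
        params = AtomPairParams()
    if not references:
        raise FingerprintError("need at least one reference molecule")
    ref_fps = [(name, atom_pair_fingerprint(mol, params)) for name, mol in references]

    rows = []
    for i, hit in enumerate(hits, start=1):
        mol = hit.mol if hasattr(hit, "mol") else hit
        fp = atom_pair_fingerprint(mol, params)
        best_t, best_ref = -1.0, ref_fps[0][0]
        for name, ref_fp in ref_fps:
            t = tanimoto(fp, ref_fp)
            if t > best_t:
                best_t, best_ref = t, name
        score = getattr(hit, "score", None)
        rows.append(
            {
                "hit_id": f"hit{i}",
                "reference_id": best_ref,
                "tanimoto": best_t,
                "docking_score": score,
            }
        )
    frame = pd.DataFrame(
        rows, columns=["hit_id", "reference_id", "tanimoto", "docking_score"]
    )
    if frame.empty:
        frame["rank"] = []
        return [], frame
    has_score = frame["docking_score"].notna()
    frame = pd.concat(
        [
            frame[has_score].sort_values(
                ["docking_score", "tanimoto", "hit_id"],
                ascending=[True, False, True],
                kind="stable",
            ),
            frame[~has_score].sort_values(
                ["tanimoto", "hit_id"], ascending=[False, True], kind="stable"
            ),
        ]
    ).reset_index(drop=True)
    frame["rank"] = np.arange(1, len(frame) + 1)

    records = [
        SimilarityRecord(
            hit_id=row.hit_id,
            reference_id=row.reference_id,
            tanimoto=float(row.tanimoto),
            docking_score=None if pd.isna(row.docking_score) else float(row.docking_score),
            rank=int(row.rank),
        )
        for row in frame.head(top_k).itertuples()
    ]
    return records, frame
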