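"""Matrix of low coupling energy (MLCE) interface prediction.

The residue-pair interaction matrix M is rank-1 approximated through its most
negative eigenpair, masked elementwise by the residue contact matrix, and the
weakest surviving couplings are selected: surface residues whose mutual
interactions are energetically non-optimized are the predicted
protein-protein interaction regions. The selected residues are merged into
spatially contiguous patches, and an ensemble of input structures is combined
into a consensus region by per-residue frequency.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial.distance import squareform, pdist

from .energetics import InteractionMatrix
from .structure_io import Structure

logger = logging.getLogger(__name__)

CONTACT_CUTOFF = 6.5  # A, between representative atoms (C-beta / C1)


class DegenerateSpectrumError(ValueError):
    """No negative leading eigenvalue: the matrix has no stabilizing mode."""


class AlignmentError(ValueError):
    """Index maps or residue identity spaces do not match."""


class EmptySelectionError(ValueError):
    """The masked matrix has no non-zero couplings to rank."""


@dataclass
class SpectralDecomposition:
    """Full symmetric eigendecomposition, eigenvalues sorted ascending."""

    eigenvalues: np.ndarray  # lambda_1 (most negative) first
    eigenvectors: np.ndarray  # column k pairs with eigenvalues[k]
    labels: list[str]


@dataclass
class ApproxMatrix:
    """Rank-1 approximation lambda_1 * w^1 (w^1)^T of the interaction matrix."""

    values: np.ndarray
    labels: list[str]


@dataclass
class ContactMatrix:
    """Binary residue contact matrix at a representative-atom cutoff."""

    values: np.ndarray  # (N, N) of {0, 1}
    labels: list[str]
    cutoff: float = CONTACT_CUTOFF

    def __post_init__(self):
        v = np.asarray(self.values)
        if not np.array_equal(v, v.T) or np.any(np.diag(v) != 0):
            raise ValueError("contact matrix must be symmetric with zero diagonal")
        if not np.isin(v, (0, 1)).all():
            raise ValueError("contact matrix entries must be 0 or 1")
        self.values = v.astype(np.int8)


@dataclass
class MLCEMatrix:
    """Rank-1 energy approximation masked by the contact matrix."""

    values: np.ndarray
    labels: list[str]


@dataclass
class SelectionParams:
    """Thresholds controlling soft-pair selection, merging, and consensus."""

    soft_fraction: float = 0.15
    rank_by: str = "magnitude"  # magnitude | signed
    min_patch_size: int = 3
    burial_filter: bool = True
    burial_radius: float = 10.0
    burial_neighbor_threshold: int = 22
    consensus_min_frequency: float = 4.0 / 7.0

    def __post_init__(self):
        if not 0 < self.soft_fraction <= 1:
            raise ValueError("soft_fraction must be in (0, 1]")
        if self.rank_by not in ("magnitude", "signed"):
            raise ValueError("rank_by must be 'magnitude' or 'signed'")
        if self.min_patch_size < 1:
            raise ValueError("min_patch_size must be >= 1")


@dataclass
class Patch:
    """A contiguous set of selected surface residues (one predicted region)."""

    residues: frozenset  # residue labels
    centroid: np.ndarray

    @property
    def size(self) -> int:
        return len(self.residues)


@dataclass
class ConsensusRegion:
    """Residues predicted across a sufficient fraction of an ensemble."""

    residues: frozenset
    frequencies: dict  # label -> fraction of structures containing it

    @property
    def size(self) -> int:
        return len(self.residues)


def spectral_decompose(matrix: InteractionMatrix) -> SpectralDecomposition:
    """Full eigendecomposition of the symmetric interaction matrix."""
    if not np.all(np.isfinite(matrix.values)):
        raise ValueError("interaction matrix contains non-finite entries")
    eigenvalues, eigenvectors = np.linalg.eigh(matrix.values)
    return SpectralDecomposition(
        eigenvalues=eigenvalues, eigenvectors=eigenvectors, labels=list(matrix.labels)
    )


def rank1_approximation(dec: SpectralDecomposition) -> ApproxMatrix:
    """M~ = lambda_1 w^1 (w^1)^T from the most negative eigenpair.

    Invariant under the sign of w^1. Raises if the smallest eigenvalue is
    non-negative: without a stabilizing mode the method's premise fails.
    """
    lam = dec.eigenvalues[0]
    if lam >= 0:
        raise DegenerateSpectrumError(
            f"smallest eigenvalue {lam:.4g} is non-negative"
        )
    if len(dec.eigenvalues) > 1 and abs(dec.eigenvalues[1] - lam) < 1e-10:
        logger.warning(
            "smallest eigenvalue is (near-)degenerate; using the first "
            "eigenvector of the sorted decomposition"
        )
    w1 = dec.eigenvectors[:, 0]
    return ApproxMatrix(values=lam * np.outer(w1, w1), labels=list(dec.labels))


def contact_matrix(structure: Structure, cutoff: float = CONTACT_CUTOFF) -> ContactMatrix:
    """C_ij = 1 iff representative atoms of i and j are closer than ``cutoff``."""
    coords = structure.representative_coords()
    dist = squareform(pdist(coords))
    values = (dist < cutoff).astype(np.int8)
    np.fill_diagonal(values, 0)
    return ContactMatrix(values=values, labels=structure.labels(), cutoff=cutoff)


def mlce_matrix(approx: ApproxMatrix, contacts: ContactMatrix) -> MLCEMatrix:
    """Hadamard product of the rank-1 approximation and the contact mask."""
    if list(approx.labels) != list(contacts.labels):
        raise AlignmentError("approximation and contact matrix label maps differ")
    return MLCEMatrix(
        values=approx.values * contacts.values, labels=list(approx.labels)
    )


def select_soft_pairs(
    mlce: MLCEMatrix, params: SelectionParams | None = None
) -> list[tuple[int, int]]:
    """The ceil(soft_fraction * |P|) least energetic non-zero pairs (i < j).

    Pairs are ranked by |MLCE_ij| ascending (``rank_by="magnitude"``, the
    default: low coupling energy) or by signed value descending-stability
    (``rank_by="signed"``: least stabilizing first); ties break on (i, j)
    ascending for determinism.
    """
    if params is None:
        params = SelectionParams()
    iu, ju = np.triu_indices(mlce.values.shape[0], k=1)
    vals = mlce.values[iu, ju]
    nonzero = vals != 0.0
    if not np.any(nonzero):
        raise EmptySelectionError("MLCE matrix has no non-zero couplings")
    pairs = list(zip(iu[nonzero].tolist(), ju[nonzero].tolist(), vals[nonzero]))
    if params.rank_by == "magnitude":
        pairs.sort(key=lambda p: (abs(p[2]), p[0], p[1]))
    else:  # least stabilizing = largest signed value first
        pairs.sort(key=lambda p: (-p[2], p[0], p[1]))
    n_select = math.ceil(params.soft_fraction * len(pairs))
    return [(i, j) for i, j, _ in pairs[:n_select]]


def select_soft_residues(
    mlce: MLCEMatrix, params: SelectionParams | None = None
) -> tuple[set, list[tuple[int, int]]]:
    """Residue labels incident to the selected soft pairs, plus the pair list."""
    pairs = select_soft_pairs(mlce, params)
    labels = mlce.labels
    residues = {labels[i] for i, j in pairs} | {labels[j] for i, j in pairs}
    return residues, pairs


def buried_residues(
    structure: Structure, params: SelectionParams
) -> set:
    """Coordination-number burial proxy: a residue is buried iff more than
    ``burial_neighbor_threshold`` representative atoms lie within
    ``burial_radius``."""
    coords = structure.representative_coords()
    dist = squareform(pdist(coords))
    counts = np.sum((dist < params.burial_radius), axis=1) - 1  # exclude self
    labels = structure.labels()
    return {
        labels[i]
        for i in range(len(labels))
        if counts[i] > params.burial_neighbor_threshold
    }


def merge_patches(
    selected: set,
    contacts: ContactMatrix,
    structure: Structure,
    params: SelectionParams | None = None,
) -> list[Patch]:
    """Merge selected residues into contiguous patches.

    Patches are connected components of the contact graph restricted to the
    selected residues (after the optional burial filter); components smaller
    than ``min_patch_size`` are dropped. Sorted by size descending, ties by
    smallest matrix index.
    """
    if params is None:
        params = SelectionParams()
    labels = structure.labels()
    index_of = {lab: i for i, lab in enumerate(labels)}
    unknown = set(selected) - set(index_of)
    if unknown:
        raise AlignmentError(f"selected residues not in structure: {sorted(unknown)}")
    keep = set(selected)
    if params.burial_filter:
        keep -= buried_residues(structure, params)

    graph = nx.Graph()
    graph.add_nodes_from(keep)
    keep_idx = sorted(index_of[lab] for lab in keep)
    for a_pos, i in enumerate(keep_idx):
        for j in keep_idx[a_pos + 1 :]:
            if contacts.values[i, j]:
                graph.add_edge(labels[i], labels[j])

    rep_coords = structure.representative_coords()
    patches = []
    for component in nx.connected_components(graph):
        if len(component) < params.min_patch_size:
            continue
        idx = [index_of[lab] for lab in component]
        patches.append(
            Patch(residues=frozenset(component), centroid=rep_coords[idx].mean(axis=0))
        )
    patches.sort(key=lambda p: (-p.size, min(index_of[lab] for lab in p.residues)))
    return patches


def consensus_region(
    patch_sets: list[list[Patch]], params: SelectionParams | None = None
) -> ConsensusRegion:
    """Residue-frequency consensus over an ensemble of per-structure patches.

    A residue is kept iff it belongs to any patch in at least
    ``consensus_min_frequency`` of the input structures (default 4/7, the
    majority over a minimized structure plus six cluster representatives).
    """
    if params is None:
        params = SelectionParams()
    if not patch_sets:
        raise AlignmentError("need patches from at least one structure")
    n_structures = len(patch_sets)
    counts: dict = {}
    for patches in patch_sets:
        members = set().union(*(p.residues for p in patches)) if patches else set()
        for lab in members:
            counts[lab] = counts.get(lab, 0) + 1
    frequencies = {lab: c / n_structures for lab, c in counts.items()}
    kept = {
        lab
        for lab, f in frequencies.items()
        if f >= params.consensus_min_frequency - 1e-12
    }
    return ConsensusRegion(
        residues=frozenset(kept),
        frequencies={lab: frequencies[lab] for lab in kept},
    )


def predict_patches(
    matrix: InteractionMatrix,
    structure: Structure,
    params: SelectionParams | None = None,
    cutoff: float = CONTACT_CUTOFF,
) -> list[Patch]:
    """Full single-structure MLCE prediction: matrix -> patches."""
    if params is None:
        params = SelectionParams()
    dec = spectral_decompose(matrix)
    approx = rank1_approximation(dec)
    contacts = contact_matrix(structure, cutoff=cutoff)
    masked = mlce_matrix(approx, contacts)
    selected, _ = select_soft_residues(masked, params)
    return merge_patches(selected, contacts, structure, params)
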