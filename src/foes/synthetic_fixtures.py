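"""Synthetic inputs for exercising every pipeline stage without downloads.

Three generators: an ideal poly-alanine-style alpha-helix with backbone and
C-beta atoms, residue interaction matrices with a planted weakly-coupled
surface block (known truth labels for recovery tests), and a small library of
drug-like fragments covering the common pharmacophore motifs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import Atom, Residue, Structure

# Ideal alpha-helix geometry: 1.5 A rise and 100 deg twist per residue,
# C-alpha ring radius 2.3 A.
RISE = 1.5
TWIST_DEG = 100.0
CA_RADIUS = 2.3

_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth for a planted weak-coupling surface block.

    The planted residues receive contact couplings ~10x weaker in magnitude
    than the background, mimicking a locally non-optimized (frustrated)
    surface substructure available for partner binding.
    """

    planted: frozenset
    background_scale: float = 3.0
    patch_scale: float = 0.3
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if not self.planted:
            raise ValueError("planted set must be non-empty")


def default_planted_truth(
    n_residues: int = 60,
    patch_size: int = 12,
    seed: int = 0,
    chain_id: str = "A",
    **kwargs,
) -> PlantedTruth:
    """Canonical planted truth: a C-terminal block of ``patch_size`` residues.

    A real interaction patch sits on the surface of a connected fold; on a
    one-dimensional helix only a terminal segment leaves the background
    contact graph connected (a mid-helix weak block would sever the helix in
    two, which no surface patch does to a protein core, and would delocalize
    the leading eigenvector away from one half).
    """
    start = n_residues - patch_size + 1
    planted = frozenset(
        (chain_id, n, "") for n in range(start, n_residues + 1)
    )
    return PlantedTruth(planted=planted, seed=seed, **kwargs)


def ideal_helix(
    n_residues: int, sequence: str | None = None, chain_id: str = "A"
) -> Structure:
    """Build an ideal alpha-helix with N, CA, C, O and CB atoms.

    C-beta sits 1.2 A radially outward and 0.95 A toward the N-terminus from
    C-alpha (bond length 1.53 A), which reproduces the helical i+/-1, i+/-3,
    i+/-4 contact pattern at the standard 6.5 A C-beta cutoff. Glycine
    residues get no C-beta. Deterministic: no randomness involved.
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    if sequence is None:
        sequence = "A" * n_residues
    if len(sequence) != n_residues:
        raise ValueError("sequence length must equal n_residues")
    bad = set(sequence) - set(_AA3)
    if bad:
        raise ValueError(f"invalid sequence letters: {sorted(bad)}")

    omega = np.deg2rad(TWIST_DEG)
    residues = []
    for i, letter in enumerate(sequence):
        theta = i * omega
        radial = np.array([np.cos(theta), np.sin(theta), 0.0])
        tangent = np.array([-np.sin(theta), np.cos(theta), 0.0])
        ca = CA_RADIUS * radial + np.array([0.0, 0.0, i * RISE])
        # Backbone N/C offset along the helix path; O hangs off the carbonyl.
        n_at = ca - 1.20 * tangent - np.array([0.0, 0.0, 0.70])
        c_at = ca + 1.15 * tangent + np.array([0.0, 0.0, 0.65])
        o_at = c_at + 1.05 * radial + np.array([0.0, 0.0, 0.70])
        name = _AA3[letter]
        atoms = [
            Atom("N", "N", n_at),
            Atom("CA", "C", ca),
            Atom("C", "C", c_at),
            Atom("O", "O", o_at),
        ]
        if name != "GLY":
            cb = ca + 1.20 * radial - np.array([0.0, 0.0, 0.95])
            atoms.append(Atom("CB", "C", cb))
        residues.append(
            Residue(chain_id=chain_id, number=i + 1, name=name, atoms=atoms)
        )
    return Structure(id=f"helix{n_residues}", residues=residues, source="synthetic")


def planted_patch_matrix(structure: Structure, truth: PlantedTruth):
    """Symmetric interaction matrix with a planted weakly-coupled block.

    Contacts (6.5 A representative-atom cutoff) between two planted residues
    are drawn at the weak ``patch_scale``; every other contact at the strong
    ``background_scale``; non-contact pairs carry small noise only. All
    couplings are negative (stabilizing) up to noise.
    """
    from .energetics import InteractionMatrix
    from .mlce_core import contact_matrix

    index_map = structure.index_map
    unknown = set(truth.planted) - set(index_map)
    if unknown:
        raise ValueError(f"planted residues not in structure: {sorted(unknown)}")
    planted_idx = {index_map[k] for k in truth.planted}

    n = len(structure)
    contacts = contact_matrix(structure).values
    rng = np.random.default_rng(truth.seed)
    values = np.zeros((n, n))
    small = 0.05 * truth.background_scale
    for i in range(n):
        for j in range(i + 1, n):
            if contacts[i, j]:
                scale = (
                    truth.patch_scale
                    if i in planted_idx and j in planted_idx
                    else truth.background_scale
                )
                v = -scale + rng.normal(0.0, truth.noise_sd)
            else:
                v = rng.normal(0.0, small) if truth.noise_sd > 0 else 0.0
            values[i, j] = values[j, i] = v
    return InteractionMatrix(
        values=values, labels=structure.labels(), provenance="builtin"
    )


# Small drug-like fragments (<= 12 heavy atoms) covering aromatic rings,
# H-bond donors/acceptors, and a sulfonamide motif.
TOY_FRAGMENT_SMILES = [
    ("benzene", "c1ccccc1"),
    ("methanol", "CO"),
    ("phenol", "Oc1ccccc1"),
    ("benzenesulfonamide", "NS(=O)(=O)c1ccccc1"),
    ("methanesulfonamide", "CS(N)(=O)=O"),
    ("acetamide", "CC(N)=O"),
    ("imidazole", "c1c[nH]cn1"),
    ("pyridine", "c1ccncc1"),
    ("furan", "c1ccoc1"),
    ("acetic_acid", "CC(O)=O"),
    ("ethylamine", "CCN"),
    ("toluene", "Cc1ccccc1"),
    ("pyrrolidine", "C1CCNC1"),
    ("anisole", "COc1ccccc1"),
]


def toy_fragment_library(seed: int = 0):
    """Fixed library of small drug-like fragments (deterministic)."""
    from .docking import Fragment

    del seed  # library content is fixed; the argument keeps call sites uniform
    return [Fragment.from_smiles(smiles, frag_id=name)
            for name, smiles in TOY_FRAGMENT_SMILES]


def write_toy_library_smiles(path) -> None:
    """Write the toy library as a two-column SMILES file."""
    with open(path, "w") as fh:
        for name, smiles in TOY_FRAGMENT_SMILES:
            fh.write(f"{smiles} {name}\n")
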