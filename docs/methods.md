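# Methods

## Scope and assumptions

`foes` predicts protein–protein interaction regions from the internal
energetics of a single structure and turns the prediction into candidate
ligands by fragment docking and linking. The central assumption is
energetic frustration: networks of strongly coupled residues stabilize the
fold, while surface substructures that are weakly coupled to the rest of the
protein are not internally optimized and are therefore available — indeed
preorganized — for partner binding. The pipeline consumes any symmetric
residue-pair energy matrix, so the prediction quality is bounded by the
energy model feeding it.

## Interaction energetics

The built-in energy model is a deliberately simple heavy-atom surrogate for a
full molecular-mechanics/implicit-solvent decomposition:

* pairwise Lennard-Jones with per-element parameters (Amber-like ε, σ),
  Lorentz–Berthelot combining, 10 Å cutoff;
* Coulomb electrostatics `332.06 q_i q_j / (ε(r)·r)` with a
  distance-dependent dielectric ε(r) = 4r, a standard implicit-solvent
  screening shortcut; no cutoff (the screening decays it quadratically);
* partial charges from a compact per-(residue, atom) template table for the
  20 standard amino acids: shared backbone charges plus side-chain values
  concentrated on polar and formally charged groups. Atoms without a template
  entry get q = 0 and default LJ parameters; hydrogens are not modelled.

Units are kcal/mol and Å throughout. Adjacent-residue pairs are included by
default (`exclude_adjacent` turns them off). Energies computed externally
(e.g. a generalized-Born per-residue decomposition) can be imported from
CSV/TSV; the matrix is symmetrized as (M + Mᵀ)/2 with a warning when the
asymmetry exceeds 1e-6, and reordered to the structure's residue order by
label.

The surrogate is not a force field: its absolute energies are not meaningful,
only the relative coupling structure is. That is sufficient because every
downstream step is invariant under positive rescaling of the matrix.

## Interface prediction

1. Full symmetric eigendecomposition (`numpy.linalg.eigh`), eigenvalues
   ascending. A non-negative smallest eigenvalue is an error: without a
   stabilizing mode the method's premise fails. A (near-)degenerate smallest
   eigenvalue (gap < 1e-10) keeps the decomposition's first eigenvector and
   logs a warning.
2. Rank-1 approximation M̃ = λ₁ w¹(w¹)ᵀ, invariant under the sign of w¹.
3. Contact mask: C_ij = 1 iff representative atoms are closer than 6.5 Å.
   Representative atoms are Cβ (protein), Cα (glycine, and as a logged
   fallback for truncated side chains), C1 (glycans).
4. Soft-pair selection: among the non-zero masked couplings, the
   ceil(0.15·|P|) pairs of smallest magnitude |MLCE_ij| ("low coupling
   energy"), ties broken by (i, j) ascending for determinism. `ceil` rather
   than `floor` so a positive fraction never selects zero pairs. A
   `rank_by="signed"` switch selects the least-stabilizing (largest signed)
   couplings instead, for users who prefer that reading.
5. Patches: connected components of the 6.5 Å contact graph restricted to the
   selected residues; components below `min_patch_size` (default 3) are
   dropped. An optional burial filter (default on) removes residues whose
   coordination number — representative atoms within 10 Å — exceeds 22; this
   is a SASA-free surface proxy and all three numbers are configurable.
6. Consensus over an ensemble: a residue is kept iff it appears in any patch
   in ≥ `consensus_min_frequency` of the structures. The default 4/7 is a
   majority over the typical ensemble of one minimized structure plus six
   cluster representatives; the rule operates on residue frequency (not
   whole-patch overlap), which is the simpler and more permissive choice
   where the two differ.

## Windows and docking boxes

Manual windows are lists of author-numbered residue ranges and take precedence
when reproducing a published layout. Automatic windowing orders the region's
residues along the principal axis of their representative coordinates and
cuts consecutive groups of `target_size` (default 16, the size of the
smallest published manual window) with at least `overlap_fraction` (default
0.3) shared members between neighbors; the final window is anchored at the
region's end so coverage is always complete. The axis orientation is fixed
deterministically (lowest-index member projects first), making the
decomposition independent of input order. A docking box is the axis-aligned
bounding box of the window's representative atoms inflated by 4 Å padding.

## Docking stage

The built-in stage exists to exercise the pipeline end to end, not to rival a
production engine. Each fragment gets one seeded ETKDG conformer and is placed
rigidly: uniform random centroid translation inside the box and uniform random
rotation, `n_generated` times (default 10,000), keeping the best
`n_kept_intermediate` (1,000) and returning the best `n_final_per_fragment`
(1). The score is softened Lennard-Jones (interatomic distances clamped at
1.2 Å so steric overlap is penalized but finite) plus screened Coulomb using
Gasteiger charges on the fragment and the template charges on the protein,
minus 1 per donor/acceptor N/O pair within 3.5 Å. One random stream is derived
per (seed, fragment, window) triple, so results are independent of the order
in which fragments and windows are processed.

Externally docked poses are imported from SDF with a score tag. The two score
scales must not be mixed: absolute cutoffs (e.g. −3.5) are only meaningful
for imported scores, so the pose filter applies `score_cutoff` to imported
poses and `percentile_cutoff` (default: best 20%) to built-in poses. The
percentile of a built-in pose is computed once, against the score
distribution of its own sampling run, and stored on the pose — this keeps
filtering idempotent. The optional contact requirement keeps poses with at
least one heavy atom within 4.5 Å (a standard contact distance) of any heavy
atom of a user-supplied residue set.

## Assembly

Attachment sites are hydrogen-bearing heavy atoms; since hydrogens are
implicit, the outward direction is taken from the heavy atom away from the
molecular centroid. A join of two placed fragments through sites (a, b) and a
linker of n ∈ {0, 1, 2} methylenes is feasible when the inter-site distance
falls in the linker's window — defaults direct (0.8, 2.2) Å, one CH₂
(2.0, 3.2) Å, two CH₂ (3.0, 4.6) Å, centered near ideal 1.54 Å C–C chain
geometry — and both site directions are within 45° of the bond vector. All
feasible joinings are enumerated and ranked by (clash count, |distance −
ideal|) rather than sampled randomly. Linker carbons are placed by linear
interpolation; no minimization is performed (hits are raw by design), no
stereocenters are assigned, and clashes (non-bonded heavy-atom pairs from
different fragments closer than 2 Å) are counted and reported, not fatal.
Heavy-atom bookkeeping holds by construction: a hit's heavy-atom count equals
the sum over its fragments plus the number of methylenes.

The core-then-grow strategy joins the two anchor poses into cores
(deduplicated by canonical SMILES) and then adds one to three further
fragments breadth-first, each pose used at most once per growth path. A
per-window cap (default 20 poses by score) bounds the pairwise enumeration.

Final rescoring evaluates each assembled hit's existing coordinates with the
built-in scoring function against the predicted region's box. Re-sampling
placements of a rigid multi-fragment molecule was deliberately avoided: the
hits are already in the frame in which their fragments docked, and an
in-place rescore ranks them on the same scale without pretending to a search
the naive sampler could not perform.

## Similarity

Atom types are (element, heavy-atom degree, π flag, formal charge), the π
flag meaning aromatic or multiply bonded — an approximation of
hybridization-aware typing. Every unordered heavy-atom pair yields a
(min-type, max-type, distance) feature; distances are bond-path lengths
(topological, default) or Cartesian distances binned at 1 Å and capped at
20 Å (geometric; requires coordinates). Features are hashed with blake2b to
64-bit identifiers and stored sparsely, so collisions are negligible at
fragment/hit sizes and the fingerprint is exactly order-invariant. Tanimoto
is binary |A∩B|/|A∪B| by default (a count-based min/max variant is a flag);
two empty fingerprints score 0 with a warning. The ranking table sorts by
docking score ascending, annotates each hit's best Tanimoto over the
references, and returns the top 30 by default.

## Synthetic fixtures

The fixture module generates everything the tests and the demo need:

* **Ideal helix** — backbone N/CA/C/O plus Cβ on ideal α-helix geometry
  (1.5 Å rise, 100°/residue, 2.3 Å Cα radius). Cβ sits 1.2 Å radially outward
  and 0.95 Å toward the N-terminus from Cα (1.53 Å bond), reproducing the
  i±1, i±3, i±4 helical contact pattern at the 6.5 Å Cβ cutoff. No side
  chains beyond Cβ — sufficient for contact, window, and energy logic.
* **Planted-patch matrix** — contacts inside a designated residue block get
  weak couplings (−0.3 ± noise), all other contacts strong ones
  (−3.0 ± noise, i.e. 10× contrast with noise sd 10% of background), and
  non-contacts carry only small noise. The canonical block is the C-terminal
  12 residues of the 60-residue helix: a surface patch leaves the rest of a
  fold connected, and on a one-dimensional helix only a terminal block has
  that property — a mid-helix weak block severs the contact graph in two and
  localizes the leading eigenvector on one half, a pathology of the 1D
  geometry rather than of the method. With the terminal block the full
  prediction recovers the planted set at mean Jaccard ≈ 0.83 over 20 seeds.
* **Toy fragment library** — 14 fixed drug-like fragments (≤ 12 heavy atoms)
  covering aromatic rings, H-bond donors/acceptors, amines, acids, and two
  sulfonamides.

What the fixtures do *not* emulate: real side-chain packing and rotamers,
MD-quality conformational ensembles, realistic force-field energetics, and
real binding-site shapes. Passing tests therefore demonstrate the
correctness of the algorithmic machinery (decomposition, selection, merging,
retention, joining, ranking) and the method's internal consistency, not
predictive accuracy on real proteins — for that, feed the pipeline real
structures and imported MM/GBSA matrices and docked poses.

## Numerical and design notes

* Matrices are validated on construction (symmetry, zero diagonal,
  finiteness); every derived object carries the residue-label index map.
* All selections and orderings have explicit deterministic tie-breaks;
  reruns with the same config and seed are artifact-checksum identical.
* Alternate locations keep the highest-occupancy conformer; multi-model
  files default to the first model.
* Problem sizes in the test suite and the acceptance script are scaled down
  (hundreds to a thousand docking samples per fragment, 60-residue
  fixtures); the defaults on `DockingPolicy` remain the full
  10,000 → 1,000 → 1 ladder.
* Known limitations: the built-in scorer's absolute values are
  engine-specific and must not be compared to external scores; assembled
  hits are unminimized and may strain; synthesizability is not assessed;
  protonation/tautomer/stereoisomer enumeration is out of scope.
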