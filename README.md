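# foes — fragments on energy surfaces

`foes` is an ab initio pipeline for designing starting-point ("raw hit")
ligands against protein–protein interaction (PPI) surfaces. PPI interfaces are
large, flat, and pocket-poor, which defeats classical pocket-centric docking;
`foes` instead works from the energetic signature of a single structure (or a
small structural ensemble): it predicts where on the surface a partner protein
would bind, docks a library of small drug-like fragments into overlapping
windows tiling that prediction, fuses the retained fragments with short
methylene linkers into candidate molecules, and ranks the candidates by
atom-pair Tanimoto similarity against known reference ligands.

It is intended for structural bioinformaticians and computational medicinal
chemists who want unbiased lead hypotheses for difficult or orphan targets,
starting from nothing but a PDB file and a fragment library.

## The method

**Interface prediction (matrix of low coupling energy).** For a protein of
*N* residues, build the symmetric residue-pair nonbonded interaction matrix
*M* (kcal/mol), either with the built-in heavy-atom surrogate
(Lennard-Jones + Coulomb screened by a distance-dependent dielectric
ε(r) = 4r) or imported from an external per-residue energy decomposition
(e.g. MM/GBSA). Decompose it,

    M = Σ_k λ_k w^k (w^k)ᵀ,

with eigenvalues sorted ascending so λ₁ is the most negative. The leading
eigenpair carries most of the energetic information; the rank-1 approximation

    M̃_ij = λ₁ w_i¹ w_j¹

is masked elementwise (Hadamard product) by the residue contact matrix *C*
(C_ij = 1 iff the representative atoms — Cβ for protein residues, Cα for
glycine, C1 for glycans — lie within 6.5 Å):

    MLCE = M̃ ⊗ C.

Residue pairs in the weakest 15% of the non-zero couplings (smallest
|MLCE_ij|) are *soft*: locally non-optimized substructures, preorganized to
bind a partner rather than stabilize the fold. Soft residues are merged into
spatially contiguous patches (connected components of the contact graph,
optional burial filter, minimum patch size 3). Over a structural ensemble, a
residue enters the consensus region if it appears in patches in ≥ 4/7 of the
structures.

**Fragment docking and assembly.** The consensus region is cut into
overlapping windows (manual residue ranges, or automatic principal-axis
sweep); each window's bounding box is a docking target. The built-in docking
stage samples rigid random placements (default 10,000 generated → best 1,000
kept → best pose saved), scoring with a softened-steric + screened-Coulomb +
H-bond-count function; externally docked poses with scores (SDF) can be
imported instead, where an absolute score cutoff such as −3.5 applies.
Retained poses are joined — directly, or via one or two CH₂ bridges placed
along the inter-site vector — either pairwise or with a core-then-grow
strategy (link two anchor fragments, then add one to three more). Hits are
rescored in place against the predicted region, and each hit's atom-pair
fingerprint (64-bit hashed (type, type, distance) features; topological or
geometric distances) is compared to the references by Tanimoto similarity;
the 30 best-scoring molecules form the final table.

## Worked example

Everything below runs on the package's own synthetic fixtures (a 60-residue
ideal α-helix with a planted weakly-coupled 12-residue surface block, the
14-fragment toy library, and a sulfonamide reference ligand):

```python
import foes
from pathlib import Path
from foes.docking import DockingPolicy
from foes.pipeline import RunConfig, run_pipeline
from foes.similarity import load_references

helix  = foes.ideal_helix(60)
truth  = foes.default_planted_truth(seed=0)        # weak block: residues 49-60
matrix = foes.planted_patch_matrix(helix, truth)

patches = foes.predict_patches(matrix, helix)
print([sorted(p.residues) for p in patches])

Path("refs.smi").write_text("NS(=O)(=O)c1ccc(O)cc1 sulfonamide_ref\n")
cfg = RunConfig(
    policy=DockingPolicy(n_generated=500, n_kept_intermediate=50,
                         n_final_per_fragment=1),
    window_target_size=8, seed=17, output_dir="out",
)
manifest = run_pipeline(cfg, structures=[helix], matrices=[matrix],
                        fragments=foes.toy_fragment_library(),
                        references=load_references("refs.smi"))
print(manifest["counts"])
```

This prints one predicted patch of 17 residues (A:42–A:60, the planted block
plus a small soft shoulder) and the stage counts

```
{"structures": 1, "patches_per_structure_total": 1, "consensus_residues": 17,
 "windows": 3, "poses_docked": 42, "poses_kept": 42, "hits": 9,
 "similarity_rows": 9}
```

i.e. the 17-residue prediction was tiled by 3 overlapping windows, the 14
fragments produced 42 best poses (one per fragment per window), and assembly
yielded 9 valid multi-fragment hits. `out/similarity_top.csv` holds the
ranked table; its first rows here were

```
hit_id    reference_id  tanimoto  docking_score  rank
  hit1 sulfonamide_ref  0.102041      -3.809457     1
  hit2 sulfonamide_ref  0.116279      -3.367243     2
```

Docking scores are on the built-in scorer's scale (lower is better) and the
Tanimoto values are low because the toy fixtures are deliberately tiny; with
real structures, an external docking engine's poses, and a real fragment
library, the same code paths apply unchanged.

The same workflow is available from the shell:

```bash
foes synth --outdir fixtures          # write demo helix/matrix/fragments
foes predict fixtures/helix.pdb --matrix fixtures/matrix.csv
foes run config.yaml                  # full pipeline from a YAML config
```

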