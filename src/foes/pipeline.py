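"""End-to-end orchestration: structures -> patches -> windows -> docked
fragments -> assembled hits -> similarity ranking.

A single :class:`RunConfig` drives the whole run; one top-level seed derives
every stage seed, so a rerun with the same config is artifact-identical. All
artifacts are written in plain formats (CSV/JSON/SDF/PDB) and listed in a run
manifest together with their checksums and the stage counts.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import assembly as asm
from . import docking as dk
from . import energetics as en
from . import mlce_core as mlce
from . import similarity as sim
from . import structure_io as sio
from . import windows as win

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything needed for one reproducible run."""

    structure_paths: list = field(default_factory=list)
    energy_matrix_paths: list | None = None  # one per structure, else builtin
    selection: mlce.SelectionParams = field(default_factory=mlce.SelectionParams)
    window_spec: list | None = None  # manual residue ranges, else auto
    window_target_size: int = 16
    window_overlap: float = 0.3
    box_padding: float = 4.0
    policy: dk.DockingPolicy = field(default_factory=dk.DockingPolicy)
    linkers: tuple = asm.DEFAULT_LINKERS
    combine_strategy: str = "pairwise"  # pairwise | core_grow
    max_additions: int = 3
    assembly_pose_cap: int = 20  # best poses entering assembly, per window
    similarity: sim.AtomPairParams = field(default_factory=sim.AtomPairParams)
    fragment_library_path: str | None = None
    reference_path: str | None = None
    top_k: int = 30
    seed: int = 0
    output_dir: str = "foes_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        config = cls()
        simple = {
            "structure_paths", "energy_matrix_paths", "window_spec",
            "window_target_size", "window_overlap", "box_padding",
            "combine_strategy", "max_additions", "assembly_pose_cap",
            "fragment_library_path", "reference_path", "top_k", "seed",
            "output_dir",
        }
        for key, value in raw.items():
            if key in simple:
                setattr(config, key, value)
            elif key == "selection":
                config.selection = mlce.SelectionParams(**value)
            elif key == "policy":
                config.policy = dk.DockingPolicy(**value)
            elif key == "similarity":
                config.similarity = sim.AtomPairParams(**value)
            elif key == "linkers":
                config.linkers = tuple(asm.LinkerSpec(**spec) for spec in value)
            else:
                raise PipelineError(f"unknown config key {key!r}")
        if config.combine_strategy not in ("pairwise", "core_grow"):
            raise PipelineError("combine_strategy must be pairwise or core_grow")
        return config


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str):
    def decorate(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return decorate


def run_pipeline(
    config: RunConfig,
    structures: list | None = None,
    matrices: list | None = None,
    fragments: list | None = None,
    references: list | None = None,
) -> dict:
    """Execute the full workflow and return the run manifest.

    ``structures``/``matrices``/``fragments``/``references`` may be passed as
    in-memory objects (as the synthetic-fixture path does); otherwise they are
    loaded from the paths in the config.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    counts: dict[str, int] = {}

    def _write(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        artifacts[name] = _sha256(path)
        return path

    # --- load inputs -----------------------------------------------------
    if structures is None:
        if not config.structure_paths:
            raise PipelineError("stage 'load' failed: no structures given")
        structures = [
            sio.load_structure(p) for p in config.structure_paths
        ]
    if matrices is None and config.energy_matrix_paths:
        if len(config.energy_matrix_paths) != len(structures):
            raise PipelineError(
                "stage 'load' failed: need one energy matrix per structure"
            )
        matrices = [
            en.read_energy_matrix(p, structure)
            for p, structure in zip(config.energy_matrix_paths, structures)
        ]
    if fragments is None:
        if config.fragment_library_path is None:
            raise PipelineError("stage 'load' failed: no fragment library given")
        fragments = dk.load_fragment_library(config.fragment_library_path)
    if references is None:
        if config.reference_path is None:
            raise PipelineError("stage 'load' failed: no reference ligands given")
        references = sim.load_references(config.reference_path)

    reference_structure = structures[0]

    # --- per-structure MLCE ----------------------------------------------
    patch_sets = []
    for k, structure in enumerate(structures):
        matrix = (
            matrices[k]
            if matrices is not None
            else _stage("energetics")(en.energy_matrix)(structure)
        )
        if matrices is None and k == 0:
            _write("interaction_matrix.csv", matrix.write_csv)
        patches = _stage("mlce")(mlce.predict_patches)(
            matrix, structure, config.selection
        )
        patch_sets.append(patches)
    counts["structures"] = len(structures)
    counts["patches_per_structure_total"] = sum(len(p) for p in patch_sets)

    region = _stage("consensus")(mlce.consensus_region)(patch_sets, config.selection)
    if not region.residues:
        raise PipelineError("stage 'consensus' failed: empty consensus region")
    counts["consensus_residues"] = region.size
    by_label = {r.label: r for r in reference_structure.residues}
    _write(
        "consensus.json",
        lambda p: p.write_text(
            json.dumps(
                {
                    "residues": sio.selection_to_text(
                        [by_label[lab] for lab in sorted(region.residues)]
                    ).split(),
                    "frequencies": {
                        lab: region.frequencies[lab] for lab in sorted(region.residues)
                    },
                },
                indent=2,
            )
        ),
    )

    # --- windows ----------------------------------------------------------
    if config.window_spec:
        window_list = _stage("windows")(win.windows_from_spec)(
            config.window_spec, reference_structure
        )
    else:
        window_list = _stage("windows")(win.auto_windows)(
            region,
            reference_structure,
            target_size=config.window_target_size,
            overlap_fraction=config.window_overlap,
        )
    counts["windows"] = len(window_list)
    _write(
        "windows.json",
        lambda p: p.write_text(
            json.dumps(
                [
                    {
                        "id": w.id,
                        "ranges": [f"{c}:{lo}-{hi}" for c, lo, hi in w.ranges],
                        "members": sorted(w.members),
                    }
                    for w in window_list
                ],
                indent=2,
            )
        ),
    )

    # --- docking ----------------------------------------------------------
    policy = dk.DockingPolicy(
        **{**_policy_dict(config.policy), "seed": config.seed}
    )
    poses = []
    for window in window_list:
        box = win.docking_box(window, reference_structure, config.box_padding)
        for fragment in fragments:
            poses.extend(
                _stage("docking")(dk.dock_fragment)(
                    fragment, box, reference_structure, policy, window_id=window.id
                )
            )
    counts["poses_docked"] = len(poses)
    kept = _stage("filtering")(dk.filter_poses)(poses, policy, reference_structure)
    counts["poses_kept"] = len(kept)
    if kept:
        _write("poses.sdf", lambda p: dk.write_poses(kept, p))

    # --- assembly ----------------------------------------------------------
    hits = _stage("assembly")(_assemble)(kept, config)
    for hit in hits:
        asm.validate_hit(hit)
    hits = [h for h in hits if h.valid]
    counts["hits"] = len(hits)

    # --- final rescoring of raw hits ---------------------------------------
    region_window = win.Window(
        id="region", ranges=[], members=frozenset(region.residues)
    )
    region_box = win.docking_box(
        region_window, reference_structure, config.box_padding
    )
    for hit in hits:
        hit.score = _stage("rescoring")(dk.score_pose_mol)(
            hit.mol, region_box, reference_structure
        )
    hits.sort(key=lambda h: (h.score, h.smiles))
    if hits:
        _write("hits.sdf", lambda p: asm.write_hits_sdf(hits, p))
        _write(
            "hits.csv",
            lambda p: _hits_csv(hits, p),
        )

    # --- similarity ---------------------------------------------------------
    records, table = _stage("similarity")(sim.similarity_table)(
        hits, references, config.similarity, top_k=config.top_k
    )
    counts["similarity_rows"] = len(records)
    _write("similarity_full.csv", lambda p: table.to_csv(p, index=False))
    _write(
        "similarity_top.csv",
        lambda p: table.head(config.top_k).to_csv(p, index=False),
    )

    manifest = {
        "seed": config.seed,
        "parameters": _config_summary(config),
        "counts": counts,
        "artifacts": artifacts,
        "top_similarity": float(table["tanimoto"].max()) if len(table) else None,
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _assemble(kept_poses, config: RunConfig):
    """Combine filtered poses according to the configured strategy."""
    by_window: dict[str, list] = {}
    for pose in kept_poses:
        by_window.setdefault(pose.window_id, []).append(pose)
    pool = []
    for window_id in sorted(by_window):
        group = sorted(by_window[window_id], key=lambda p: (p.score, p.fragment_id))
        pool.extend(group[: config.assembly_pose_cap])
    if len(pool) < 2:
        return []

    hits = []
    seen: set[str] = set()
    if config.combine_strategy == "pairwise":
        for pose_a, pose_b in itertools.combinations(pool, 2):
            for hit in asm.join_pair(pose_a, pose_b, config.linkers):
                if hit.smiles not in seen:
                    seen.add(hit.smiles)
                    hits.append(hit)
    else:  # core_grow: anchor on the two best-scoring poses overall
        anchors = sorted(pool, key=lambda p: (p.score, p.fragment_id))[:2]
        others = [p for p in pool if p not in anchors]
        cores = asm.build_cores(anchors, config.linkers)
        for core in cores:
            if core.smiles not in seen:
                seen.add(core.smiles)
                hits.append(core)
            for grown in asm.grow_core(
                core, others, config.linkers, config.max_additions
            ):
                if grown.smiles not in seen:
                    seen.add(grown.smiles)
                    hits.append(grown)
    return hits


def _hits_csv(hits, path: Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "hit_id": f"hit{i}",
                "smiles": h.smiles,
                "fragments": ",".join(h.fragment_ids),
                "windows": ",".join(h.window_ids),
                "linker_methylenes": ",".join(map(str, h.linker_methylenes)),
                "heavy_atoms": h.heavy_atom_count,
                "clash_count": h.clash_count,
                "score": h.score,
            }
            for i, h in enumerate(hits, start=1)
        ]
    ).to_csv(path, index=False)


def _policy_dict(policy: dk.DockingPolicy) -> dict:
    d = asdict(policy)
    if d.get("required_contact_residues") is not None:
        d["required_contact_residues"] = frozenset(d["required_contact_residues"])
    return d


def _config_summary(config: RunConfig) -> dict:
    return {
        "selection": asdict(config.selection),
        "policy": {
            k: (sorted(v) if isinstance(v, frozenset) else v)
            for k, v in _policy_dict(config.policy).items()
        },
        "linkers": [asdict(l) for l in config.linkers],
        "similarity": asdict(config.similarity),
        "combine_strategy": config.combine_strategy,
        "max_additions": config.max_additions,
        "assembly_pose_cap": config.assembly_pose_cap,
        "window_spec": config.window_spec,
        "window_target_size": config.window_target_size,
        "window_overlap": config.window_overlap,
        "box_padding": config.box_padding,
        "top_k": config.top_k,
    }
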