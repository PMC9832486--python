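"""Subdivide predicted interaction regions into overlapping docking windows.

Large predicted surfaces are cut into windows of roughly constant size so
fragment docking can sample the whole region exhaustively; neighbors share a
configurable fraction of residues. Windows can also be specified manually as
author-numbered residue ranges (e.g. ``"57-65, 94-101"``), which takes
precedence when reproducing published window layouts.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np

from .mlce_core import ConsensusRegion
from .structure_io import Structure

_RANGE_RE = re.compile(r"^(?:(?P<chain>[A-Za-z0-9]+):)?(?P<lo>-?\d+)(?:-(?P<hi>-?\d+))?$")


class WindowSpecError(ValueError):
    """A residue range does not resolve against the structure."""


@dataclass
class Window:
    """A docking window: a set of member residues plus its defining ranges."""

    id: str
    ranges: list[tuple[str, int, int]]  # (chain, start, stop) inclusive
    members: frozenset  # residue labels

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class DockingBox:
    """Axis-aligned box enclosing a window's representative atoms plus padding."""

    center: np.ndarray
    half_extents: np.ndarray

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.half_extents = np.asarray(self.half_extents, dtype=float)
        if np.any(self.half_extents <= 0):
            raise ValueError("half-extents must be positive")

    def contains(self, points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        points = np.atleast_2d(points)
        return np.all(
            np.abs(points - self.center) <= self.half_extents + tol, axis=1
        )

    def intersects(self, other: "DockingBox") -> bool:
        gap = np.abs(self.center - other.center) - (
            self.half_extents + other.half_extents
        )
        return bool(np.all(gap <= 0))


def parse_range(spec: str, default_chain: str) -> tuple[str, int, int]:
    """Parse ``"60-75"`` or ``"A:60-75"`` or a single residue ``"42"``."""
    m = _RANGE_RE.match(spec.strip())
    if not m:
        raise WindowSpecError(f"cannot parse residue range {spec!r}")
    chain = m.group("chain") or default_chain
    lo = int(m.group("lo"))
    hi = int(m.group("hi")) if m.group("hi") is not None else lo
    if hi < lo:
        raise WindowSpecError(f"range {spec!r} is reversed")
    return chain, lo, hi


def windows_from_spec(
    spec: list[list[str]], structure: Structure, default_chain: str | None = None
) -> list[Window]:
    """One window per spec entry; each entry is a list of residue ranges.

    Ranges use author numbering; all listed residues must exist in the
    structure. Overlapping ranges within one window union their members.
    """
    if default_chain is None:
        default_chain = structure.residues[0].chain_id
    by_key = {(r.chain_id, r.number): r for r in structure.residues if not r.icode}
    windows = []
    for w_idx, entry in enumerate(spec, start=1):
        ranges = [parse_range(s, default_chain) for s in entry]
        members = set()
        for chain, lo, hi in ranges:
            for num in range(lo, hi + 1):
                res = by_key.get((chain, num))
                if res is None:
                    raise WindowSpecError(
                        f"residue {chain}:{num} (window {w_idx}) not in structure"
                    )
                members.add(res.label)
        if not members:
            raise WindowSpecError(f"window {w_idx} is empty")
        windows.append(
            Window(id=f"w{w_idx}", ranges=ranges, members=frozenset(members))
        )
    return windows


def auto_windows(
    region: ConsensusRegion | frozenset,
    structure: Structure,
    target_size: int = 16,
    overlap_fraction: float = 0.3,
) -> list[Window]:
    """Cut a region into overlapping windows along its principal axis.

    Region residues are ordered by their projection onto the principal axis
    of their representative coordinates and grouped into consecutive windows
    of ``target_size`` members, consecutive windows sharing at least
    ``overlap_fraction * target_size`` members. Every region residue belongs
    to at least one window. Deterministic and independent of input order.
    """
    members = region.residues if isinstance(region, ConsensusRegion) else region
    if not members:
        raise WindowSpecError("region is empty")
    index_of = {lab: i for i, lab in enumerate(structure.labels())}
    unknown = set(members) - set(index_of)
    if unknown:
        raise WindowSpecError(f"region residues not in structure: {sorted(unknown)}")
    idx = sorted(index_of[lab] for lab in members)
    labels = structure.labels()
    coords = structure.representative_coords()[idx]

    if len(idx) <= target_size:
        ordered = [labels[i] for i in idx]
        return [_window_from_members("w1", ordered, structure)]

    center = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - center, full_matrices=False)
    axis = vt[0]
    # Deterministic orientation: the lowest-index member projects first.
    proj = (coords - center) @ axis
    if proj[0] > proj[-1]:
        proj = -proj
    order = np.lexsort((np.array(idx), proj))
    ordered = [labels[idx[k]] for k in order]

    min_overlap = max(1, math.ceil(overlap_fraction * target_size))
    step = max(1, target_size - min_overlap)
    starts = list(range(0, len(ordered) - target_size + 1, step))
    if starts[-1] + target_size < len(ordered):
        starts.append(len(ordered) - target_size)
    windows = []
    for w_idx, start in enumerate(starts, start=1):
        group = ordered[start : start + target_size]
        windows.append(_window_from_members(f"w{w_idx}", group, structure))
    return windows


def _window_from_members(
    window_id: str, members: list, structure: Structure
) -> Window:
    by_label = {r.label: r for r in structure.residues}
    ranges = _contiguous_ranges([by_label[lab] for lab in members])
    return Window(id=window_id, ranges=ranges, members=frozenset(members))


def _contiguous_ranges(residues) -> list[tuple[str, int, int]]:
    ordered = sorted({(r.chain_id, r.number) for r in residues})
    ranges = []
    start = prev = None
    chain = None
    for c, num in ordered:
        if chain == c and prev is not None and num == prev + 1:
            prev = num
        else:
            if start is not None:
                ranges.append((chain, start, prev))
            chain, start, prev = c, num, num
    if start is not None:
        ranges.append((chain, start, prev))
    return ranges


def docking_box(
    window: Window, structure: Structure, padding: float = 4.0
) -> DockingBox:
    """Bounding box of the window's representative atoms inflated by padding."""
    index_of = {lab: i for i, lab in enumerate(structure.labels())}
    idx = [index_of[lab] for lab in window.members]
    coords = structure.representative_coords()[idx]
    lo = coords.min(axis=0) - padding
    hi = coords.max(axis=0) + padding
    return DockingBox(center=0.5 * (lo + hi), half_extents=0.5 * (hi - lo))
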