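"""Voxel lattice, hierarchical region ontology and inter-region geometry.

The mouse brain is represented on a regular 100 μm voxel grid.  Regions come
from a hierarchical parcellation ("structure graph"): a tree of structures in
which the finest annotated structures — the *leafs* — partition the annotated
voxels.  Sources live in one designated hemisphere; targets comprise the
ipsilateral leafs plus the mirrored (contralateral) leafs, so the number of
targets is the number of source-hemisphere leafs plus the number of leafs
that also have voxels in the opposite hemisphere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "VoxelLattice",
    "Node",
    "RegionOntology",
    "load_ontology",
    "region_distance",
    "contralateral_target_count",
]

DEFAULT_SPACING_UM = 100.0


@dataclass
class VoxelLattice:
    """A regular 3D voxel grid with physical spacing in micrometres.

    Voxel indices are 0-based; the physical centre of voxel ``(i, j, k)`` is
    ``(index + 0.5) * spacing_um`` on each axis.  The last axis is the
    left-right axis used to split hemispheres at the midline plane.
    """

    shape: tuple[int, int, int]
    spacing_um: float = DEFAULT_SPACING_UM
    brain_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.spacing_um <= 0:
            raise ValueError("spacing_um must be positive")
        self.shape = tuple(int(n) for n in self.shape)
        if len(self.shape) != 3 or any(n <= 0 for n in self.shape):
            raise ValueError(f"shape must be a positive integer triple, got {self.shape}")
        if self.brain_mask is not None:
            self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
            if self.brain_mask.shape != self.shape:
                raise ValueError("brain_mask shape does not match lattice shape")

    def positions_um(self, indices: np.ndarray) -> np.ndarray:
        """Physical centres (μm) of voxels given as an (N, 3) index array."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return (idx + 0.5) * self.spacing_um

    @property
    def midline_um(self) -> float:
        """Physical coordinate of the midline plane on the hemisphere axis."""
        return self.shape[2] * self.spacing_um / 2.0

    def hemisphere_of(self, indices: np.ndarray) -> np.ndarray:
        """Hemisphere code per voxel: 'L' (source side), 'R', or 'M' (midline)."""
        pos = self.positions_um(indices)[:, 2]
        out = np.full(pos.shape, "M", dtype="<U1")
        out[pos < self.midline_um] = "L"
        out[pos > self.midline_um] = "R"
        return out


@dataclass
class Node:
    id: int
    acronym: str
    parent_id: int | None
    children: list[int] = field(default_factory=list)


class RegionOntology:
    """Hierarchical parcellation with voxel assignment and hemisphere split.

    Parameters
    ----------
    nodes : dict mapping structure id to :class:`Node`.
    annotation : integer array over the lattice; 0 marks unannotated voxels,
        any other value must be a structure id present in ``nodes``.
    lattice : the :class:`VoxelLattice` the annotation lives on.
    """

    def __init__(self, nodes: dict[int, Node], annotation: np.ndarray, lattice: VoxelLattice):
        self.nodes = nodes
        self.lattice = lattice
        self.annotation = np.asarray(annotation)
        if self.annotation.shape != lattice.shape:
            raise ValueError("annotation shape does not match lattice shape")

        roots = [n.id for n in nodes.values() if n.parent_id is None]
        if len(roots) != 1:
            raise ValueError(f"ontology must have exactly one root, found {roots}")
        self.root_id = roots[0]

        annotated_ids = set(np.unique(self.annotation)) - {0}
        unknown = sorted(annotated_ids - set(nodes))
        if unknown:
            raise ValueError(f"annotation labels absent from structure graph: {unknown}")

        # leafs: annotated structures with no annotated descendant
        self._descendants: dict[int, set[int]] = {}
        self._compute_descendants()
        self.leaf_ids: list[int] = sorted(
            sid for sid in annotated_ids
            if not (self._descendants[sid] & annotated_ids)
        )

        # voxel assignment per leaf and hemisphere; midline voxels count as 'L'
        self._voxels: dict[tuple[int, str], np.ndarray] = {}
        all_idx = np.argwhere(self.annotation != 0)
        labels = self.annotation[tuple(all_idx.T)]
        hemis = lattice.hemisphere_of(all_idx)
        hemis = np.where(hemis == "M", "L", hemis)
        for leaf in self.leaf_ids:
            sel = labels == leaf
            for h in ("L", "R"):
                self._voxels[(leaf, h)] = all_idx[sel & (hemis == h)]

        self.source_leafs: list[int] = [
            leaf for leaf in self.leaf_ids if len(self._voxels[(leaf, "L")]) > 0
        ]
        #: target identity: (leaf id, 'ipsi'|'contra'); contra targets exist only
        #: for leafs with voxels strictly across the midline
        self.targets: list[tuple[int, str]] = (
            [(leaf, "ipsi") for leaf in self.source_leafs]
            + [(leaf, "contra") for leaf in self.leaf_ids if len(self._voxels[(leaf, "R")]) > 0]
        )

    def _compute_descendants(self) -> None:
        order: list[int] = []
        seen: set[int] = set()

        def visit(sid: int, stack: set[int]) -> None:
            if sid in stack:
                raise ValueError(f"cyclic parent links at structure {sid}")
            if sid in seen:
                return
            stack.add(sid)
            for child in self.nodes[sid].children:
                visit(child, stack)
            stack.discard(sid)
            seen.add(sid)
            order.append(sid)

        visit(self.root_id, set())
        unreached = set(self.nodes) - seen
        if unreached:
            raise ValueError(f"structures unreachable from root (cycle or orphan): {sorted(unreached)}")
        for sid in order:  # children visited before parents
            desc: set[int] = set()
            for child in self.nodes[sid].children:
                desc.add(child)
                desc |= self._descendants[child]
            self._descendants[sid] = desc

    # -- bookkeeping ---------------------------------------------------------

    @property
    def n_sources(self) -> int:
        return len(self.source_leafs)

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    def acronym(self, sid: int) -> str:
        return self.nodes[sid].acronym

    def target_labels(self) -> list[str]:
        return [f"{self.acronym(leaf)}-{side}" for leaf, side in self.targets]

    def major_of(self, leaf: int) -> int:
        """The major structure (depth-1 ancestor) containing a leaf."""
        sid = leaf
        while self.nodes[sid].parent_id not in (None, self.root_id):
            sid = self.nodes[sid].parent_id
        if self.nodes[sid].parent_id is None:  # leaf is the root itself
            return sid
        return sid

    @property
    def major_ids(self) -> list[int]:
        return sorted({self.major_of(leaf) for leaf in self.leaf_ids})

    def voxels(self, leaf: int, hemi: str = "L") -> np.ndarray:
        """(N, 3) voxel indices of a leaf in hemisphere 'L', 'R' or 'both'."""
        if hemi == "both":
            return np.concatenate([self._voxels[(leaf, "L")], self._voxels[(leaf, "R")]])
        return self._voxels[(leaf, hemi)]

    def target_voxels(self, target: tuple[int, str]) -> np.ndarray:
        leaf, side = target
        return self.voxels(leaf, "L" if side == "ipsi" else "R")

    def source_size(self, leaf: int) -> int:
        """|s|: number of voxels of a source leaf (source hemisphere)."""
        return len(self._voxels[(leaf, "L")])

    def target_size(self, target: tuple[int, str]) -> int:
        """|t|: number of voxels of a target (leaf, side)."""
        return len(self.target_voxels(target))

    def leaf_at(self, position_um: np.ndarray) -> int | None:
        """Leaf id whose annotated voxel contains a physical position, else None."""
        idx = np.floor(np.asarray(position_um, dtype=float) / self.lattice.spacing_um).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.array(self.lattice.shape)):
            return None
        label = int(self.annotation[tuple(idx)])
        return label if label in set(self.leaf_ids) else None


def load_ontology(path, annotation: np.ndarray, lattice: VoxelLattice) -> RegionOntology:
    """Read a structure graph (Allen structure-graph JSON dialect) and bind it
    to an annotation volume.

    The JSON is either a list of records or ``{"msg": [...]}``, each record
    carrying ``id``, ``acronym`` and ``parent_structure_id`` (null at the root).
    """
    with open(path) as fh:
        raw = json.load(fh)
    records = raw["msg"] if isinstance(raw, dict) and "msg" in raw else raw
    nodes: dict[int, Node] = {}
    for rec in records:
        nid = int(rec["id"])
        parent = rec.get("parent_structure_id")
        nodes[nid] = Node(nid, str(rec["acronym"]), None if parent is None else int(parent))
    for node in nodes.values():
        if node.parent_id is not None:
            if node.parent_id not in nodes:
                raise ValueError(
                    f"structure {node.id} ({node.acronym}) names parent "
                    f"{node.parent_id} which is not in the file"
                )
            nodes[node.parent_id].children.append(node.id)
    for node in nodes.values():
        node.children.sort()
    return RegionOntology(nodes, annotation, lattice)


def region_distance(
    voxels_a: np.ndarray,
    voxels_b: np.ndarray,
    spacing_um: float = DEFAULT_SPACING_UM,
    mode: str = "min_voxel",
) -> float:
    """Distance in μm between two voxel sets.

    ``centroid`` mode is the Euclidean distance between the mean voxel
    centres; ``min_voxel`` is the minimum pairwise voxel-centre distance.
    Both are symmetric and zero for a region against itself.
    """
    a = np.atleast_2d(np.asarray(voxels_a, dtype=float))
    b = np.atleast_2d(np.asarray(voxels_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("region_distance requires non-empty regions")
    a = (a + 0.5) * spacing_um
    b = (b + 0.5) * spacing_um
    if mode == "centroid":
        return float(np.linalg.norm(a.mean(axis=0) - b.mean(axis=0)))
    if mode == "min_voxel":
        return float(cdist(a, b).min())
    raise ValueError(f"unknown distance mode {mode!r}")


def contralateral_target_count(n_sources: int, n_targets: int) -> int:
    """Number of contralateral targets implied by source/target leaf counts.

    Targets are the source-hemisphere leafs plus their mirrored counterparts,
    so the contralateral count is the total target count minus the source
    count (e.g. 1,123 targets against 564 sources leaves 559 contralateral).
    """
    if n_targets < n_sources:
        raise ValueError("target count cannot be smaller than source count")
    return int(n_targets) - int(n_sources)
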