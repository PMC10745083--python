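"""Synthetic tracing datasets with known ground-truth connectivity.

The generator embodies the modeling assumptions under test: projection
patterns vary *smoothly* with source position within a leaf but may change
*sharply* across leaf boundaries and between cell classes.  Each (class,
leaf) pair carries a sparse nonnegative target pattern P(v, l); the
ground-truth voxel connectivity is

    f_true(v, voxel, t) = P(v, leaf(voxel))[t] · g_leaf(position)

with g a smooth positive scalar field per leaf.  Simulated experiments drop a
truncated Gaussian injection blob in a leaf, read out the regionalized
ground truth at the injection centroid, and corrupt it with entrywise
multiplicative log-normal noise (emulating fluorescence-intensity
variability).  Injection blobs are normalized to unit total mass so the
noiseless readout equals f_true at the centroid exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .brain_model import Node, RegionOntology, VoxelLattice
from .tracer_data import Dataset, Experiment, compute_centroid, regionalize_sources

__all__ = [
    "GroundTruth",
    "make_brain",
    "sample_ground_truth",
    "simulate_experiments",
    "dense_design",
    "write_brain",
]

ROOT_ID = 1


def make_brain(
    n_major: int = 4,
    leafs_per_major: int = 3,
    leaf_shape_voxels: tuple[int, int, int] = (3, 3, 3),
    spacing_um: float = 100.0,
    seed: int = 0,
) -> tuple[VoxelLattice, RegionOntology]:
    """Axis-aligned block parcellation with two mirrored hemispheres.

    Leafs are stacked along the first axis (leafs of a major adjacent), the
    third axis is mirrored across the midline, and the ontology is a
    two-level tree root → majors → leafs.  Construction is deterministic;
    ``seed`` is accepted for interface uniformity.
    """
    lx, ly, lz = (int(n) for n in leaf_shape_voxels)
    if min(lx, ly, lz) < 1 or n_major < 1 or leafs_per_major < 1:
        raise ValueError("sizes must be positive")
    n_leafs = n_major * leafs_per_major
    shape = (n_leafs * lx, ly, 2 * lz)
    annotation = np.zeros(shape, dtype=int)

    nodes: dict[int, Node] = {ROOT_ID: Node(ROOT_ID, "root", None)}
    for m in range(n_major):
        mid = 100 + m
        nodes[mid] = Node(mid, f"MJ{m + 1}", ROOT_ID)
        nodes[ROOT_ID].children.append(mid)
        for j in range(leafs_per_major):
            leaf_idx = m * leafs_per_major + j
            lid = 1000 + 100 * m + j
            nodes[mid].children.append(lid)
            nodes[lid] = Node(lid, f"MJ{m + 1}L{j + 1}", mid)
            x0 = leaf_idx * lx
            annotation[x0:x0 + lx, :ly, :lz] = lid  # left hemisphere
            annotation[x0:x0 + lx, :ly, shape[2] - lz:] = lid  # mirrored

    lattice = VoxelLattice(shape, spacing_um, brain_mask=annotation != 0)
    return lattice, RegionOntology(nodes, annotation, lattice)


def write_brain(ontology: RegionOntology, json_path, annotation_path) -> None:
    """Write the structure graph (Allen-dialect JSON) and the annotation
    volume (compressed numpy container)."""
    records = [
        {"id": n.id, "acronym": n.acronym, "parent_structure_id": n.parent_id}
        for n in sorted(ontology.nodes.values(), key=lambda n: n.id)
    ]
    with open(json_path, "w") as fh:
        json.dump({"msg": records}, fh, indent=1)
    np.savez_compressed(
        annotation_path, annotation=ontology.annotation,
        spacing_um=ontology.lattice.spacing_um,
    )


@dataclass
class GroundTruth:
    """Known class-specific connectivity for scoring estimators."""

    ontology: RegionOntology
    classes: list[str]
    patterns: dict[tuple[str, int], np.ndarray]  # P(v, l): T-vector
    field_direction: dict[int, np.ndarray]  # unit 3-vector per leaf
    field_phase: dict[int, float]
    smoothness_scale_um: float

    def spatial_field(self, leaf: int, positions_um: np.ndarray) -> np.ndarray:
        """Smooth positive modulation g_leaf at physical positions (μm)."""
        pos = np.atleast_2d(np.asarray(positions_um, dtype=float))
        u = self.field_direction[leaf]
        return np.exp(np.sin(pos @ u / self.smoothness_scale_um + self.field_phase[leaf]))

    def f_true(self, v: str, position_um: np.ndarray, leaf: int | None = None) -> np.ndarray:
        """Regionalized ground-truth projection vector at one source position."""
        if leaf is None:
            leaf = self.ontology.leaf_at(position_um)
        if leaf is None:
            raise ValueError("position is outside the annotated leafs")
        g = float(self.spatial_field(leaf, position_um)[0])
        return self.patterns[(v, leaf)] * g

    def connectivity(self, v: str) -> np.ndarray:
        """True strength matrix C_true(v): row s sums f_true over voxels of s."""
        ont = self.ontology
        C = np.zeros((ont.n_sources, ont.n_targets))
        for si, leaf in enumerate(ont.source_leafs):
            pos = ont.lattice.positions_um(ont.voxels(leaf, "L"))
            C[si] = self.patterns[(v, leaf)] * self.spatial_field(leaf, pos).sum()
        return C


def sample_ground_truth(
    ontology: RegionOntology,
    n_classes: int = 3,
    pattern_sparsity: float = 0.5,
    class_effect: float = 1.0,
    smoothness_scale_um: float = 1000.0,
    seed: int = 0,
) -> GroundTruth:
    """Draw sparse per-(class, leaf) target patterns and smooth spatial fields.

    Each leaf gets a base pattern: a Bernoulli(1 − sparsity) support over
    targets with Gamma-distributed positive weights, normalized to unit sum
    (a sparse Dirichlet draw).  Class v perturbs the base multiplicatively by
    exp(class_effect · z) with z standard normal, so ``class_effect = 0``
    makes all classes share the base pattern and larger values drive the
    class patterns apart.  The spatial field is a sinusoid of the position
    along a random direction, scaled by ``smoothness_scale_um``: an infinite
    scale makes f_true constant within each leaf.
    """
    if pattern_sparsity < 0 or pattern_sparsity >= 1:
        raise ValueError("pattern_sparsity must lie in [0, 1)")
    if class_effect < 0 or smoothness_scale_um <= 0:
        raise ValueError("class_effect must be >= 0 and smoothness_scale_um > 0")
    rng = np.random.default_rng(seed)
    classes = ["wt"] + [f"C{k}" for k in range(1, n_classes)]
    T = ontology.n_targets
    patterns: dict[tuple[str, int], np.ndarray] = {}
    direction: dict[int, np.ndarray] = {}
    phase: dict[int, float] = {}
    for leaf in ontology.leaf_ids:
        support = rng.random(T) >= pattern_sparsity
        if not support.any():
            support[rng.integers(T)] = True
        base = np.where(support, rng.gamma(2.0, 1.0, size=T), 0.0)
        base /= base.sum()
        for v in classes:
            z = rng.standard_normal(T)
            p = base * np.exp(class_effect * z)
            patterns[(v, leaf)] = p / p.sum()
        u = rng.standard_normal(3)
        direction[leaf] = u / np.linalg.norm(u)
        phase[leaf] = float(rng.uniform(0, 2 * np.pi))
    return GroundTruth(ontology, classes, patterns, direction, phase, float(smoothness_scale_um))


def dense_design(
    gt: GroundTruth, n_per_cell: int, classes: list[str] | None = None
) -> list[tuple[str, int, int]]:
    """A (class, leaf, n) design covering every source leaf for every class."""
    classes = classes if classes is not None else gt.classes
    return [(v, leaf, n_per_cell) for v in classes for leaf in gt.ontology.source_leafs]


def simulate_experiments(
    gt: GroundTruth,
    design: list[tuple[str, int, int]],
    noise_sd: float = 0.2,
    seed: int = 0,
    injection_sd_voxels: float = 1.5,
    store_volumes: bool = False,
) -> Dataset:
    """Simulate tracing experiments from a (class, leaf, n) design table.

    Per experiment: the blob centre is sampled uniformly over the leaf's
    voxel interior; the injection is a Gaussian blob (sd 1.5 voxels)
    truncated to the leaf and normalized to unit mass, so the centroid is
    unambiguous and inside the leaf; the regionalized projection is
    y_T = f_true(v, centroid) ⊙ exp(N(0, noise_sd)) entrywise.
    """
    ont = gt.ontology
    rng = np.random.default_rng(seed)
    leaf_set = set(ont.source_leafs)
    classes = set(gt.classes)
    experiments: list[Experiment] = []
    k = 0
    for v, leaf, n in design:
        if leaf not in leaf_set:
            raise ValueError(f"design references unknown source leaf {leaf}")
        if v not in classes:
            raise ValueError(f"design references unknown class {v!r}")
        vox = ont.voxels(leaf, "L")
        for _ in range(int(n)):
            center_idx = vox[rng.integers(len(vox))] + rng.uniform(0.25, 0.75, size=3)
            center_um = center_idx * ont.lattice.spacing_um
            pos = ont.lattice.positions_um(vox)
            d2 = np.sum((pos - center_um) ** 2, axis=1)
            blob = np.exp(-d2 / (2 * (injection_sd_voxels * ont.lattice.spacing_um) ** 2))
            field = np.zeros(ont.lattice.shape)
            field[tuple(vox.T)] = blob / blob.sum()
            centroid = compute_centroid(field, ont.lattice)
            y = gt.f_true(v, centroid, leaf=leaf)
            if noise_sd > 0:
                y = y * np.exp(rng.normal(0.0, noise_sd, size=y.shape))
            experiments.append(Experiment(
                id=f"sim{k:05d}",
                cell_class=v,
                centroid_um=centroid,
                regionalized=y,
                injection=field if store_volumes else None,
                n_injection_voxels=int(len(vox)),
                regionalized_injection=regionalize_sources(field, ont),
            ))
            k += 1
    return Dataset(experiments, ont)
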