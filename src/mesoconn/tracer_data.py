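"""Tracing-experiment representation and regionalization.

Each anterograde tracing experiment *i* carries a cell-class label v(i) (the
Cre-line × transgene combination; wild type is one class), an injection
signal x(i) and a projection signal y(i) over the voxel lattice, an injection
centroid c(i) (signal-weighted mean position), and the regionalized
projection y_T(i): the projection signal summed within each target leaf,
ipsilateral and contralateral targets counted separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .brain_model import RegionOntology, VoxelLattice

__all__ = [
    "Experiment",
    "Dataset",
    "compute_centroid",
    "regionalize",
    "regionalize_sources",
    "normalize_experiment",
    "apply_detection_limit",
    "fit_detection_limit",
    "read_manifest",
    "write_manifest",
    "write_regionalized_table",
]

log = logging.getLogger(__name__)

NORMALIZATION_MODES = ("total_projection", "injection_volume", "none")


@dataclass(frozen=True)
class Experiment:
    """One tracing experiment: class label, centroid and regionalized projection."""

    id: str
    cell_class: str
    centroid_um: np.ndarray  # (3,)
    regionalized: np.ndarray  # y_T, (T,)
    injection: np.ndarray | None = None  # voxel field x(i), optional
    projection: np.ndarray | None = None  # voxel field y(i), optional
    n_injection_voxels: int = 0
    regionalized_injection: np.ndarray | None = None  # x_S over source leafs, (S,)

    def __post_init__(self):
        object.__setattr__(self, "centroid_um", np.asarray(self.centroid_um, dtype=float))
        object.__setattr__(self, "regionalized", np.asarray(self.regionalized, dtype=float))
        if np.any(self.regionalized < 0):
            raise ValueError(f"experiment {self.id}: regionalized projection has negative entries")


def compute_centroid(injection: np.ndarray, lattice: VoxelLattice) -> np.ndarray:
    """Signal-weighted mean of voxel-centre positions (μm) of an injection field."""
    field = np.asarray(injection, dtype=float)
    if np.any(field < 0):
        raise ValueError("injection field must be nonnegative")
    total = field.sum()
    if total <= 0:
        raise ValueError("cannot compute centroid of an all-zero injection field")
    idx = np.argwhere(field > 0)
    weights = field[tuple(idx.T)]
    return (weights[:, None] * lattice.positions_um(idx)).sum(axis=0) / total


def regionalize(field: np.ndarray, ontology: RegionOntology) -> np.ndarray:
    """Sum a voxel field within each target (leaf × hemisphere) -> T-vector."""
    field = np.asarray(field, dtype=float)
    out = np.empty(ontology.n_targets)
    for j, target in enumerate(ontology.targets):
        vox = ontology.target_voxels(target)
        out[j] = field[tuple(vox.T)].sum() if len(vox) else 0.0
    return out


def regionalize_sources(field: np.ndarray, ontology: RegionOntology) -> np.ndarray:
    """Sum a voxel field within each source leaf (source hemisphere) -> S-vector."""
    field = np.asarray(field, dtype=float)
    out = np.empty(ontology.n_sources)
    for j, leaf in enumerate(ontology.source_leafs):
        vox = ontology.voxels(leaf, "L")
        out[j] = field[tuple(vox.T)].sum() if len(vox) else 0.0
    return out


def normalize_experiment(e: Experiment, mode: str = "total_projection") -> Experiment:
    """Rescale y_T so the chosen normalizer equals one.

    ``total_projection`` divides by the sum of y_T; ``injection_volume``
    divides by the number of injection voxels; ``none`` is the identity.
    """
    if mode not in NORMALIZATION_MODES:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if mode == "none":
        return e
    if mode == "total_projection":
        norm = e.regionalized.sum()
    else:
        norm = float(e.n_injection_voxels)
    if norm <= 0:
        raise ValueError(f"experiment {e.id}: zero normalizer for mode {mode!r}")
    return replace(e, regionalized=e.regionalized / norm)


def apply_detection_limit(y: np.ndarray, epsilon: float) -> np.ndarray:
    """Zero out entries below the lower limit of detection. Idempotent."""
    if epsilon < 0:
        raise ValueError("detection limit must be nonnegative")
    y = np.asarray(y, dtype=float)
    return np.where(y < epsilon, 0.0, y)


def fit_detection_limit(Y: np.ndarray, percentile: float = 5.0) -> float:
    """Detection limit as a percentile of the positive regionalized entries."""
    pos = np.asarray(Y, dtype=float)
    pos = pos[pos > 0]
    if pos.size == 0:
        return 0.0
    return float(np.percentile(pos, percentile))


class Dataset:
    """A collection of experiments with deterministic index-set bookkeeping.

    Index sets are recomputed from centroids and class labels: I_l (centroid
    in leaf l), I_m (centroid in major structure m), I_v (class v).
    Experiments whose centroid falls outside the annotated leafs are excluded
    with a logged warning.
    """

    def __init__(self, experiments: list[Experiment], ontology: RegionOntology):
        self.ontology = ontology
        kept, leaves = [], []
        for e in experiments:
            leaf = ontology.leaf_at(e.centroid_um)
            if leaf is None:
                log.warning("experiment %s: centroid outside annotated leafs; excluded", e.id)
                continue
            kept.append(e)
            leaves.append(leaf)
        self.experiments: list[Experiment] = kept
        self.leaf: np.ndarray = np.array(leaves, dtype=int) if kept else np.empty(0, dtype=int)
        self.major: np.ndarray = np.array([ontology.major_of(l) for l in self.leaf], dtype=int)
        self.cell_class: np.ndarray = np.array([e.cell_class for e in kept])
        self.centroids: np.ndarray = (
            np.stack([e.centroid_um for e in kept]) if kept else np.empty((0, 3))
        )
        self.Y: np.ndarray = (
            np.stack([e.regionalized for e in kept])
            if kept else np.empty((0, ontology.n_targets))
        )

    def __len__(self) -> int:
        return len(self.experiments)

    @property
    def classes(self) -> list[str]:
        return sorted({str(v) for v in self.cell_class})

    # -- index sets (boolean masks over experiments) --------------------------

    def in_leaf(self, leaf: int) -> np.ndarray:
        return self.leaf == leaf

    def in_major(self, major: int) -> np.ndarray:
        return self.major == major

    def of_class(self, v: str) -> np.ndarray:
        return self.cell_class == v

    def subset(self, mask: np.ndarray) -> "Dataset":
        sub = Dataset.__new__(Dataset)
        sub.ontology = self.ontology
        mask = np.asarray(mask, dtype=bool)
        sub.experiments = [e for e, m in zip(self.experiments, mask) if m]
        sub.leaf = self.leaf[mask]
        sub.major = self.major[mask]
        sub.cell_class = self.cell_class[mask]
        sub.centroids = self.centroids[mask]
        sub.Y = self.Y[mask]
        return sub

    def drop(self, i: int) -> "Dataset":
        mask = np.ones(len(self), dtype=bool)
        mask[i] = False
        return self.subset(mask)

    def normalized(self, mode: str) -> "Dataset":
        return Dataset([normalize_experiment(e, mode) for e in self.experiments], self.ontology)

    def with_detection_limit(self, epsilon: float) -> "Dataset":
        exps = [
            replace(e, regionalized=apply_detection_limit(e.regionalized, epsilon))
            for e in self.experiments
        ]
        return Dataset(exps, self.ontology)


# -- on-disk exchange ---------------------------------------------------------

MANIFEST_COLUMNS = [
    "id", "cell_class", "centroid_x_um", "centroid_y_um", "centroid_z_um",
    "injection_path", "projection_path",
]


def write_manifest(dataset: Dataset, path) -> None:
    rows = []
    for e in dataset.experiments:
        rows.append({
            "id": e.id, "cell_class": e.cell_class,
            "centroid_x_um": e.centroid_um[0],
            "centroid_y_um": e.centroid_um[1],
            "centroid_z_um": e.centroid_um[2],
            "injection_path": "", "projection_path": "",
        })
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)


def write_regionalized_table(dataset: Dataset, path) -> None:
    """Experiments × target-leaf table of regionalized projections (TSV)."""
    df = pd.DataFrame(
        dataset.Y,
        index=[e.id for e in dataset.experiments],
        columns=dataset.ontology.target_labels(),
    )
    df.index.name = "id"
    df.to_csv(path, sep="\t")


def read_manifest(manifest_path, regionalized_path, ontology: RegionOntology) -> Dataset:
    """Load a dataset from a manifest TSV plus a regionalized-projection table."""
    man = pd.read_csv(manifest_path, sep="\t", dtype={"id": str})
    reg = pd.read_csv(regionalized_path, sep="\t", index_col="id")
    reg.index = reg.index.astype(str)
    labels = ontology.target_labels()
    if list(reg.columns) != labels:
        raise ValueError("regionalized table columns do not match ontology targets")
    exps = []
    for _, row in man.iterrows():
        exps.append(Experiment(
            id=row["id"],
            cell_class=row["cell_class"],
            centroid_um=np.array([row["centroid_x_um"], row["centroid_y_um"], row["centroid_z_um"]]),
            regionalized=reg.loc[row["id"]].to_numpy(dtype=float),
        ))
    return Dataset(exps, ontology)
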