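"""Class-specific regionalized connectivity matrices and derived products.

The regionalized connectivity strength from source leaf s to target t for
class v sums the voxel-level prediction over the source's voxels:

    C(v, s, t)   = Σ_{l_s ∈ s} f̂(l_s or s, v)[t]
    C_N(v, s, t) = C(v, s, t) / |s|          (normalized strength)
    C_D(v, s, t) = C(v, s, t) / (|s| · |t|)  (projection density)

where |s| and |t| are voxel counts.  Rows are estimated only where the class
has at least one injection centroid in the source leaf; elsewhere they are
*missing* (NaN), which is distinct from an estimated zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .brain_model import RegionOntology, region_distance
from .estimators import EstimatorModel
from .tracer_data import Dataset

__all__ = [
    "ConnectivityTensor",
    "build_connectivity",
    "build_tensor",
    "normalize_connectivity",
    "cre_average_matrix",
    "top_targets",
    "distal_mask",
    "write_wide_csv",
    "write_long_tsv",
]

VARIANTS = ("strength", "normalized", "density")


def build_connectivity(
    model: EstimatorModel,
    d: Dataset,
    ontology: RegionOntology,
    v: str,
    mode: str = "structure",
    require_class_centroid: bool = True,
) -> np.ndarray:
    """S×T connectivity strength matrix for one class (NaN rows = missing).

    ``structure`` mode evaluates one structure-level prediction per source
    leaf — the voxel-average of f̂ over the leaf — and multiplies by |s|;
    ``voxel`` mode sums f̂ over each source voxel explicitly.  NNLS already
    predicts at the structure level, so both modes coincide for it.
    """
    if mode not in ("structure", "voxel"):
        raise ValueError(f"unknown mode {mode!r}")
    S, T = ontology.n_sources, ontology.n_targets
    C = np.full((S, T), np.nan)
    for si, leaf in enumerate(ontology.source_leafs):
        has_class = (d.in_leaf(leaf) & d.of_class(v)).any()
        if require_class_centroid and not has_class:
            continue
        if model.kind == "nnls":
            rows = model.nnls_rows or {}
            if leaf in rows:
                C[si] = rows[leaf]
            continue
        if not d.in_leaf(leaf).any():
            continue
        vox = ontology.voxels(leaf, "L")
        positions = ontology.lattice.positions_um(vox)
        if mode == "voxel":
            acc = np.zeros(T)
            ok = True
            for pos in positions:
                pred = model.predict(pos, v, d, leaf=leaf)
                if pred is None:
                    ok = False
                    break
                acc += pred
            if ok:
                C[si] = acc
        else:
            preds = [model.predict(pos, v, d, leaf=leaf) for pos in positions]
            if all(p is not None for p in preds):
                C[si] = len(vox) * np.mean(np.stack(preds), axis=0)
    return C


@dataclass
class ConnectivityTensor:
    """Class × source × target connectivity with missing-value semantics."""

    values: np.ndarray  # (V, S, T), NaN = missing
    classes: list[str]
    source_leafs: list[int]
    targets: list[tuple[int, str]]
    variant: str = "strength"
    provenance: np.ndarray | None = None  # (V, S) experiment counts

    def matrix(self, v: str) -> np.ndarray:
        return self.values[self.classes.index(v)]


def build_tensor(
    model: EstimatorModel,
    d: Dataset,
    ontology: RegionOntology,
    classes: list[str] | None = None,
    mode: str = "structure",
) -> ConnectivityTensor:
    """Stack per-class connectivity matrices, recording per-(class, source)
    experiment counts as provenance."""
    classes = list(classes) if classes is not None else d.classes
    model.fit(d)
    mats, prov = [], []
    for v in classes:
        mats.append(build_connectivity(model, d, ontology, v, mode=mode))
        prov.append([
            int((d.in_leaf(leaf) & d.of_class(v)).sum()) for leaf in ontology.source_leafs
        ])
    return ConnectivityTensor(
        values=np.stack(mats), classes=classes,
        source_leafs=list(ontology.source_leafs), targets=list(ontology.targets),
        provenance=np.array(prov),
    )


def normalize_connectivity(C: np.ndarray, ontology: RegionOntology, variant: str) -> np.ndarray:
    """Convert a strength matrix to normalized strength or density.

    Missing entries stay missing; ``strength`` is the identity.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    C = np.asarray(C, dtype=float)
    if variant == "strength":
        return C.copy()
    s_sizes = np.array([ontology.source_size(leaf) for leaf in ontology.source_leafs], dtype=float)
    out = C / s_sizes[:, None]
    if variant == "density":
        t_sizes = np.array([ontology.target_size(t) for t in ontology.targets], dtype=float)
        out = out / t_sizes[None, :]
    return out


def cre_average_matrix(tensor: ConnectivityTensor) -> np.ndarray:
    """Entrywise mean over classes, ignoring missing entries; rows missing in
    every class stay missing."""
    with np.errstate(invalid="ignore"):
        counts = np.sum(~np.isnan(tensor.values), axis=0)
        out = np.where(counts > 0, np.nansum(tensor.values, axis=0), np.nan)
        return np.divide(out, counts, out=out, where=counts > 0)


def top_targets(row: np.ndarray, percentile: float = 90.0) -> np.ndarray:
    """Indices of targets at or above the p-th percentile of a row's weights
    (ties at the cut included); p = 0 returns every target."""
    row = np.asarray(row, dtype=float)
    finite = row[~np.isnan(row)]
    if finite.size == 0:
        raise ValueError("cannot take top targets of an empty/missing row")
    if not 0.0 <= percentile < 100.0:
        raise ValueError("percentile must lie in [0, 100)")
    cut = np.percentile(finite, percentile)
    return np.flatnonzero(~np.isnan(row) & (row >= cut))


def distal_mask(
    ontology: RegionOntology, threshold_um: float = 1500.0, mode: str = "min_voxel"
) -> np.ndarray:
    """S×T boolean mask keeping source-target pairs at least ``threshold_um``
    apart; pairs strictly closer are masked out (short-range injection-site
    and traveling-fiber artifacts)."""
    if threshold_um < 0:
        raise ValueError("threshold must be nonnegative")
    S, T = ontology.n_sources, ontology.n_targets
    keep = np.zeros((S, T), dtype=bool)
    spacing = ontology.lattice.spacing_um
    src_vox = [ontology.voxels(leaf, "L") for leaf in ontology.source_leafs]
    tgt_vox = [ontology.target_voxels(t) for t in ontology.targets]
    for i in range(S):
        for j in range(T):
            dist = region_distance(src_vox[i], tgt_vox[j], spacing, mode=mode)
            keep[i, j] = dist >= threshold_um
    return keep


# -- writers --------------------------------------------------------------------


def _frame(C: np.ndarray, ontology: RegionOntology) -> pd.DataFrame:
    return pd.DataFrame(
        C,
        index=[f"{ontology.acronym(l)}-L" for l in ontology.source_leafs],
        columns=ontology.target_labels(),
    )


def write_wide_csv(C: np.ndarray, ontology: RegionOntology, path, log10: bool = False) -> None:
    """Wide CSV, one row per source leaf; missing entries are empty fields,
    never zeros.  ``log10`` is a display transform for plotting only."""
    df = _frame(C, ontology)
    if log10:
        with np.errstate(divide="ignore"):
            df = np.log10(df)
    df.index.name = "source"
    df.to_csv(path, na_rep="")


def write_long_tsv(tensor: ConnectivityTensor, ontology: RegionOntology, path) -> None:
    """Long TSV: class, source, target, variant, value, n_experiments, with a
    missing flag instead of fabricated zeros."""
    rows = []
    labels = ontology.target_labels()
    for vi, v in enumerate(tensor.classes):
        for si, leaf in enumerate(tensor.source_leafs):
            n = int(tensor.provenance[vi, si]) if tensor.provenance is not None else 0
            for ti, label in enumerate(labels):
                val = tensor.values[vi, si, ti]
                rows.append({
                    "cell_class": v,
                    "source": f"{ontology.acronym(leaf)}-L",
                    "target": label,
                    "variant": tensor.variant,
                    "value": "" if np.isnan(val) else repr(float(val)),
                    "missing": int(np.isnan(val)),
                    "n_experiments": n,
                })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
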