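"""Connectivity estimators: NNLS, Nadaraya-Watson, Cre-NW and the
expected-loss (EL) estimator.

All four predict the regionalized projection vector y_T at a source location.
The NNLS baseline is a linear model from regionalized injection to
regionalized projection, fit per major structure.  The Nadaraya-Watson (NW)
family are kernel-weighted local averages of training projections:

* NW smooths over 3D centroid position only, using every experiment in the
  major structure regardless of class.
* Cre-NW restricts the support to same-class experiments in the source leaf,
  so it fills spatial gaps within a class but cannot fill class gaps.
* EL shares information *between* classes: it blends the class-leaf mean
  projection m(v, l) with a product-kernel regression over all experiments in
  the leaf, where each experiment is weighted both by spatial proximity of
  its centroid and by proximity of its cell class in an abstract class space
  (classes embedded by their averaged regionalized projections):

      f̂_EL(loc, v) = α · m(v, l) + (1 − α) · g(loc, v, l)
      g = Σ_i K(‖loc − c(i)‖ / σ_x) K(d_V(v, v_i) / σ_c) y_T(i) / Σ_i (·)

  with Gaussian kernels K(u) = exp(−u²/2).  α weighs the regionally averaged
  cell-class projection against centroid position.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls as _scipy_nnls

from .tracer_data import Dataset

_log = logging.getLogger(__name__)

__all__ = [
    "ClassSpace",
    "EstimatorModel",
    "build_class_space",
    "gaussian_weights",
    "nw_predict",
    "cre_nw_predict",
    "el_predict",
    "class_leaf_mean",
    "nnls_fit",
    "nnls_predict_rows",
]

ESTIMATOR_KINDS = ("nnls", "nw", "cre_nw", "el")


def gaussian_weights(distances: np.ndarray, sigma: float) -> np.ndarray:
    """Stable Gaussian kernel weights exp(−(d/σ)²/2), shifted so the largest
    weight is exactly 1 (the shift cancels in Nadaraya-Watson ratios and
    avoids underflow at small bandwidths)."""
    if sigma <= 0:
        raise ValueError("kernel bandwidth must be positive")
    z = 0.5 * (np.asarray(distances, dtype=float) / sigma) ** 2
    return np.exp(-(z - z.min()))


@dataclass
class ClassSpace:
    """Embedding of cell classes by their mean normalized regionalized
    projections, with a distance between classes."""

    classes: list[str]
    global_embedding: dict[str, np.ndarray]
    leaf_embedding: dict[tuple[str, int], np.ndarray]
    metric: str = "cosine"

    def distance(self, v: str, w: str) -> float:
        """d_V(v, w): 1 − cosine similarity (or Euclidean) of global embeddings."""
        if v == w:
            return 0.0
        a, b = self.global_embedding[v], self.global_embedding[w]
        if self.metric == "euclidean":
            return float(np.linalg.norm(a - b))
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0 or nb == 0:
            return 0.0 if (na == nb) else 1.0
        return float(np.clip(1.0 - a @ b / (na * nb), 0.0, 2.0))

    def distances_to(self, v: str, others: np.ndarray) -> np.ndarray:
        return np.array([self.distance(v, w) for w in others])


def build_class_space(d: Dataset, metric: str = "cosine") -> ClassSpace:
    """Embed every class by its mean y_T, globally and per leaf."""
    if len(d) == 0:
        raise ValueError("cannot build a class space from an empty dataset")
    global_emb: dict[str, np.ndarray] = {}
    leaf_emb: dict[tuple[str, int], np.ndarray] = {}
    for v in d.classes:
        mask = d.of_class(v)
        if not mask.any():
            raise ValueError(f"class {v!r} has no experiments")
        global_emb[v] = d.Y[mask].mean(axis=0)
        for leaf in np.unique(d.leaf[mask]):
            leaf_emb[(v, int(leaf))] = d.Y[mask & d.in_leaf(int(leaf))].mean(axis=0)
    return ClassSpace(d.classes, global_emb, leaf_emb, metric)


def nw_predict(
    loc: np.ndarray, centroids: np.ndarray, Y: np.ndarray, sigma_x: float
) -> np.ndarray | None:
    """Nadaraya-Watson prediction at a location from a support set.

    Returns the kernel-weighted average of the support's y_T vectors — a
    convex combination — or None when the support is empty (the caller marks
    the entry missing).
    """
    if len(Y) == 0:
        return None
    dists = np.linalg.norm(np.asarray(centroids, dtype=float) - np.asarray(loc, dtype=float), axis=1)
    w = gaussian_weights(dists, sigma_x)
    return (w[:, None] * Y).sum(axis=0) / w.sum()


def cre_nw_predict(
    loc: np.ndarray, v: str, d: Dataset, sigma_x: float, leaf: int | None = None
) -> np.ndarray | None:
    """Class-restricted NW: support is the same-class experiments in the leaf
    containing ``loc`` (I_l ∩ I_v); None if the class is absent from the leaf."""
    if leaf is None:
        leaf = d.ontology.leaf_at(loc)
    if leaf is None:
        return None
    mask = d.in_leaf(leaf) & d.of_class(v)
    return nw_predict(loc, d.centroids[mask], d.Y[mask], sigma_x)


def class_leaf_mean(d: Dataset, space: ClassSpace, v: str, leaf: int) -> np.ndarray | None:
    """m(v, l): mean class-v projection in leaf l, falling back to the global
    class mean, then the all-class leaf mean."""
    if (v, leaf) in space.leaf_embedding:
        return space.leaf_embedding[(v, leaf)]
    if v in space.global_embedding:
        return space.global_embedding[v]
    mask = d.in_leaf(leaf)
    if mask.any():
        return d.Y[mask].mean(axis=0)
    return None


def el_predict(
    loc: np.ndarray,
    v: str,
    d: Dataset,
    space: ClassSpace,
    sigma_x: float,
    sigma_c: float,
    alpha: float,
    leaf: int | None = None,
) -> np.ndarray | None:
    """Expected-loss prediction: α·m(v, l) + (1 − α)·g(loc, v, l).

    The kernel term g runs over *all* experiments with centroids in the leaf,
    down-weighting those of dissimilar classes via the class-space distance.
    None when the leaf holds no experiments.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if leaf is None:
        leaf = d.ontology.leaf_at(loc)
    if leaf is None:
        return None
    mask = d.in_leaf(leaf)
    if not mask.any():
        return None
    m = class_leaf_mean(d, space, v, leaf)
    g = _el_kernel_term(loc, v, d, space, sigma_x, sigma_c, mask)
    return alpha * m + (1.0 - alpha) * g


def _el_kernel_term(loc, v, d: Dataset, space: ClassSpace, sigma_x, sigma_c, mask) -> np.ndarray:
    cents, Y, classes = d.centroids[mask], d.Y[mask], d.cell_class[mask]
    if sigma_x <= 0 or sigma_c <= 0:
        raise ValueError("kernel bandwidths must be positive")
    dx = np.linalg.norm(cents - np.asarray(loc, dtype=float), axis=1)
    dc = space.distances_to(v, classes)
    z = 0.5 * ((dx / sigma_x) ** 2 + (dc / sigma_c) ** 2)
    w = np.exp(-(z - z.min()))
    return (w[:, None] * Y).sum(axis=0) / w.sum()


def nnls_fit(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Solve min ‖X W − Y‖² s.t. W ≥ 0 column by column (scipy NNLS).

    Rows of X are regionalized injections (n × S), rows of Y regionalized
    projections (n × T).  An all-zero column of X yields a zero row of W with
    a warning, since that source carries no information.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if np.any(X < 0) or np.any(Y < 0):
        raise ValueError("NNLS inputs must be nonnegative")
    S, T = X.shape[1], Y.shape[1]
    W = np.zeros((S, T))
    dead = np.flatnonzero(X.sum(axis=0) == 0)
    if dead.size:
        _log.warning(
            "NNLS: %d source column(s) are all-zero; their rows are set to 0", dead.size
        )
    live = np.flatnonzero(X.sum(axis=0) > 0)
    Xl = X[:, live]
    for t in range(T):
        w, _ = _scipy_nnls(Xl, Y[:, t])
        W[live, t] = w
    return W


def nnls_predict_rows(d: Dataset, source_leafs: list[int]) -> dict[int, np.ndarray]:
    """Fit NNLS per major structure and return the predicted y_T row per
    source leaf (the model applied to that leaf's indicator injection)."""
    ont = d.ontology
    X_rows = []
    for e in d.experiments:
        if e.regionalized_injection is None:
            raise ValueError(f"experiment {e.id} lacks a regionalized injection (needed for NNLS)")
        X_rows.append(e.regionalized_injection)
    X = np.stack(X_rows) if X_rows else np.empty((0, ont.n_sources))
    rows: dict[int, np.ndarray] = {}
    leaf_index = {leaf: j for j, leaf in enumerate(ont.source_leafs)}
    for major in ont.major_ids:
        mask = d.in_major(major)
        if not mask.any():
            continue
        # per-major fit over that major's source columns only (I_m / I_m)
        cols = [leaf_index[l] for l in ont.source_leafs if ont.major_of(l) == major]
        W = nnls_fit(X[np.ix_(mask, cols)], d.Y[mask])
        for wi, l in enumerate(l for l in ont.source_leafs if ont.major_of(l) == major):
            if l in source_leafs:
                rows[l] = W[wi]
    return rows


@dataclass
class EstimatorModel:
    """A fitted connectivity predictor.

    Hyperparameters may be scalars or per-major-structure mappings (the
    selection procedure tunes them per major); α may additionally vary per
    (major, class).  ``fit`` precomputes the class space (and NNLS rows);
    ``predict`` evaluates f̂ at a location for a class.
    """

    kind: str
    sigma_x: float | dict = 1000.0
    sigma_c: float | dict = 1.0
    alpha: float | dict = 0.5
    normalization: str = "total_projection"
    class_metric: str = "cosine"
    class_space: ClassSpace | None = field(default=None, repr=False)
    nnls_rows: dict | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.kind not in ESTIMATOR_KINDS:
            raise ValueError(f"unknown estimator kind {self.kind!r}")

    def _param(self, value, major, v=None):
        if isinstance(value, dict):
            if v is not None and (major, v) in value:
                return value[(major, v)]
            return value.get(major, value.get(None))
        return value

    def fit(self, d: Dataset) -> "EstimatorModel":
        if self.kind in ("nw", "cre_nw", "el"):
            self.class_space = build_class_space(d, self.class_metric)
        if self.kind == "nnls":
            self.nnls_rows = nnls_predict_rows(d, list(d.ontology.source_leafs))
        return self

    def predict(self, loc: np.ndarray, v: str, d: Dataset, leaf: int | None = None) -> np.ndarray | None:
        """f̂ at a location for class v, using the kind's support policy."""
        ont = d.ontology
        if leaf is None:
            leaf = ont.leaf_at(np.asarray(loc, dtype=float))
        if leaf is None:
            return None
        major = ont.major_of(leaf)
        sx = self._param(self.sigma_x, major)
        if self.kind == "nnls":
            rows = self.nnls_rows or nnls_predict_rows(d, [leaf])
            return rows.get(leaf)
        if self.kind == "nw":
            mask = d.in_major(major)
            return nw_predict(loc, d.centroids[mask], d.Y[mask], sx)
        if self.kind == "cre_nw":
            return cre_nw_predict(loc, v, d, sx, leaf=leaf)
        space = self.class_space or build_class_space(d, self.class_metric)
        return el_predict(
            loc, v, d, space, sx,
            self._param(self.sigma_c, major),
            self._param(self.alpha, major, v),
            leaf=leaf,
        )

    # -- serialization --------------------------------------------------------

    def to_json(self) -> str:
        def enc(value):
            if isinstance(value, dict):
                out = {}
                for k, val in value.items():
                    if k is None:
                        out["__default__"] = val
                    elif isinstance(k, tuple):
                        out["|".join(map(str, k))] = val
                    else:
                        out[str(k)] = val
                return out
            return value
        return json.dumps({
            "kind": self.kind,
            "sigma_x": enc(self.sigma_x),
            "sigma_c": enc(self.sigma_c),
            "alpha": enc(self.alpha),
            "normalization": self.normalization,
            "class_metric": self.class_metric,
        }, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "EstimatorModel":
        raw = json.loads(text)

        def dec(value):
            if isinstance(value, dict):
                out = {}
                for k, val in value.items():
                    if k == "__default__":
                        out[None] = val
                        continue
                    parts = k.split("|")
                    key = tuple(int(p) if p.lstrip("-").isdigit() else p for p in parts)
                    out[key[0] if len(key) == 1 else key] = val
                return out
            return value

        return cls(
            kind=raw["kind"], sigma_x=dec(raw["sigma_x"]), sigma_c=dec(raw["sigma_c"]),
            alpha=dec(raw["alpha"]), normalization=raw["normalization"],
            class_metric=raw["class_metric"],
        )
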