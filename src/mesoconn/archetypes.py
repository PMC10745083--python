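"""Masked, L1-penalized nonnegative matrix factorization of connectivity
matrices, with rank selection and stability clustering of components.

Distal connectivity (source-target pairs farther than the proximity
threshold) is decomposed as C ≈ W H with W ∈ R_{≥0}^{S×q} ("weights") and
H ∈ R_{≥0}^{q×T} ("hidden units" — the archetypes), minimizing

    ½ ‖M ⊙ (C − W H)‖² + λ (‖H‖₁ + ‖W‖₁)

where M is a boolean mask selecting the modeled (distal) entries; masked
entries of C have no influence on the fit.  λ encourages sparse, more
interpretable components.  The solver is a mask-aware multiplicative update;
with the L1 term absorbed into the update denominators the objective is
non-increasing at every iteration.  Since NMF is sensitive to initialization,
archetypes are stabilized by clustering the components of many restarts and
taking element-wise medians of frequently recurring clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "ArchetypeDecomposition",
    "StabilityResult",
    "nmf_objective",
    "masked_sparse_nmf",
    "select_rank",
    "stability_archetypes",
]

_EPS = 1e-12


def nmf_objective(C: np.ndarray, M: np.ndarray, W: np.ndarray, H: np.ndarray, lam: float) -> float:
    """½‖M ⊙ (C − WH)‖² + λ(‖H‖₁ + ‖W‖₁)."""
    R = np.where(M, C - W @ H, 0.0)
    return float(0.5 * np.sum(R * R) + lam * (np.sum(np.abs(H)) + np.sum(np.abs(W))))


@dataclass
class ArchetypeDecomposition:
    """Result of one masked sparse NMF run.

    H rows are stored unit-L2-normalized with the scale absorbed into W, so
    W @ H is unchanged and archetypes are comparable across runs.
    """

    W: np.ndarray
    H: np.ndarray
    q: int
    lam: float
    mask: np.ndarray
    objective_trace: np.ndarray
    seed: int

    @property
    def objective(self) -> float:
        return float(self.objective_trace[-1])


def masked_sparse_nmf(
    C: np.ndarray,
    M: np.ndarray | None = None,
    q: int = 15,
    lam: float = 0.002,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> ArchetypeDecomposition:
    """Fit W, H ≥ 0 minimizing the masked sparse NMF objective.

    Multiplicative updates with λ folded into the denominators (the standard
    majorize-minimize step for the L1-penalized Frobenius objective), so the
    objective is monotonically non-increasing.  Iteration stops when the
    relative objective change drops below ``tol``.
    """
    C = np.asarray(C, dtype=float)
    if not np.all(np.isfinite(np.where(np.isnan(C), 0.0, C))):
        raise ValueError("non-finite values in input matrix")
    S, T = C.shape
    if M is None:
        M = ~np.isnan(C)
    M = np.asarray(M, dtype=bool) & ~np.isnan(C)
    if q < 1 or q > min(S, T):
        raise ValueError(f"rank q={q} must lie in [1, min(S, T)={min(S, T)}]")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    Cm = np.where(M, C, 0.0)
    if np.any(Cm < 0):
        raise ValueError("unmasked entries of C must be nonnegative")

    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(Cm[M].mean() if M.any() else 1.0, _EPS) / q)
    W = rng.uniform(0.1, 1.0, size=(S, q)) * scale
    H = rng.uniform(0.1, 1.0, size=(q, T)) * scale

    trace = [nmf_objective(Cm, M, W, H, lam)]
    Mf = M.astype(float)
    for _ in range(max_iter):
        WH = (W @ H) * Mf
        W *= (Cm @ H.T) / (WH @ H.T + lam + _EPS)
        WH = (W @ H) * Mf
        H *= (W.T @ Cm) / (W.T @ WH + lam + _EPS)
        obj = nmf_objective(Cm, M, W, H, lam)
        trace.append(obj)
        prev = trace[-2]
        if prev > 0 and (prev - obj) / prev < tol:
            break

    # absorb scale: unit-L2 H rows
    norms = np.linalg.norm(H, axis=1)
    nz = norms > 0
    H[nz] /= norms[nz, None]
    W[:, nz] *= norms[nz][None, :]
    return ArchetypeDecomposition(W, H, q, lam, M, np.asarray(trace), seed)


def select_rank(
    C: np.ndarray,
    M: np.ndarray | None = None,
    q_grid=(1, 2, 3, 4, 5, 6),
    holdout_fraction: float = 0.2,
    n_repeats: int = 10,
    seed: int = 0,
    lam: float = 0.002,
    max_iter: int = 500,
) -> int:
    """Choose the rank q by unsupervised cross-validation.

    Each repeat hides a random subset of the unmasked entries (they join the
    mask during fitting), fits each candidate rank, and scores the mean
    squared reconstruction error on the hidden entries; the q with the lowest
    mean held-out error wins, ties going to the smaller rank.
    """
    C = np.asarray(C, dtype=float)
    if M is None:
        M = ~np.isnan(C)
    M = np.asarray(M, dtype=bool) & ~np.isnan(C)
    if not 0.0 < holdout_fraction < 0.5:
        raise ValueError("holdout_fraction must lie in (0, 0.5)")
    q_grid = sorted(set(int(q) for q in q_grid))
    rng = np.random.default_rng(seed)
    obs = np.argwhere(M)
    n_hold = max(1, int(round(holdout_fraction * len(obs))))
    errors = np.zeros((len(q_grid), n_repeats))
    for r in range(n_repeats):
        hidden = obs[rng.choice(len(obs), size=n_hold, replace=False)]
        M_fit = M.copy()
        M_fit[tuple(hidden.T)] = False
        for qi, q in enumerate(q_grid):
            dec = masked_sparse_nmf(
                C, M_fit, q=q, lam=lam,
                seed=int(rng.integers(0, 2**31 - 1)), max_iter=max_iter,
            )
            R = C - dec.W @ dec.H
            errors[qi, r] = np.mean(R[tuple(hidden.T)] ** 2)
    return int(q_grid[int(np.argmin(errors.mean(axis=1)))])


@dataclass
class StabilityResult:
    """Clusters of NMF components pooled across replicate restarts."""

    clusters: list[np.ndarray]  # member H rows per cluster (deduped per replicate)
    frequencies: list[int]  # distinct replicates represented
    medians: np.ndarray = field(repr=False)  # element-wise medians, one per cluster
    top: np.ndarray = field(repr=False)  # top-k medians by frequency
    replicate_seeds: list[int] = field(default_factory=list)


def stability_archetypes(
    C: np.ndarray,
    M: np.ndarray | None = None,
    q: int = 15,
    lam: float = 0.002,
    n_replicates: int = 30,
    match_threshold: float = 0.3,
    top_k: int = 15,
    seed: int = 0,
    seeds: list[int] | None = None,
    max_iter: int = 1000,
) -> StabilityResult:
    """Stability-select archetypes across NMF restarts.

    All H rows from ``n_replicates`` runs (seeds ``seed+1 .. seed+R``) are
    pooled after unit normalization and clustered (average linkage, cosine
    distance, cut at ``match_threshold``).  Clusters are ranked by how many
    distinct replicates they draw on; each cluster's archetype is the
    element-wise median of its members, with at most one member per replicate
    (the one nearest the cluster mean).
    """
    if seeds is None:
        if n_replicates < 2:
            raise ValueError("need at least two replicates")
        seeds = [seed + 1 + r for r in range(n_replicates)]
    rows, owner = [], []
    for ri, s in enumerate(seeds):
        dec = masked_sparse_nmf(C, M, q=q, lam=lam, seed=s, max_iter=max_iter)
        for h in dec.H:
            norm = np.linalg.norm(h)
            if norm > 0:
                rows.append(h / norm)
                owner.append(ri)
    X = np.stack(rows)
    owner = np.array(owner)
    if len(X) == 1:
        labels = np.array([1])
    else:
        Z = linkage(X, method="average", metric="cosine")
        labels = fcluster(Z, t=match_threshold, criterion="distance")

    clusters, freqs, medians = [], [], []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        members, owners = X[idx], owner[idx]
        # keep one component per replicate: the one closest to the cluster mean
        center = members.mean(axis=0)
        keep = []
        for rep in np.unique(owners):
            cand = np.flatnonzero(owners == rep)
            keep.append(cand[np.argmin(np.linalg.norm(members[cand] - center, axis=1))])
        members = members[np.sort(np.asarray(keep))]
        clusters.append(members)
        freqs.append(len(np.unique(owners)))
        medians.append(np.median(members, axis=0))
    order = sorted(range(len(clusters)), key=lambda i: (-freqs[i], -len(clusters[i]), i))
    clusters = [clusters[i] for i in order]
    freqs = [freqs[i] for i in order]
    medians = np.stack([medians[i] for i in order])
    return StabilityResult(
        clusters=clusters, frequencies=freqs, medians=medians,
        top=medians[:top_k], replicate_seeds=list(seeds),
    )
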