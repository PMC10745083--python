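"""Model evaluation: weighted l2-loss, leave-one-out cross-validation and
hyperparameter selection.

The evaluation set is the collection of (leaf, class) cells with at least two
experiments.  For a prediction f̂ of a held-out experiment's regionalized
projection, the loss is the squared Euclidean distance
ℓ(y, ŷ) = ‖y − ŷ‖²; the overall score averages per-cell mean losses

    ℒ = (1/|SV|) Σ_{(s,v)} (1/|I_s ∩ I_v|) Σ_{i ∈ I_s ∩ I_v} ℓ_i,

so rare (leaf, class) combinations weigh as much as abundant ones.  All
data-dependent quantities (class space, class means, NNLS fits) are recomputed
on each leave-one-out training set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimators import (
    EstimatorModel,
    build_class_space,
    class_leaf_mean,
    gaussian_weights,
    _el_kernel_term,
)
from .tracer_data import Dataset

__all__ = [
    "l2_loss",
    "eval_set",
    "loocv_weighted_loss",
    "select_hyperparameters",
    "EvaluationReport",
]


def l2_loss(y: np.ndarray, yhat: np.ndarray) -> float:
    """Squared Euclidean distance Σ_t (y_t − ŷ_t)²."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    diff = y - yhat
    return float(diff @ diff)


def eval_set(d: Dataset) -> list[tuple[int, str]]:
    """All (leaf, class) cells with at least two experiments."""
    cells = []
    for leaf in np.unique(d.leaf):
        in_leaf = d.in_leaf(int(leaf))
        for v in sorted(set(d.cell_class[in_leaf])):
            if (in_leaf & d.of_class(v)).sum() >= 2:
                cells.append((int(leaf), v))
    return cells


@dataclass
class EvaluationReport:
    """Weighted LOOCV loss with per-cell and per-major breakdowns."""

    overall: float
    cells: pd.DataFrame  # columns: major, leaf, cell_class, n, mean_loss
    per_major: dict[int, float]

    def write(self, tsv_path, json_path=None) -> None:
        self.cells.to_csv(tsv_path, sep="\t", index=False)
        if json_path is not None:
            import json as _json
            with open(json_path, "w") as fh:
                _json.dump(
                    {"overall_weighted_loss": self.overall,
                     "per_major": {str(k): v for k, v in self.per_major.items()},
                     "n_cells": int(len(self.cells))},
                    fh, indent=2, sort_keys=True)


def _fallback_prediction(training: Dataset, v: str, leaf: int) -> np.ndarray:
    """Class-mean fallback chain for a missing held-out prediction; a zero
    vector only when the training set offers nothing at all."""
    space = build_class_space(training)
    m = class_leaf_mean(training, space, v, leaf)
    if m is None:
        m = np.zeros(training.ontology.n_targets)
    return m


def _held_out_prediction(model: EstimatorModel, training: Dataset, loc, v, leaf) -> np.ndarray:
    model.fit(training)
    pred = model.predict(loc, v, training, leaf=leaf)
    if pred is None:
        pred = _fallback_prediction(training, v, leaf)
    return pred


def loocv_weighted_loss(model: EstimatorModel, d: Dataset) -> EvaluationReport:
    """Leave-one-out weighted l2-loss of an estimator on a dataset.

    Each experiment of each evaluation cell is held out in turn; everything
    the model learns from data is refit on the remainder.  A missing
    prediction falls back to the class-mean chain rather than being dropped,
    so models with different coverage stay comparable.
    """
    cells = eval_set(d)
    if not cells:
        raise ValueError("evaluation set is empty (no (leaf, class) cell occurs twice)")
    rows = []
    for leaf, v in cells:
        members = np.flatnonzero(d.in_leaf(leaf) & d.of_class(v))
        losses = []
        for i in members:
            training = d.drop(int(i))
            pred = _held_out_prediction(model, training, d.centroids[i], v, leaf)
            losses.append(l2_loss(d.Y[i], pred))
        rows.append({
            "major": int(d.ontology.major_of(leaf)),
            "leaf": leaf,
            "cell_class": v,
            "n": int(len(members)),
            "mean_loss": float(np.mean(losses)),
        })
    cells_df = pd.DataFrame(rows)
    per_major = {
        int(m): float(g["mean_loss"].mean()) for m, g in cells_df.groupby("major")
    }
    return EvaluationReport(float(cells_df["mean_loss"].mean()), cells_df, per_major)


# -- hyperparameter selection --------------------------------------------------


def _precompute_folds(d: Dataset, kind: str):
    """Per held-out experiment, cache everything the kernel grids reuse:
    support distances, support projections, and (for EL) the class-leaf mean
    and class-space distances rebuilt without the held-out point."""
    folds = []
    for leaf, v in eval_set(d):
        members = np.flatnonzero(d.in_leaf(leaf) & d.of_class(v))
        for i in members:
            i = int(i)
            training = d.drop(i)
            major = int(d.ontology.major_of(leaf))
            loc = d.centroids[i]
            if kind == "nw":
                mask = training.in_major(major)
            elif kind == "cre_nw":
                mask = training.in_leaf(leaf) & training.of_class(v)
            else:  # el
                mask = training.in_leaf(leaf)
            fold = {
                "leaf": leaf, "v": v, "major": major, "y": d.Y[i],
                "cell": (leaf, v), "Ys": training.Y[mask],
                "dx": np.linalg.norm(training.centroids[mask] - loc, axis=1),
            }
            if kind == "el":
                space = build_class_space(training)
                fold["m"] = class_leaf_mean(training, space, v, leaf)
                fold["dc"] = space.distances_to(v, training.cell_class[mask])
            if fold["Ys"].shape[0] == 0:
                fold["fallback"] = _fallback_prediction(training, v, leaf)
            folds.append(fold)
    return folds


def _kernel_pred(fold, sigma_x) -> np.ndarray:
    if fold["Ys"].shape[0] == 0:
        return fold["fallback"]
    w = gaussian_weights(fold["dx"], sigma_x)
    return (w[:, None] * fold["Ys"]).sum(axis=0) / w.sum()


def _el_terms(fold, sigma_x, sigma_c) -> tuple[np.ndarray, np.ndarray]:
    z = 0.5 * ((fold["dx"] / sigma_x) ** 2 + (fold["dc"] / sigma_c) ** 2)
    w = np.exp(-(z - z.min()))
    g = (w[:, None] * fold["Ys"]).sum(axis=0) / w.sum()
    return fold["m"], g


def _weighted(cell_losses: dict) -> float:
    """Mean over cells of within-cell mean losses."""
    return float(np.mean([np.mean(v) for v in cell_losses.values()]))


def select_hyperparameters(
    kind: str,
    d: Dataset,
    sigma_x_grid=(100.0, 316.0, 1000.0, 3162.0, 10000.0),
    sigma_c_grid=(0.01, 0.1, 1.0, 10.0),
    alpha_grid=tuple(np.round(np.arange(0.0, 1.01, 0.1), 1)),
    normalization: str = "total_projection",
) -> EstimatorModel:
    """Grid-search hyperparameters by LOOCV weighted loss, per major structure.

    σ_x (and σ_c for EL) are selected per major; EL's blend weight α is
    selected per (major, class).  Ties break toward larger bandwidths
    (smoother fits) and larger α.  NNLS has no hyperparameters and is
    returned as-is.
    """
    if kind == "nnls":
        return EstimatorModel(kind="nnls", normalization=normalization)
    if not sigma_x_grid:
        raise ValueError("empty hyperparameter grid")
    folds = _precompute_folds(d, kind)
    if not folds:
        raise ValueError("evaluation set is empty; cannot select hyperparameters")
    majors = sorted({f["major"] for f in folds})

    if kind in ("nw", "cre_nw"):
        best: dict[int, tuple[float, float]] = {}
        for sx in sorted(sigma_x_grid):
            per_major_cells: dict[int, dict] = {m: {} for m in majors}
            for f in folds:
                loss = l2_loss(f["y"], _kernel_pred(f, sx))
                per_major_cells[f["major"]].setdefault(f["cell"], []).append(loss)
            for m in majors:
                score = _weighted(per_major_cells[m])
                if m not in best or score <= best[m][0]:  # ties -> larger sigma_x
                    best[m] = (score, sx)
        sigma_x = {m: best[m][1] for m in majors}
        sigma_x[None] = float(np.median(list(sigma_x.values())))
        return EstimatorModel(kind=kind, sigma_x=sigma_x, normalization=normalization)

    # EL: joint (sigma_x, sigma_c) per major with alpha per (major, class)
    if kind != "el":
        raise ValueError(f"unknown estimator kind {kind!r}")
    alpha_grid = np.asarray(sorted(alpha_grid), dtype=float)
    best_el: dict[int, tuple] = {}
    for sx in sorted(sigma_x_grid):
        for sc in sorted(sigma_c_grid):
            # losses per (major, class, cell) as a function of alpha
            tables: dict[tuple[int, str], dict] = {}
            for f in folds:
                if f["Ys"].shape[0] == 0:
                    preds = [f["fallback"]] * len(alpha_grid)
                else:
                    m, g = _el_terms(f, sx, sc)
                    preds = [a * m + (1 - a) * g for a in alpha_grid]
                losses = np.array([l2_loss(f["y"], p) for p in preds])
                tables.setdefault((f["major"], f["v"]), {}).setdefault(f["cell"], []).append(losses)
            # choose alpha per (major, class); ties -> larger alpha
            alpha_choice: dict[tuple[int, str], float] = {}
            chosen_cell_losses: dict[int, dict] = {m: {} for m in majors}
            for (m, v), cells in tables.items():
                curves = np.stack([np.mean(np.stack(ls), axis=0) for ls in cells.values()])
                mean_curve = curves.mean(axis=0)
                k = len(mean_curve) - 1 - int(np.argmin(mean_curve[::-1]))
                alpha_choice[(m, v)] = float(alpha_grid[k])
                for cell, ls in cells.items():
                    chosen_cell_losses[m][cell] = [row[k] for row in ls]
            for m in majors:
                score = _weighted(chosen_cell_losses[m])
                if m not in best_el or score <= best_el[m][0]:
                    best_el[m] = (score, sx, sc, {v: a for (mm, v), a in alpha_choice.items() if mm == m})
    sigma_x = {m: best_el[m][1] for m in majors}
    sigma_c = {m: best_el[m][2] for m in majors}
    alpha = {(m, v): a for m in majors for v, a in best_el[m][3].items()}
    sigma_x[None] = float(np.median(list(sigma_x.values())))
    sigma_c[None] = float(np.median(list(sigma_c.values())))
    alpha[None] = 0.5
    return EstimatorModel(
        kind="el", sigma_x=sigma_x, sigma_c=sigma_c, alpha=alpha,
        normalization=normalization,
    )
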