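"""End-to-end orchestration: simulate → regionalize → evaluate →
build-connectome → factorize, driven by a single TOML config.

Outputs are deterministic given the seed; every artifact names the hash of
the config that produced it (a leading ``# config_hash:`` comment on tabular
files, a ``config_hash`` key in JSON files), and a provenance record is
written alongside the results.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .archetypes import masked_sparse_nmf, select_rank, stability_archetypes
from .brain_model import RegionOntology, VoxelLattice, load_ontology
from .connectome import (
    build_tensor,
    cre_average_matrix,
    distal_mask,
    normalize_connectivity,
    write_long_tsv,
    write_wide_csv,
)
from .evaluation import loocv_weighted_loss, select_hyperparameters
from .synthetic import make_brain, sample_ground_truth, simulate_experiments, dense_design, write_brain
from .tracer_data import Dataset, fit_detection_limit, read_manifest, write_manifest, write_regionalized_table

__all__ = ["RunConfig", "run_pipeline", "load_brain"]

log = logging.getLogger(__name__)

_SCHEMA: dict[str, dict] = {
    "run": {"seed": 0, "log_level": "INFO", "out": "scratch/run"},
    "data": {"manifest": "", "regionalized": "", "ontology_json": "", "annotation": ""},
    "simulate": {
        "enabled": True, "n_major": 2, "leafs_per_major": 2,
        "leaf_shape_voxels": [3, 3, 3], "n_classes": 3, "pattern_sparsity": 0.5,
        "class_effect": 1.0, "smoothness_scale_um": 1000.0, "n_per_cell": 3,
        "noise_sd": 0.2, "spacing_um": 100.0,
    },
    "estimator": {
        "kind": "el", "normalization": "total_projection",
        "sigma_x_grid": [50.0, 100.0, 200.0, 400.0, 800.0],
        "sigma_c_grid": [0.01, 0.1, 1.0, 10.0],
        "alpha_grid": [0.0, 0.25, 0.5, 0.75, 1.0],
        "detection_limit": "none", "mode": "structure",
    },
    "mask": {"threshold_um": 1500.0, "mode": "min_voxel"},
    "nmf": {
        "q": 3, "q_grid": [1, 2, 3, 4, 5, 6], "lambda": 0.002, "replicates": 10,
        "match_threshold": 0.3, "top_k": 15, "matrix_class": "wt",
        "variant": "normalized", "select_q": False,
    },
}


@dataclass
class RunConfig:
    """Validated pipeline configuration (TOML sections, unknown keys rejected)."""

    sections: dict = field(default_factory=dict)

    def __post_init__(self):
        merged = {}
        for section, defaults in _SCHEMA.items():
            given = self.sections.get(section, {})
            unknown = set(given) - set(defaults)
            if unknown:
                raise ValueError(f"unknown config keys in [{section}]: {sorted(unknown)}")
            merged[section] = {**defaults, **given}
        unknown_sections = set(self.sections) - set(_SCHEMA)
        if unknown_sections:
            raise ValueError(f"unknown config sections: {sorted(unknown_sections)}")
        self.sections = merged

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            return cls(tomllib.load(fh))

    def __getitem__(self, section: str) -> dict:
        return self.sections[section]

    def to_dict(self) -> dict:
        return self.sections

    @property
    def hash(self) -> str:
        blob = json.dumps(self.sections, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_brain(ontology_json, annotation_path) -> tuple[VoxelLattice, RegionOntology]:
    """Load a structure-graph JSON plus an annotation volume (.npz)."""
    with np.load(annotation_path) as z:
        annotation = z["annotation"]
        spacing = float(z["spacing_um"])
    lattice = VoxelLattice(annotation.shape, spacing, brain_mask=annotation != 0)
    return lattice, load_ontology(ontology_json, annotation, lattice)


def _tabular(path: Path, cfg_hash: str, writer) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {cfg_hash}\n")
        writer(fh)


def _json_out(path: Path, cfg_hash: str, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump({"config_hash": cfg_hash, **payload}, fh, indent=2, sort_keys=True)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


@_stage("data")
def _get_dataset(config: RunConfig, seed: int, out: Path) -> Dataset:
    sim = config["simulate"]
    if sim["enabled"]:
        lattice, ontology = make_brain(
            sim["n_major"], sim["leafs_per_major"], tuple(sim["leaf_shape_voxels"]),
            spacing_um=sim["spacing_um"], seed=seed,
        )
        gt = sample_ground_truth(
            ontology, n_classes=sim["n_classes"], pattern_sparsity=sim["pattern_sparsity"],
            class_effect=sim["class_effect"], smoothness_scale_um=sim["smoothness_scale_um"],
            seed=seed,
        )
        d = simulate_experiments(gt, dense_design(gt, sim["n_per_cell"]),
                                 noise_sd=sim["noise_sd"], seed=seed + 1)
        write_brain(ontology, out / "structure_graph.json", out / "annotation.npz")
        return d
    data = config["data"]
    for key in ("manifest", "regionalized", "ontology_json", "annotation"):
        if not data[key]:
            raise FileNotFoundError(f"config [data].{key} is required when simulation is disabled")
        if not Path(data[key]).exists():
            raise FileNotFoundError(f"[data].{key} path does not exist: {data[key]}")
    _, ontology = load_brain(data["ontology_json"], data["annotation"])
    return read_manifest(data["manifest"], data["regionalized"], ontology)


def run_pipeline(config: RunConfig, out_dir=None, seed: int | None = None) -> Path:
    """Run the full pipeline and return the artifact directory."""
    run = config["run"]
    seed = run["seed"] if seed is None else int(seed)
    logging.basicConfig(level=run["log_level"])
    out = Path(out_dir if out_dir is not None else run["out"])
    out.mkdir(parents=True, exist_ok=True)
    h = config.hash

    d = _get_dataset(config, seed, out)
    est = config["estimator"]
    d = d.normalized(est["normalization"])
    limit = est["detection_limit"]
    if limit == "auto":
        limit = fit_detection_limit(d.Y)
    if limit not in ("none", None):
        d = d.with_detection_limit(float(limit))
    _tabular(out / "manifest.tsv", h, lambda fh: write_manifest(d, fh))
    _tabular(out / "regionalized.tsv", h, lambda fh: write_regionalized_table(d, fh))

    @_stage("evaluate")
    def _evaluate():
        model = select_hyperparameters(
            est["kind"], d,
            sigma_x_grid=tuple(est["sigma_x_grid"]),
            sigma_c_grid=tuple(est["sigma_c_grid"]),
            alpha_grid=tuple(est["alpha_grid"]),
            normalization=est["normalization"],
        )
        report = loocv_weighted_loss(model, d)
        _tabular(out / "evaluation.tsv", h,
                 lambda fh: report.cells.to_csv(fh, sep="\t", index=False))
        _json_out(out / "evaluation.json", h, {
            "overall_weighted_loss": report.overall,
            "per_major": {str(k): v for k, v in report.per_major.items()},
        })
        (out / "model.json").write_text(model.to_json())
        return model

    model = _evaluate()

    @_stage("build-connectome")
    def _connectome():
        tensor = build_tensor(model, d, d.ontology, mode=est["mode"])
        _tabular(out / "connectivity_long.tsv", h,
                 lambda fh: write_long_tsv(tensor, d.ontology, fh))
        for v in tensor.classes:
            _tabular(out / f"connectivity_{v}.csv", h,
                     lambda fh, v=v: write_wide_csv(tensor.matrix(v), d.ontology, fh))
        avg = cre_average_matrix(tensor)
        _tabular(out / "connectivity_cre_average.csv", h,
                 lambda fh: write_wide_csv(avg, d.ontology, fh))
        return tensor

    tensor = _connectome()

    @_stage("nmf")
    def _nmf():
        nmf_cfg = config["nmf"]
        v = nmf_cfg["matrix_class"]
        C = normalize_connectivity(tensor.matrix(v), d.ontology, nmf_cfg["variant"])
        M = distal_mask(d.ontology, config["mask"]["threshold_um"], config["mask"]["mode"])
        q = nmf_cfg["q"]
        if nmf_cfg["select_q"]:
            q = select_rank(C, M, q_grid=nmf_cfg["q_grid"], seed=seed, lam=nmf_cfg["lambda"])
        q = min(int(q), min(C.shape))
        dec = masked_sparse_nmf(C, M, q=q, lam=nmf_cfg["lambda"], seed=seed)
        import pandas as pd
        _tabular(out / "W.csv", h, lambda fh: pd.DataFrame(dec.W).to_csv(fh, index=False))
        _tabular(out / "H.csv", h, lambda fh: pd.DataFrame(dec.H).to_csv(fh, index=False))
        _tabular(out / "objective_trace.tsv", h, lambda fh: pd.DataFrame(
            {"iteration": range(len(dec.objective_trace)), "objective": dec.objective_trace}
        ).to_csv(fh, sep="\t", index=False))
        stab = stability_archetypes(
            C, M, q=q, lam=nmf_cfg["lambda"], n_replicates=nmf_cfg["replicates"],
            match_threshold=nmf_cfg["match_threshold"], top_k=nmf_cfg["top_k"], seed=seed,
        )
        _json_out(out / "stability.json", h, {
            "q": q,
            "cluster_frequencies": stab.frequencies,
            "n_replicates": nmf_cfg["replicates"],
            "top_archetypes": [list(map(float, row)) for row in stab.top],
        })

    _nmf()
    _json_out(out / "provenance.json", h, {
        "package": "mesoconn",
        "version": __version__,
        "seed": seed,
        "config": config.to_dict(),
    })
    return out
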