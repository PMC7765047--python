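"""Cell-table readers/writers, run configuration and the pipeline driver.

Cell tables travel as CSV or Parquet with a versioned column schema and a
JSON sidecar carrying the schema version and marker list; every pipeline
output directory receives a run-metadata sidecar with the config hash and
seed so that runs are reproducible and diffable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("spherovar")

SCHEMA_VERSION = 1
REQUIRED_COLUMNS = (
    "cell_id",
    "sphere_id",
    "image_id",
    "site_id",
    "plate_id",
    "pos_x",
    "pos_y",
    "area",
    "dist_border",
    "r_real",
)

__all__ = [
    "read_cell_table",
    "write_cell_table",
    "RunConfig",
    "run_pipeline",
    "SCHEMA_VERSION",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def marker_names(table: pd.DataFrame, prefix: str = "raw_") -> list[str]:
    return [c[len(prefix):] for c in table.columns if c.startswith(prefix)]


def write_cell_table(table: pd.DataFrame, path) -> None:
    """Write a cell table as CSV or Parquet (by extension) plus sidecar."""
    path = Path(path)
    if path.suffix == ".parquet":
        table.to_parquet(path, index=False)
    elif path.suffix == ".csv":
        table.to_csv(path, index=False)
    else:
        raise ValueError(f"unsupported extension {path.suffix!r} (use .csv or .parquet)")
    meta = {
        "schema_version": SCHEMA_VERSION,
        "markers": marker_names(table),
        "n_cells": int(len(table)),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_cell_table(path) -> pd.DataFrame:
    """Read a cell table, validating the versioned column schema.

    A schema-version mismatch or missing required columns raise an explicit
    error naming the offending columns.
    """
    path = Path(path)
    if path.suffix == ".parquet":
        table = pd.read_parquet(path)
    elif path.suffix == ".csv":
        table = pd.read_csv(path)
    else:
        raise ValueError(f"unsupported extension {path.suffix!r} (use .csv or .parquet)")
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
        if meta.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(
                f"schema version {meta.get('schema_version')} != {SCHEMA_VERSION}"
            )
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cell table missing required columns: {missing}")
    if not marker_names(table) and not marker_names(table, "value_"):
        raise ValueError("cell table has no marker columns (raw_* or value_*)")
    return table


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (YAML-loadable).

    ``synthetic`` holds keyword overrides of the generator defaults;
    thresholds default to the analysis' standard values.
    """

    out_dir: str = "spherovar_run"
    seed: int = 0
    condition: str = "condition"
    synthetic: dict = field(default_factory=dict)
    n_knots: int = 10
    n_clusters: int = 7
    winsor_lower: float = 0.1
    winsor_upper: float = 99.9
    perturbation: dict | None = None  # effects table records + run options
    exclude_images: list = field(default_factory=list)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _build_synthetic_config(cfg: RunConfig):
    from .synthetic import SyntheticConfig, MarkerSpec

    kw = dict(cfg.synthetic)
    if "markers" in kw:
        kw["markers"] = [MarkerSpec(**m) for m in kw["markers"]]
    if "barcode_scheme" in kw:
        kw["barcode_scheme"] = tuple(kw["barcode_scheme"])
    return SyntheticConfig(**kw)


def run_pipeline(cfg: RunConfig) -> Path:
    """simulate → debarcode → geometry/QC → transform → decompose →
    correlate → (perturb); writes all report tables under ``cfg.out_dir``.

    Deterministic in (config, seed): rerunning with the same inputs
    reproduces every table bit for bit.
    """
    from . import barcoding, decomposition, perturbation, preprocess, spatial
    from .geometry import build_neighbor_graph
    from .synthetic import generate_condition, generate_perturbation

    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        syn_cfg = _build_synthetic_config(cfg)
        markers = [m.name for m in syn_cfg.markers]
        if cfg.perturbation:
            effects = pd.DataFrame(
                cfg.perturbation.get("effects", []),
                columns=["construct", "marker", "class", "log10_effect"],
            )
            opts = {
                k: v
                for k, v in cfg.perturbation.items()
                if k in ("constructs", "spheres_per_construct", "mock_spheres",
                         "target_fraction", "spill_fraction", "n_plates")
            }
            cells, truth = generate_perturbation(syn_cfg, effects, cfg.seed, **opts)
        else:
            cells, truth = generate_condition(syn_cfg, cfg.seed)
        write_cell_table(cells, out / "cells.csv")
        truth.to_json(out / "truth.json")

        stage = "debarcode"
        n_ch, k_on = syn_cfg.barcode_scheme
        code_set = barcoding.enumerate_codes(n_ch, k_on)
        bc_cols = [f"bc_{c}" for c in range(n_ch)]
        bits = barcoding.binarize_channels(
            cells[bc_cols], border_distance=cells["dist_border"]
        )
        assignments = []
        for img, grp in cells.groupby("image_id", sort=False):
            eligible = bits.loc[grp.index]
            eligible = eligible[eligible["eligible"]]
            a = barcoding.assign_slice(eligible[bc_cols].to_numpy(), code_set, img)
            assignments.append(
                {"image_id": img, "well": a.well, "majority": a.majority_count,
                 "runner_up": a.runner_up_count, "reason": a.reason}
            )
        pd.DataFrame(assignments).to_csv(out / "debarcoding.tsv", sep="\t", index=False)

        stage = "qc"
        graph = build_neighbor_graph(
            cells[["pos_x", "pos_y"]].to_numpy(),
            cells["image_id"].to_numpy(),
            syn_cfg.contact_radius,
            cell_ids=cells["cell_id"].to_numpy(),
        )
        flags = preprocess.cell_qc(cells, graph)
        img_report = preprocess.image_qc(
            cells, flags["valid"], exclude_images=set(cfg.exclude_images)
        )
        img_report.to_csv(out / "image_qc.tsv", sep="\t", index=False)
        keep_imgs = set(img_report.loc[img_report["keep"], "image_id"])
        valid = flags["valid"].to_numpy() & cells["image_id"].isin(keep_imgs).to_numpy()

        stage = "transform"
        raw = cells[[f"raw_{m}" for m in markers]]
        trans = preprocess.transform_intensities(
            raw, cfg.winsor_lower, cfg.winsor_upper
        )
        for m in markers:
            cells[f"value_{m}"] = trans[f"raw_{m}"]
        graph.edge_list().to_csv(out / "neighbor_edges.csv", index=False)

        kept = cells.loc[valid].reset_index(drop=True)
        kept_graph = build_neighbor_graph(
            kept[["pos_x", "pos_y"]].to_numpy(),
            kept["image_id"].to_numpy(),
            syn_cfg.contact_radius,
            cell_ids=kept["cell_id"].to_numpy(),
        )

        stage = "decompose"
        cc = [m.name for m in syn_cfg.markers if m.class_label == "cell_cycle"]
        decomp = decomposition.decompose_condition(
            kept, markers, kept_graph, condition=cfg.condition,
            cc_markers=cc or None, n_knots=cfg.n_knots,
        )
        decomp.to_csv(out / "decomposition.tsv", sep="\t", index=False)

        stage = "correlate"
        bundle = spatial.correlation_bundle(kept, markers, kept_graph)
        bundle.intracellular.to_csv(out / "correlation_intracellular.tsv", sep="\t")
        bundle.neighbor.to_csv(out / "correlation_neighbor.tsv", sep="\t")
        bundle.autocorrelation.to_csv(out / "autocorrelation.tsv", sep="\t")
        labels, _ = spatial.cluster_markers(bundle.intracellular, cfg.n_clusters)
        labels.to_csv(out / "marker_clusters.tsv", sep="\t")
        spatial.distance_profiles(kept, markers).to_csv(
            out / "distance_profiles.tsv", sep="\t", index=False
        )

        if cfg.perturbation:
            stage = "perturb"
            kept = kept.copy()
            kept["expression_class"] = perturbation.classify_expression(
                kept, neighbor_distance=syn_cfg.contact_radius
            )
            spec = perturbation.EffectModelSpec(n_knots=cfg.n_knots)
            tables = [
                perturbation.fit_construct_lmm(kept, m, spec) for m in markers
            ]
            called = perturbation.call_effects(pd.concat(tables, ignore_index=True))
            called.to_csv(out / "effects.tsv", sep="\t", index=False)
            report = perturbation.recovery_report(called, truth.effects)
            report.to_csv(out / "effect_recovery.tsv", sep="\t", index=False)
    except Exception:
        log.error("pipeline failed at stage %r; partial outputs kept in %s", stage, out)
        raise

    (out / "run_meta.json").write_text(
        json.dumps(
            {"config_hash": cfg.digest(), "seed": cfg.seed,
             "schema_version": SCHEMA_VERSION},
            indent=1,
        )
    )
    return out
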