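"""Shared fixtures: small generated conditions reused across test modules."""

import numpy as np
import pandas as pd
import pytest

import spherovar as sv
from spherovar import preprocess


def attach_values(cells: pd.DataFrame, markers: list[str]) -> pd.DataFrame:
    """Transform raw intensities into value_ columns in place."""
    trans = preprocess.transform_intensities(cells[[f"raw_{m}" for m in markers]])
    for m in markers:
        cells[f"value_{m}"] = trans[f"raw_{m}"]
    return cells


def build_graph(cells: pd.DataFrame, cfg: sv.SyntheticConfig) -> sv.NeighborGraph:
    return sv.build_neighbor_graph(
        cells[["pos_x", "pos_y"]].to_numpy(),
        cells["image_id"].to_numpy(),
        cfg.contact_radius,
        cell_ids=cells["cell_id"].to_numpy(),
    )


@pytest.fixture(scope="session")
def default_condition():
    """Default 20-marker condition (~4-5k cells) with transformed values."""
    cfg = sv.SyntheticConfig()
    cells, truth = sv.generate_condition(cfg, seed=7)
    markers = [m.name for m in cfg.markers]
    attach_values(cells, markers)
    graph = build_graph(cells, cfg)
    return cfg, cells, truth, graph, markers


@pytest.fixture(scope="session")
def small_condition():
    """Tiny 3-sphere condition for fast unit tests."""
    cfg = sv.SyntheticConfig(
        n_spheres=3, slices_per_sphere=2, sphere_radius_mean=70.0, sphere_radius_sd=4.0
    )
    cells, truth = sv.generate_condition(cfg, seed=11)
    markers = [m.name for m in cfg.markers]
    attach_values(cells, markers)
    graph = build_graph(cells, cfg)
    return cfg, cells, truth, graph, markers
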