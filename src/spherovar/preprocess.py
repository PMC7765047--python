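"""Intensity transform, winsorization, cell/image QC, image residualization.

The per-cell readout is the (spillover-compensated) mean pixel intensity per
cell area, a count-like nonnegative quantity.  Analysis operates on
``log10(x + 0.1)``-transformed values winsorized at extreme percentiles; QC
removes mis-segmented, ambiguous and border cells and under-populated slice
images; per-image mean subtraction strips staining/acquisition batch offsets
before correlation analyses.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .geometry import NeighborGraph

__all__ = [
    "transform_intensities",
    "cell_qc",
    "image_qc",
    "residualize_image_effects",
    "QC_FLAGS",
]

# Cell-level QC flags, in the order they are computed.  NOT_MAIN depends on
# the other flags (largest component of the *valid* cell graph) and is
# therefore always computed last.
QC_FLAGS = ("OUTSIDE", "AMBIG_SPHERE", "TOO_SMALL", "BORDER", "NOT_MAIN")

MIN_CELL_AREA = 10.0  # µm² (px); smaller objects are segmentation debris
AMBIG_SPHERE_UM = 20.0  # cells closer than this to another sphere are ambiguous
MIN_VALID_CELLS_PER_IMAGE = 10


def transform_intensities(
    raw: pd.DataFrame,
    lower_pct: float = 0.1,
    upper_pct: float = 99.9,
    group_ids: np.ndarray | pd.Series | None = None,
) -> pd.DataFrame:
    """``log10(raw + 0.1)`` then two-sided winsorization per marker.

    Winsorization clips each marker's transformed values to its
    [``lower_pct``, ``upper_pct``] percentile interval, computed within each
    group of ``group_ids`` (a condition: cell line × growth condition) when
    given, else over all rows.  Pass ``upper_pct=None`` for one-sided
    clipping of the lower tail only.

    Raw intensities must be nonnegative: negative values indicate spillover
    compensation artifacts that must be clipped upstream.
    """
    values = raw.to_numpy(dtype=float) if isinstance(raw, pd.DataFrame) else np.asarray(raw, float)
    if np.any(values < 0):
        raise ValueError("negative raw intensities; clip compensation artifacts upstream")
    trans = np.log10(values + 0.1)

    if group_ids is None:
        groups = np.zeros(len(trans), dtype=int)
    else:
        groups = np.asarray(group_ids)
    out = trans.copy()
    for g in pd.unique(groups):
        m = groups == g
        lo = np.percentile(trans[m], lower_pct, axis=0)
        if upper_pct is None:
            out[m] = np.maximum(trans[m], lo)
        else:
            hi = np.percentile(trans[m], upper_pct, axis=0)
            out[m] = np.clip(trans[m], lo, hi)
    if isinstance(raw, pd.DataFrame):
        return pd.DataFrame(out, index=raw.index, columns=raw.columns)
    return out


def _largest_component_mask(graph: NeighborGraph, candidate: np.ndarray) -> np.ndarray:
    """Mask of candidate cells in the largest connected candidate component."""
    from scipy.sparse.csgraph import connected_components

    sub = graph.adjacency[np.ix_(candidate.nonzero()[0], candidate.nonzero()[0])]
    n_comp, labels = connected_components(sub, directed=False)
    if n_comp <= 1:
        return candidate.copy()
    largest = np.bincount(labels).argmax()
    keep = np.zeros_like(candidate)
    keep[candidate.nonzero()[0][labels == largest]] = True
    return keep


def cell_qc(
    cells: pd.DataFrame,
    graph: NeighborGraph,
    other_sphere_distance: np.ndarray | pd.Series | None = None,
    min_area: float = MIN_CELL_AREA,
    ambig_distance: float = AMBIG_SPHERE_UM,
) -> pd.DataFrame:
    """Cell-level QC flags; a cell is valid when no flag is set.

    ``cells`` needs columns ``image_id``, ``area`` and ``dist_border`` (the
    uncorrected planar distance to the slice border, µm).  Flags:

    - ``OUTSIDE``: cell center outside the slice boundary (negative
      distance to border).
    - ``AMBIG_SPHERE``: closer than ``ambig_distance`` µm to another
      sphere's boundary (possible misassignment between touching spheres).
    - ``TOO_SMALL``: area below ``min_area`` µm² (segmentation debris).
    - ``BORDER``: touching the slice boundary — in point mode, center within
      half a contact radius of it.
    - ``NOT_MAIN``: not in the largest connected component of the
      otherwise-valid cells of its image (detached fragments); computed
      last, per image.
    """
    n = len(cells)
    flags = pd.DataFrame(
        {f: np.zeros(n, dtype=bool) for f in QC_FLAGS}, index=cells.index
    )
    dist = cells["dist_border"].to_numpy(dtype=float)
    flags["OUTSIDE"] = dist < 0
    flags["TOO_SMALL"] = cells["area"].to_numpy(dtype=float) < min_area
    flags["BORDER"] = (~flags["OUTSIDE"].to_numpy()) & (
        dist < graph.contact_radius / 2.0
    )
    if other_sphere_distance is not None:
        flags["AMBIG_SPHERE"] = (
            np.asarray(other_sphere_distance, dtype=float) < ambig_distance
        )

    valid_so_far = ~flags[["OUTSIDE", "AMBIG_SPHERE", "TOO_SMALL", "BORDER"]].any(axis=1)
    not_main = np.zeros(n, dtype=bool)
    image_ids = cells["image_id"].to_numpy()
    positions = np.arange(n)
    for img in pd.unique(image_ids):
        in_img = image_ids == img
        cand = in_img & valid_so_far.to_numpy()
        if cand.sum() == 0:
            continue
        keep = _largest_component_mask(graph, cand)
        not_main[positions[cand & ~keep]] = True
    flags["NOT_MAIN"] = not_main
    flags["valid"] = ~flags[list(QC_FLAGS)].any(axis=1)
    return flags


def image_qc(
    cells: pd.DataFrame,
    valid: np.ndarray | pd.Series,
    min_valid_cells: int = MIN_VALID_CELLS_PER_IMAGE,
    exclude_images: set | None = None,
) -> pd.DataFrame:
    """Keep/drop decision per image with the reason.

    Slices with fewer than ``min_valid_cells`` valid cells are dropped;
    images on the manual exclusion list (visual artifacts: folds, bubbles,
    tears) are dropped with reason ``"manual"``.
    """
    exclude_images = exclude_images or set()
    valid = np.asarray(valid, dtype=bool)
    rows = []
    for img, grp in cells.groupby("image_id", sort=False):
        n_valid = int(valid[cells.index.get_indexer(grp.index)].sum())
        if img in exclude_images:
            keep, reason = False, "manual"
        elif n_valid < min_valid_cells:
            keep, reason = False, f"fewer than {min_valid_cells} valid cells"
        else:
            keep, reason = True, ""
        rows.append(
            {"image_id": img, "n_cells": len(grp), "n_valid": n_valid, "keep": keep, "reason": reason}
        )
    return pd.DataFrame(rows)


def residualize_image_effects(
    values: pd.DataFrame,
    image_ids: np.ndarray | pd.Series,
    min_cells: int = 2,
) -> pd.DataFrame:
    """Subtract the per-image mean of every column (fitting an image intercept).

    Removes technical staining/acquisition offsets before correlation
    analyses.  Images with fewer than ``min_cells`` cells cannot separate
    offset from signal and are dropped with a warning.
    """
    image_ids = pd.Series(np.asarray(image_ids), index=values.index, name="image_id")
    counts = image_ids.value_counts()
    small = counts[counts < min_cells].index
    if len(small):
        warnings.warn(f"dropping {len(small)} image(s) with < {min_cells} cells")
        keep = ~image_ids.isin(small)
        values = values.loc[keep]
        image_ids = image_ids.loc[keep]
    return values - values.groupby(image_ids).transform("mean")
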