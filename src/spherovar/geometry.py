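"""Slice geometry: distance to border, spherical-cap correction, neighbor graphs.

A histological section through a spheroid is a disk (a spherical segment at
height ``h`` above the equator).  The planar distance from a cell to the disk
boundary overestimates its true 3D distance to the sphere surface; the
correction below maps one to the other assuming a spherical spheroid whose
radius ``R`` is known from bright-field imaging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.spatial import cKDTree
from shapely import MultiPoint, minimum_bounding_circle

__all__ = [
    "SliceGeometry",
    "NeighborGraph",
    "distance_to_border",
    "correct_distance",
    "build_neighbor_graph",
    "slice_radius",
]


@dataclass(frozen=True)
class SliceGeometry:
    """Geometry of one sphere slice.

    Parameters
    ----------
    R : float
        Sphere radius from bright-field imaging, in µm.
    r : float
        Radius of the sliced segment (disk), in µm.
    R_estimated : bool
        True when ``R`` was not measured but back-filled from the largest
        observed slice radius of the sphere (degrades the correction to the
        equatorial identity for that slice).
    """

    R: float
    r: float
    R_estimated: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.r <= self.R):
            raise ValueError(f"need 0 < r <= R, got r={self.r}, R={self.R}")

    @property
    def h(self) -> float:
        """Height of the slice plane above the equator (µm)."""
        return math.sqrt(self.R**2 - self.r**2)


def distance_to_border(
    positions: np.ndarray,
    slice_center: np.ndarray,
    r: float,
) -> np.ndarray:
    """Planar distance from each cell to the slice boundary.

    Returns ``x = r - |position - center|`` per cell.  Cells outside the disk
    get a negative value; callers flag and exclude them.
    """
    positions = np.asarray(positions, dtype=float)
    center = np.asarray(slice_center, dtype=float)
    return r - np.linalg.norm(positions - center, axis=-1)


def correct_distance(x, r, R):
    """Correct planar distance-to-border for slice height (spherical cap).

    A slice at height h = sqrt(R² − r²) overestimates the distance of its
    cells to the sphere surface.  The corrected value is

        r_real = R − sqrt(R² − 2·r·x + x²)

    which satisfies 0 ≤ r_real ≤ x, with equality at x = 0 (boundary cell)
    or r = R (equatorial slice).

    Parameters are broadcast; all in µm.
    """
    x = np.asarray(x, dtype=float)
    r = np.asarray(r, dtype=float)
    R = np.asarray(R, dtype=float)
    if np.any(x < -1e-9) or np.any(x > r + 1e-9):
        raise ValueError("require 0 <= x <= r")
    if np.any(r > R + 1e-9):
        raise ValueError("require r <= R")
    x = np.clip(x, 0.0, r)
    # the equatorial slice (r = R) reduces algebraically to the identity;
    # return it exactly rather than through the sqrt round-trip
    return np.where(r == R, x, R - np.sqrt(R**2 - 2.0 * r * x + x**2))


def slice_radius(positions: np.ndarray, contact_radius: float) -> tuple[float, np.ndarray]:
    """Slice radius and center from cell centers.

    Point-mode surrogate for the segmentation boundary: the radius of the
    smallest enclosing circle of the cell centers plus half the contact
    radius (cells are points with an effective footprint).
    """
    positions = np.asarray(positions, dtype=float)
    if len(positions) == 1:
        return contact_radius / 2.0, positions[0].copy()
    circle = minimum_bounding_circle(MultiPoint(positions))
    center = np.array(circle.centroid.coords[0])
    radius = float(np.max(np.linalg.norm(positions - center, axis=1)))
    return radius + contact_radius / 2.0, center


@dataclass
class NeighborGraph:
    """Per-image undirected contact graph over cell sections.

    Edges connect cells of the same image whose center distance is at most
    ``contact_radius``.  Stored as a symmetric sparse adjacency plus a
    cell-id index; no self-edges.
    """

    cell_ids: np.ndarray
    adjacency: csr_matrix
    contact_radius: float
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {c: i for i, c in enumerate(self.cell_ids)}

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(int)

    def isolated(self) -> np.ndarray:
        """Boolean mask of cells without any contact neighbor."""
        return self.degrees() == 0

    def neighbors_of(self, cell_id) -> np.ndarray:
        i = self._index[cell_id]
        row = self.adjacency.indices[
            self.adjacency.indptr[i] : self.adjacency.indptr[i + 1]
        ]
        return self.cell_ids[row]

    def neighbor_mean(self, values: np.ndarray) -> np.ndarray:
        """Mean of ``values`` over each cell's direct neighbors.

        ``values`` is aligned with ``cell_ids``; rows may be a matrix
        (cells × features).  Isolated cells get NaN.
        """
        values = np.asarray(values, dtype=float)
        deg = self.degrees().astype(float)
        sums = self.adjacency @ values
        with np.errstate(invalid="ignore", divide="ignore"):
            if values.ndim == 1:
                return sums / np.where(deg > 0, deg, np.nan)
            return sums / np.where(deg > 0, deg, np.nan)[:, None]

    def edge_list(self) -> pd.DataFrame:
        """Two-column edge list (each undirected edge once, id_a < id_b)."""
        coo = self.adjacency.tocoo()
        mask = coo.row < coo.col
        return pd.DataFrame(
            {
                "cell_a": self.cell_ids[coo.row[mask]],
                "cell_b": self.cell_ids[coo.col[mask]],
            }
        )


def build_neighbor_graph(
    positions: np.ndarray,
    image_ids: np.ndarray,
    contact_radius: float,
    cell_ids: np.ndarray | None = None,
) -> NeighborGraph:
    """Contact graph: edge iff same image and center distance ≤ contact_radius.

    Mirrors mask-based neighbor detection (dilate each cell, find touching
    objects) in point mode, with the dilation distance folded into
    ``contact_radius``.
    """
    if contact_radius <= 0:
        raise ValueError("contact_radius must be positive")
    positions = np.asarray(positions, dtype=float)
    image_ids = np.asarray(image_ids)
    n = len(positions)
    if cell_ids is None:
        cell_ids = np.arange(n)
    else:
        cell_ids = np.asarray(cell_ids)

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    for img in pd.unique(image_ids):
        idx = np.flatnonzero(image_ids == img)
        if len(idx) < 2:
            continue
        tree = cKDTree(positions[idx])
        pairs = tree.query_pairs(contact_radius, output_type="ndarray")
        if len(pairs) == 0:
            continue
        a, b = idx[pairs[:, 0]], idx[pairs[:, 1]]
        rows.append(np.concatenate([a, b]))
        cols.append(np.concatenate([b, a]))

    if rows:
        row = np.concatenate(rows)
        col = np.concatenate(cols)
        data = np.ones(len(row), dtype=np.int8)
    else:
        row = col = np.array([], dtype=int)
        data = np.array([], dtype=np.int8)
    adj = csr_matrix((data, (row, col)), shape=(n, n))
    return NeighborGraph(cell_ids=cell_ids, adjacency=adj, contact_radius=contact_radius)
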