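"""Image-residualized correlation structure of spheroid cell tables.

Intracellular marker-marker correlations, cell-versus-neighbor-mean
correlations (whose diagonal is the spatial autocorrelation), hierarchical
marker clustering and distance-to-border marker profiles.  All correlations
are computed after per-image mean subtraction so staining offsets cannot
masquerade as biology; the corrected distance to border is appended as a
pseudo-marker, giving a direct readout of how strongly each marker tracks
the global gradient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import pdist

from .geometry import NeighborGraph
from .preprocess import residualize_image_effects

__all__ = [
    "CorrelationBundle",
    "correlation_bundle",
    "cluster_markers",
    "distance_profiles",
    "DISTANCE_PSEUDO_MARKER",
]

DISTANCE_PSEUDO_MARKER = "dist_border"


@dataclass
class CorrelationBundle:
    """Correlation structure of one condition.

    ``intracellular``: symmetric Pearson matrix of markers within cells;
    ``neighbor``: markers in cells (rows) versus neighbor means (columns);
    ``autocorrelation``: its diagonal — corr(marker, neighbor mean of the
    same marker); ``dropped`` lists zero-variance markers recorded as NaN.
    """

    intracellular: pd.DataFrame
    neighbor: pd.DataFrame
    autocorrelation: pd.Series
    dropped: list[str]


def _pearson_cross(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    an = a.to_numpy(dtype=float)
    bn = b.to_numpy(dtype=float)
    an = an - an.mean(axis=0)
    bn = bn - bn.mean(axis=0)
    sa = an.std(axis=0)
    sb = bn.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = (an.T @ bn) / len(an) / np.outer(sa, sb)
    return pd.DataFrame(c, index=a.columns, columns=b.columns)


def correlation_bundle(
    cells: pd.DataFrame,
    markers: list[str],
    graph: NeighborGraph,
    value_prefix: str = "value_",
    include_distance: bool = True,
    distance_col: str = "r_real",
) -> CorrelationBundle:
    """Residualized Pearson correlations within cells and against neighbors.

    Per-image intercepts are subtracted from all columns (including the
    distance pseudo-marker) before correlating; isolated cells drop out of
    the neighbor matrix only.
    """
    vals = cells[[f"{value_prefix}{m}" for m in markers]].copy()
    vals.columns = list(markers)
    if include_distance:
        vals[DISTANCE_PSEUDO_MARKER] = cells[distance_col].to_numpy(dtype=float)

    dropped = [c for c in vals.columns if vals[c].std(ddof=0) == 0]
    resid = residualize_image_effects(vals, cells["image_id"])

    nb = graph.neighbor_mean(vals.to_numpy(dtype=float))
    nb = pd.DataFrame(nb, index=vals.index, columns=vals.columns)
    nb_resid = residualize_image_effects(nb, cells["image_id"])

    ok = ~nb_resid.isna().any(axis=1)
    intra = _pearson_cross(resid, resid)
    neighbor = _pearson_cross(resid.loc[ok], nb_resid.loc[ok])
    auto = pd.Series(
        np.diag(neighbor).copy(), index=neighbor.index, name="autocorrelation"
    )
    for c in dropped:
        intra.loc[c] = np.nan
        intra[c] = np.nan
        neighbor.loc[c] = np.nan
        auto[c] = np.nan
    np.fill_diagonal(intra.values, 1.0)
    return CorrelationBundle(intra, neighbor, auto, dropped)


def cluster_markers(
    intracellular: pd.DataFrame,
    n_clusters: int = 7,
) -> tuple[pd.Series, np.ndarray]:
    """Agglomerative clustering of marker correlation profiles.

    Rows of the intracellular correlation matrix are clustered with cosine
    distance and average linkage; NaN rows (zero-variance markers) are
    dropped first.  Returns labels per marker and the SciPy linkage matrix.
    """
    mat = intracellular.dropna(axis=0, how="all").dropna(axis=1, how="all")
    mat = mat.loc[mat.index, mat.index]
    if len(mat) < 2:
        raise ValueError("need at least 2 markers to cluster")
    dist = pdist(mat.to_numpy(dtype=float), metric="cosine")
    # cosine distance of identical rows can dip epsilon-negative
    dist = np.clip(dist, 0.0, None)
    linkage = average(dist)
    labels = fcluster(linkage, t=min(n_clusters, len(mat)), criterion="maxclust")
    return pd.Series(labels, index=mat.index, name="cluster"), linkage


def plot_correlation_heatmap(matrix: pd.DataFrame, path=None, vmax: float = 1.0):
    """Heat-map rendering of a (possibly asymmetric) correlation matrix."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(matrix.to_numpy(dtype=float), vmin=-vmax, vmax=vmax,
                   cmap="RdBu_r")
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=90,
                  fontsize="x-small")
    ax.set_yticks(range(len(matrix.index)), matrix.index, fontsize="x-small")
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


def distance_profiles(
    cells: pd.DataFrame,
    markers: list[str],
    n_bins: int = 10,
    value_prefix: str = "value_",
    distance_col: str = "r_real",
    min_cells_per_bin: int = 20,
) -> pd.DataFrame:
    """Median marker level per corrected-distance bin, centered at zero.

    Bins hold equal cell counts (quantile edges) so the sparsely populated
    sphere center does not produce unstable medians; bins that still fall
    under ``min_cells_per_bin`` are merged into their inner neighbor.  Each
    marker's overall median is subtracted, centering profiles around 0.
    Values are residualized per image first.
    """
    vals = cells[[f"{value_prefix}{m}" for m in markers]].copy()
    vals.columns = list(markers)
    resid = residualize_image_effects(vals, cells["image_id"])
    d = cells.loc[resid.index, distance_col].to_numpy(dtype=float)

    edges = np.unique(np.quantile(d, np.linspace(0, 1, n_bins + 1)))
    bins = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, len(edges) - 2)
    # merge under-populated bins inward (toward smaller distance)
    counts = np.bincount(bins, minlength=len(edges) - 1)
    for b in range(len(counts) - 1, 0, -1):
        if counts[b] < min_cells_per_bin:
            bins[bins == b] = b - 1
            counts[b - 1] += counts[b]
            counts[b] = 0

    out = resid.copy()
    out["_bin"] = bins
    out["_d"] = d
    prof = out.groupby("_bin").median()
    prof = prof.rename(columns={"_d": "distance"})
    centered = prof[list(markers)] - prof[list(markers)].median()
    centered.insert(0, "distance", prof["distance"])
    return centered.reset_index(drop=True)
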