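"""Modular linear-model variance decomposition of single-cell marker levels.

Each marker's transformed level is modeled per condition as

    y_p = beta_pi + BS(d) + sum_{m != p} beta_m^nb x_m^nb
               + beta_p^nb x_p^nb + sum_{m != p} beta_m^int x_m^int + eps

with per-image intercepts ``beta_pi`` absorbing staining/batch offsets, a
cubic B-spline of the corrected distance to border ``d`` (the global
environment), neighbor means of all other markers (local neighborhood),
the neighbor mean of the target itself (spatial autocorrelation) and the
cell's other internal markers (internal state).  Explained variance is
reported as corrected R² relative to the image-intercept-only technical
baseline:

    R2 = 1 - (1 - R2_uncorr) / (1 - R2_tech)

Marginal contributions of the four predictor modules are evaluated over all
module orderings; the ordering minimizing the mean variance of its marginals
defines the reported hierarchy, and order-averaged marginals are the
modules' Shapley values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .geometry import NeighborGraph

__all__ = [
    "MODULES",
    "FitResult",
    "ModuleMatrices",
    "spline_basis",
    "neighbor_features",
    "build_modules",
    "fit_submodel",
    "corrected_r2",
    "marginal_sequence",
    "order_scan",
    "shapley_average",
    "decompose_condition",
]

# Canonical module order used for lexicographic tie-breaks.
MODULES = ("dist", "nb", "self", "int")
MODULES_CC = ("dist", "nb", "self", "cc", "int")


def spline_basis(
    values: np.ndarray, n_knots: int = 10, degree: int = 3
) -> np.ndarray:
    """Cubic B-spline basis with interior knots at empirical quantiles.

    ``n_knots`` interior knots sit at the boundaries of ``n_knots + 1``
    equal-probability bins of ``values`` (for the default 10, the deciles of
    an 11-quantile split).  Duplicate knots from heavily tied values are
    collapsed with a warning.  No intercept column is removed here; the
    image intercepts of the model absorb the constant direction, and fits
    handle the resulting rank deficiency by column dropping.
    """
    values = np.asarray(values, dtype=float)
    if len(np.unique(values)) < n_knots + degree + 1:
        raise ValueError("too few distinct values for the requested knots")
    qs = np.linspace(0, 1, n_knots + 2)[1:-1]
    interior = np.quantile(values, qs)
    uniq = np.unique(interior)
    if len(uniq) < len(interior):
        import warnings

        warnings.warn("tied distance quantiles: collapsed duplicate knots")
        interior = uniq
    lo, hi = values.min(), values.max()
    t = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    x = np.clip(values, lo, hi)
    return BSpline.design_matrix(x, t, degree, extrapolate=False).toarray()


def neighbor_features(
    values: pd.DataFrame, graph: NeighborGraph
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-cell mean of each marker over direct neighbors.

    Returns the feature frame (NaN rows for isolated cells) and the boolean
    isolation mask; isolated cells are excluded from model fitting.
    """
    means = graph.neighbor_mean(values.to_numpy(dtype=float))
    feats = pd.DataFrame(means, index=values.index,
                         columns=[f"nb_{c}" for c in values.columns])
    return feats, graph.isolated()


@dataclass
class FitResult:
    """OLS fit of one module subset for one target marker."""

    modules: frozenset
    r2_uncorr: float  # adjusted R² of the fit
    n_cells: int
    n_params: int
    coef: np.ndarray | None = None
    dropped_cols: int = 0


def _adjusted_r2(y: np.ndarray, X: np.ndarray) -> tuple[float, int, np.ndarray, int]:
    """Adjusted R² of an OLS fit, rank-deficiency tolerant.

    Uses the standard small-sample correction
    ``1 - (1 - R²) (n - 1) / (n - p - 1)`` with ``p`` the effective number
    of non-intercept parameters (matrix rank minus one, the design always
    containing the image intercepts which span the constant).
    """
    n = len(y)
    coef, rss_, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    p = rank - 1  # constant direction lives in the image intercepts
    if n - p - 1 <= 0:
        raise ValueError("more parameters than cells")
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return adj, rank, coef, X.shape[1] - rank


@dataclass
class ModuleMatrices:
    """Design blocks for one target marker within one condition.

    ``image_dummies`` is always part of the design (the technical baseline);
    ``blocks`` maps module name -> column block.  The target never appears
    among its own predictors except through the ``self`` module.
    """

    target: str
    y: np.ndarray
    image_dummies: np.ndarray
    blocks: dict[str, np.ndarray]
    _cache: dict = field(default_factory=dict, repr=False)

    def design(self, modules: frozenset) -> np.ndarray:
        parts = [self.image_dummies] + [
            self.blocks[m] for m in sorted(modules)
        ]
        return np.column_stack(parts)

    def fit(self, modules: frozenset) -> FitResult:
        modules = frozenset(modules)
        unknown = modules - set(self.blocks)
        if unknown:
            raise KeyError(f"unknown modules {sorted(unknown)}")
        if modules not in self._cache:
            adj, rank, coef, dropped = _adjusted_r2(self.y, self.design(modules))
            self._cache[modules] = FitResult(
                modules, adj, len(self.y), rank, coef, dropped
            )
        return self._cache[modules]

    @property
    def r2_tech(self) -> float:
        """Adjusted R² of the image-intercept-only technical baseline."""
        return self.fit(frozenset()).r2_uncorr

    def corrected(self, modules: frozenset) -> float:
        return corrected_r2(self.fit(frozenset(modules)).r2_uncorr, self.r2_tech)


def build_modules(
    cells: pd.DataFrame,
    target: str,
    markers: list[str],
    graph: NeighborGraph | None = None,
    nb_feats: pd.DataFrame | None = None,
    distance_col: str = "r_real",
    n_knots: int = 10,
    cc_markers: list[str] | None = None,
    value_prefix: str = "value_",
) -> ModuleMatrices:
    """Assemble the predictor blocks for ``target`` from a cell table.

    ``cells`` must hold transformed marker values in ``value_<marker>``
    columns, image ids and the corrected distance.  Neighbor-mean features
    are computed from ``graph`` unless precomputed ones are passed.  When
    ``cc_markers`` is given, the internal-state block is split into a
    cell-cycle block ``cc`` and the remaining internal markers ``int``.
    Rows with any NaN predictor (isolated cells) are dropped.
    """
    if target not in markers:
        raise ValueError(f"target {target!r} not in marker list")
    value_cols = {m: f"{value_prefix}{m}" for m in markers}
    vals = cells[[value_cols[m] for m in markers]].copy()
    vals.columns = markers
    if nb_feats is None:
        if graph is None:
            raise ValueError("need graph or precomputed neighbor features")
        nb_feats, _ = neighbor_features(vals, graph)

    others = [m for m in markers if m != target]
    keep = ~nb_feats.isna().any(axis=1)
    y = vals.loc[keep, target].to_numpy(dtype=float)
    if len(y) < 50:
        raise ValueError("fewer than 50 cells after exclusions")

    img = pd.get_dummies(cells.loc[keep, "image_id"]).to_numpy(dtype=float)
    dist = spline_basis(cells.loc[keep, distance_col].to_numpy(), n_knots=n_knots)

    blocks = {
        "dist": dist,
        "nb": nb_feats.loc[keep, [f"nb_{m}" for m in others]].to_numpy(dtype=float),
        "self": nb_feats.loc[keep, [f"nb_{target}"]].to_numpy(dtype=float),
    }
    if cc_markers is not None:
        cc = [m for m in others if m in set(cc_markers)]
        rest = [m for m in others if m not in set(cc_markers)]
        blocks["cc"] = vals.loc[keep, cc].to_numpy(dtype=float)
        blocks["int"] = vals.loc[keep, rest].to_numpy(dtype=float)
    else:
        blocks["int"] = vals.loc[keep, others].to_numpy(dtype=float)
    return ModuleMatrices(target=target, y=y, image_dummies=img, blocks=blocks)


def fit_submodel(mm: ModuleMatrices, modules) -> FitResult:
    """OLS of the target on image intercepts plus the selected modules."""
    return mm.fit(frozenset(modules))


def corrected_r2(r2_uncorr: float, r2_tech: float) -> float:
    """Variance explained beyond the per-image technical baseline.

    ``1 - (1 - R2_uncorr) / (1 - R2_tech)``; may be negative (recorded raw).
    """
    if r2_tech >= 1:
        raise ValueError("technical baseline R² must be < 1")
    return 1.0 - (1.0 - r2_uncorr) / (1.0 - r2_tech)


def marginal_sequence(mm: ModuleMatrices, ordering) -> np.ndarray:
    """Corrected-R² increments along one ordering of the modules.

    ``m_k = R²(modules 1..k) − R²(modules 1..k−1)``; the increments
    telescope to the full-model corrected R².
    """
    out = np.empty(len(ordering))
    prev = 0.0
    included: list[str] = []
    for k, mod in enumerate(ordering):
        included.append(mod)
        cur = mm.corrected(frozenset(included))
        out[k] = cur - prev
        prev = cur
    return out


def order_scan(mm: ModuleMatrices, modules=None) -> pd.DataFrame:
    """Marginal contributions and their variance for every module ordering.

    Returns one row per ordering with the per-module marginals and the
    population variance of the marginals.  Since the total explained
    variance is order-independent, low variance means the explained
    variance is spread over many modules — the signature of an ordering
    consistent with the underlying dependency hierarchy.
    """
    modules = tuple(modules) if modules is not None else tuple(
        m for m in (MODULES_CC if "cc" in mm.blocks else MODULES) if m in mm.blocks
    )
    rows = []
    for perm in permutations(modules):
        marg = marginal_sequence(mm, perm)
        row = {"ordering": perm, "variance": float(np.var(marg))}
        row.update({f"m_{mod}": marg[i] for i, mod in enumerate(perm)})
        rows.append(row)
    return pd.DataFrame(rows)


def select_ordering(scans: list[pd.DataFrame]) -> tuple[str, ...]:
    """Ordering minimizing the mean variance of marginals across markers.

    Ties break lexicographically on the module-name sequence.
    """
    combined = pd.concat(
        [s[["ordering", "variance"]] for s in scans], ignore_index=True
    )
    mean_var = combined.groupby("ordering", sort=False)["variance"].mean()
    best = mean_var.min()
    candidates = sorted(o for o, v in mean_var.items() if v <= best + 0.0)
    return candidates[0]


def shapley_average(scan: pd.DataFrame) -> pd.Series:
    """Each module's marginal contribution averaged over all orderings.

    These are the modules' Shapley values; they sum to the full-model
    corrected R².
    """
    cols = [c for c in scan.columns if c.startswith("m_")]
    return scan[cols].mean().rename(lambda c: c[2:])


def plot_stacked_contributions(result: pd.DataFrame, path=None):
    """Stacked-bar rendering of a decomposition table.

    Negative marginals are floored at zero for display only; tables keep
    raw values.  Returns the matplotlib figure.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    rows = result[result.get("reason", "").fillna("") == ""]
    stack_cols = [c for c in rows.columns if c.startswith("stack_")]
    fig, ax = plt.subplots(figsize=(max(6, 0.4 * len(rows)), 4))
    bottom = np.zeros(len(rows))
    for c in stack_cols:
        vals = np.clip(rows[c].to_numpy(dtype=float), 0, None)
        ax.bar(rows["marker"], vals, bottom=bottom, label=c[len("stack_"):])
        bottom += vals
    ax.set_ylabel("corrected R²")
    ax.legend(fontsize="small")
    ax.tick_params(axis="x", rotation=90)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


def decompose_condition(
    cells: pd.DataFrame,
    markers: list[str],
    graph: NeighborGraph,
    condition: str = "",
    cc_markers: list[str] | None = None,
    n_knots: int = 10,
    ordering: tuple[str, ...] | None = None,
    value_prefix: str = "value_",
) -> pd.DataFrame:
    """Full decomposition of every marker in one condition.

    Returns a tidy table with, per marker: the technical baseline R², the
    corrected R² of each single module and of the full model, per-ordering
    scan summaries, the Shapley-averaged contributions, and the stacked
    marginals along the selected (or supplied) ordering plus the
    unexplained remainder.  Zero-variance markers yield a NaN row with the
    reason recorded.
    """
    value_cols = {m: f"{value_prefix}{m}" for m in markers}
    vals = cells[[value_cols[m] for m in markers]].copy()
    vals.columns = markers
    nb_feats, _ = neighbor_features(vals, graph)

    mms: dict[str, ModuleMatrices] = {}
    scans: dict[str, pd.DataFrame] = {}
    skipped: dict[str, str] = {}
    for m in markers:
        if vals[m].std(ddof=0) == 0:
            skipped[m] = "zero variance"
            continue
        mm = build_modules(
            cells, m, markers, nb_feats=nb_feats, n_knots=n_knots,
            cc_markers=cc_markers, value_prefix=value_prefix,
        )
        mms[m] = mm
        scans[m] = order_scan(mm)

    if ordering is None and scans:
        ordering = select_ordering(list(scans.values()))

    rows = []
    for m in markers:
        if m in skipped:
            rows.append({"marker": m, "condition": condition, "reason": skipped[m]})
            continue
        mm = mms[m]
        scan = scans[m]
        module_names = tuple(
            mo for mo in (MODULES_CC if cc_markers is not None else MODULES)
            if mo in mm.blocks
        )
        full = mm.corrected(frozenset(module_names))
        row = {
            "marker": m,
            "condition": condition,
            "r2_tech": mm.r2_tech,
            "r2_full": full,
            "unexplained": 1.0 - full,
            "selected_ordering": "|".join(ordering),
            "reason": "",
        }
        for mod in module_names:
            row[f"r2_{mod}_alone"] = mm.corrected(frozenset([mod]))
        stacked = marginal_sequence(mm, ordering)
        for i, mod in enumerate(ordering):
            row[f"stack_{mod}"] = stacked[i]
        shap = shapley_average(scan)
        for mod, v in shap.items():
            row[f"shapley_{mod}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
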