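"""Synthetic spheroid-slice cell tables with known ground truth.

Emulates the post-segmentation data of a pooled-spheroid multiplexed imaging
experiment: spheres of a given radius are sliced at random heights, cells are
laid out on a jittered hexagonal grid in each slice disk, and each marker's
(log-scale) level is a linear combination of latent factors —

- ``u1``: a radially symmetric global gradient, a fixed shape function of
  the corrected distance to the sphere border (nutrient/oxygen gradients);
- ``g`` / ``u2``: a per-cell white "source" field and its graph-smoothed
  version (cells express a local factor; responders integrate it over their
  direct neighborhood);
- ``u3``: shared intrinsic cell-state factors (e.g. cell-cycle stage),
  white across space;
- ``b_i``: per-image staining/acquisition offsets; plus i.i.d. noise.

Raw intensities are emitted as ``max(0, 10^z − 0.1)`` so the analysis
transform ``log10(x + 0.1)`` inverts the generator exactly wherever
``z ≥ −1`` (clipping at zero intensity is the only lossy step).  Barcode
channels follow each sphere's well codeword with well-separated positive and
negative log-normal intensity distributions.

All latent factors are standardized over the generated condition, so squared
loadings are directly interpretable as variance shares — the basis of the
parameter-recovery tests downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .barcoding import enumerate_codes
from .geometry import build_neighbor_graph, correct_distance, NeighborGraph

__all__ = [
    "MarkerSpec",
    "SyntheticConfig",
    "SyntheticTruth",
    "GRADIENT_SHAPES",
    "generate_condition",
    "generate_perturbation",
    "default_panel",
    "recovery_panel",
]


# ---------------------------------------------------------------------------
# Gradient shape registry (phenomenological, not reaction-diffusion).
# Input: corrected distance to sphere border in µm.  Shapes are standardized
# downstream, so only the form matters, not scale or sign conventions.

GRADIENT_SHAPES = {
    # deeper = higher (e.g. hypoxia-induced markers at the core)
    "monotone_in": lambda d: d,
    # deeper = lower (e.g. growth signaling fed from the rim)
    "monotone_out": lambda d: -d,
    # peak just under the rim (proliferative band)
    "rim_peaked": lambda d: np.exp(-(((d - 25.0) / 15.0) ** 2)),
}


@dataclass(frozen=True)
class MarkerSpec:
    """Loadings of one marker on the latent factors.

    ``w1`` weights the global gradient (shape ``gradient_shape``), ``w2``
    the shared smoothed neighbor field, ``w2_own`` a marker-specific smoothed
    patch field (patchiness that only the marker's own spatial
    autocorrelation can reveal), ``w2_src`` the cell's own unsmoothed source
    field (a "ligand expression" term), and ``w3`` the shared intrinsic
    factors.  ``noise_sd`` overrides the config-level residual noise when
    set.  All on the log10 scale.
    """

    name: str
    class_label: str = "other"  # cell_cycle | signaling | other
    w1: float = 0.0
    w2: float = 0.0
    w2_own: float = 0.0
    w2_src: float = 0.0
    w3: tuple[float, ...] = ()
    gradient_shape: str = "monotone_out"
    baseline: float = 1.0
    noise_sd: float | None = None

    def __post_init__(self) -> None:
        if self.gradient_shape not in GRADIENT_SHAPES:
            raise ValueError(f"unknown gradient_shape {self.gradient_shape!r}")
        vals = [self.w1, self.w2, self.w2_own, self.w2_src, self.baseline, *self.w3]
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite loadings for marker {self.name!r}")
        if self.class_label not in ("cell_cycle", "signaling", "other"):
            raise ValueError(f"unknown class_label {self.class_label!r}")

    def total_variance(self, noise_sd: float) -> float:
        sd = self.noise_sd if self.noise_sd is not None else noise_sd
        return (
            self.w1**2
            + self.w2**2
            + self.w2_own**2
            + self.w2_src**2
            + float(np.sum(np.square(self.w3)))
            + sd**2
        )


@dataclass
class SyntheticConfig:
    """Study-condition parameters of the generator.

    Defaults emulate one cell line × growth condition of the pooled-spheroid
    design: five replicate spheres, ~5 random sections each, ~12 µm cell
    pitch, yielding a few thousand cell sections per condition.
    """

    n_spheres: int = 5
    sphere_radius_mean: float = 110.0  # µm
    sphere_radius_sd: float = 8.0  # µm
    slices_per_sphere: int = 5
    cell_spacing: float = 12.0  # µm center-to-center pitch
    markers: list[MarkerSpec] = field(default_factory=lambda: default_panel())
    image_offset_sd: float = 0.2  # log10 units, per-image staining offset
    noise_sd: float = 0.3  # log10 units, per-cell residual
    smoothing_steps: int = 1  # rounds of neighbor averaging for the shared field
    patch_smoothing_steps: int = 3  # patch size of marker-specific fields
    intrinsic_smoothness: float = 0.0  # variance fraction of u3 that is spatially smooth
    barcode_scheme: tuple[int, int] = (8, 4)
    # The arithmetic-mean binarization threshold of a lognormal mixture sits
    # only ~log10(1/positive fraction) below the positive mode, so clean
    # per-cell codes need a channel spread well under that margin.
    barcode_separation: float = 1.5  # log10 gap between neg/pos channel means
    barcode_channel_sd: float = 0.05  # log10 spread within neg/pos
    min_cells_per_slice: int = 10
    height_fraction: float = 0.9  # slice heights drawn in (−f·R, f·R)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_spheres < 1:
            raise ValueError("n_spheres must be >= 1")
        if self.cell_spacing <= 0:
            raise ValueError("cell_spacing must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        n_ch, k_on = self.barcode_scheme
        if k_on > n_ch:
            raise ValueError("barcode k_on must not exceed n_channels")
        lens = {len(m.w3) for m in self.markers}
        if len(lens) > 1:
            raise ValueError("all markers must have w3 vectors of equal length")

    @property
    def n_intrinsic_factors(self) -> int:
        return len(self.markers[0].w3) if self.markers else 0

    @property
    def contact_radius(self) -> float:
        # Point-mode analogue of mask dilation: ~6-neighbor contact topology
        # of hexagonally packed cells.
        return 1.5 * self.cell_spacing


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated cell table."""

    config: SyntheticConfig
    latents: pd.DataFrame  # per-cell: d (=r_real), g, u2, u3_*, u1_<shape>*
    image_offsets: pd.Series  # b_i per image id
    shares: pd.DataFrame  # per marker: variance shares of each factor block
    effects: pd.DataFrame | None = None  # construct × class × marker injections
    sphere_wells: dict = field(default_factory=dict)  # sphere id -> well id

    def to_json(self, path) -> None:
        payload = {
            "config": _config_to_dict(self.config),
            "image_offsets": self.image_offsets.to_dict(),
            "shares": self.shares.to_dict(orient="index"),
            "sphere_wells": self.sphere_wells,
            "effects": None if self.effects is None else self.effects.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=str)


def _config_to_dict(config: SyntheticConfig) -> dict:
    d = asdict(config)
    d["markers"] = [asdict(m) for m in config.markers]
    return d


# ---------------------------------------------------------------------------
# Panels


def default_panel(n_intrinsic: int = 3) -> list[MarkerSpec]:
    """A ~20-marker panel with the causal structure of a spheroid experiment.

    Growth-signaling markers follow the global gradient (with marker-specific
    shapes), a ligand/receptor pair couples cells to their neighborhood,
    cell-cycle markers share an intrinsic cycle factor with a gradient
    component (position in the gradient biases cycle state), and structural
    markers load on further intrinsic factors.  Intrinsic loadings are
    spread over several markers so that the internal-state module is the
    most information-rich block, the neighborhood module largely captures
    the gradient, and the gradient module captures only itself — the
    hierarchy the decomposition is designed to expose.
    """

    def w3(*pairs):
        v = [0.0] * n_intrinsic
        for i, x in pairs:
            v[i] = x
        return tuple(v)

    z = tuple([0.0] * n_intrinsic)
    panel = [
        # Rim-fed growth-signaling markers: modest gradients, a shared
        # signaling-state factor, modest marker-specific patchiness.
        MarkerSpec("pS6", "signaling", w1=0.35, w2=0.2, w2_own=0.2, w3=w3((1, 0.5)), gradient_shape="monotone_out"),
        MarkerSpec("pERK", "signaling", w1=0.3, w2=0.25, w2_own=0.25, w3=w3((1, 0.55)), gradient_shape="monotone_out"),
        MarkerSpec("pAKT", "signaling", w1=0.25, w2=0.2, w2_own=0.25, w3=w3((1, 0.55)), gradient_shape="monotone_out"),
        MarkerSpec("pGSK3b", "signaling", w1=0.2, w2=0.15, w2_own=0.2, w3=w3((1, 0.5)), gradient_shape="monotone_out"),
        MarkerSpec("pMEK", "signaling", w1=0.3, w2=0.2, w2_own=0.2, w3=w3((1, 0.45)), gradient_shape="monotone_out"),
        # Hypoxia/core markers: the strongest gradients in the panel.
        MarkerSpec("CA9", "signaling", w1=0.55, w2=0.1, w2_own=0.2, w3=w3((2, 0.3)), gradient_shape="monotone_in"),
        MarkerSpec("HIF1a", "signaling", w1=0.4, w2=0.1, w2_own=0.25, w3=w3((2, 0.45)), gradient_shape="monotone_in"),
        # Rim-band adhesion/mechanics.
        MarkerSpec("pFAK", "signaling", w1=0.35, w2=0.1, w2_own=0.25, w3=w3((2, 0.4)), gradient_shape="rim_peaked"),
        MarkerSpec("pSRC", "signaling", w1=0.25, w2=0.1, w2_own=0.2, w3=w3((2, 0.5)), gradient_shape="rim_peaked"),
        # Neighbor-coupled set: a secreted source and its responders.
        MarkerSpec("Ligand", "signaling", w2_src=0.5, w2_own=0.25, w3=w3((1, 0.2)), w1=0.1),
        MarkerSpec("pSTAT3", "signaling", w2=0.45, w1=0.15, w2_own=0.25, w3=w3((1, 0.35))),
        MarkerSpec("pSMAD", "signaling", w2=0.4, w1=0.12, w2_own=0.25, w3=w3((1, 0.3))),
        MarkerSpec("pNFkB", "signaling", w2=0.3, w1=0.1, w2_own=0.3, w3=w3((2, 0.35))),
        # Cell-cycle block: a dominant shared cycle factor u3_0 with
        # gradient-biased entry and no local synchrony (cycle stage is not
        # patchy in neighborhoods).
        MarkerSpec("pRB", "cell_cycle", w1=0.3, w3=w3((0, 0.6)), gradient_shape="monotone_out"),
        MarkerSpec("CyclinB1", "cell_cycle", w1=0.2, w3=w3((0, 0.65)), gradient_shape="monotone_out"),
        MarkerSpec("pHH3", "cell_cycle", w1=0.15, w3=w3((0, 0.55)), gradient_shape="monotone_out"),
        MarkerSpec("Ki67", "cell_cycle", w1=0.25, w3=w3((0, 0.6)), gradient_shape="monotone_out"),
        MarkerSpec("cPARP", "cell_cycle", w1=0.2, w3=w3((0, -0.35)), gradient_shape="monotone_in"),
        # Structural / housekeeping; Vimentin visibly patchy.
        MarkerSpec("HistoneH3", "other", w3=w3((2, 0.5)), w1=0.05, w2_own=0.15),
        MarkerSpec("Vimentin", "other", w3=w3((2, 0.4), (1, 0.2)), w1=0.1, w2_own=0.35),
    ]
    return panel


def hierarchy_panel(n_markers: int = 12) -> list[MarkerSpec]:
    """Panel realizing a strict global → local → autocorrelation → internal
    dependency hierarchy.

    Every marker is autocrine: it expresses the secreted coupling factor
    (``w2_src``) and responds to the factor's neighborhood average
    (``w2``), so the neighborhood module reads the coupling exactly while
    the cell's own source expression is part of its internal state.  Each
    marker further carries a comparable gradient share, a marker-specific
    patch field (readable only by the marker's own spatial autocorrelation)
    and a single shared intrinsic state factor loaded by the whole panel —
    making the internal-state module an accurate readout that subsumes the
    information of the modules before it.  With partly smooth intrinsic
    factors (``hierarchy_config``), this is the regime in which the order
    scan recovers the conceptual hierarchy.
    """
    shapes = ["monotone_out", "monotone_in"]
    return [
        MarkerSpec(
            f"M{i:02d}",
            "signaling",
            w1=[0.25, 0.3, 0.35][i % 3],
            w2=0.3,
            w2_src=0.3,
            w2_own=0.33,
            w3=(0.5,),
            gradient_shape=shapes[i % 2],
        )
        for i in range(n_markers)
    ]


def hierarchy_config(**overrides) -> SyntheticConfig:
    """Study condition embodying the strict dependency hierarchy."""
    kw = dict(markers=hierarchy_panel(), intrinsic_smoothness=0.5)
    kw.update(overrides)
    return SyntheticConfig(**kw)


def perturbation_panel(n_markers: int = 12) -> list[MarkerSpec]:
    """Compact low-variance panel for perturbation-effect benchmarks.

    Markers carry mild gradients, faint patchiness and a weak shared state
    factor but deliberately low total variance: patchy background fields do
    not average out within the contiguous overexpression patch of a sphere
    and would dominate the sphere-level sampling noise of class means, so
    the benchmark keeps them small and detection reflects the inferential
    machinery rather than background biology.
    """
    shapes = ["monotone_out", "monotone_in"]
    return [
        MarkerSpec(
            f"P{i:02d}",
            "signaling",
            w1=0.1,
            w2_own=0.02,
            w3=(0.15,),
            noise_sd=0.2,
            gradient_shape=shapes[i % 2],
        )
        for i in range(n_markers)
    ]


def perturbation_config(**overrides) -> SyntheticConfig:
    """Study condition for chimeric-overexpression benchmarks.

    Small spheres (two sections each) keep mixed-model fits fast; the
    9-choose-4 barcode scheme provides capacity for ~100 wells; staining
    offsets are modest so construct effects of ~0.18 log10 units are
    recoverable to a few percent when averaged over constructs.
    """
    kw = dict(
        markers=perturbation_panel(),
        sphere_radius_mean=80.0,
        sphere_radius_sd=5.0,
        slices_per_sphere=2,
        image_offset_sd=0.03,
        barcode_scheme=(9, 4),
    )
    kw.update(overrides)
    return SyntheticConfig(**kw)


def recovery_config(**overrides) -> SyntheticConfig:
    """Parameter-recovery study condition.

    Near-equatorial sections of size-matched spheres (so the gradient's
    between-image variance — absorbed by the image intercepts of the
    technical baseline — is negligible and squared loadings map directly
    onto stacked contributions), one smoothing round for the shared field
    (its neighborhood average is then exactly the responders' input), and
    the noise-free reporter panel of :func:`recovery_panel`.
    """
    kw = dict(
        markers=recovery_panel(),
        smoothing_steps=1,
        sphere_radius_mean=92.0,
        sphere_radius_sd=1.0,
        height_fraction=0.15,
    )
    kw.update(overrides)
    return SyntheticConfig(**kw)


def recovery_panel(
    w1: float = 0.55,
    w2: float = 0.45,
    w3_loading: float = 0.5,
    noise_sd: float = 0.3,
) -> list[MarkerSpec]:
    """Panel for parameter-recovery tests: every factor has a clean readout.

    Target markers load on the gradient, the smoothed neighbor field and one
    intrinsic factor.  Noise-free reporter markers expose each factor to the
    module that owns it: ``Ligand_rep`` emits the unsmoothed source field
    (its neighbor mean *is* the smoothed field, so the neighborhood module
    captures the w2 share exactly at one smoothing round), and intrinsic
    reporters emit the u3 factors (the internal-state module captures the w3
    share).  The gradient is a deterministic function of corrected distance,
    so the distance spline captures the w1 share by construction.
    """
    z3 = (0.0, 0.0)
    return [
        MarkerSpec("target_A", "signaling", w1=w1, w2=w2, w3=(w3_loading, 0.0),
                   gradient_shape="monotone_out", noise_sd=noise_sd),
        MarkerSpec("target_B", "signaling", w1=w2, w2=w1, w3=(0.0, w3_loading),
                   gradient_shape="monotone_in", noise_sd=noise_sd),
        MarkerSpec("Ligand_rep", "signaling", w2_src=1.0, w3=z3, noise_sd=0.0),
        MarkerSpec("u3_rep_0", "other", w3=(1.0, 0.0), noise_sd=0.0),
        MarkerSpec("u3_rep_1", "other", w3=(0.0, 1.0), noise_sd=0.0),
    ]


# ---------------------------------------------------------------------------
# Core generation


def _sphere_rng(seed: int, sphere_index: int, stream: int = 0) -> np.random.Generator:
    # Counter-based substreams: sphere k's stream depends only on
    # (seed, k, stream), so increasing n_spheres never reshuffles existing
    # spheres and geometry / latent-field / barcode draws never interleave.
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(sphere_index, stream))
    )


def _hex_positions(r: float, spacing: float, rng: np.random.Generator) -> np.ndarray:
    dy = spacing * np.sqrt(3) / 2.0
    ys = np.arange(-r, r + dy, dy)
    pts = []
    for row, y in enumerate(ys):
        off = (spacing / 2.0) if row % 2 else 0.0
        xs = np.arange(-r + off, r + spacing, spacing)
        pts.append(np.column_stack([xs, np.full_like(xs, y)]))
    pts = np.concatenate(pts)
    pts = pts + rng.normal(0.0, 0.08 * spacing, size=pts.shape)
    keep = np.linalg.norm(pts, axis=1) <= r - spacing / 2.0
    return pts[keep]


def _generate_geometry(config: SyntheticConfig, seed: int) -> pd.DataFrame:
    """Positions and slice geometry for every cell; one image per slice."""
    rows = []
    for k in range(config.n_spheres):
        rng = _sphere_rng(seed, k)
        R = max(
            rng.normal(config.sphere_radius_mean, config.sphere_radius_sd),
            5 * config.cell_spacing,
        )
        sphere_id = f"S{k:03d}"
        for s in range(config.slices_per_sphere):
            for _attempt in range(200):
                h = rng.uniform(-config.height_fraction * R, config.height_fraction * R)
                r = float(np.sqrt(R**2 - h**2))
                pos = _hex_positions(r, config.cell_spacing, rng)
                if len(pos) >= config.min_cells_per_slice:
                    break
            else:  # pragma: no cover - config with absurdly small spheres
                raise RuntimeError(f"could not place >= {config.min_cells_per_slice} cells")
            image_id = f"{sphere_id}_Z{s}"
            dist = r - np.linalg.norm(pos, axis=1)
            r_real = correct_distance(dist, r, R)
            area = np.maximum(rng.normal(80.0, 10.0, size=len(pos)), 20.0)
            rows.append(
                pd.DataFrame(
                    {
                        "sphere_id": sphere_id,
                        "image_id": image_id,
                        "site_id": f"sec{s}",
                        "plate_id": "p1",
                        "pos_x": pos[:, 0],
                        "pos_y": pos[:, 1],
                        "area": area,
                        "dist_border": dist,
                        "r_real": r_real,
                        "r_slice": r,
                        "R_sphere": R,
                        "slice_index": s,
                        "sphere_index": k,
                    }
                )
            )
    cells = pd.concat(rows, ignore_index=True)
    cells.insert(0, "cell_id", np.arange(len(cells)))
    return cells


def _smooth_field(
    g: np.ndarray, graph: NeighborGraph, steps: int
) -> np.ndarray:
    """``steps`` rounds of excluding-self neighbor averaging; isolated cells
    keep their value."""
    v = g.astype(float).copy()
    deg = graph.degrees().astype(float)
    has_nb = deg > 0
    for _ in range(steps):
        nb = graph.adjacency @ v
        v = np.where(has_nb, nb / np.where(has_nb, deg, 1.0), v)
    return v


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        return v - v.mean()
    return (v - v.mean()) / sd


def _choose_balanced_wells(code_set, n: int, rng: np.random.Generator) -> list[int]:
    """Pick ``n`` wells keeping per-channel positive counts balanced.

    Mirrors real plate layouts, which spread each metal evenly over the
    plug so that the mean-intensity binarization threshold falls between
    the negative and positive populations of every channel.
    """
    order = rng.permutation(len(code_set.codewords))
    words = [np.array(code_set.codewords[i]) for i in order]
    chosen: list[int] = []
    totals = np.zeros(code_set.n_channels)
    remaining = list(range(len(words)))
    for _ in range(n):
        best, best_cost = None, None
        for j in remaining:
            t = totals + words[j]
            cost = t.max() - t.min()
            if best_cost is None or cost < best_cost:
                best, best_cost = j, cost
        chosen.append(int(order[best]))
        totals += words[best]
        remaining.remove(best)
    return chosen


def generate_condition(
    config: SyntheticConfig, seed: int | None = None
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate one condition's cell table plus its ground truth.

    Deterministic in ``(config, seed)``; ``seed`` defaults to
    ``config.seed``.  Latent factors are standardized over the condition so
    squared loadings are variance shares of the (image-offset-free)
    log-scale marker variance.
    """
    if seed is None:
        seed = config.seed
    cells = _generate_geometry(config, seed)
    n = len(cells)
    graph = build_neighbor_graph(
        cells[["pos_x", "pos_y"]].to_numpy(),
        cells["image_id"].to_numpy(),
        config.contact_radius,
        cell_ids=cells["cell_id"].to_numpy(),
    )

    n_markers = len(config.markers)
    n_u3 = config.n_intrinsic_factors

    # Per-sphere substreams for all random fields.
    g = np.empty(n)
    g_own = np.empty((n, n_markers))
    u3 = np.empty((n, n_u3))
    u3_spatial = np.empty((n, n_u3))
    eps = np.empty((n, n_markers))
    offsets: dict[str, float] = {}
    sphere_index = cells["sphere_index"].to_numpy()
    for k in range(config.n_spheres):
        rng = _sphere_rng(seed, k, stream=1)
        m = sphere_index == k
        nk = int(m.sum())
        g[m] = rng.normal(size=nk)
        u3[m] = rng.normal(size=(nk, n_u3))
        eps[m] = rng.normal(size=(nk, n_markers))
        g_own[m] = rng.normal(size=(nk, n_markers))
        u3_spatial[m] = rng.normal(size=(nk, n_u3))
        for img in pd.unique(cells.loc[m, "image_id"]):
            offsets[img] = rng.normal(0.0, config.image_offset_sd)

    u2_raw = _smooth_field(g, graph, config.smoothing_steps)
    u2 = _standardize(u2_raw)
    g_std = _standardize(g)
    # marker-specific patch fields: independent white sources, own patch scale
    u2_own = np.column_stack(
        [
            _standardize(_smooth_field(g_own[:, j], graph, config.patch_smoothing_steps))
            for j in range(n_markers)
        ]
    )
    # intrinsic factors: optionally part-smooth (cell states cluster in space:
    # adjacent siblings, locally shared metabolic states)
    rho = config.intrinsic_smoothness
    if rho > 0:
        for j in range(n_u3):
            smooth = _standardize(
                _smooth_field(u3_spatial[:, j], graph, config.patch_smoothing_steps)
            )
            u3[:, j] = np.sqrt(1.0 - rho) * u3[:, j] + np.sqrt(rho) * smooth

    d = cells["r_real"].to_numpy()
    u1_by_shape = {
        shape: _standardize(fn(d)) for shape, fn in GRADIENT_SHAPES.items()
    }

    b = cells["image_id"].map(offsets).to_numpy()

    latents = pd.DataFrame({"cell_id": cells["cell_id"], "g": g_std, "u2": u2})
    for shape, u1 in u1_by_shape.items():
        latents[f"u1_{shape}"] = u1
    for j in range(n_u3):
        latents[f"u3_{j}"] = u3[:, j]
    for j, mk in enumerate(config.markers):
        if mk.w2_own != 0:
            latents[f"u2_own_{mk.name}"] = u2_own[:, j]

    share_rows = {}
    for j, mk in enumerate(config.markers):
        sd_m = mk.noise_sd if mk.noise_sd is not None else config.noise_sd
        z = (
            mk.baseline
            + mk.w1 * u1_by_shape[mk.gradient_shape]
            + mk.w2 * u2
            + mk.w2_own * u2_own[:, j]
            + mk.w2_src * g_std
            + u3 @ np.asarray(mk.w3)
            + b
            + sd_m * eps[:, j]
        )
        cells[f"raw_{mk.name}"] = np.maximum(0.0, 10.0**z - 0.1)
        V = mk.total_variance(config.noise_sd)
        share_rows[mk.name] = {
            "dist": mk.w1**2 / V,
            "nb": mk.w2**2 / V,
            "self": mk.w2_own**2 / V,
            "src": mk.w2_src**2 / V,
            "int": float(np.sum(np.square(mk.w3))) / V,
            "noise": (sd_m**2) / V,
            "class_label": mk.class_label,
        }

    # Barcode channels per sphere well.
    n_ch, k_on = config.barcode_scheme
    code_set = enumerate_codes(n_ch, k_on)
    if config.n_spheres > len(code_set.codewords):
        raise ValueError(
            f"{config.n_spheres} spheres exceed the "
            f"{len(code_set.codewords)}-well capacity of the "
            f"{n_ch}-choose-{k_on} scheme"
        )
    well_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(10_000,)))
    well_ids = _choose_balanced_wells(code_set, config.n_spheres, well_rng)
    sphere_wells = {}
    neg_mu, pos_mu = -0.3, -0.3 + config.barcode_separation
    for k in range(config.n_spheres):
        word = code_set.codewords[well_ids[k]]
        sphere_id = f"S{k:03d}"
        sphere_wells[sphere_id] = code_set.well_map[word]
        m = sphere_index == k
        rng = _sphere_rng(seed, k, stream=2)
        for c in range(n_ch):
            mu = pos_mu if word[c] else neg_mu
            vals = 10.0 ** rng.normal(mu, config.barcode_channel_sd, size=int(m.sum()))
            cells.loc[m, f"bc_{c}"] = vals

    truth = SyntheticTruth(
        config=config,
        latents=latents,
        image_offsets=pd.Series(offsets, name="b_i"),
        shares=pd.DataFrame.from_dict(share_rows, orient="index"),
        sphere_wells=sphere_wells,
    )
    return cells, truth


# ---------------------------------------------------------------------------
# Perturbation runs (chimeric overexpression)


def generate_perturbation(
    config: SyntheticConfig,
    effects: pd.DataFrame,
    seed: int | None = None,
    constructs: list[str] | None = None,
    spheres_per_construct: int = 6,
    mock_spheres: int = 12,
    target_fraction: float = 0.2,
    spill_fraction: float = 0.3,
    n_plates: int = 2,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Chimeric-overexpression run: per-sphere overexpressing patches.

    ``effects`` has columns ``construct``, ``marker``, ``class`` (one of
    ``oexp`` / ``neighbor`` / ``bystander``) and ``log10_effect``; the listed
    constructs (plus any in ``constructs``) each get
    ``spheres_per_construct`` transfected spheres in which a random connected
    patch of ~``target_fraction`` of each slice's cells overexpresses.
    Patch cells receive the ``oexp`` effects, their contact neighbors the
    ``neighbor`` effects, everything else the ``bystander`` effects; mock
    spheres receive none.  A probability-like overexpression score is
    emitted: high in the patch, a low noise floor elsewhere, with
    intermediate "spill" for ``spill_fraction`` of patch-contact cells
    (signal bleed-over that the classifier must flag as ambiguous).
    """
    if seed is None:
        seed = config.seed
    if len(effects):
        missing = set(effects["marker"]) - {m.name for m in config.markers}
        if missing:
            raise ValueError(f"effects reference unknown markers: {sorted(missing)}")
        bad = set(effects["class"]) - {"oexp", "neighbor", "bystander"}
        if bad:
            raise ValueError(f"unknown effect classes: {sorted(bad)}")

    all_constructs = list(dict.fromkeys(
        (constructs or []) + (list(effects["construct"].unique()) if len(effects) else [])
    ))
    n_spheres = len(all_constructs) * spheres_per_construct + mock_spheres
    cfg = SyntheticConfig(**{**_config_to_dict(config), "markers": config.markers,
                             "n_spheres": n_spheres})
    cells, truth = generate_condition(cfg, seed)

    # Construct assignment: mocks first, then constructs, shuffled over
    # plates so plate effects are not confounded with constructs.
    labels = ["mock"] * mock_spheres + [
        c for c in all_constructs for _ in range(spheres_per_construct)
    ]
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(20_000,)))
    order = rng.permutation(n_spheres)
    sphere_construct = {f"S{k:03d}": labels[order[k]] for k in range(n_spheres)}
    cells["construct"] = cells["sphere_id"].map(sphere_construct)
    plate_of = {f"S{k:03d}": f"p{(k % n_plates) + 1}" for k in range(n_spheres)}
    cells["plate_id"] = cells["sphere_id"].map(plate_of)

    graph = build_neighbor_graph(
        cells[["pos_x", "pos_y"]].to_numpy(),
        cells["image_id"].to_numpy(),
        cfg.contact_radius,
        cell_ids=cells["cell_id"].to_numpy(),
    )

    n = len(cells)
    true_class = np.full(n, "bystander", dtype=object)
    score = np.abs(rng.normal(0.0, 0.002, size=n))  # noise floor, << 0.01

    adj = graph.adjacency
    for sphere_id, construct in sphere_construct.items():
        if construct == "mock":
            continue
        in_sphere = (cells["sphere_id"] == sphere_id).to_numpy()
        for img in pd.unique(cells.loc[in_sphere, "image_id"]):
            idx = np.flatnonzero((cells["image_id"] == img).to_numpy())
            target = max(1, int(round(target_fraction * len(idx))))
            # grow a connected patch from a random seed cell by BFS
            start = rng.choice(idx)
            patch = [int(start)]
            seen = {int(start)}
            frontier = [int(start)]
            while len(patch) < target and frontier:
                nxt = []
                for i in frontier:
                    nbrs = adj.indices[adj.indptr[i] : adj.indptr[i + 1]]
                    for jj in nbrs:
                        if jj not in seen:
                            seen.add(int(jj))
                            nxt.append(int(jj))
                rng.shuffle(nxt)
                for jj in nxt:
                    if len(patch) >= target:
                        break
                    patch.append(jj)
                frontier = nxt
            patch = np.array(patch[:target])
            true_class[patch] = "oexp"
            score[patch] = rng.uniform(0.3, 1.0, size=len(patch))
            # contact neighbors of the patch
            nb_mask = np.zeros(n, dtype=bool)
            nb_mask[np.unique(adj[patch].indices)] = True
            nb_mask[patch] = False
            nb_idx = np.flatnonzero(nb_mask)
            true_class[nb_idx] = "neighbor"
            spill = nb_idx[rng.random(len(nb_idx)) < spill_fraction]
            score[spill] = rng.uniform(0.011, 0.08, size=len(spill))

    cells["true_class"] = true_class
    cells["oe_score"] = np.clip(score, 0.0, 1.0)

    # Inject effects on the transformed scale by scaling raw intensities:
    # adding delta to z multiplies (raw + 0.1) by 10^delta.
    if len(effects):
        class_map = {"oexp": "oexp", "neighbor": "neighbor", "bystander": "bystander"}
        for _, row in effects.iterrows():
            m = (
                (cells["construct"] == row["construct"])
                & (cells["true_class"] == class_map[row["class"]])
            ).to_numpy()
            col = f"raw_{row['marker']}"
            cells.loc[m, col] = np.maximum(
                0.0, (cells.loc[m, col] + 0.1) * 10.0 ** row["log10_effect"] - 0.1
            )

    truth.effects = effects.reset_index(drop=True) if len(effects) else pd.DataFrame(
        columns=["construct", "marker", "class", "log10_effect"]
    )
    truth.sphere_wells = {s: truth.sphere_wells[s] for s in truth.sphere_wells}
    cells.attrs["sphere_construct"] = sphere_construct
    return cells, truth
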