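# Methods

This note documents the models implemented in `spherovar`, the assumptions
behind them, the synthetic data they are validated on, and the numerical
and design choices that were genuinely open.

## The measurement model

The unit of analysis is a *cell section*: one segmented cell in one
histological slice (image) of one spheroid. The readout per cell and marker
is a mean intensity per unit area, a nonnegative count-like quantity.
Analysis operates on `v = log10(raw + 0.1)`, winsorized two-sided at the
0.1th/99.9th percentiles per marker within a condition. The paper-standard
`+0.1` offset keeps zero intensities finite (`v = −1`); winsorization is
symmetric by default (the one-sided variant is a flag) because extreme
outliers occur in both tails of compensated IMC data. Percentile limits are
computed per condition (cell line × growth condition) to match
per-condition modeling; whether limits should instead be pooled across
conditions is unstated in the underlying protocol — per-condition was
chosen and all submodels of one condition reuse the same limits.

## Geometry

A slice at height `h` above the equator of a sphere of radius `R` is a disk
of radius `r = √(R² − h²)`. The planar distance `x` of a cell to the disk
boundary overestimates its 3D distance to the sphere surface; assuming
sphericity the corrected distance is `r_real = R − √(R² − 2rx + x²)`, with
`0 ≤ r_real ≤ x`, equality at `x = 0` or `r = R`. The equatorial case is
returned through the algebraic identity rather than the sqrt round-trip so
it is exact in floating point.

The package works in *point mode*: cells are positions with a contact
radius, not pixel masks. Consequences, each a documented surrogate for the
mask-based original:

- neighbor graphs connect cells of the same image within a contact radius;
  the default `1.5 × cell_spacing` reproduces the ~6-neighbor topology of
  hexagonally packed cells (the mask-based pipeline dilates objects by
  3 px at 1 µm/px);
- a slice's radius is the smallest enclosing circle of its cell centers
  plus half a contact radius;
- "touching the border" becomes "center within half a contact radius of
  the boundary";
- the 6 px contact rule for perturbation neighbor classes becomes the same
  contact-radius threshold (two 6 px dilated masks touch roughly when the
  centers are a cell pitch apart; a literal 6 µm center distance would
  connect nothing at a 12 µm pitch).

When a sphere's bright-field radius is missing, `R` falls back to the
largest observed slice radius of that sphere, flagging the estimate; the
correction then degrades gracefully toward the identity.

## Quality control

Cell-level flags: outside the slice boundary; closer than 20 µm to another
sphere (ambiguous assignment); area < 10 µm²; touching the slice border;
not in the largest connected component of the remaining valid cells
(computed last, per image, because it depends on the other flags).
Image-level: fewer than 10 valid cells, or membership in a manual exclusion
list (the pixel-based fold classifier of the original pipeline requires
image data and is replaced by that list in point mode).

## Debarcoding

Each well's spheroid carries a k-of-n metal code (60 of the 70 words of
8-choose-4 for the growth-condition datasets; 126 words of 9-choose-4 for
the overexpression dataset). Binarization thresholds each channel at its
mean raw intensity over eligible cells (within 30 µm of the slice border)
of a plug, cell-weighted across the plug's images. A slice is assigned to
the most frequent valid codeword if it has ≥ 10 cells and is ≥ 2× the
runner-up. Any two equal-weight codewords differ in ≥ 2 positions, so a
single binarization error cannot convert one valid word into another.
Cisplatin labels (Pt194/Pt198) multiply the layout capacity; a slice's
label requires > 70 % positive cells on one Pt channel and < 30 % on the
other (the source protocol states no threshold; these are configurable).

A structural note on mean-intensity binarization: for a lognormal mixture
the threshold sits only about `log10(1/positive fraction)` below the
positive mode in log space. Reliable per-cell codes therefore require both
a large positive/negative separation and channel-balanced layouts; the
generator defaults (1.5 decades separation, 0.05 decade channel spread,
greedy channel-balanced well selection, mirroring real plate layouts)
place thresholds ≥ 5σ from both populations.

## The variance decomposition

Per marker and condition, OLS of the transformed level on per-image
intercepts plus four predictor modules: `dist` (cubic B-spline of
`r_real`), `nb` (neighbor means of all other markers), `self` (neighbor
mean of the target), `int` (the cell's other markers; optionally split into
cell-cycle and remaining internal markers for a 5-module variant). Isolated
cells are excluded from all submodels of a marker, so every subset fit uses
one analysis set.

- **Spline.** "10 knots at the deciles" is read as 10 interior knots at
  the boundaries of an 11-quantile split of `r_real`; degree 3; duplicate
  knots from ties are collapsed with a warning. The basis keeps its
  constant direction — the image intercepts span it and fits are
  rank-tolerant (`lstsq`; effective parameter count = design rank).
- **Adjusted R².** The standard `1 − (1 − R²)(n − 1)/(n − p − 1)`
  correction (the source names "adjusted" without a formula).
- **Corrected R².** `1 − (1 − R²_uncorr)/(1 − R²_tech)` with `R²_tech`
  the adjusted R² of the image-intercept-only model; negative values are
  recorded raw and floored at zero only in stacked-bar rendering.
- **Order scan.** Marginal contributions `m_k = R²(S_k) − R²(S_{k−1})`
  along every ordering; per ordering, the *population* variance of its
  marginals (the sample convention differs by a constant factor and cannot
  change the argmin). The selected ordering minimizes the mean variance
  across markers, ties broken lexicographically. Order-averaged marginals
  are exactly the modules' Shapley values and sum to the full corrected R².
  All subset fits are cached; the scan costs 2⁴ − 1 fits per marker.

### Why the variance-of-marginals criterion selects the hierarchy

Since the total explained variance is order-independent, the variance of an
ordering's marginals measures how unevenly it distributes credit. If the
modules form a dependency chain in which each later module subsumes the
information of the earlier ones, adding a more powerful module first
strands the downstream modules at zero — high variance — whereas the
chain-consistent order lets each module claim exactly its own increment.
Two structural conditions matter, and the synthetic `hierarchy_config`
realizes both:

1. later modules must *actually* subsume earlier ones (the neighborhood
   must read the gradient through other markers' neighbor means, and the
   internal state must be an accurate readout of the shared factors — a
   noisy internal readout instead acts as a suppressor and pushes the
   autocorrelation module to the end);
2. intrinsic cell state must itself be partly spatially coherent
   (`intrinsic_smoothness`), so the target's own neighbor mean is
   partially redundant with — not complementary to — the internal module.

The realistic default panel does not enforce the strict chain and its
selected ordering varies; the hierarchy claim is tested on the panel built
to embody the conceptual model, which is what the claim is about.

## Correlation structure

Pearson correlations are computed after subtracting per-image means from
every column (staining offsets would otherwise masquerade as biology),
pooling replicate spheres of a condition. The corrected distance enters as
a pseudo-marker; its autocorrelation (correlation with the neighbor-mean
distance) is near 1 by construction of smooth gradients and serves as a
positive control. Marker rows of the correlation matrix are clustered with
cosine distance and average linkage (default cut at 7 clusters, a
configuration choice, not a claim about synthetic data). Distance profiles
use equal-count bins (the sphere core is sparse; equal-width bins produce
unstable medians), per-bin medians, each marker centered at its overall
median.

## Perturbation analysis

Chimeric overexpression produces spheres in which a patch of cells
overexpresses a construct. Classification from a probability-like score:
overexpressing if score > 0.01 and ≥ 30 % of the maximal score among
contact neighbors; ambiguous if above threshold but below the spill
criterion; neighbor if in contact with an overexpressor; else bystander.
FLAG-only constructs are all-bystander. Effects per construct × class ×
marker come from a REML linear mixed-effects model: fixed distance spline,
construct × class intercepts against mock-transfected cells, plate
intercepts; random intercepts for spheroid, acquisition site and image.
Two implementation choices:

- with fewer than 8 acquisition sites the site term is folded into the
  fixed effects — a variance component is not meaningfully estimable from
  a handful of levels — which also makes the random structure nested
  (image ⊂ sphere) and fast; with many sites the crossed structure is fit
  as variance components in a single group;
- p-values use the large-sample normal approximation to the coefficient
  t-statistics (a Satterthwaite denominator-df correction is not available
  in the fitting backend); the class contrasts are identified across tens
  of spheres, where the two agree closely, and null simulations confirm
  rejection at or slightly below the nominal 1 %.

Significance requires jointly `p < 0.01`, Benjamini–Hochberg `q < 0.1`
(pooled over all tests of a run), `|fold − 1| > 0.2` with
`fold = 10^estimate`, and for neighbor/bystander rows an estimate exceeding
10 % of the same construct's cell-autonomous estimate. Ambiguous-class
coefficients are estimated but never called. The stereotypic stress markers
(p-p38, p-SAPK/JNK) are flagged and excluded from headline counts.

## The synthetic generator

Per sphere: radius `R ~ N(mean, sd)`, slices at heights uniform in
`(−0.9R, 0.9R)` (slices with < 10 cells are redrawn — tiny caps are
discarded by QC anyway), cells on a jittered hexagonal grid. Latent factors
per cell, standardized per condition so squared loadings are variance
shares:

- `u1`: a fixed shape function of `r_real` (monotone-in, monotone-out or
  rim-peaked; phenomenological, not reaction–diffusion);
- `g` and `u2`: a white per-cell source field and its excluding-self
  neighbor average (`smoothing_steps` rounds) — cells express a factor,
  responders integrate it over their neighborhood;
- per-marker patch fields at their own smoothing scale
  (`patch_smoothing_steps`; patch size is a free parameter, chosen at 3
  rounds ≈ 2–3 cell diameters);
- `u3`: shared intrinsic factors, optionally partly spatially smooth
  (`intrinsic_smoothness` — adjacent siblings and locally shared states);
- per-image offsets `b_i ~ N(0, 0.2²)` log10 units and i.i.d. noise.

Raw intensity is `max(0, 10^z − 0.1)`, making the analysis transform an
exact inverse wherever `z ≥ −1`; clipping at zero intensity is the only
lossy step. Seeding is counter-based per sphere, so adding spheres never
reshuffles existing ones (marker values still shift through condition-level
standardization). Perturbation runs grow a connected patch per slice to a
target overexpression fraction (default 0.2, spill score for 30 % of
contact cells), add log10 effects by true class, and record everything in
the truth object.

What the generator does *not* emulate: segmentation errors, spillover
between channels, anisotropic or non-spherical spheroids, spatially
correlated measurement noise, 3D neighbor relations across slices, and
real panel covariance structure. Passing tests therefore validate the
inferential machinery under the stated model, not robustness to these
artifacts.

### Study conditions used by the validation suite

- `SyntheticConfig()` — the realistic default: 5 spheres × 5 slices,
  ~5,000 cell sections, a 20-marker panel mixing gradient, hypoxia,
  rim-band, ligand/responder, cell-cycle and structural markers. Its panel
  medians (gradient-alone ≈ 0.09, neighborhood-alone ≈ 0.12,
  internal-alone ≈ 0.6, full ≈ 0.7) reproduce the qualitative regime of
  real spheroid panels: internal state dominant, the neighborhood largely
  containing the gradient.
- `recovery_config()` — parameter recovery: near-equatorial sections of
  size-matched spheres (the gradient otherwise has between-image variance
  that the technical baseline absorbs, biasing the distance share), one
  smoothing round, and noise-free reporter markers exposing each latent
  factor to the module that owns it.
- `hierarchy_config()` — the strict dependency chain described above.
- `perturbation_config()` — ~100 small spheres, two sections each, a
  deliberately near-inert 12-marker panel (patchy background does not
  average out within a contiguous patch and would dominate sphere-level
  class-mean noise), modest staining offsets, 9-choose-4 barcodes, 24 mock
  spheres so the control baseline is tight.

Problem sizes throughout (cells per condition, seeds per claim, constructs
per run) are the package's chosen validation scale: large enough that
Monte-Carlo error is well inside each asserted tolerance, small enough to
keep the full suite interactive.

## Known limitations

Linear marker relationships only; residual spatial correlation beyond the
random-intercept structure is not modeled (both acknowledged limitations of
the approach itself). Point mode cannot reproduce mask-geometry effects.
The mean-intensity binarization is fragile for unbalanced plugs, which is a
property of the method, deliberately preserved. Negative corrected R² (a
submodel fitting worse than the technical baseline plus penalty) is
reported raw.
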