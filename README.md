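# spherovar

Deconvolution of single-cell marker variability in 3D spheroid imaging data
into global-environment, local-neighborhood, spatial-autocorrelation and
internal-cell-state contributions.

Spheroids are clonal 3D microtissues in which nutrient and oxygen gradients,
cell–cell contacts and intrinsic cell state jointly shape every marker a
multiplexed imaging experiment measures. `spherovar` implements the
quantitative machinery for analyzing such experiments at the cell-table
level — the per-cell measurement tables produced downstream of segmentation
of imaging mass cytometry (IMC) sections of pooled, metal-barcoded
spheroids — together with a synthetic spheroid generator with full ground
truth, so that every inferential step can be validated against known
parameters.

## What it computes

**Variance decomposition (the core).** Per condition, the transformed level
of marker *p* in each cell section is modeled as

```
y_p = β_pi + BS(d) + Σ_{m≠p} β_m^nb x_m^nb + β_p^nb x_p^nb + Σ_{m≠p} β_m^int x_m^int + ε
```

where `β_pi` are per-image intercepts (staining/batch offsets), `BS(d)` is a
cubic B-spline of the corrected distance to the sphere border (global
environment), `x_m^nb` are neighbor means of the other markers (local
neighborhood), `x_p^nb` is the neighbor mean of the target itself
(autocorrelation) and `x_m^int` are the cell's other markers (internal
state). Explained variance is reported as corrected R² relative to the
image-intercept-only technical baseline,

```
R² = 1 − (1 − R²_uncorr) / (1 − R²_tech),
```

and each module's contribution is the corrected-R² increment when it is
added along an ordering of the four modules. All 4! orderings are scanned;
the ordering minimizing the mean variance of the increments defines the
reported hierarchy, and order-averaged increments are the modules' Shapley
values.

**Supporting machinery.**

- spherical-cap correction of the planar distance to border,
  `r_real = R − √(R² − 2rx + x²)`, plus per-image contact graphs;
- k-of-n combinatorial metal debarcoding with majority, minimum-count and
  dominance rules, and cisplatin plate-group capacity doubling;
- `log10(x + 0.1)` intensity transform with percentile winsorization,
  cell- and image-level quality control, per-image residualization;
- image-residualized correlation structure: marker–marker and
  cell-versus-neighbor matrices, spatial autocorrelation, cosine/average
  hierarchical marker clustering, distance-to-border profiles;
- chimeric-overexpression effect calling: overexpressor / ambiguous /
  neighbor / bystander classification and a linear mixed-effects model with
  sphere/site/image intercepts, Benjamini–Hochberg FDR and joint
  significance criteria;
- a synthetic generator producing spheroid-slice cell tables with radial
  gradients, neighbor-coupled fields, shared intrinsic factors, staining
  offsets, barcodes and perturbation patches — all with ground truth.

## Worked example

```python
import spherovar as sv
from spherovar import preprocess

cfg = sv.SyntheticConfig()                      # 5 spheres x 5 slices, 20 markers
cells, truth = sv.generate_condition(cfg, seed=7)
markers = [m.name for m in cfg.markers]
trans = preprocess.transform_intensities(cells[[f"raw_{m}" for m in markers]])
for m in markers:
    cells[f"value_{m}"] = trans[f"raw_{m}"]
graph = sv.build_neighbor_graph(
    cells[["pos_x", "pos_y"]].to_numpy(), cells["image_id"].to_numpy(),
    cfg.contact_radius, cells["cell_id"].to_numpy(),
)
result = sv.decompose_condition(cells, markers, graph, condition="demo",
                                ordering=("dist", "nb", "self", "int"))
```

On the default condition (4,957 cell sections) this prints, for a few
markers:

```
  marker  r2_full  stack_dist  stack_nb  stack_self  stack_int
     pS6    0.762       0.182     0.047       0.024      0.510
     CA9    0.739       0.492     0.015       0.039      0.193
  pSTAT3    0.701       0.048     0.204       0.050      0.399
     pRB    0.777       0.123     0.001       0.000      0.653
Vimentin    0.644       0.028     0.012       0.133      0.472
```

Reading: the hypoxia marker CA9 is dominated by the radial gradient
(`stack_dist` 0.49 of its variance), the ligand-responsive pSTAT3 by its
neighborhood (0.20), the patchy structural marker Vimentin by its own
spatial autocorrelation (0.13), and the cell-cycle marker pRB by internal
state (0.65) with a residual gradient component — the spatial segregation
patterns the generator was configured to produce. Panel medians on this run
are dist-alone 0.093, nb-alone 0.115, int-alone 0.593, full model 0.713.

The same pipeline is available from the shell:

```bash
spherovar pipeline --seed 7 --out runs/demo
spherovar report --run-dir runs/demo
```

## Layout

```
src/spherovar/
  synthetic.py      generator: geometry, latent fields, barcodes, patches
  geometry.py       distance to border, spherical-cap correction, graphs
  barcoding.py      k-of-n codes, binarization, slice assignment, cisplatin
  preprocess.py     transform, winsorization, QC, residualization
  decomposition.py  modular model, corrected R2, order scan, Shapley
  spatial.py        correlations, autocorrelation, clustering, profiles
  perturbation.py   expression classes, mixed-effects effect calling
  io.py             cell-table IO, run config, pipeline driver
  cli.py            command-line interface
```
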