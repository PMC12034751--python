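# Methods

## Box-counting dimension

The estimator follows the published box-counting procedure for laser-scanned
trees. The initial box is the axis-aligned cube whose edge equals the
largest axis extent of the cloud, anchored at the minimum corner. Edges are
halved while they remain at or above a lower cutoff (default 0.1 m — about
the scale of scanner noise and registration error; configurable). Cells are
half-open, `[a, a + edge)` per axis, with points on the global maximum face
assigned to the last cell, so every point falls in exactly one box. D_b is
the ordinary-least-squares slope of ln N against ln(1/s), all scales
weighted equally; the fit R² is reported so poor log-linearity is visible.
A single fixed lattice is used — no rotation or anchor averaging — so the
estimate is deterministic and exactly invariant under translation (the
anchor follows the cloud). Because the lower cutoff is an absolute length,
scale invariance holds in the relative sense: scaling the cloud and the
cutoff by the same factor reproduces the identical dyadic ladder and
therefore the identical slope.

`box_dimension` also accepts `n_scales` to pin the ladder depth explicitly.
This matters for analytic reference objects where the finest edge is part
of the object's definition: a 64³ grid filling a cube is counted down to a
1/64 edge (7 scales) and returns D_b = 3.000; 4096 collinear points return
1.000; a regular planar grid returns 2.000.

For a finite sample of a finite prefractal the choice of window is a
genuine trade-off. A level-3 Menger-sponge prefractal (Hausdorff dimension
log 20 / log 3 ≈ 2.727) is self-similar only between its outer scale and
its construction resolution 3⁻³; at the coarsest dyadic scales the counts
are those of a nearly solid cube (positive bias), and once boxes shrink
toward the mean inter-point spacing the counts saturate at the sample size
(negative bias). The validation uses 5×10⁵ points and an 8-scale ladder
(finest edge 1/128), which spans the self-similar band symmetrically; the
estimate is 2.712 ± 0.001 across seeds, within 0.015 of the analytic value.
With fewer points or a ladder stopping at the construction resolution the
two biases no longer balance and the estimate drifts toward 2.8–2.9; this
is a finite-size property of dyadic counting on base-3 objects, not an
estimator defect.

Stand-level D_b concatenates the member trees' clouds and re-runs the
identical estimator, so a single-tree plot reproduces that tree's value
exactly and the result is independent of roster order.

## Synthetic forest generator

The generator emulates a mountain-forest study design: 14 circular plots of
25 m diameter on slopes of 2–40°, elevations 1300–3400 m, mean annual
precipitation 1180–3600 mm yr⁻¹, stem densities 245–2242 ha⁻¹, seven
needle-leaved and seven broad-leaved plots (11 monospecific, 3 two-species
conifer mixtures), multi-stem broad-leaved trees with 2–8 stems combined by
the quadratic-sum DBH rule, heights up to ~36 m and DBH 3–73 cm.

Trees are geometric primitives. Stems are vertical cylinder surfaces of the
specified diameter (multi-stems offset on a small ring, sharing one unified
crown envelope). Conifer crowns are cone surfaces from the crown base to
the apex; broad-leaved crowns are ellipsoids. Three rendering intensities
control realism:

- **surface spacing** 0.02 m (comparable to a field cloud subsampled at
  0.01 m minimum spacing), of which only a 10 % random subset of envelope
  points is kept — real crowns are foliage and branches, not closed
  shells, and a dense shell would force every crown's D_b above 2;
- **crown_fill** in (0, 1]: interior points at one per (14 × spacing)³
  cell at fill 1 — D_b increases strictly in this parameter;
- **branch_density**: line segments from the stem axis to the envelope
  (3 per meter of crown length per unit density), the 1D skeleton.

With these settings the suite's 507 trees span D_b ≈ 1.7–2.4 (conifers
lower, broadleaves higher), matching the span reported for scanned
mountain-forest trees, and every tree stays below the 2.72 ceiling. Plots
place each tree on the inclined plane given by slope and aspect, add a
ground disc (5 cm mean spacing, extended past the plot edge so overhanging
crowns sit above sampled terrain) and label every point with its tree id
(0 = ground). All sampling is driven by per-spec seeds; identical specs
yield bit-identical clouds.

What the generator does **not** emulate: occlusion by a moving scanner,
leaf-level geometry, biologically faithful branching (no L-systems),
registration error, intensity/RGB. Passing tests therefore demonstrate the
correctness of the estimators and pipeline plumbing on clouds with known
truth, not the field accuracy of any metric on real scans.

## Preprocessing

The chain is fixed and logged: radius noise filter (0.1 m, ≥ 4 neighbors;
the neighbor count is this package's convention — a common
statistical-outlier default, configurable), ground normalization, voxel
subsampling (0.01 m, keeping the point nearest each cell centroid on an
origin-anchored lattice, which makes the operation idempotent), circular
clipping to the slope-corrected radius r·cos α (closed boundary: a point at
exactly r_corr is retained). Only the clipping radius is slope-corrected,
not the coordinates. The terrain model is the per-cell minimum z on a 1 m
grid, empty cells filled from the nearest occupied cell, bilinearly
interpolated between cell centers. On sloped plots ground normalization
necessarily warps heights that are not directly above the terrain — the
uphill edge of a crown appears lower by up to tan(slope) × crown radius;
this is a property of the operation itself, so crown-base recovery is
validated on gentle slopes and tree height (which uses the cloud's own
extremes) on steep ones. Trees below 3 m total height are excluded
(inclusive threshold).

## Architecture metrics

Heights are measured above the cloud's lowest point (zero for normalized
clouds). DBH uses an algebraic (Kåsa) circle fit on the horizontal
projection of the 1.3 ± 0.05 m slice; slices that decompose into several
point clusters (single-linkage at 0.15 m) are fitted per stem and combined
by the quadratic sum, mirroring the treatment of stems separated below
breast height; with fewer than 10 slice points the estimate falls back to
the maximum chord between two opposing points and is flagged. The crown
base is the lower bound of the lowest 10 cm layer whose horizontal hull
area exceeds 3 × the stem cross-section sustained over 3 consecutive
layers — the threshold factor is this package's operationalization of
"lowest leaf-bearing branch" (the source description is morphological, not
algorithmic); on clean synthetic trees the recovered CBH moves by at most
one layer for factors 2–4. Crown volume sums layer hull areas × 0.1 m
(a 3D-hull volume would ignore concavity in z). Mean crown radius averages
the per-sector maxima over the non-empty one-degree sectors (empty sectors
are excluded, their count reported). Crown asymmetry is the horizontal
distance from the stem base to the area centroid of the maximal-layer hull
polygon; ties between equally maximal layers break toward the lowest. AGB
multiplies an externally supplied aboveground volume (e.g. from a cylinder
QSM, which this package does not fit) by species wood density.

## Statistics

OLS, VIF (auxiliary regressions, warning above 5) and bidirectional
stepwise AIC (starting from the full model; ties break toward fewer terms,
then lexicographically — the final AIC can never exceed the full model's)
operate on log-transformed architecture predictors; natural logs are used
throughout (the base only rescales coefficients). Mixed models are
random-intercept-per-plot fits by maximum likelihood (not REML, so AICs are
comparable across fixed-effect structures), with predictors standardized to
mean 0 / SD 1 beforehand; marginal and conditional R² follow the
variance-partition definition (fixed / total and fixed-plus-random /
total). Singular fits (group variance → 0) are flagged and returned, with
marginal residuals substituted where conditional ones are undefined.
Moran's I uses inverse-Euclidean-distance weights with zero diagonal and no
row standardization, and a two-sided p-value from the normal approximation
under the normality assumption (E[I] = −1/(n−1)); in the pipeline it is
applied to plot-mean residuals at plot centers. Welch's t reports the
Welch–Satterthwaite df; all tests are two-sided at α = 0.05. Sample (n−1)
standard deviations are used for the per-plot D_b summaries (small n); the
SD is undefined and flagged for single-tree plots.

The generative parameter-recovery experiment simulates tree tables from the
best architecture model of tree D_b,

```
D_b = 1.95 + 0.067·log CL + 0.155·log CV − 0.312·log TTH + ε,  ε ~ N(0, 0.10),
```

with heights lognormal around 12 m, crown length a uniform 0.3–0.9 fraction
of height, and crown volume ∝ radius² × length with lognormal scatter —
correlated the way the synthetic suite's trees are (all VIFs < 5) without
being collinear. Refitting OLS on 200 replicates of n = 546 recovers every
coefficient; the acceptance script reports the mean intercept and mean
log-height coefficient.

## Problem sizes and numerical choices

The default suite totals ~500 trees and runs in about half a minute for
tree-level D_b (the full pipeline with preprocessing takes a few minutes);
unit tests use three 8-tree plots. Box counting packs cell indices into a
single 64-bit key before deduplication. Convex hulls come from Qhull via
scipy; degenerate layers (< 3 points or collinear) get area 0, and a
degenerate (coplanar) crown is rejected with a flag rather than silently
returning 0. The synthetic landscape assigns plot centers at least 500 m
apart inside a 20 km window purely to give Moran's I realistic coordinates.

## Known limitations

- D_b depends mildly on the lower cutoff; the default 0.1 m is reported in
  every result object and the full scale/count arrays are emitted for
  audit.
- The CBH layer-threshold rule and the crown-asymmetry definition
  (stem-base to maximal-layer centroid) are this package's conventions;
  other operationalizations exist and the source descriptions are
  ambiguous.
- Stand D_b ≥ max member D_b holds throughout the synthetic suite and is
  asserted there, but it is an empirical regularity of merging, not a
  theorem: merging changes the bounding cube as well as the counts.
- Mixed-model p-values are Wald-type; with 14 plots the between-plot
  predictors carry few effective degrees of freedom.
- XYZ text is the only cloud format read and written.
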