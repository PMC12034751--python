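# canopyfractal

Structural complexity of forest point clouds: box-counting fractal dimension
(D_b) at tree and stand level, crown-architecture metrics, plot
preprocessing, stand aggregation, and the statistical models that relate
them — together with a synthetic mountain-forest generator so the entire
analysis chain can be exercised and validated without any field data.

## The problem

Terrestrial and mobile laser scanning deliver dense 3D point clouds of
forest stands. A single number that summarizes how completely a tree (or a
whole stand) fills the 3D space it occupies is the **box-counting
dimension**

```
D_b = slope of  ln N(s)  versus  ln(1 / s)
```

where boxes of edge `s` (relative to the initial bounding cube) are laid
over the cloud in a dyadic cascade — the bounding cube is halved
repeatedly — and `N(s)` is the number of boxes containing at least one
point. A pole-like object has D_b ≈ 1, a flat surface 2, a solid cube 3;
real trees lie between, with a theoretical ceiling well below 2.72.

Around the estimator, the package computes the standard single-tree
architectural attributes from a segmented, ground-normalized cloud — total
tree height (TTH), diameter at breast height (DBH, circle fit at 1.3 m,
quadratic-sum combination `sqrt(Σ d_i²)` for multi-stem trees), crown base
height (CBH), layered 10-cm convex-hull crown areas (Max_crownarea,
H_maxarea), crown surface area (CSA), mean crown radius (MCR, 360
one-degree sectors), crown volume, crown length (CL = TTH − CBH), crown
asymmetry, and AGB = volume × wood density — plus plot-level descriptors
(stem density on the slope-corrected area r·cos α, Shannon diversity,
northness/eastness aspect transforms) and the statistics used in this
literature: Spearman correlations, Welch's t, multiple regression with
stepwise-AIC selection and VIF screening, random-intercept mixed models
with marginal/conditional R², Moran's I on residuals, and simple
regressions of stand D_b on the sum/max/SD of member-tree D_b.

## Worked example

```python
from canopyfractal import TreeSpec, generate_tree
from canopyfractal.architecture import analyze_tree

spec = TreeSpec(
    species_label="Pinus", form="conifer",
    tth=15.0, cbh=6.0, crown_radius=2.2,
    stem_dbh_cm=[30.0], crown_fill=0.7, branch_density=1.0, rng_seed=5,
)
cloud = generate_tree(spec, point_spacing=0.02).cloud
rec = analyze_tree(1, spec.species_label, cloud, stem_base_xy=(0.0, 0.0))
```

prints (via the obvious format strings):

```
points:        54099
TTH  =  15.00 m      DBH =  30.0 cm   CBH =  6.0 m
CL   =   9.00 m      MCR =  2.18 m    CSA =  79.0 m^2
CrownVolume =   45.9 m^3   Max_crownarea = 15.12 m^2
D_b  = 1.970  (log-log fit R^2 = 0.9939, 8 scales)
counts per scale: [1, 2, 8, 30, 135, 743, 2906, 8354]
```

Every ground-truth parameter of the synthetic tree is recovered: the
15 m height and 6 m crown base exactly, the 30 cm DBH from the circle fit,
the 2.2 m crown radius as MCR ≈ 2.18 (sector maxima of a sparsely sampled
envelope), and a D_b of 1.97 — inside the 1.7–2.2 band typical of scanned
conifers, far from the solid-cube limit of 3.

The full pipeline (generate or read plots → noise filter → ground
normalization → voxel subsampling → circular clip → per-tree metrics and
D_b → stand aggregation → statistics → figures) runs from the command
line:

```
canopyfractal run --config run.yaml      # or: --seed 1 --out results_dir
canopyfractal boxdim --input tree.xyz --lower-cutoff 0.1 --json out.json
canopyfractal preprocess --input plot.xyz --output clean.xyz --slope 12
canopyfractal architecture --tree tree.xyz --stem-base 0,0
```

and writes `trees.csv` (one row per tree, Table-style columns TTH, DBH,
CBH, CSA, Max_crownarea, H_maxarea, MCR, CrownVolume, CL, CrownAsymmetry,
AGB, Db), `plots.csv`, fitted model summaries under `models/`, scatter
figures, a run log, and a provenance record echoing every parameter and
seed.

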