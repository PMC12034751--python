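"""Config-driven end-to-end run: clouds -> preprocessing -> tree metrics and
D_b -> stand aggregation -> statistics -> CSV/JSON report with provenance.

The stage order is fixed: generate or read labeled plot clouds, noise
filtering, ground normalization, voxel subsampling, circular clipping,
tree segmentation by label, the >= 3 m height filter, per-tree
architecture and box-dimension, stand-level box-dimension and summaries,
then the statistical models. Identical config and seeds give identical
CSV outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .architecture import analyze_tree
from .boxdim import box_dimension, stand_box_dimension
from .cloud import (
    PointCloud,
    clip_circular,
    normalize_ground,
    radius_noise_filter,
    read_xyz,
    slope_corrected_radius,
    voxel_subsample,
)
from .stand import PlotRecord, summarize_plot
from .stats import (
    lmm_random_intercept,
    morans_i,
    spearman,
    stepwise_aic,
    tree_to_stand_regression,
    vif,
)
from .synthetic import default_suite, generate_plot, generate_tree

__all__ = ["RunConfig", "run_pipeline", "suite_tree_db_table"]

log = logging.getLogger("canopyfractal")

#: Reference wood densities (kg m^-3) for the suite's species labels.
WOOD_DENSITY = {
    "Pinus": 430.0,
    "Abies": 390.0,
    "Cupressus": 470.0,
    "Alnus": 370.0,
    "Acer": 530.0,
    "Daphniphyllum": 500.0,
}

TREE_CSV_COLUMNS = [
    "plot_id",
    "tree_id",
    "species",
    "TTH",
    "DBH",
    "CBH",
    "CSA",
    "Max_crownarea",
    "H_maxarea",
    "MCR",
    "CrownVolume",
    "CL",
    "CrownAsymmetry",
    "AGB",
    "Db",
]


@dataclass
class RunConfig:
    """Parameters of one pipeline run; everything echoed into provenance."""

    mode: str = "synthetic"  # "synthetic" or "files"
    seed: int = 1
    out_dir: str = "canopyfractal_run"
    n_plots: int = 14  # synthetic mode: first n plots of the default suite
    point_spacing: float = 0.02
    voxel_spacing: float = 0.01
    noise_radius: float = 0.1
    min_neighbors: int = 4
    terrain_cell: float = 1.0
    lower_cutoff: float = 0.1
    min_height: float = 3.0
    make_figures: bool = True
    plot_files: list = field(default_factory=list)  # files mode: xyz paths
    plot_meta: list = field(default_factory=list)  # files mode: dicts per plot

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _preprocess_plot(cloud: PointCloud, cfg: RunConfig, slope_deg: float, radius_m: float):
    """Noise filter -> ground normalization -> subsampling -> clipping."""
    t0 = time.perf_counter()
    filtered = radius_noise_filter(cloud, cfg.noise_radius, cfg.min_neighbors)
    if filtered.is_empty:
        raise RuntimeError("radius_noise_filter removed every point")
    normalized, terrain = normalize_ground(filtered, cfg.terrain_cell)
    subsampled = voxel_subsample(normalized, cfg.voxel_spacing)
    r_corr = slope_corrected_radius(radius_m, slope_deg)
    clipped = clip_circular(subsampled, (0.0, 0.0), r_corr)
    if clipped.is_empty:
        raise RuntimeError("clip_circular removed every point")
    log.info(
        "preprocess: %d -> %d -> %d -> %d points (%.1f s)",
        len(cloud),
        len(filtered),
        len(subsampled),
        len(clipped),
        time.perf_counter() - t0,
    )
    return subsampled, clipped, terrain, r_corr


def _segment_trees(cloud: PointCloud):
    """Split a labeled cloud into per-tree clouds (label 0 = ground)."""
    if cloud.labels is None:
        raise RuntimeError("segmentation requires per-point tree labels")
    out = {}
    for tid in np.unique(cloud.labels):
        if tid == 0:
            continue
        out[int(tid)] = cloud.select(cloud.labels == tid)
    return out


def _plot_locations(n: int, seed: int) -> np.ndarray:
    """Synthetic plot-center coordinates (m) in a 20 km landscape window."""
    rng = np.random.default_rng(seed + 777)
    pts = []
    while len(pts) < n:
        p = rng.uniform(0, 20000, 2)
        if all(np.hypot(*(p - q)) > 500 for q in pts):
            pts.append(p)
    return np.asarray(pts)


def run_pipeline(config: RunConfig, specs=None) -> dict:
    """Execute the full analysis; returns paths of the written artifacts.

    ``specs`` optionally supplies an explicit list of PlotSpec objects in
    synthetic mode (otherwise the default suite is used). Any stage failure
    halts the run with a diagnostic naming the stage; partial outputs
    already written are retained.
    """
    out_dir = Path(config.out_dir)
    (out_dir / "models").mkdir(parents=True, exist_ok=True)
    if config.make_figures:
        (out_dir / "figures").mkdir(exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    timings: dict[str, float] = {}
    artifacts = {"out_dir": str(out_dir)}
    try:
        t0 = time.perf_counter()
        if config.mode == "synthetic":
            roster = specs if specs is not None else default_suite(config.seed)[: config.n_plots]
            plots_in = [(s, generate_plot(s, config.point_spacing).cloud) for s in roster]
        elif config.mode == "files":
            if not config.plot_files:
                raise RuntimeError("stage input: files mode needs plot_files")
            plots_in = []
            for path, meta in zip(config.plot_files, config.plot_meta):
                spec = _FileMeta(**meta)
                plots_in.append((spec, read_xyz(path)))
        else:
            raise RuntimeError(f"stage input: unknown mode {config.mode!r}")
        timings["generate_or_read"] = time.perf_counter() - t0
        log.info("input: %d plots", len(plots_in))

        tree_rows, plot_rows, plot_records = [], [], []
        centers = _plot_locations(len(plots_in), config.seed)
        t0 = time.perf_counter()
        for (spec, raw_cloud), center in zip(plots_in, centers):
            normalized, clipped, _terrain, r_corr = _preprocess_plot(
                raw_cloud, config, spec.slope_deg, getattr(spec, "radius", 12.5)
            )
            segments = _segment_trees(normalized)
            records = []
            spec_trees = getattr(spec, "tree_specs", None)
            for tid, tcloud in sorted(segments.items()):
                ts = spec_trees[tid - 1] if spec_trees else None
                species = ts.species_label if ts else f"sp{tid}"
                base = ts.stem_base_xy if ts else tuple(tcloud.xyz[:, :2].mean(axis=0))
                if len(tcloud) < 100:
                    log.info("plot %s tree %d: too few points, skipped", spec.plot_id, tid)
                    continue
                rec = analyze_tree(
                    tid,
                    species,
                    tcloud,
                    stem_base_xy=base,
                    wood_density_kg_m3=WOOD_DENSITY.get(species),
                    agb_volume_m3=None,
                    lower_cutoff=config.lower_cutoff,
                )
                records.append(rec)
            kept = [r for r in records if r.metrics.tth_m >= config.min_height]
            if not kept:
                raise RuntimeError(
                    f"stage height_filter: no tree of plot {spec.plot_id} reaches "
                    f"{config.min_height} m"
                )
            plot = PlotRecord(
                plot_id=spec.plot_id,
                radius_m=getattr(spec, "radius", 12.5),
                slope_deg=spec.slope_deg,
                aspect_deg=spec.aspect_deg,
                elevation_m=spec.elevation_m,
                precipitation_mm=spec.precipitation_mm,
                trees=kept,
            )
            plot.stand_db = stand_box_dimension(kept, lower_cutoff=config.lower_cutoff)
            summary = summarize_plot(plot)
            plot_records.append(plot)
            for r in kept:
                m = r.metrics
                tree_rows.append(
                    {
                        "plot_id": spec.plot_id,
                        "tree_id": r.tree_id,
                        "species": r.species_label,
                        "TTH": m.tth_m,
                        "DBH": m.dbh_cm,
                        "CBH": m.cbh_m,
                        "CSA": m.csa_m2,
                        "Max_crownarea": m.max_crownarea_m2,
                        "H_maxarea": m.h_maxarea_m,
                        "MCR": m.mcr_m,
                        "CrownVolume": m.crown_volume_m3,
                        "CL": m.cl_m,
                        "CrownAsymmetry": m.crown_asymmetry_m,
                        "AGB": m.agb_kg,
                        "Db": r.db.db,
                    }
                )
            plot_rows.append(
                {
                    "plot_id": spec.plot_id,
                    "center_x": center[0],
                    "center_y": center[1],
                    "radius_m": plot.radius_m,
                    "r_corr_m": r_corr,
                    "slope_deg": spec.slope_deg,
                    "aspect_deg": spec.aspect_deg,
                    "elevation_m": spec.elevation_m,
                    "precipitation_mm": spec.precipitation_mm,
                    "n_trees": len(kept),
                    "stem_density_ha": summary.stem_density_ha,
                    "richness": summary.richness,
                    "shannon_h": summary.shannon_h,
                    "northness": summary.northness,
                    "eastness": summary.eastness,
                    "db_sum": summary.db_sum,
                    "db_max": summary.db_max,
                    "db_sd": summary.db_sd,
                    "db_mean": summary.db_mean,
                    "stand_db": plot.stand_db.db,
                }
            )
            log.info(
                "plot %s: %d trees kept, stand Db %.3f",
                spec.plot_id,
                len(kept),
                plot.stand_db.db,
            )
        timings["plots"] = time.perf_counter() - t0

        trees_df = pd.DataFrame(tree_rows, columns=TREE_CSV_COLUMNS)
        plots_df = pd.DataFrame(plot_rows)
        trees_path = out_dir / "trees.csv"
        plots_path = out_dir / "plots.csv"
        trees_df.to_csv(trees_path, index=False, float_format="%.6f")
        plots_df.to_csv(plots_path, index=False, float_format="%.6f")
        artifacts["trees_csv"] = str(trees_path)
        artifacts["plots_csv"] = str(plots_path)

        t0 = time.perf_counter()
        stats_out = _run_statistics(trees_df, plots_df, out_dir)
        artifacts.update(stats_out)
        timings["statistics"] = time.perf_counter() - t0

        if config.make_figures:
            t0 = time.perf_counter()
            _make_figures(trees_df, plots_df, out_dir / "figures")
            timings["figures"] = time.perf_counter() - t0

        provenance = {
            "package": "canopyfractal",
            "version": __version__,
            "config": dataclasses.asdict(config),
            "timings_s": {k: round(v, 3) for k, v in timings.items()},
            "n_trees": len(trees_df),
            "n_plots": len(plots_df),
        }
        with open(out_dir / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=2)
        artifacts["provenance"] = str(out_dir / "provenance.json")
        return artifacts
    finally:
        log.removeHandler(handler)
        handler.close()


@dataclass
class _FileMeta:
    """Plot metadata accompanying an XYZ file in files mode."""

    plot_id: str
    slope_deg: float = 0.0
    aspect_deg: float = 0.0
    elevation_m: float = 0.0
    precipitation_mm: float = 0.0
    radius: float = 12.5
    tree_specs = None


def _run_statistics(trees_df: pd.DataFrame, plots_df: pd.DataFrame, out_dir: Path) -> dict:
    """Correlations, stepwise OLS, mixed models, Moran's I, tree-to-stand."""
    models_dir = out_dir / "models"
    artifacts = {}

    # Spearman correlations of Db with each architecture metric
    corr_rows = []
    for col in ("TTH", "DBH", "CBH", "CSA", "Max_crownarea", "H_maxarea", "MCR",
                "CrownVolume", "CL", "CrownAsymmetry"):
        sub = trees_df[["Db", col]].dropna()
        if len(sub) >= 3 and sub[col].nunique() > 1:
            rho, p = spearman(sub[col], sub["Db"])
            corr_rows.append({"metric": col, "rho": rho, "p": p, "n": len(sub)})
    pd.DataFrame(corr_rows).to_csv(models_dir / "spearman.csv", index=False,
                                   float_format="%.6f")

    # multiple regression of Db on log-transformed architecture
    table = trees_df.copy()
    for col, name in (("CL", "log_cl"), ("CrownVolume", "log_cv"), ("TTH", "log_tth"),
                      ("MCR", "log_mcr")):
        table[name] = np.where(table[col] > 0, np.log(table[col].astype(float)), np.nan)
    table = table.dropna(subset=["Db", "log_cl", "log_cv", "log_tth", "log_mcr"])
    candidates = ["log_cl", "log_cv", "log_tth", "log_mcr"]
    best = stepwise_aic(table, "Db", candidates)
    vifs = vif(table, [c for c in candidates if c in best.params])
    for name, value in vifs.items():
        if value > 5:
            log.warning("VIF above 5 for %s: %.2f", name, value)
    _write_model(models_dir / "ols_architecture.json", best, extra={"vif": vifs})

    # mixed models: plot as random intercept
    merged = trees_df.merge(
        plots_df[["plot_id", "stem_density_ha", "shannon_h", "richness",
                  "elevation_m", "precipitation_mm", "slope_deg",
                  "center_x", "center_y"]],
        on="plot_id",
    )
    lmm_results = {}
    for name, fixed in (
        ("lmm_interaction_full", ["shannon_h", "richness", "stem_density_ha"]),
        ("lmm_interaction_best", ["stem_density_ha"]),
        ("lmm_environment_full", ["elevation_m", "precipitation_mm", "slope_deg"]),
        ("lmm_environment_best", ["precipitation_mm"]),
    ):
        usable = [f for f in fixed if merged[f].std(ddof=1) > 0]
        if not usable:
            continue
        # plot-level predictors: the between-plot design must have full rank
        plot_design = merged.groupby("plot_id")[usable].first()
        if np.linalg.matrix_rank(np.column_stack(
                [np.ones(len(plot_design)), plot_design.to_numpy()])) < len(usable) + 1:
            log.warning("%s: rank-deficient plot-level design, skipped", name)
            continue
        try:
            res = lmm_random_intercept(merged, "Db", usable, "plot_id")
        except np.linalg.LinAlgError:
            log.warning("%s: singular mixed-model fit, skipped", name)
            continue
        lmm_results[name] = res
        _write_model(models_dir / f"{name}.json", res)
    artifacts["models_dir"] = str(models_dir)

    # Moran's I on plot-mean residuals of the best interaction model, at the
    # plot centers (spatial dependency is a between-plot question here)
    if "lmm_interaction_best" in lmm_results and merged["plot_id"].nunique() >= 3:
        res = lmm_results["lmm_interaction_best"]
        resid_df = merged[["plot_id", "center_x", "center_y"]].iloc[: len(res.residuals)].copy()
        resid_df["resid"] = res.residuals
        by_plot = resid_df.groupby("plot_id", sort=True).mean(numeric_only=True)
        i_obs, p = morans_i(
            by_plot["resid"].to_numpy(), by_plot[["center_x", "center_y"]].to_numpy()
        )
        with open(models_dir / "morans_i.json", "w") as fh:
            json.dump({"moran_i": i_obs, "p": p, "n": int(len(by_plot))}, fh, indent=2)

    # tree-to-stand regressions
    t2s = tree_to_stand_regression(plots_df.dropna(subset=["db_sd"]))
    summary_rows = []
    for pred, fit in t2s.items():
        summary_rows.append(
            {
                "predictor": pred,
                "slope": fit.params[pred],
                "intercept": fit.params["const"],
                "r2": fit.r2,
                "p": fit.pvalues[pred],
                "n": fit.n,
            }
        )
    pd.DataFrame(summary_rows).to_csv(models_dir / "tree_to_stand.csv", index=False,
                                      float_format="%.6f")
    return artifacts


def _write_model(path: Path, result, extra: dict | None = None) -> None:
    payload = {
        "formula": result.formula,
        "params": {k: float(v) for k, v in result.params.items()},
        "bse": {k: float(v) for k, v in result.bse.items()},
        "pvalues": {k: float(v) for k, v in result.pvalues.items()},
        "aic": result.aic,
        "r2": result.r2,
        "r2_marginal": result.r2_marginal,
        "r2_conditional": result.r2_conditional,
        "rmse": result.rmse,
        "n": result.n,
        "flags": result.flags,
    }
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def _make_figures(trees_df: pd.DataFrame, plots_df: pd.DataFrame, fig_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    metrics = ["TTH", "DBH", "CBH", "H_maxarea", "Max_crownarea", "CSA", "MCR", "CL"]
    fig, axes = plt.subplots(2, 4, figsize=(16, 8))
    for ax, col in zip(axes.ravel(), metrics):
        for sp, grp in trees_df.groupby("species"):
            ax.scatter(grp[col], grp["Db"], s=6, alpha=0.6, label=sp)
        ax.set_xlabel(col)
        ax.set_ylabel("D_b")
    axes[0, 0].legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(fig_dir / "db_vs_architecture.png", dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    for ax, pred in zip(axes, ("db_sum", "db_max", "db_sd")):
        sub = plots_df.dropna(subset=[pred])
        ax.scatter(sub[pred], sub["stand_db"], s=20)
        ax.set_xlabel(f"tree {pred}")
        ax.set_ylabel("stand D_b")
    fig.tight_layout()
    fig.savefig(fig_dir / "tree_to_stand.png", dpi=120)
    plt.close(fig)


def suite_tree_db_table(
    seed: int = 1,
    n_plots: int = 14,
    point_spacing: float = 0.02,
    lower_cutoff: float = 0.1,
    min_height: float = 3.0,
) -> pd.DataFrame:
    """Tree-level D_b for every tree of the default synthetic suite.

    Trees are rendered individually (box-dimension is translation
    invariant, so placing them on the plot plane and re-normalizing the
    ground would give the same estimate) and trees below the height
    threshold are excluded, as in the plot pipeline.
    """
    rows = []
    for spec in default_suite(seed)[:n_plots]:
        for j, ts in enumerate(spec.tree_specs, start=1):
            if ts.tth < min_height:
                continue
            cloud = generate_tree(ts, point_spacing).cloud
            res = box_dimension(cloud, lower_cutoff=lower_cutoff)
            rows.append(
                {
                    "plot_id": spec.plot_id,
                    "tree_id": j,
                    "species": ts.species_label,
                    "form": ts.form,
                    "crown_fill": ts.crown_fill,
                    "tth": ts.tth,
                    "db": res.db,
                    "fit_r2": res.fit_r2,
                }
            )
    return pd.DataFrame(rows)
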