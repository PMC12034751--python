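"""Plot-level descriptors: stem density, diversity, environment transforms,
and tree-D_b summaries used to predict stand-level D_b."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .boxdim import BoxDimResult
from .cloud import slope_corrected_radius

__all__ = [
    "PlotSummary",
    "PlotRecord",
    "stem_density",
    "shannon_index",
    "northness_eastness",
    "db_summaries",
    "summarize_plot",
]


@dataclass
class PlotSummary:
    stem_density_ha: float = None
    richness: int = None
    shannon_h: float = None
    db_sum: float = None
    db_max: float = None
    db_sd: float = None  # None (flagged) for single-tree plots
    db_mean: float = None
    northness: float = None
    eastness: float = None
    flags: list = field(default_factory=list)


@dataclass
class PlotRecord:
    plot_id: str
    radius_m: float
    slope_deg: float
    aspect_deg: float
    elevation_m: float
    precipitation_mm: float
    trees: list = field(default_factory=list)  # TreeRecord, all >= 3 m
    stand_db: BoxDimResult = None
    summaries: PlotSummary = None

    @property
    def area_ha(self) -> float:
        r_corr = slope_corrected_radius(self.radius_m, self.slope_deg)
        return math.pi * r_corr**2 / 1e4


def stem_density(n_trees: int, radius_m: float, slope_deg: float) -> float:
    """Stems per hectare on the slope-corrected horizontal plot area."""
    if n_trees < 0:
        raise ValueError("tree count cannot be negative")
    if n_trees == 0:
        return 0.0
    r_corr = slope_corrected_radius(radius_m, slope_deg)
    return n_trees / (math.pi * r_corr**2) * 1e4


def shannon_index(species_counts) -> float:
    """Shannon diversity H = -sum p_i ln p_i over species proportions.

    ``species_counts`` may be a mapping species -> count, or a sequence of
    counts; fractional values are treated as proportions and must sum to 1.
    A monospecific plot yields exactly 0.
    """
    if hasattr(species_counts, "values"):
        values = np.asarray(list(species_counts.values()), dtype=float)
    else:
        values = np.asarray(list(species_counts), dtype=float)
    values = values[values > 0]
    if len(values) == 0:
        raise ValueError("no species with positive abundance")
    total = values.sum()
    is_proportions = np.all(values <= 1.0) and not np.allclose(values, np.round(values))
    if is_proportions and not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError("species proportions must sum to 1")
    p = values / total
    return float(-np.sum(p * np.log(p)) + 0.0)  # +0.0 avoids -0.0


def northness_eastness(aspect_deg: float) -> tuple[float, float]:
    """(cos, sin) of the aspect angle converted to radians.

    Northness approaches 1 for north-facing and -1 for south-facing
    slopes; eastness approaches 1 for east-facing and -1 for west-facing.
    """
    rad = math.radians(aspect_deg)
    return math.cos(rad), math.sin(rad)


def db_summaries(trees) -> dict:
    """Sum, max, sample SD (n-1) and mean of member tree D_b values.

    ``trees`` is a sequence of TreeRecord (db attribute) or raw floats.
    For a single tree the SD is undefined and returned as None.
    """
    vals = []
    for t in trees:
        db = getattr(t, "db", t)
        vals.append(db.db if hasattr(db, "db") else float(db))
    if not vals:
        raise ValueError("no trees")
    arr = np.asarray(vals, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else None
    return {
        "db_sum": float(arr.sum()),
        "db_max": float(arr.max()),
        "db_sd": sd,
        "db_mean": float(arr.mean()),
    }


def summarize_plot(plot: PlotRecord) -> PlotSummary:
    """Fill a PlotSummary from the plot's tree roster and geometry."""
    s = PlotSummary()
    n = len(plot.trees)
    s.stem_density_ha = stem_density(n, plot.radius_m, plot.slope_deg)
    species = [t.species_label for t in plot.trees]
    counts = {sp: species.count(sp) for sp in set(species)}
    s.richness = len(counts)
    s.shannon_h = shannon_index(counts) if counts else None
    if any(t.db is not None for t in plot.trees):
        d = db_summaries([t for t in plot.trees if t.db is not None])
        s.db_sum, s.db_max, s.db_sd, s.db_mean = (
            d["db_sum"],
            d["db_max"],
            d["db_sd"],
            d["db_mean"],
        )
        if s.db_sd is None:
            s.flags.append("db_sd_undefined_single_tree")
    s.northness, s.eastness = northness_eastness(plot.aspect_deg)
    plot.summaries = s
    return s
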