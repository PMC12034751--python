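"""Synthetic mountain-forest point clouds with known ground truth.

Every downstream stage (preprocessing, box-dimension, crown architecture,
stand aggregation, statistics) is testable against the parameters used to
build the clouds, so no field data are required. Trees are geometric
primitives: vertical cylinder stems plus a cone-surface crown for
needle-leaved (conifer) forms or an ellipsoid crown for broad-leaved forms,
with interior filling governed by ``crown_fill`` and line-like branch
scatter governed by ``branch_density``. Multi-stem broad-leaved trees
(2-8 stems) share one unified crown envelope.

The module also provides analytic fractal reference objects (line, plane,
cube, Menger sponge) whose box-dimension is known in closed form; these
are the estimator's oracles.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .cloud import PointCloud, write_xyz

__all__ = [
    "TreeSpec",
    "PlotSpec",
    "LabeledCloud",
    "generate_tree",
    "generate_plot",
    "sample_fractal",
    "default_suite",
    "write_labeled_cloud",
]

#: Default point spacing on rendered surfaces (m); comparable to a cloud
#: subsampled to 0.01 m minimum spacing.
DEFAULT_SPACING = 0.02

#: Interior crown filling uses an effective spacing of this multiple of the
#: surface spacing at crown_fill = 1 (one point per (14*spacing)^3 cell).
_INTERIOR_SPACING_FACTOR = 14.0

#: Fraction of full-density crown-envelope points retained. Real crowns are
#: foliage and branch structure, not closed shells; rendering the envelope
#: sparsely (with branch lines providing the 1D skeleton) reproduces the
#: tree-level D_b range reported for scanned mountain-forest trees
#: (roughly 1.0-2.2) instead of pushing every crown above 2.
_SURFACE_COVERAGE = 0.1

#: Branch line segments per meter of crown length per unit branch_density.
_BRANCHES_PER_METER = 3.0


@dataclass
class TreeSpec:
    """Ground-truth parameters of one synthetic tree.

    ``tth`` total tree height (m), ``cbh`` crown base height (m),
    ``crown_radius`` (m), ``stem_dbh_cm`` per-stem diameters at breast
    height (cm, one entry per stem), ``crown_fill`` in (0, 1] controls
    interior point intensity, ``branch_density`` >= 0 controls the number
    of branch line segments per meter of crown length.
    """

    species_label: str
    form: str  # "conifer" or "broadleaf"
    tth: float
    cbh: float
    crown_radius: float
    stem_dbh_cm: list
    stem_base_xy: tuple = (0.0, 0.0)
    crown_fill: float = 0.7
    branch_density: float = 1.0
    rng_seed: int = 0

    @property
    def n_stems(self) -> int:
        return len(self.stem_dbh_cm)

    def validate(self) -> None:
        if self.form not in ("conifer", "broadleaf"):
            raise ValueError(f"form must be conifer or broadleaf, got {self.form!r}")
        if not 0 < self.cbh < self.tth:
            raise ValueError("constraint violated: 0 < cbh < tth")
        if self.crown_radius <= 0:
            raise ValueError("constraint violated: crown_radius > 0")
        if not 1 <= self.n_stems <= 8:
            raise ValueError("constraint violated: n_stems in 1..8")
        if self.form == "conifer" and self.n_stems != 1:
            raise ValueError("constraint violated: conifer form requires a single stem")
        if any(d <= 0 for d in self.stem_dbh_cm):
            raise ValueError("constraint violated: stem diameters must be positive")
        if not 0 < self.crown_fill <= 1:
            raise ValueError("constraint violated: crown_fill in (0, 1]")
        if self.branch_density < 0:
            raise ValueError("constraint violated: branch_density >= 0")


@dataclass
class PlotSpec:
    """Ground-truth parameters of one synthetic circular plot.

    The plot is a disc of ``radius`` m (default 12.5, i.e. 25 m diameter)
    on a plane of inclination ``slope_deg`` facing ``aspect_deg`` (azimuth
    of the downhill direction, clockwise from north).
    """

    plot_id: str
    tree_specs: list
    radius: float = 12.5
    slope_deg: float = 0.0
    aspect_deg: float = 0.0
    elevation_m: float = 2000.0
    precipitation_mm: float = 2000.0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.radius <= 0:
            raise ValueError("constraint violated: radius > 0")
        if not 0 <= self.slope_deg < 90:
            raise ValueError("constraint violated: 0 <= slope_deg < 90")
        if not 0 <= self.aspect_deg < 360:
            raise ValueError("constraint violated: 0 <= aspect_deg < 360")
        r_corr = self.radius * math.cos(math.radians(self.slope_deg))
        for ts in self.tree_specs:
            ts.validate()
            bx, by = ts.stem_base_xy
            if math.hypot(bx, by) > r_corr + 1e-9:
                raise ValueError(
                    "constraint violated: stem base outside slope-corrected radius"
                )


@dataclass
class LabeledCloud:
    """A generated cloud together with its ground truth.

    ``per_point_tree_id`` assigns every point to exactly one tree
    (0 = ground surface in plot clouds).
    """

    cloud: PointCloud
    truth: object
    per_point_tree_id: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        if self.per_point_tree_id is None:
            self.per_point_tree_id = (
                self.cloud.labels
                if self.cloud.labels is not None
                else np.zeros(len(self.cloud), dtype=int)
            )


def _cylinder_surface(rng, center_xy, radius, z0, z1, spacing):
    area = 2 * math.pi * radius * max(z1 - z0, 0.0)
    n = max(int(area / spacing**2), 8)
    theta = rng.uniform(0, 2 * math.pi, n)
    z = rng.uniform(z0, z1, n)
    x = center_xy[0] + radius * np.cos(theta)
    y = center_xy[1] + radius * np.sin(theta)
    return np.column_stack([x, y, z])


def _cone_surface(rng, apex_xy, base_radius, z_base, z_apex, spacing):
    """Lateral surface of a cone, apex up, sampled uniformly by area."""
    height = z_apex - z_base
    slant = math.hypot(base_radius, height)
    area = math.pi * base_radius * slant
    n = max(int(area / spacing**2), 16)
    f = np.sqrt(rng.uniform(0, 1, n))  # radial fraction from apex, area-uniform
    theta = rng.uniform(0, 2 * math.pi, n)
    r = base_radius * f
    z = z_apex - height * f
    x = apex_xy[0] + r * np.cos(theta)
    y = apex_xy[1] + r * np.sin(theta)
    return np.column_stack([x, y, z])


def _ellipsoid_surface(rng, center, a, b, c, spacing):
    # Knud Thomsen approximation of the surface area
    p = 1.6075
    area = 4 * math.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3) ** (1 / p)
    n = max(int(area / spacing**2), 16)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    pts = v * np.array([a, b, c]) + np.asarray(center)
    return pts


def _cone_interior(rng, apex_xy, base_radius, z_base, z_apex, n):
    t = rng.uniform(0, 1, n) ** (1 / 3)  # fraction from apex, volume-uniform
    theta = rng.uniform(0, 2 * math.pi, n)
    u = np.sqrt(rng.uniform(0, 1, n))
    r = base_radius * t * u
    z = z_apex - (z_apex - z_base) * t
    x = apex_xy[0] + r * np.cos(theta)
    y = apex_xy[1] + r * np.sin(theta)
    return np.column_stack([x, y, z])


def _ellipsoid_interior(rng, center, a, b, c, n):
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    v *= rng.uniform(0, 1, (n, 1)) ** (1 / 3)
    return v * np.array([a, b, c]) + np.asarray(center)


def _branch_lines(rng, spec: TreeSpec, surface_point_fn, n_branches, spacing):
    """Line-like branch scatter from the stem axis to the crown envelope."""
    pts = []
    x0, y0 = spec.stem_base_xy
    for _ in range(n_branches):
        end = surface_point_fn()
        zb = rng.uniform(spec.cbh, min(end[2], spec.tth))
        start = np.array([x0, y0, zb])
        seg = end - start
        length = float(np.linalg.norm(seg))
        n = max(int(length / spacing), 2)
        t = np.linspace(0, 1, n)[:, None]
        pts.append(start + t * seg)
    return np.vstack(pts) if pts else np.empty((0, 3))


def generate_tree(spec: TreeSpec, point_spacing: float = DEFAULT_SPACING) -> LabeledCloud:
    """Render one tree as a labeled point cloud with its base at z = 0.

    The cloud's vertical extent equals ``spec.tth`` exactly (base and top
    points are placed deterministically); all other sampling is driven by
    ``spec.rng_seed``, so identical specs yield identical clouds.
    """
    if point_spacing <= 0:
        raise ValueError("point_spacing must be positive")
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    x0, y0 = spec.stem_base_xy
    parts = [np.array([[x0, y0, 0.0], [x0, y0, spec.tth]])]

    # stems: single stems run up into the crown; multi-stems stop at the
    # unified crown base
    if spec.n_stems == 1:
        stem_top = spec.tth * 0.95 if spec.form == "conifer" else spec.cbh + 0.25 * (
            spec.tth - spec.cbh
        )
        r_stem = spec.stem_dbh_cm[0] / 200.0
        parts.append(_cylinder_surface(rng, (x0, y0), r_stem, 0.0, stem_top, point_spacing))
    else:
        ring = min(0.35, spec.crown_radius / 3)
        angles = np.linspace(0, 2 * math.pi, spec.n_stems, endpoint=False)
        offsets = rng.uniform(0.5, 1.0, spec.n_stems)[:, None] * ring
        for ang, off, d_cm in zip(angles, offsets[:, 0], spec.stem_dbh_cm):
            cx = x0 + off * math.cos(ang)
            cy = y0 + off * math.sin(ang)
            top = spec.cbh + rng.uniform(0.0, 0.2) * (spec.tth - spec.cbh)
            parts.append(
                _cylinder_surface(rng, (cx, cy), d_cm / 200.0, 0.0, top, point_spacing)
            )

    cl = spec.tth - spec.cbh
    interior_spacing = _INTERIOR_SPACING_FACTOR * point_spacing
    if spec.form == "conifer":
        surface = _cone_surface(
            rng, (x0, y0), spec.crown_radius, spec.cbh, spec.tth, point_spacing
        )
        volume = math.pi * spec.crown_radius**2 * cl / 3
        n_fill = int(spec.crown_fill * volume / interior_spacing**3)
        fill = (
            _cone_interior(rng, (x0, y0), spec.crown_radius, spec.cbh, spec.tth, n_fill)
            if n_fill > 0
            else None
        )
    else:
        center = (x0, y0, spec.cbh + cl / 2)
        a = b = spec.crown_radius
        c = cl / 2
        surface = _ellipsoid_surface(rng, center, a, b, c, point_spacing)
        volume = 4 / 3 * math.pi * a * b * c
        n_fill = int(spec.crown_fill * volume / interior_spacing**3)
        fill = _ellipsoid_interior(rng, center, a, b, c, n_fill) if n_fill > 0 else None

    keep = rng.uniform(size=len(surface)) < _SURFACE_COVERAGE
    parts.append(surface[keep])
    if fill is not None:
        parts.append(fill)

    n_branches = int(round(_BRANCHES_PER_METER * spec.branch_density * cl))
    if n_branches > 0:
        ends = surface[rng.integers(0, len(surface), n_branches)]

        def _surf_pt(_it=iter(ends)):
            return next(_it)

        parts.append(_branch_lines(rng, spec, _surf_pt, n_branches, point_spacing))

    xyz = np.vstack(parts)
    xyz[:, 2] = np.clip(xyz[:, 2], 0.0, spec.tth)
    labels = np.ones(len(xyz), dtype=int)
    return LabeledCloud(
        cloud=PointCloud(xyz, labels=labels, source=f"synthetic tree {spec.species_label}"),
        truth=spec,
        per_point_tree_id=labels,
    )


def generate_plot(spec: PlotSpec, point_spacing: float = DEFAULT_SPACING) -> LabeledCloud:
    """Render a circular plot: ground plane plus every tree of the roster.

    Trees sit on the inclined plane defined by slope/aspect, each labeled
    1..n in roster order; ground points carry label 0. Stem bases closer
    than 0.1 m are rejected.
    """
    spec.validate()
    bases = np.array([ts.stem_base_xy for ts in spec.tree_specs], dtype=float)
    if len(bases) >= 2:
        d = np.linalg.norm(bases[:, None, :] - bases[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() < 0.1:
            raise ValueError("overlapping stem bases closer than 0.1 m")

    slope = math.radians(spec.slope_deg)
    az = math.radians(spec.aspect_deg)
    downhill = np.array([math.sin(az), math.cos(az)])

    def ground_z(x, y):
        return -math.tan(slope) * (np.asarray(x) * downhill[0] + np.asarray(y) * downhill[1])

    rng = np.random.default_rng(spec.rng_seed)
    r_corr = spec.radius * math.cos(slope)
    # ground disc; dense enough (mean spacing 5 cm) to survive the standard
    # 0.1 m / 4-neighbor noise filter, and wide enough that overhanging
    # crowns of edge trees still sit above sampled terrain
    g_spacing = 0.05
    overhang = max((ts.crown_radius for ts in spec.tree_specs), default=0.0)
    g_radius = r_corr + overhang + 0.5
    n_ground = max(int(math.pi * g_radius**2 / g_spacing**2), 100)
    gr = g_radius * np.sqrt(rng.uniform(0, 1, n_ground))
    gth = rng.uniform(0, 2 * math.pi, n_ground)
    gx = gr * np.cos(gth)
    gy = gr * np.sin(gth)
    parts = [np.column_stack([gx, gy, ground_z(gx, gy)])]
    labels = [np.zeros(n_ground, dtype=int)]

    for i, ts in enumerate(spec.tree_specs, start=1):
        tree = generate_tree(ts, point_spacing)
        bx, by = ts.stem_base_xy
        xyz = tree.cloud.xyz + np.array([0.0, 0.0, float(ground_z(bx, by))])
        parts.append(xyz)
        labels.append(np.full(len(xyz), i, dtype=int))

    xyz = np.vstack(parts)
    lab = np.concatenate(labels)
    return LabeledCloud(
        cloud=PointCloud(xyz, labels=lab, source=f"synthetic plot {spec.plot_id}"),
        truth=spec,
        per_point_tree_id=lab,
    )


def sample_fractal(kind: str, level: int = 1, n_points: int = 4096, seed: int = 0) -> PointCloud:
    """Reference objects of known dimension for the box-counting estimator.

    ``line`` -> D = 1 (collinear equally spaced points), ``plane`` -> D = 2
    (regular 2D grid in 3D), ``cube`` -> D = 3 (regular 3D grid), ``menger``
    -> D = log 20 / log 3 ~ 2.727 (uniform sample of the level-``level``
    Menger-sponge prefractal). Grids are deterministic; the sponge sample
    is deterministic per ``seed``.
    """
    if kind == "line":
        z = np.linspace(0.0, 10.0, n_points)
        xyz = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
    elif kind == "plane":
        side = max(int(round(math.sqrt(n_points))), 2)
        g = np.linspace(0.0, 1.0, side)
        xx, yy = np.meshgrid(g, g, indexing="ij")
        xyz = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(side * side)])
    elif kind == "cube":
        side = max(int(round(n_points ** (1 / 3))), 2)
        g = np.linspace(0.0, 1.0, side)
        xx, yy, zz = np.meshgrid(g, g, g, indexing="ij")
        xyz = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    elif kind == "menger":
        if level < 1:
            raise ValueError("menger level must be >= 1")
        if n_points < 1000:
            raise ValueError("need at least 1000 points for a stochastic sample")
        rng = np.random.default_rng(seed)
        # offsets of the 20 retained subcubes of the sponge
        keep = np.array(
            [
                (i, j, k)
                for i in range(3)
                for j in range(3)
                for k in range(3)
                if sum(v == 1 for v in (i, j, k)) < 2
            ],
            dtype=float,
        )
        pts = rng.uniform(0, 1, (n_points, 3))
        scale = 1.0
        origin = np.zeros((n_points, 3))
        for _ in range(level):
            scale /= 3.0
            choice = keep[rng.integers(0, len(keep), n_points)]
            origin = origin + choice * scale
        xyz = origin + pts * scale
    else:
        raise ValueError(f"unknown fractal kind {kind!r}")
    return PointCloud(xyz, source=f"fractal:{kind}")


def write_labeled_cloud(lc: LabeledCloud, xyz_path, truth_path=None) -> None:
    """Write XYZ text with a tree-id column plus a JSON ground-truth sidecar."""
    write_xyz(lc.cloud, xyz_path)
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            json.dump(asdict(lc.truth), fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# The default 14-plot study configuration
# ---------------------------------------------------------------------------

# (species tuple, form, target stems/ha, elevation m, precipitation mm/yr,
#  slope deg, aspect deg) -- needle-leaved plots occupy the drier, higher
# leeward end of the gradient, broad-leaved plots the wetter windward end;
# 11 plots are monospecific, 3 mix two conifer species.
_SUITE = [
    (("Pinus",), "conifer", 2242, 2900, 1250, 30, 180),
    (("Pinus",), "conifer", 1800, 3100, 1180, 25, 200),
    (("Pinus", "Cupressus"), "conifer", 1400, 2800, 1350, 35, 160),
    (("Pinus", "Cupressus"), "conifer", 1100, 2600, 1400, 40, 220),
    (("Pinus", "Abies"), "conifer", 950, 3300, 1500, 20, 140),
    (("Abies",), "conifer", 800, 3400, 1600, 15, 90),
    (("Cupressus",), "conifer", 1250, 2400, 1300, 38, 250),
    (("Alnus",), "broadleaf", 245, 1300, 3600, 10, 45),
    (("Alnus",), "broadleaf", 380, 1500, 3200, 12, 30),
    (("Alnus",), "broadleaf", 520, 1700, 2900, 8, 60),
    (("Daphniphyllum",), "broadleaf", 660, 2000, 2600, 18, 120),
    (("Daphniphyllum",), "broadleaf", 800, 2200, 2400, 22, 300),
    (("Acer",), "broadleaf", 520, 2300, 2000, 28, 330),
    (("Acer",), "broadleaf", 380, 2100, 2200, 2, 10),
]

_CROWN_FILLS = (0.1, 0.4, 0.7, 1.0)


def _place_bases(rng, n, r_corr, min_dist=0.6):
    """Random stem bases in the disc with a minimum spacing (dart throwing)."""
    bases = []
    attempts = 0
    while len(bases) < n and attempts < 20000:
        attempts += 1
        r = r_corr * math.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * math.pi)
        p = (r * math.cos(th), r * math.sin(th))
        if all(math.hypot(p[0] - q[0], p[1] - q[1]) >= min_dist for q in bases):
            bases.append(p)
    if len(bases) < n:
        raise RuntimeError("could not place stem bases without overlap")
    return bases


def default_suite(seed: int = 1) -> list:
    """The 14-plot synthetic study configuration.

    Stem densities span 245-2242 ha^-1, elevations 1300-3400 m,
    precipitation 1180-3600 mm/yr, slopes 2-40 degrees; seven plots are
    needle-leaved and seven broad-leaved, with multi-stem trees in the
    Daphniphyllum plots and crown fill cycling over 0.1/0.4/0.7/1.0.
    Per-plot seeds derive from ``seed`` so the whole suite is reproducible.
    """
    plots = []
    for i, (species, form, density, elev, precip, slope, aspect) in enumerate(_SUITE):
        plot_seed = (1000 * seed + i + 1) % (2**31)
        rng = np.random.default_rng(plot_seed)
        r_corr = 12.5 * math.cos(math.radians(slope))
        area_ha = math.pi * r_corr**2 / 1e4
        n_trees = max(int(round(density * area_ha)), 4)
        bases = _place_bases(rng, n_trees, r_corr - 0.3)
        # taller trees on sparser plots (self-thinning trend)
        mean_tth = float(np.clip(22.0 - 0.006 * density, 7.0, 22.0))
        tree_specs = []
        for j in range(n_trees):
            sp = species[j % len(species)]  # exact proportions for mixtures
            tth = float(np.clip(mean_tth * rng.lognormal(0.0, 0.30), 2.0, 36.0))
            cbh = float(np.clip(tth * rng.uniform(0.25, 0.5), 0.5, tth - 1.0))
            if form == "conifer":
                crad = float(np.clip(0.13 * tth * rng.lognormal(0, 0.2), 0.4, 5.0))
            else:
                crad = float(np.clip(0.20 * tth * rng.lognormal(0, 0.2), 0.5, 7.0))
            dbh = float(np.clip(1.9 * tth**1.1 * rng.lognormal(0, 0.15), 3.0, 73.0))
            if sp == "Daphniphyllum" and rng.uniform() < 0.35:
                n_stems = int(rng.integers(2, 9))
                w = rng.lognormal(0, 0.2, n_stems)
                stems = list(dbh * w / math.sqrt(float(np.sum(w**2))))
            else:
                stems = [dbh]
            tree_specs.append(
                TreeSpec(
                    species_label=sp,
                    form=form,
                    tth=tth,
                    cbh=cbh,
                    crown_radius=crad,
                    stem_dbh_cm=stems,
                    stem_base_xy=bases[j],
                    crown_fill=_CROWN_FILLS[j % len(_CROWN_FILLS)],
                    branch_density=float(rng.uniform(0.5, 2.0)),
                    rng_seed=int(rng.integers(0, 2**31)),
                )
            )
        plots.append(
            PlotSpec(
                plot_id=f"P{i + 1:02d}",
                tree_specs=tree_specs,
                radius=12.5,
                slope_deg=slope,
                aspect_deg=aspect,
                elevation_m=elev,
                precipitation_mm=precip,
                rng_seed=plot_seed,
            )
        )
    return plots
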