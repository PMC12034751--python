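"""Single-tree architectural attributes from a segmented, ground-normalized cloud.

Implements the standard crown morphometrics used in terrestrial/mobile
laser scanning studies: total tree height (TTH), diameter at breast height
(DBH, via algebraic circle fitting of the 1.3 m stem slice, with a
quadratic-sum combination for multi-stem trees), crown base height (CBH),
layered convex-hull crown areas (Max_crownarea, H_maxarea), crown surface
area (CSA, 3D hull), mean crown radius (MCR, 360 one-degree sectors),
crown volume (layered area x thickness), crown length (CL = TTH - CBH),
crown asymmetry, and aboveground biomass (volume x wood density).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .cloud import PointCloud
from .boxdim import BoxDimResult, box_dimension

__all__ = [
    "ArchitectureMetrics",
    "TreeRecord",
    "total_height",
    "fit_circle",
    "dbh_circle_fit",
    "dbh_quadratic_sum",
    "crown_base_height",
    "layer_hulls",
    "max_crown_area",
    "crown_surface_area",
    "mean_crown_radius",
    "crown_volume",
    "crown_length",
    "crown_asymmetry",
    "aboveground_biomass",
    "analyze_tree",
]

LAYER_THICKNESS = 0.1  # m, vertical layer used for crown hull slicing


@dataclass
class ArchitectureMetrics:
    tth_m: float = None
    dbh_cm: float = None
    cbh_m: float = None
    csa_m2: float = None
    max_crownarea_m2: float = None
    h_maxarea_m: float = None
    mcr_m: float = None
    crown_volume_m3: float = None
    cl_m: float = None
    crown_asymmetry_m: float = None
    agb_kg: float = None
    flags: list = field(default_factory=list)


@dataclass
class TreeRecord:
    """One segmented tree: cloud, stems, derived metrics, box-dimension."""

    tree_id: int
    species_label: str
    cloud: PointCloud
    stem_base_xy: tuple = (0.0, 0.0)
    stems: list = field(default_factory=list)  # per-stem DBH (cm)
    metrics: ArchitectureMetrics = None
    db: BoxDimResult = None


def total_height(cloud: PointCloud) -> float:
    """Distance between the tree's lowest and highest points (m)."""
    z = cloud.xyz[:, 2]
    if len(z) == 0:
        raise ValueError("empty cloud")
    return float(z.max() - z.min())


def fit_circle(xy: np.ndarray) -> tuple[float, float, float]:
    """Algebraic (Kasa) least-squares circle fit; returns (cx, cy, r)."""
    xy = np.asarray(xy, dtype=float)
    x, y = xy[:, 0], xy[:, 1]
    a = np.column_stack([2 * x, 2 * y, np.ones(len(x))])
    b = x**2 + y**2
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    cx, cy, c = sol
    r = math.sqrt(max(c + cx**2 + cy**2, 0.0))
    return float(cx), float(cy), float(r)


def _stem_clusters(xy: np.ndarray, link: float = 0.15) -> list[np.ndarray]:
    """Greedy single-linkage clustering of slice points (multi-stem split)."""
    tree = cKDTree(xy)
    n = len(xy)
    labels = np.full(n, -1, dtype=int)
    current = 0
    for i in range(n):
        if labels[i] != -1:
            continue
        stack = [i]
        labels[i] = current
        while stack:
            j = stack.pop()
            for k in tree.query_ball_point(xy[j], link):
                if labels[k] == -1:
                    labels[k] = current
                    stack.append(k)
        current += 1
    return [np.flatnonzero(labels == c) for c in range(current)]


def dbh_circle_fit(
    cloud: PointCloud,
    slice_center: float = 1.3,
    slice_halfwidth: float = 0.05,
) -> tuple[float, list]:
    """DBH (cm) from the stem slice at 1.3 m above the cloud base.

    The horizontal projection of slice points is circle-fitted per stem
    cluster; multiple clusters (stems separated below 1.3 m) are combined
    by the quadratic-sum rule. With fewer than 10 slice points the
    estimate falls back to the maximum chord between two opposing points
    (the manual cross-section measurement) and is flagged.
    """
    z = cloud.xyz[:, 2] - cloud.xyz[:, 2].min()
    mask = np.abs(z - slice_center) <= slice_halfwidth
    xy = cloud.xyz[mask, :2]
    flags: list[str] = []
    if len(xy) < 3:
        raise ValueError("no usable stem slice at breast height")
    if len(xy) < 10:
        # max chord between two opposing points
        d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
        flags.append("dbh_two_point_fallback")
        return float(d.max() * 100.0), flags
    clusters = _stem_clusters(xy)
    clusters = [c for c in clusters if len(c) >= 5]
    if not clusters:
        clusters = [np.arange(len(xy))]
    diameters = []
    for c in clusters:
        _, _, r = fit_circle(xy[c])
        diameters.append(2 * r * 100.0)
    if len(diameters) > 1:
        flags.append(f"multi_stem:{len(diameters)}")
    return dbh_quadratic_sum(diameters), flags


def dbh_quadratic_sum(stem_dbhs) -> float:
    """Single DBH for a multi-stem tree: sqrt of the sum of squared diameters."""
    d = np.asarray(list(stem_dbhs), dtype=float)
    if len(d) == 0 or np.any(d <= 0):
        raise ValueError("stem diameters must be positive")
    return float(math.sqrt(float(np.sum(d**2))))


def _hull_area_2d(xy: np.ndarray) -> float:
    """Area of the 2D convex hull; 0 for < 3 points or collinear layers."""
    if len(xy) < 3:
        return 0.0
    try:
        return float(ConvexHull(xy).volume)  # 'volume' is area in 2D
    except QhullError:
        return 0.0


def crown_base_height(
    cloud: PointCloud,
    stem_radius_m: float,
    layer: float = LAYER_THICKNESS,
    area_factor: float = 3.0,
    persistence: int = 3,
) -> tuple[float, list]:
    """Height of the lowest crown layer above the ground (m).

    The crown base is the lower bound of the lowest ``layer``-thick slab
    whose horizontal convex-hull area exceeds ``area_factor`` times the
    stem cross-section, sustained over ``persistence`` consecutive layers.
    Returns 0 (flagged) when the crown reaches the ground.
    """
    z = cloud.xyz[:, 2] - cloud.xyz[:, 2].min()
    n_layers = max(int(math.ceil(z.max() / layer)), 1)
    threshold = area_factor * math.pi * stem_radius_m**2
    idx = np.minimum((z / layer).astype(int), n_layers - 1)
    exceed = np.zeros(n_layers, dtype=bool)
    for li in range(n_layers):
        pts = cloud.xyz[idx == li, :2]
        exceed[li] = _hull_area_2d(pts) > threshold
    run = 0
    for li in range(n_layers):
        run = run + 1 if exceed[li] else 0
        if run >= persistence:
            base = float((li - persistence + 1) * layer)
            return base, ([] if base > 0 else ["cbh_crown_to_ground"])
    return 0.0, ["cbh_crown_to_ground"]


def layer_hulls(cloud: PointCloud, cbh: float, layer: float = LAYER_THICKNESS):
    """Per-layer (10 cm) horizontal convex-hull areas of the crown.

    Returns a list of (mid-height, area) tuples from ``cbh`` upward;
    layers with fewer than 3 non-collinear points get area 0.
    """
    zmin = cloud.xyz[:, 2].min()
    z = cloud.xyz[:, 2] - zmin
    crown = cloud.xyz[z >= cbh]
    zc = z[z >= cbh]
    if len(crown) == 0:
        raise ValueError("no points above the crown base")
    n_layers = max(int(math.ceil((zc.max() - cbh) / layer)), 1)
    idx = np.minimum(((zc - cbh) / layer).astype(int), n_layers - 1)
    out = []
    for li in range(n_layers):
        pts = crown[idx == li, :2]
        out.append((cbh + (li + 0.5) * layer, _hull_area_2d(pts)))
    return out


def max_crown_area(layers) -> tuple[float, float]:
    """Largest per-layer crown area and its (mid-layer) height.

    Ties are broken toward the lowest layer.
    """
    if not layers:
        raise ValueError("no layers")
    areas = np.array([a for _, a in layers])
    i = int(np.argmax(areas))  # argmax returns the first (lowest) maximum
    return float(areas[i]), float(layers[i][0])


def crown_surface_area(cloud: PointCloud, cbh: float) -> float:
    """Surface area (m^2) of the 3D convex hull of points at or above CBH."""
    z = cloud.xyz[:, 2] - cloud.xyz[:, 2].min()
    crown = cloud.xyz[z >= cbh]
    if len(crown) < 4:
        raise ValueError("fewer than 4 crown points; surface undefined")
    try:
        hull = ConvexHull(crown)
    except QhullError as exc:
        raise ValueError("degenerate (coplanar) crown") from exc
    return float(hull.area)


def mean_crown_radius(
    cloud: PointCloud, cbh: float, axis_xy, n_sectors: int = 360
) -> tuple[float, int]:
    """Mean of 360 one-degree-sector maximum horizontal crown extents.

    Empty sectors are excluded from the mean; their count is returned.
    """
    z = cloud.xyz[:, 2] - cloud.xyz[:, 2].min()
    crown = cloud.xyz[z >= cbh]
    if len(crown) == 0:
        raise ValueError("no crown points")
    dx = crown[:, 0] - axis_xy[0]
    dy = crown[:, 1] - axis_xy[1]
    r = np.hypot(dx, dy)
    sector = ((np.arctan2(dy, dx) + 2 * math.pi) % (2 * math.pi) / (2 * math.pi) * n_sectors)
    sector = np.minimum(sector.astype(int), n_sectors - 1)
    max_r = np.zeros(n_sectors)
    np.maximum.at(max_r, sector, r)
    occupied = np.zeros(n_sectors, dtype=bool)
    occupied[sector] = True
    n_empty = int(n_sectors - occupied.sum())
    if not occupied.any():
        raise ValueError("no occupied sectors")
    return float(max_r[occupied].mean()), n_empty


def crown_volume(layers, layer_thickness: float = LAYER_THICKNESS) -> float:
    """Crown volume (m^3) as the sum of layer area x layer thickness."""
    return float(sum(a for _, a in layers) * layer_thickness)


def crown_length(tth: float, cbh: float) -> float:
    """Crown length (m): TTH - CBH."""
    return tth - cbh


def _hull_polygon_centroid(xy: np.ndarray) -> np.ndarray:
    """Area centroid of the convex-hull polygon of 2D points."""
    hull = ConvexHull(xy)
    v = xy[hull.vertices]
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = cross.sum() / 2.0
    if abs(area) < 1e-12:
        return v.mean(axis=0)
    cx = ((x + xn) * cross).sum() / (6 * area)
    cy = ((y + yn) * cross).sum() / (6 * area)
    return np.array([cx, cy])


def crown_asymmetry(cloud: PointCloud, cbh: float, stem_base_xy,
                    layer: float = LAYER_THICKNESS) -> float:
    """Horizontal offset (m) between the crown center and the stem base.

    The crown center is the centroid of the convex-hull polygon of the
    maximal-crown-area layer.
    """
    layers = layer_hulls(cloud, cbh, layer)
    _, h = max_crown_area(layers)
    zmin = cloud.xyz[:, 2].min()
    z = cloud.xyz[:, 2] - zmin
    mask = np.abs(z - h) <= layer / 2
    xy = cloud.xyz[mask, :2]
    if len(xy) < 3:
        centroid = xy.mean(axis=0)
    else:
        try:
            centroid = _hull_polygon_centroid(xy)
        except QhullError:
            centroid = xy.mean(axis=0)
    return float(math.hypot(centroid[0] - stem_base_xy[0], centroid[1] - stem_base_xy[1]))


def aboveground_biomass(volume_m3: float, wood_density_kg_m3: float) -> float:
    """AGB (kg) = aboveground volume (m^3) x species wood density (kg m^-3)."""
    if volume_m3 <= 0 or wood_density_kg_m3 <= 0:
        raise ValueError("volume and wood density must be positive")
    return volume_m3 * wood_density_kg_m3


def analyze_tree(
    tree_id: int,
    species_label: str,
    cloud: PointCloud,
    stem_base_xy=(0.0, 0.0),
    wood_density_kg_m3: float = None,
    agb_volume_m3: float = None,
    lower_cutoff: float = 0.1,
    compute_db: bool = True,
) -> TreeRecord:
    """Compute the full metric set (and optionally D_b) for one tree.

    ``agb_volume_m3`` is the aboveground woody volume (e.g. from a
    quantitative structure model); it enters AGB as an input value and is
    never derived from the crown hull.
    """
    m = ArchitectureMetrics()
    m.tth_m = total_height(cloud)
    try:
        m.dbh_cm, dbh_flags = dbh_circle_fit(cloud)
        m.flags.extend(dbh_flags)
    except ValueError:
        m.flags.append("dbh_unavailable")
    stem_r = (m.dbh_cm / 200.0) if m.dbh_cm else 0.05
    m.cbh_m, cbh_flags = crown_base_height(cloud, stem_r)
    m.flags.extend(cbh_flags)
    m.cl_m = crown_length(m.tth_m, m.cbh_m)
    layers = layer_hulls(cloud, m.cbh_m)
    m.max_crownarea_m2, m.h_maxarea_m = max_crown_area(layers)
    m.crown_volume_m3 = crown_volume(layers)
    try:
        m.csa_m2 = crown_surface_area(cloud, m.cbh_m)
    except ValueError:
        m.flags.append("csa_degenerate")
    m.mcr_m, n_empty = mean_crown_radius(cloud, m.cbh_m, stem_base_xy)
    if n_empty:
        m.flags.append(f"mcr_empty_sectors:{n_empty}")
    m.crown_asymmetry_m = crown_asymmetry(cloud, m.cbh_m, stem_base_xy)
    if wood_density_kg_m3 is not None and agb_volume_m3 is not None:
        m.agb_kg = aboveground_biomass(agb_volume_m3, wood_density_kg_m3)
    record = TreeRecord(
        tree_id=tree_id,
        species_label=species_label,
        cloud=cloud,
        stem_base_xy=tuple(stem_base_xy),
        metrics=m,
    )
    if compute_db:
        record.db = box_dimension(cloud, lower_cutoff=lower_cutoff)
    return record
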