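"""Point-cloud container, XYZ text I/O, and the plot preprocessing chain.

Clouds live in plot-local metric coordinates (meters, z vertical); there is
no CRS handling. The preprocessing chain used for field-style plots is
noise filtering -> ground normalization -> voxel subsampling -> circular
clipping, in that order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "PointCloud",
    "TerrainModel",
    "read_xyz",
    "write_xyz",
    "voxel_subsample",
    "radius_noise_filter",
    "normalize_ground",
    "slope_corrected_radius",
    "clip_circular",
    "height_filter",
]


@dataclass
class PointCloud:
    """A set of 3D points in meters with optional per-point integer labels.

    Parameters
    ----------
    xyz : (n, 3) float array
        Point coordinates; must be finite.
    labels : (n,) int array, optional
        Per-point tree ids (or any integer labelling).
    source : str, optional
        Free-text provenance note.
    """

    xyz: np.ndarray
    labels: np.ndarray | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must be an (n, 3) array")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("coordinates must be finite")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (len(self.xyz),):
                raise ValueError("labels must be one integer per point")

    def __len__(self) -> int:
        return len(self.xyz)

    @property
    def is_empty(self) -> bool:
        return len(self.xyz) == 0

    def select(self, mask: np.ndarray) -> "PointCloud":
        """Subset by boolean mask or index array, keeping labels aligned."""
        labels = self.labels[mask] if self.labels is not None else None
        return PointCloud(self.xyz[mask], labels=labels, source=self.source)

    def translated(self, offset) -> "PointCloud":
        off = np.asarray(offset, dtype=float).reshape(3)
        return PointCloud(self.xyz + off, labels=self.labels, source=self.source)

    def extent(self) -> np.ndarray:
        """Axis-aligned extent (max - min) per axis."""
        if self.is_empty:
            raise ValueError("empty cloud has no extent")
        return self.xyz.max(axis=0) - self.xyz.min(axis=0)


@dataclass
class TerrainModel:
    """Gridded ground model: per-cell minimum z with bilinear interpolation.

    The grid is anchored at (x0, y0) with square cells of edge ``cell``;
    ``ground`` holds the ground elevation at cell centers.
    """

    cell: float
    x0: float
    y0: float
    ground: np.ndarray = field(repr=False)

    def elevation(self, x, y) -> np.ndarray:
        """Bilinear ground elevation at (x, y); clamped at the grid border."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        nx, ny = self.ground.shape
        # continuous cell-center coordinates, clamped to the center lattice
        gx = np.clip((x - self.x0) / self.cell - 0.5, 0.0, nx - 1.0)
        gy = np.clip((y - self.y0) / self.cell - 0.5, 0.0, ny - 1.0)
        i0 = np.clip(np.floor(gx).astype(int), 0, nx - 2) if nx > 1 else np.zeros_like(gx, dtype=int)
        j0 = np.clip(np.floor(gy).astype(int), 0, ny - 2) if ny > 1 else np.zeros_like(gy, dtype=int)
        fx = gx - i0
        fy = gy - j0
        i1 = np.minimum(i0 + 1, nx - 1)
        j1 = np.minimum(j0 + 1, ny - 1)
        g = self.ground
        return (
            g[i0, j0] * (1 - fx) * (1 - fy)
            + g[i1, j0] * fx * (1 - fy)
            + g[i0, j1] * (1 - fx) * fy
            + g[i1, j1] * fx * fy
        )


def read_xyz(path) -> PointCloud:
    """Read a whitespace- or comma-delimited ``x y z [label]`` text file.

    Raises ``ValueError`` naming the 1-based line number of the first
    malformed line.
    """
    rows: list[list[float]] = []
    ncols: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            parts = stripped.replace(",", " ").split()
            try:
                values = [float(p) for p in parts]
            except ValueError:
                raise ValueError(f"{path}: malformed line {lineno}: {stripped!r}") from None
            if len(values) not in (3, 4):
                raise ValueError(
                    f"{path}: malformed line {lineno}: expected 3 or 4 columns, got {len(values)}"
                )
            if ncols is None:
                ncols = len(values)
            elif len(values) != ncols:
                raise ValueError(f"{path}: malformed line {lineno}: inconsistent column count")
            rows.append(values)
    if not rows:
        raise ValueError(f"{path}: no points")
    arr = np.asarray(rows, dtype=float)
    labels = arr[:, 3].astype(int) if arr.shape[1] == 4 else None
    return PointCloud(arr[:, :3], labels=labels, source=str(path))


def write_xyz(cloud: PointCloud, path) -> None:
    """Write ``x y z [label]`` text; coordinates keep 6 decimals (1e-6 m)."""
    with open(path, "w") as fh:
        if cloud.labels is not None:
            for (x, y, z), lab in zip(cloud.xyz, cloud.labels):
                fh.write(f"{x:.6f} {y:.6f} {z:.6f} {lab:d}\n")
        else:
            for x, y, z in cloud.xyz:
                fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")


def voxel_subsample(cloud: PointCloud, spacing: float = 0.01) -> PointCloud:
    """Keep at most one point per cubic cell of edge ``spacing``.

    Within each occupied cell the retained point is the one nearest the
    cell centroid, so the output is a subset of the input. The lattice is
    anchored at the coordinate origin, which makes the operation idempotent.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if cloud.is_empty:
        raise ValueError("cannot subsample an empty cloud")
    idx = np.floor(cloud.xyz / spacing).astype(np.int64)
    _, inverse = np.unique(idx, axis=0, return_inverse=True)
    centroid = (idx + 0.5) * spacing
    dist = np.linalg.norm(cloud.xyz - centroid, axis=1)
    order = np.lexsort((dist, inverse))
    first = np.ones(len(order), dtype=bool)
    first[1:] = inverse[order][1:] != inverse[order][:-1]
    keep = np.sort(order[first])
    return cloud.select(keep)


def radius_noise_filter(
    cloud: PointCloud, radius: float = 0.1, min_neighbors: int = 4
) -> PointCloud:
    """Drop points with fewer than ``min_neighbors`` others within ``radius``.

    May return an empty cloud; callers should test ``is_empty``.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if cloud.is_empty:
        return cloud
    tree = cKDTree(cloud.xyz)
    counts = tree.query_ball_point(cloud.xyz, radius, return_length=True)
    keep = (counts - 1) >= min_neighbors  # exclude the point itself
    return cloud.select(keep)


def normalize_ground(cloud: PointCloud, cell: float = 1.0) -> tuple[PointCloud, TerrainModel]:
    """Remove topographic relief: z' = z - terrain(x, y).

    The terrain is the per-cell minimum z on a square grid of edge ``cell``,
    with empty cells filled from the nearest occupied cell and bilinear
    interpolation between cell centers.
    """
    if cloud.is_empty:
        raise ValueError("cannot normalize an empty cloud")
    if cell <= 0:
        raise ValueError("cell must be positive")
    xyz = cloud.xyz
    x0, y0 = xyz[:, 0].min(), xyz[:, 1].min()
    nx = max(1, int(math.ceil((xyz[:, 0].max() - x0) / cell)) + 1)
    ny = max(1, int(math.ceil((xyz[:, 1].max() - y0) / cell)) + 1)
    ij = np.floor((xyz[:, :2] - [x0, y0]) / cell).astype(int)
    ij[:, 0] = np.clip(ij[:, 0], 0, nx - 1)
    ij[:, 1] = np.clip(ij[:, 1], 0, ny - 1)
    ground = np.full((nx, ny), np.inf)
    np.minimum.at(ground, (ij[:, 0], ij[:, 1]), xyz[:, 2])
    occupied = np.isfinite(ground)
    if not occupied.all():
        occ_idx = np.argwhere(occupied)
        empty_idx = np.argwhere(~occupied)
        tree = cKDTree(occ_idx)
        _, nearest = tree.query(empty_idx)
        ground[tuple(empty_idx.T)] = ground[tuple(occ_idx[nearest].T)]
    terrain = TerrainModel(cell=cell, x0=float(x0), y0=float(y0), ground=ground)
    z_new = xyz[:, 2] - terrain.elevation(xyz[:, 0], xyz[:, 1])
    out = PointCloud(
        np.column_stack([xyz[:, 0], xyz[:, 1], z_new]),
        labels=cloud.labels,
        source=cloud.source,
    )
    return out, terrain


def slope_corrected_radius(r: float, alpha: float) -> float:
    """Horizontal plot radius on sloped terrain: r_corr = r * cos(alpha).

    ``alpha`` is the slope angle in degrees, 0 <= alpha < 90.
    """
    if not 0 <= alpha < 90:
        raise ValueError("slope angle must satisfy 0 <= alpha < 90 degrees")
    if r <= 0:
        raise ValueError("radius must be positive")
    return r * math.cos(math.radians(alpha))


def clip_circular(cloud: PointCloud, center_xy, r_corr: float) -> PointCloud:
    """Keep points with horizontal distance to ``center_xy`` <= ``r_corr``.

    The boundary is closed: a point at exactly ``r_corr`` is retained.
    """
    if r_corr <= 0:
        raise ValueError("clip radius must be positive")
    cx, cy = float(center_xy[0]), float(center_xy[1])
    d2 = (cloud.xyz[:, 0] - cx) ** 2 + (cloud.xyz[:, 1] - cy) ** 2
    return cloud.select(d2 <= r_corr**2)


def height_filter(trees, min_height: float = 3.0):
    """Keep trees whose total height is at least ``min_height`` (inclusive).

    Works on any sequence of objects exposing a total height, either via a
    ``metrics.tth_m`` attribute (TreeRecord) or a ``tth_m`` attribute.
    Order is preserved.
    """

    def _tth(tree) -> float:
        metrics = getattr(tree, "metrics", None)
        if metrics is not None and getattr(metrics, "tth_m", None) is not None:
            return metrics.tth_m
        tth = getattr(tree, "tth_m", None)
        if tth is None:
            raise ValueError("tree has no computed total height")
        return tth

    return [t for t in trees if _tth(t) >= min_height]
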