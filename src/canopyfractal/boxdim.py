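"""Box-counting fractal dimension (D_b) of 3D point clouds.

The box-dimension measures how completely an object fills 3D space across
scales: boxes (voxels) of decreasing size are laid over the cloud and the
number N(s) of boxes containing at least one point is recorded. D_b is the
least-squares slope of ln N against ln(1/s), with s the box edge relative
to the initial bounding box. A pole-like object yields D_b near 1, a flat
surface near 2, and a solid cube 3; tree crowns fall in between, with a
theoretical ceiling for trees well below 2.72.

Procedure: the initial box is the axis-aligned cube whose edge equals the
largest axis extent of the cloud, anchored at the min corner; edges are
halved while they remain >= a lower cutoff (default 0.1 m, roughly the
scanner-noise scale). Cells are half-open, [a, a + edge) per axis, with
points on the global max face assigned to the last cell, so every point
lies in exactly one box. A single fixed lattice is used (no rotation or
anchor averaging) so results are deterministic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .cloud import PointCloud

__all__ = ["BoxDimResult", "box_count", "box_dimension", "stand_box_dimension"]

#: Theoretical ceiling reported for real trees.
TREE_DB_CEILING = 2.72


@dataclass
class BoxDimResult:
    """Fitted box-dimension together with the raw scale sweep.

    Attributes
    ----------
    db : float
        Fitted slope of ln N vs ln(1/s); flagged if outside [1, 3].
    scales : list of float
        Absolute box edge lengths (m), largest first.
    counts : list of int
        Occupied-box counts per scale; counts[0] == 1 at the bounding box.
    fit_r2 : float
        R^2 of the log-log fit (poor log-linearity is visible here).
    n_scales : int
    lower_cutoff : float
        Smallest admissible box edge (m).
    in_theoretical_range : bool
        Whether db lies in the theoretical [1, 3] range for 3D objects.
    """

    db: float
    scales: list
    counts: list
    fit_r2: float
    n_scales: int
    lower_cutoff: float
    in_theoretical_range: bool = True

    def to_json(self) -> str:
        return json.dumps(
            {
                "db": self.db,
                "scales": list(self.scales),
                "counts": [int(c) for c in self.counts],
                "fit_r2": self.fit_r2,
                "n_scales": self.n_scales,
                "lower_cutoff": self.lower_cutoff,
                "in_theoretical_range": self.in_theoretical_range,
            },
            indent=2,
        )


def _as_xyz(cloud) -> np.ndarray:
    if isinstance(cloud, PointCloud):
        return cloud.xyz
    return np.asarray(cloud, dtype=float)


def box_count(cloud, edge: float, anchor) -> int:
    """Number of occupied axis-aligned cubic cells of side ``edge``.

    The lattice is anchored at ``anchor``; cells are half-open with points
    on the far face of the cloud's bounding region clamped into the last
    cell, so every point is counted exactly once.
    """
    if edge <= 0:
        raise ValueError("edge must be positive")
    xyz = _as_xyz(cloud)
    if len(xyz) == 0:
        raise ValueError("cannot count boxes of an empty cloud")
    anchor = np.asarray(anchor, dtype=float).reshape(3)
    rel = xyz - anchor
    ncells = np.maximum(1, np.ceil(rel.max(axis=0) / edge - 1e-12).astype(np.int64))
    idx = np.floor(rel / edge).astype(np.int64)
    idx = np.clip(idx, 0, ncells - 1)
    # pack the three indices into one integer key for a fast unique
    key = (idx[:, 0] * ncells[1] + idx[:, 1]) * ncells[2] + idx[:, 2]
    return int(np.unique(key).size)


def box_dimension(
    cloud,
    lower_cutoff: float = 0.1,
    n_scales: int | None = None,
    min_points: int = 100,
) -> BoxDimResult:
    """Estimate D_b by dyadic box counting and a log-log regression.

    Parameters
    ----------
    cloud : PointCloud or (n, 3) array
    lower_cutoff : float
        Halving stops once the edge would fall below this length (m).
    n_scales : int, optional
        Fix the ladder depth explicitly (initial box plus ``n_scales - 1``
        halvings), overriding the cutoff rule. Useful for analytic oracles
        where the finest edge is prescribed, e.g. 1/64 of the extent.
    min_points : int
        Minimum cloud size for a meaningful estimate.
    """
    xyz = _as_xyz(cloud)
    if len(xyz) < min_points:
        raise ValueError(f"need at least {min_points} points, got {len(xyz)}")
    mins = xyz.min(axis=0)
    edge0 = float((xyz.max(axis=0) - mins).max())
    if edge0 <= 0:
        raise ValueError("cloud is a single point; box dimension undefined")
    if n_scales is None:
        if edge0 <= 2 * lower_cutoff:
            raise ValueError("cloud extent must exceed twice the lower cutoff")
        n_scales = int(math.floor(math.log2(edge0 / lower_cutoff))) + 1
    if n_scales < 4:
        raise ValueError("fewer than 4 usable scales; fit would be unstable")

    rel = xyz - mins
    scales: list[float] = []
    counts: list[int] = []
    for k in range(n_scales):
        edge = edge0 / (1 << k)
        ncell = 1 << k
        idx = np.minimum((rel / edge).astype(np.int64), ncell - 1)
        key = (idx[:, 0] * ncell + idx[:, 1]) * ncell + idx[:, 2]
        scales.append(edge)
        counts.append(int(np.unique(key).size))

    log_inv_s = np.log([2.0**k for k in range(n_scales)])
    log_n = np.log(counts)
    slope, intercept = np.polyfit(log_inv_s, log_n, 1)
    fitted = slope * log_inv_s + intercept
    ss_res = float(np.sum((log_n - fitted) ** 2))
    ss_tot = float(np.sum((log_n - log_n.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    db = float(slope)
    return BoxDimResult(
        db=db,
        scales=scales,
        counts=counts,
        fit_r2=r2,
        n_scales=n_scales,
        lower_cutoff=float(scales[-1]) if n_scales else lower_cutoff,
        in_theoretical_range=1.0 - 1e-9 <= db <= 3.0 + 1e-9,
    )


def stand_box_dimension(trees, lower_cutoff: float = 0.1) -> BoxDimResult:
    """D_b of the merged point clouds of all trees on a plot.

    ``trees`` is a sequence of TreeRecord-like objects exposing ``cloud``
    (or raw clouds/arrays). Settings are identical to the tree-level
    estimate, so a single-tree plot reproduces that tree's D_b exactly and
    the result is invariant to the order of the roster.
    """
    clouds = []
    for t in trees:
        c = getattr(t, "cloud", t)
        clouds.append(_as_xyz(c))
    if not clouds:
        raise ValueError("empty tree roster")
    merged = np.vstack(clouds)
    return box_dimension(merged, lower_cutoff=lower_cutoff)
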