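"""Ground / vegetation segmentation by progressive TIN densification.

The dense photogrammetric cloud is split into ground and canopy with a
two-step geometric filter in the style of Axelsson's adaptive TIN
algorithm:

1. the cloud is divided into square cells of ``cell_size``; the lowest
   point of every non-empty cell seeds a Delaunay triangulation (TIN)
   that is the first terrain approximation;
2. iteratively, every unclassified point is tested against the facet
   below it: it is accepted as ground when its perpendicular distance
   to the facet plane is at most ``max_distance`` *and* the largest
   elevation angle from the facet's three vertices to the point is at
   most ``max_angle``.  Accepted points are added to the TIN and the
   process repeats until no point is added.

Acceptance is batched: all points passing the test against the current
TIN are added together and the TIN is rebuilt once per iteration, which
makes the result independent of point order.  Points whose horizontal
position falls outside the TIN's convex hull are evaluated against the
nearest facet.  Low outliers (well below their cell's median height)
are tagged as noise before seeding so they cannot drag the terrain
model down.

With the defaults used for trellised vineyards — 6 m cells, 15° and
1 m — the abrupt slope break between soil and the raised canopy curtain
makes the split sharp: canopy sits well above ``max_distance``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.spatial import Delaunay, QhullError, cKDTree

from .pointcloud import (
    CLASS_GROUND,
    CLASS_MEDIUM_VEGETATION,
    CLASS_NOISE,
    PointCloud,
)

__all__ = [
    "GroundFilterParams",
    "Tin",
    "TinMetrics",
    "build_seed_tin",
    "point_to_tin_metrics",
    "classify_ground",
]

log = logging.getLogger(__name__)

_MIN_MAD_SCALE = 0.02  # m; robust-sigma floor so flat cells don't flag noise
_DUP_EPS = 1e-9  # XY duplicate detection for triangulation


@dataclass(frozen=True)
class GroundFilterParams:
    """Parameters of the ground filter.

    Defaults are the values used for the vineyard case: 6 m cells, a
    15° maximum angle and a 1 m maximum distance.
    """

    cell_size: float = 6.0
    max_angle: float = 15.0
    max_distance: float = 1.0
    max_iterations: int = 50
    noise_sigma: float = 5.0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if not 0 < self.max_angle < 90:
            raise ValueError("max_angle must be in (0, 90) degrees")
        if self.max_distance < 0:
            raise ValueError("max_distance must be >= 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class Tin:
    """Triangulated irregular network over a set of 3D vertices.

    Triangulation is 2D Delaunay on the XY projection; vertex order is
    preserved from the input.  ``triangles`` indexes into ``vertices``.
    """

    vertices: np.ndarray  # (n, 3)
    triangles: np.ndarray  # (m, 3) int
    _delaunay: Delaunay | None = None
    _vertex_tree: cKDTree | None = None
    _vertex_to_triangle: np.ndarray | None = None

    @classmethod
    def from_points(cls, points: np.ndarray) -> "Tin":
        points = np.asarray(points, dtype=np.float64)
        if points.ndim != 2 or points.shape[1] != 3:
            raise ValueError("points must be (n, 3)")
        points = _dedupe_xy_lowest(points)
        if len(points) < 3:
            raise ValueError("need at least 3 points with distinct XY to triangulate")
        try:
            tri = Delaunay(points[:, :2])
        except QhullError as exc:
            raise ValueError(
                "cannot triangulate: points are collinear or degenerate"
            ) from exc
        if tri.simplices.size == 0:
            raise ValueError("cannot triangulate: points are collinear")
        return cls(points, tri.simplices, _delaunay=tri)

    def _vertex_lookup(self) -> tuple[cKDTree, np.ndarray]:
        if self._vertex_tree is None:
            self._vertex_tree = cKDTree(self.vertices[:, :2])
            v2t = np.empty(len(self.vertices), dtype=np.int64)
            order = np.arange(len(self.triangles))
            for k in range(3):  # every vertex belongs to >=1 triangle
                v2t[self.triangles[:, k]] = order
            self._vertex_to_triangle = v2t
        return self._vertex_tree, self._vertex_to_triangle

    def locate(self, xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Triangle index for each XY query and an 'extrapolated' flag
        for queries outside the convex hull (assigned to a facet of the
        nearest vertex)."""
        xy = np.atleast_2d(xy)
        simplex = self._delaunay.find_simplex(xy)
        outside = simplex < 0
        if np.any(outside):
            tree, v2t = self._vertex_lookup()
            _, nearest = tree.query(xy[outside])
            simplex = simplex.copy()
            simplex[outside] = v2t[nearest]
        return simplex, outside

    def touched_radius(self, points_xy: np.ndarray) -> float:
        """Radius around the given vertices inside which the facet
        geometry depends on them: the max XY edge length of the facets
        incident to those vertices (Delaunay cavity bound)."""
        tree, _ = self._vertex_lookup()
        d, idx = tree.query(np.atleast_2d(points_xy))
        idx = idx[d <= _DUP_EPS]
        if idx.size == 0:
            return 0.0
        mask = np.isin(self.triangles, idx).any(axis=1)
        touched = self.triangles[mask]
        if touched.size == 0:
            return 0.0
        v = self.vertices[touched, :2]
        edges = np.concatenate(
            [v[:, 1] - v[:, 0], v[:, 2] - v[:, 1], v[:, 0] - v[:, 2]]
        )
        return float(np.sqrt((edges**2).sum(axis=1).max()))


class TinMetrics(NamedTuple):
    distance: float
    angle: float
    extrapolated: bool


def _dedupe_xy_lowest(points: np.ndarray) -> np.ndarray:
    """Drop XY duplicates keeping the lowest-z representative (keeps the
    triangulation well-posed; equivalent to jittering the higher twin
    out of the way)."""
    order = np.lexsort((points[:, 2], points[:, 1], points[:, 0]))
    p = points[order]
    if len(p) < 2:
        return p
    same = (np.abs(np.diff(p[:, 0])) <= _DUP_EPS) & (
        np.abs(np.diff(p[:, 1])) <= _DUP_EPS
    )
    keep = np.concatenate([[True], ~same])
    return p[keep]


def _batch_metrics(
    points: np.ndarray, tin: Tin
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (distance, angle, extrapolated) for many query points.

    distance: plumb-line (vertical) distance from the point to the
    plane of its facet, i.e. |z - plane(x, y)|.  Identical to the
    perpendicular distance on horizontal facets, but bounded by local
    micro-relief on steep ones — a perpendicular rule would let the
    terrain model climb vegetation sideways through steep micro-facets
    at photogrammetric densities.  angle: max over the facet's three
    vertices of the angle between the facet plane and the segment
    vertex→point.
    """
    points = np.atleast_2d(points)
    simplex, outside = tin.locate(points[:, :2])
    tri = tin.triangles[simplex]  # (m, 3)
    v = tin.vertices[tri]  # (m, 3, 3)
    n = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])  # plane normal
    norm = np.linalg.norm(n, axis=1)
    norm = np.where(norm == 0, np.finfo(float).tiny, norm)
    # vertical facets (|n_z| -> 0) put the plumb-line at infinity
    nz = np.abs(n[:, 2])
    dist = np.where(
        nz > norm * 1e-12,
        np.abs(np.einsum("ij,ij->i", n, points - v[:, 0])) / np.maximum(nz, 1e-300),
        np.inf,
    )
    u = points[:, None, :] - v  # (m, 3, 3) vertex -> point
    ulen = np.linalg.norm(u, axis=2)
    ulen = np.where(ulen == 0, np.finfo(float).tiny, ulen)
    sin_a = np.abs(np.einsum("ij,ikj->ik", n, u)) / (norm[:, None] * ulen)
    angle = np.degrees(np.arcsin(np.clip(sin_a, 0.0, 1.0))).max(axis=1)
    return dist, angle, outside


def point_to_tin_metrics(point, tin: Tin) -> TinMetrics:
    """Distance/angle acceptance metrics of one point against a TIN."""
    p = np.asarray(point, dtype=float).reshape(1, 3)
    dist, angle, outside = _batch_metrics(p, tin)
    return TinMetrics(float(dist[0]), float(angle[0]), bool(outside[0]))


def _cell_ids(xy: np.ndarray, cell_size: float) -> np.ndarray:
    """Integer cell id per point, binning anchored at the cloud's XY
    minimum (keeps the filter translation invariant)."""
    mins = xy.min(axis=0)
    ij = np.floor((xy - mins) / cell_size).astype(np.int64)
    return ij[:, 0] * (ij[:, 1].max() + 1) + ij[:, 1]


def _group_lower_median(values: np.ndarray, group: np.ndarray) -> np.ndarray:
    """Per-point lower median of `values` within its group (vectorized)."""
    order = np.lexsort((values, group))
    g, v = group[order], values[order]
    starts = np.flatnonzero(np.concatenate([[True], g[1:] != g[:-1]]))
    lengths = np.diff(np.concatenate([starts, [len(g)]]))
    med_idx = starts + (lengths - 1) // 2
    med_per_group = v[med_idx]
    # map back: group label of each start -> median
    out = np.empty_like(values)
    out[order] = np.repeat(med_per_group, lengths)
    return out


def _detect_noise(xyz: np.ndarray, cell_size: float, noise_sigma: float) -> np.ndarray:
    """Low outliers: more than noise_sigma robust sigmas below the cell
    median height."""
    cell = _cell_ids(xyz[:, :2], cell_size)
    med = _group_lower_median(xyz[:, 2], cell)
    dev = np.abs(xyz[:, 2] - med)
    mad = _group_lower_median(dev, cell)
    scale = np.maximum(1.4826 * mad, _MIN_MAD_SCALE)
    return xyz[:, 2] < med - noise_sigma * scale


def _local_tin(
    xyz: np.ndarray, ground: np.ndarray, new_idx: np.ndarray, spacing: float
) -> tuple[Tin | None, float]:
    """TIN of the ground points surrounding the newly accepted ones,
    plus the radius around them within which facets may have changed.

    Inside that radius the local TIN reproduces the global one (the
    selection margin of ~20 typical point spacings dwarfs the facet
    size in dense ground).  Facets with edges longer than half the
    selection radius are artifacts of cutting the selection out of the
    full cloud — the dense global TIN has no such facets near the new
    points — and are excluded from the radius bound.  Returns (None, 0)
    when the neighbourhood is too small or nearly global, in which case
    the caller re-triangulates globally.
    """
    r_sel = 20.0 * spacing
    s_xy = xyz[new_idx, :2]
    g_idx = np.flatnonzero(ground)
    g_xy = xyz[g_idx, :2]
    # grid hash: any point within r_sel of a new point shares a cell
    # with it or one of its 8 neighbours
    anchor = g_xy.min(axis=0)
    g_cell = np.floor((g_xy - anchor) / r_sel).astype(np.int64)
    s_cell = np.floor((s_xy - anchor) / r_sel).astype(np.int64)
    offsets = np.array([(i, j) for i in (-1, 0, 1) for j in (-1, 0, 1)])
    wanted = (s_cell[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
    enc = 1 << 22
    wanted_codes = np.unique(wanted[:, 0] * enc + wanted[:, 1])
    g_codes = g_cell[:, 0] * enc + g_cell[:, 1]
    sel = g_idx[np.isin(g_codes, wanted_codes)]
    if sel.size < 3 or sel.size > 0.5 * g_idx.size:
        return None, 0.0
    try:
        tin = Tin.from_points(xyz[sel])
    except ValueError:
        return None, 0.0
    tree, _ = tin._vertex_lookup()
    d, vid = tree.query(s_xy)
    vid = vid[d <= _DUP_EPS]
    if vid.size == 0:
        return None, 0.0
    touched = tin.triangles[np.isin(tin.triangles, vid).any(axis=1)]
    if touched.size == 0:
        return None, 0.0
    v = tin.vertices[touched, :2]
    edge_len = np.sqrt(
        np.stack(
            [
                ((v[:, 1] - v[:, 0]) ** 2).sum(axis=1),
                ((v[:, 2] - v[:, 1]) ** 2).sum(axis=1),
                ((v[:, 0] - v[:, 2]) ** 2).sum(axis=1),
            ]
        ).max(axis=0)
    )
    genuine = edge_len[edge_len <= r_sel / 2]
    radius = float(genuine.max()) if genuine.size else 3.0 * spacing
    return tin, max(radius, 3.0 * spacing)


def build_seed_tin(cloud: PointCloud, cell_size: float) -> Tin:
    """Seed TIN: the lowest point of every non-empty cell, triangulated
    in XY.  First approximation of the terrain model."""
    if len(cloud) < 3:
        raise ValueError("need at least 3 points to build a seed TIN")
    seeds = _seed_indices(cloud.xyz, cell_size)
    return Tin.from_points(cloud.xyz[seeds])


def _seed_indices(xyz: np.ndarray, cell_size: float) -> np.ndarray:
    cell = _cell_ids(xyz[:, :2], cell_size)
    order = np.lexsort((xyz[:, 2], cell))
    first = np.flatnonzero(
        np.concatenate([[True], cell[order][1:] != cell[order][:-1]])
    )
    return order[first]


def classify_ground(cloud: PointCloud, params: GroundFilterParams | None = None) -> PointCloud:
    """Classify every point as ground (2), medium vegetation (4) or
    noise (7) by progressive TIN densification.

    Returns a new cloud with the ``classification`` field set; the
    input is not modified.
    """
    params = params or GroundFilterParams()
    if len(cloud) == 0:
        raise ValueError("empty point cloud")
    xyz = cloud.xyz
    n = len(cloud)

    noise = _detect_noise(xyz, params.cell_size, params.noise_sigma)
    usable = ~noise
    if usable.sum() < 3:
        raise ValueError("fewer than 3 non-noise points; cannot filter")

    usable_idx = np.flatnonzero(usable)
    seeds_local = _seed_indices(xyz[usable_idx], params.cell_size)
    ground = np.zeros(n, dtype=bool)
    ground[usable_idx[seeds_local]] = True

    candidates = usable & ~ground
    tin = Tin.from_points(xyz[ground])  # raises on collinear/degenerate input
    # typical point spacing: sets the neighbourhood size of the tail phase
    span = np.ptp(xyz[usable_idx, :2], axis=0)
    spacing = float(np.sqrt(max(span[0] * span[1], 1e-12) / usable_idx.size))

    # Re-testing is restricted to candidates whose facet may have
    # changed: inserting vertices only re-triangulates the cavity of
    # facets they touch (empty-circumcircle property), so a previously
    # rejected point farther away keeps its metrics and stays rejected.
    needs_eval = candidates.copy()
    for iteration in range(1, params.max_iterations + 1):
        cand_idx = np.flatnonzero(needs_eval & candidates)
        if cand_idx.size == 0:
            break
        dist, angle, _ = _batch_metrics(xyz[cand_idx], tin)
        accept = (dist <= params.max_distance) & (angle <= params.max_angle)
        n_new = int(accept.sum())
        log.debug(
            "ground filter iteration %d: %d candidates evaluated, %d accepted",
            iteration,
            cand_idx.size,
            n_new,
        )
        if n_new == 0:
            break
        new_idx = cand_idx[accept]
        ground[new_idx] = True
        candidates[new_idx] = False
        tail_limit = max(1000, int(0.01 * ground.sum()))
        if n_new > tail_limit:
            # bulk growth: one global re-triangulation, re-test everyone
            tin = Tin.from_points(xyz[ground])
            needs_eval = candidates.copy()
        else:
            # tail: re-triangulate only around the accepted points and
            # re-test candidates inside the changed region
            tin, radius = _local_tin(xyz, ground, new_idx, spacing)
            if tin is None:  # neighbourhood too small to certify: go global
                tin = Tin.from_points(xyz[ground])
                radius = tin.touched_radius(xyz[new_idx, :2])
            needs_eval[:] = False
            rest = np.flatnonzero(candidates)
            if rest.size and radius > 0:
                near_d, _ = cKDTree(xyz[new_idx, :2]).query(xyz[rest, :2])
                needs_eval[rest[near_d <= radius]] = True

    classification = np.full(n, CLASS_MEDIUM_VEGETATION, dtype=np.uint8)
    classification[ground] = CLASS_GROUND
    classification[noise] = CLASS_NOISE
    log.info(
        "ground filter: %d ground, %d vegetation, %d noise of %d points",
        int(ground.sum()),
        int((~ground & ~noise).sum()),
        int(noise.sum()),
        n,
    )
    return cloud.with_classification(classification)
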