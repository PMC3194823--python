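"""k-nearest-neighbour local convex hulls (k-LoCoH) and MSHC selection of k.

k-LoCoH builds, for every point, the convex hull of that point and its k-1
nearest neighbours, sorts these local hulls by ascending area (densest parts
of the pattern first), and forms the p%-isopleth as the union of the
smallest hulls needed to cover p% of the points.  Unlike parametric kernels
a 100%-isopleth exists: the union of all local hulls.

The tuning parameter k is chosen by the minimum-spurious-hole-covering
(MSHC) rule: the smallest k whose 100%-isopleth has no interior holes.  The
original rule is applied by eye with room for biologically justified holes;
the automated version here treats every hole as spurious, which is the
testable topological core of the rule.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Sequence

import numpy as np
import shapely
from scipy.spatial import ConvexHull, QhullError, cKDTree
from shapely.geometry import MultiPoint, MultiPolygon, Polygon
from shapely.ops import unary_union

from .geometry import as_point_array
from .kernels import IsoplethSet

#: holes smaller than this area are numerical slivers, not real holes
_SLIVER_AREA = 1e-12


def _local_hull(pts: np.ndarray) -> shapely.Geometry:
    """Convex hull of a small point set; degenerates to a line/point."""
    try:
        hull = ConvexHull(pts)
        return Polygon(pts[hull.vertices])
    except QhullError:  # collinear neighbourhood
        return MultiPoint(pts).convex_hull


@dataclass
class LoCoHModel:
    """Fitted k-LoCoH: local hulls sorted by area, ready for isopleths."""

    points: np.ndarray
    k: int
    hulls: list  # shapely geometries, ascending area
    hull_roots: list[int]  # root point index per sorted hull

    @cached_property
    def _covered_sets(self) -> list[np.ndarray]:
        """Indices of points covered (inside or on) each sorted hull."""
        out = []
        for g in self.hulls:
            if g.is_empty:
                out.append(np.empty(0, dtype=int))
                continue
            minx, miny, maxx, maxy = g.bounds
            cand = np.flatnonzero(
                (self.points[:, 0] >= minx - 1e-12)
                & (self.points[:, 0] <= maxx + 1e-12)
                & (self.points[:, 1] >= miny - 1e-12)
                & (self.points[:, 1] <= maxy + 1e-12)
            )
            inside = shapely.intersects_xy(g, self.points[cand, 0], self.points[cand, 1])
            out.append(cand[inside])
        return out

    def isopleth(self, level: float) -> shapely.Geometry:
        """Union of the smallest local hulls covering ``level`` percent of
        the points (a point counts as covered when inside or on a hull)."""
        if not 0 < level <= 100:
            raise ValueError("isopleth level must be in (0, 100]")
        n = len(self.points)
        needed = math.ceil(level * n / 100.0)
        covered: set[int] = set()
        chosen = []
        for g, cov in zip(self.hulls, self._covered_sets):
            chosen.append(g)
            covered.update(cov.tolist())
            if len(covered) >= needed:
                break
        geom = unary_union(chosen)
        return _drop_slivers(geom)

    def isopleth_set(self, levels: Sequence[float] | None = None) -> IsoplethSet:
        if levels is None:
            levels = [1] + list(range(5, 100, 5)) + [99, 100]
        levels = sorted(levels)
        return IsoplethSet(
            levels=list(levels), geoms={lv: self.isopleth(lv) for lv in levels}
        )

    @cached_property
    def full_union(self) -> shapely.Geometry:
        """The 100%-isopleth: union of all local hulls."""
        return _drop_slivers(unary_union(self.hulls))


def _drop_slivers(geom: shapely.Geometry) -> shapely.Geometry:
    """Remove numerically degenerate pieces and holes below the sliver area."""
    geom = geom.buffer(0)
    polys = [g for g in getattr(geom, "geoms", [geom]) if g.area > _SLIVER_AREA]
    cleaned = []
    for g in polys:
        holes = [r for r in g.interiors if Polygon(r).area > _SLIVER_AREA]
        cleaned.append(Polygon(g.exterior, holes))
    if not cleaned:
        return Polygon()
    return cleaned[0] if len(cleaned) == 1 else MultiPolygon(cleaned)


def k_locoh(points, k: int) -> LoCoHModel:
    """Fit a k-LoCoH model (k >= 3; Euclidean neighbours, distance ties
    broken by point index via the KD-tree ordering)."""
    pts = as_point_array(points)
    n = len(pts)
    if k < 3:
        raise ValueError("k must be >= 3 (smaller k gives zero-area hulls)")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of points n={n}")
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=k)
    if k == 1:
        idx = idx[:, None]
    geoms = [_local_hull(pts[idx[i]]) for i in range(n)]
    order = sorted(range(n), key=lambda i: (geoms[i].area, i))
    return LoCoHModel(
        points=pts,
        k=k,
        hulls=[geoms[i] for i in order],
        hull_roots=[int(i) for i in order],
    )


def count_holes(geom: shapely.Geometry) -> int:
    """Interior holes (above sliver tolerance) across all components."""
    total = 0
    for g in getattr(geom, "geoms", [geom]):
        if isinstance(g, Polygon):
            total += sum(1 for r in g.interiors if Polygon(r).area > _SLIVER_AREA)
    return total


def mshc_select_k(
    points, k_range: Iterable[int] | None = None, require_connected: bool = True
) -> int:
    """Minimum-spurious-hole-covering choice of k.

    Returns the smallest k in ``k_range`` (default 3..n) whose 100%-isopleth
    has no interior holes — and, by default, forms a single connected piece.
    The field rule this automates rejects topologically unjustified holes
    *and cutaways*: a territory estimate split into disjoint islands is as
    spurious as one with holes, and without the connectivity requirement
    very small k (tiny, scattered local hulls) would qualify vacuously.
    Set ``require_connected=False`` for the pure no-holes criterion.
    If no k qualifies the largest k is returned with a warning.
    """
    pts = as_point_array(points)
    n = len(pts)
    ks = list(k_range) if k_range is not None else list(range(3, n + 1))
    if not ks:
        raise ValueError("empty k_range")
    for k in ks:
        model = k_locoh(pts, k)
        union = model.full_union
        if count_holes(union) > 0:
            continue
        if require_connected and isinstance(union, MultiPolygon):
            continue
        return k
    warnings.warn(
        "no k in range yields a hole-free 100%-isopleth; returning the largest",
        stacklevel=2,
    )
    return ks[-1]
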