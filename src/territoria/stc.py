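"""The stretch-the-centre (STC) territory estimator.

STC turns a kernel density of the *calling* positions — a bounded random
pattern where parametric kernels behave well — into a territory utilization
distribution by stretching its isoclines out to the endpoints of intrusion
trials.  The stretching is a rubbersheet spatial adjustment: each trial
defines a correction link from the point where the trial's ray crosses the
central kernel's 99% isocline to the trial endpoint, every calling position
is pinned by an identity link, and all isoclines are deformed by the
piecewise-linear (TIN) transformation those links induce.  For a trial with
no response the animal claimed no ground in that direction, so the
correction link pulls the isocline back to the calling position itself.

The transformation is applied to the isocline polylines, never to the
density raster: raster warping produces severe artefacts, whereas the
polyline route honours the only hard contracts the construction states —
links are matched exactly and calling positions stay fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import shapely
from scipy.spatial import Delaunay
from shapely.geometry import LineString, MultiPolygon, Point, Polygon

from .geometry import (
    DomainError,
    Point2,
    as_point_array,
    collinear,
    ray_outermost_intersection,
)
from .kernels import (
    DEFAULT_LEVELS,
    IsoplethSet,
    KernelConfig,
    href_bandwidth,
    kde_density,
    kde_isopleth_set,
)
from .simulate import TrialSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Link:
    """A displacement link: correction (source -> target) or identity."""

    source: Point2
    target: Point2
    kind: str  # "correction" | "identity"

    def __post_init__(self) -> None:
        if self.kind not in ("correction", "identity"):
            raise ValueError(f"unknown link kind {self.kind!r}")
        if self.kind == "identity" and tuple(self.source) != tuple(self.target):
            raise ValueError("identity links must have source == target")


@dataclass
class LinkSet:
    """Links driving one rubbersheet transformation."""

    links: list[Link]

    def __post_init__(self) -> None:
        # deduplicate exact repeats (e.g. shared calling positions)
        seen = set()
        unique = []
        for ln in self.links:
            key = (tuple(ln.source), tuple(ln.target), ln.kind)
            if key not in seen:
                seen.add(key)
                unique.append(ln)
        self.links = unique
        src = self.sources()
        if len(src) < 3 or collinear(src):
            raise ValueError(
                "ill-posed transformation: need >= 3 non-collinear link sources"
            )
        _, counts = np.unique(src, axis=0, return_counts=True)
        if (counts > 1).any():
            raise ValueError("conflicting links: repeated source with distinct targets")

    def sources(self) -> np.ndarray:
        return as_point_array([ln.source for ln in self.links])

    def targets(self) -> np.ndarray:
        return as_point_array([ln.target for ln in self.links])


def build_stc_links(
    isocline99: Polygon, trials: TrialSet, calling_points=None
) -> LinkSet:
    """Correction and identity links for the STC rubbersheet.

    Per responding trial the correction link runs from the crossing of the
    trial ray (calling position, trial direction) with the 99% isocline to
    the trial endpoint; per non-responding trial it runs back to the calling
    position itself.  Every calling position becomes an identity link
    (duplicates collapsed).
    """
    links: list[Link] = []
    for t in trials.trials:
        if not isocline99.contains(Point(*t.start)):
            raise DomainError(
                f"trial ({t.individual}, {t.direction} deg): start point lies "
                "outside the 99% isocline"
            )
        source = ray_outermost_intersection(isocline99, t.start, t.direction)
        target = t.end if t.responded else t.start
        links.append(Link(source=source, target=Point2.of(target), kind="correction"))
    if calling_points is None:
        calling_points = [t.start for t in trials.trials]
    for p in calling_points:
        pt = Point2.of(p)
        links.append(Link(source=pt, target=pt, kind="identity"))
    return LinkSet(links)


class RubbersheetTransform:
    """Piecewise-linear (TIN) spatial adjustment induced by a link set.

    Displacements are interpolated barycentrically over the Delaunay
    triangulation of the link sources (zero at identity nodes); points
    outside the triangulation use the affine extension of the nearest
    triangle.  Every link source maps exactly onto its target.
    """

    def __init__(self, links: LinkSet):
        self.links = links
        self.sources = links.sources()
        self.disp = links.targets() - self.sources
        self.tri = Delaunay(self.sources)
        self._tri_polys = [
            Polygon(self.sources[s]) for s in self.tri.simplices
        ]

    def _barycentric(self, simplex: int, pts: np.ndarray) -> np.ndarray:
        T = self.tri.transform[simplex]
        b = (pts - T[2]) @ T[:2].T
        return np.column_stack([b, 1.0 - b.sum(axis=1)])

    def transform_points(self, pts) -> np.ndarray:
        pts = as_point_array(pts)
        out = pts.copy()
        simplex = self.tri.find_simplex(pts)
        outside = simplex < 0
        for s in np.unique(simplex[simplex >= 0]):
            mask = simplex == s
            bary = self._barycentric(int(s), pts[mask])
            d = bary @ self.disp[self.tri.simplices[s]]
            out[mask] += d
        if outside.any():
            ext = np.flatnonzero(outside)
            for i in ext:
                p = Point(*pts[i])
                s = min(range(len(self._tri_polys)),
                        key=lambda j: self._tri_polys[j].distance(p))
                bary = self._barycentric(s, pts[i][None, :])
                out[i] += (bary @ self.disp[self.tri.simplices[s]])[0]
        return out

    def transform_geometry(self, geom: shapely.Geometry) -> shapely.Geometry:
        """Transform a polygon/multipolygon/linestring vertex-wise; invalid
        results are repaired (buffer-0) with a logged warning."""
        if geom.is_empty:
            return geom
        if isinstance(geom, MultiPolygon):
            parts = [self.transform_geometry(g) for g in geom.geoms]
            return shapely.union_all(parts)
        if isinstance(geom, Polygon):
            ext = self.transform_points(np.asarray(geom.exterior.coords))
            holes = [self.transform_points(np.asarray(r.coords)) for r in geom.interiors]
            poly = Polygon(ext, holes)
            if not poly.is_valid:
                logger.warning("transformed isocline self-intersects; repairing")
                poly = poly.buffer(0)
            return poly
        if isinstance(geom, LineString):
            return LineString(self.transform_points(np.asarray(geom.coords)))
        raise TypeError(f"cannot rubbersheet geometry of type {type(geom)}")


def rubbersheet_transform(geom: shapely.Geometry, links: LinkSet) -> shapely.Geometry:
    """One-shot convenience around :class:`RubbersheetTransform`."""
    return RubbersheetTransform(links).transform_geometry(geom)


def _with_ring_vertices(poly: Polygon, pts: np.ndarray) -> Polygon:
    """Insert ``pts`` (points on the exterior ring) as ring vertices.

    The rubbersheet maps TIN nodes exactly but transforms polylines
    vertex-wise, so a link source must be a vertex of the ring for the
    transformed ring to pass exactly through the link target.
    """
    coords = np.asarray(poly.exterior.coords)
    line = LineString(coords)
    seglen = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    items = [(float(d), tuple(c)) for d, c in zip(cum[:-1], coords[:-1])]
    items += [(float(line.project(Point(*p))), (float(p[0]), float(p[1])))
              for p in np.atleast_2d(pts)]
    items.sort(key=lambda t: t[0])
    ring = []
    for _, c in items:
        if not ring or np.hypot(c[0] - ring[-1][0], c[1] - ring[-1][1]) > 1e-12:
            ring.append(c)
    return Polygon(ring, [r.coords for r in poly.interiors])


@dataclass
class STCResult:
    """STC output: transformed isoclines plus the ingredients that made them.

    ``ring99`` is the transformed 99% isocline as a raw polyline: it passes
    exactly through every link target (responding endpoints; calling
    positions for non-responses).  ``isopleths`` holds the polygonal
    versions, where a strongly folding displacement field may have required
    a self-intersection repair that clips such spikes.
    """

    isopleths: IsoplethSet
    central_isopleths: IsoplethSet
    links: LinkSet
    h: float
    ring99: LineString | None = None

    @property
    def headline_area(self) -> float:
        """Territory size at the conventional 95% isocline."""
        return self.isopleths.area(95)


def stc_estimate(
    calling_points,
    trials: TrialSet,
    levels: Sequence[float] = DEFAULT_LEVELS,
    grid_n: int = 256,
) -> STCResult:
    """Stretch-the-centre estimate from calling positions and trials.

    Fits a fixed kernel at the href bandwidth to the calling positions,
    extracts isoclines at ``levels``, builds the link set from the 99%
    isocline, and rubbersheets all isoclines with that one transformation.
    Nesting of the transformed isoclines is checked; violations (possible
    under strongly non-convex displacement fields) are logged, not hidden.
    """
    calling = as_point_array(calling_points)
    if len(calling) < 5:
        raise ValueError("need at least 5 calling points")
    if sum(t.responded for t in trials.trials) < 3:
        raise ValueError("need at least 3 responding trials")
    h = href_bandwidth(calling)
    grid = kde_density(calling, KernelConfig(h=h, mode="fixed", selector="HREF"),
                       grid_n=grid_n)
    levels = sorted(set(levels) | {99})
    central = kde_isopleth_set(grid, levels)
    iso99 = central.geoms[99]
    if isinstance(iso99, MultiPolygon):
        iso99 = max(iso99.geoms, key=lambda g: g.area)
    links = build_stc_links(iso99, trials, calling)
    tf = RubbersheetTransform(links)
    # the correction sources must be ring vertices for exact link matching
    corr_sources = as_point_array(
        [ln.source for ln in links.links if ln.kind == "correction"]
    )
    geoms_in = dict(central.geoms)
    geoms_in[99] = _with_ring_vertices(iso99, corr_sources)
    transformed = IsoplethSet(
        levels=list(levels),
        geoms={lv: tf.transform_geometry(geoms_in[lv]) for lv in levels},
    )
    ring99 = LineString(
        tf.transform_points(np.asarray(geoms_in[99].exterior.coords))
    )
    bad = transformed.nesting_violations()
    if bad:
        logger.warning("STC isocline nesting violated at level pairs %s", bad)
    return STCResult(isopleths=transformed, central_isopleths=central,
                     links=links, h=h, ring99=ring99)
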