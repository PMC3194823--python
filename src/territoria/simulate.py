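"""Virtual territories and simulated intrusion-trial sets.

A virtual territory is a nested pair of polygons: a central area holding the
display/resting sites of a central-place territory holder, inside a larger
outer region that the animal defends.  A simulated intrusion trial pairs a
random start point in the central area with an endpoint on the outer edge,
mimicking a phonotactic approach elicited by an intruder cue: the animal
starts at a central position and is drawn out to its territory border.

The six stock shapes span strictly convex (ellipse, triangle, circle) to
concave (star, angle) to highly concave (irregular) outlines, each scaled to
a fixed "true" area in arbitrary units so estimator output can be expressed
as a percentage of truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely import affinity
from shapely.geometry import Point, Polygon

from .geometry import (
    DomainError,
    InvalidGeometryError,
    Point2,
    as_point_array,
    make_polygon,
    polygon_area,
    ray_outermost_intersection,
    validate_polygon,
)

#: Integer divisors of 360 used as equiangular trial counts (2..360).
DIVISORS_OF_360: tuple[int, ...] = (
    2, 3, 4, 5, 6, 8, 9, 10, 12, 15, 18, 20, 24, 30, 36, 40, 45, 60,
    72, 90, 120, 180, 360,
)

#: Default true areas (arbitrary units) of the six stock territory shapes.
DEFAULT_TRUE_AREAS: dict[str, float] = {
    "ellipse": 243.58,
    "star": 130.09,
    "triangle": 88.0,
    "circle": 200.04,
    "angle": 155.63,
    "irregular": 395.11,
}


@dataclass(frozen=True)
class Territory:
    """A virtual territory with known true area.

    ``central`` is strictly inside ``outer``; ``true_area`` equals the outer
    polygon's area (this is the ground truth estimators are scored against).
    """

    outer: Polygon
    central: Polygon
    true_area: float
    shape_name: str = "custom"

    def __post_init__(self) -> None:
        validate_polygon(self.outer)
        validate_polygon(self.central)
        if not self.outer.contains(self.central):
            raise InvalidGeometryError("central area must lie strictly inside outer")
        if not math.isclose(self.true_area, self.outer.area, rel_tol=1e-6):
            raise InvalidGeometryError(
                f"true_area {self.true_area} != outer area {self.outer.area}"
            )


@dataclass(frozen=True)
class Trial:
    """One intrusion experiment: a start point and an endpoint (or none)."""

    individual: str
    direction: float  # geographic bearing, degrees in [0, 360)
    start: Point2
    end: Point2 | None
    responded: bool

    def __post_init__(self) -> None:
        if self.responded != (self.end is not None):
            raise ValueError("responded flag must match presence of an endpoint")
        if not 0.0 <= self.direction < 360.0:
            raise ValueError(f"direction {self.direction} outside [0, 360)")


@dataclass
class TrialSet:
    """Trials for one or more individuals; directions unique per individual."""

    trials: list[Trial]
    n_directions: int = 360

    def __post_init__(self) -> None:
        seen: set[tuple[str, float]] = set()
        for t in self.trials:
            key = (t.individual, t.direction)
            if key in seen:
                raise ValueError(f"duplicate direction {t.direction} for {t.individual}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.trials)

    def for_directions(self, directions: Iterable[float]) -> "TrialSet":
        wanted = set(float(d) for d in directions)
        return TrialSet(
            [t for t in self.trials if float(t.direction) in wanted],
            n_directions=len(wanted),
        )

    def points(self, include_nonresponse_starts: bool = True) -> np.ndarray:
        """Start points plus endpoints of responded trials, as an (n, 2) array."""
        pts: list[Point2] = []
        for t in self.trials:
            if t.responded or include_nonresponse_starts:
                pts.append(t.start)
            if t.responded and t.end is not None:
                pts.append(t.end)
        return as_point_array(pts)

    def start_points(self) -> np.ndarray:
        return as_point_array([t.start for t in self.trials])

    def end_points(self) -> np.ndarray:
        return as_point_array([t.end for t in self.trials if t.responded])


# ---------------------------------------------------------------------------
# Base shapes (unit scale; scaled to the requested true area on construction)
# ---------------------------------------------------------------------------

def _ellipse_ring(aspect: float = 2.0, n: int = 720) -> list[tuple[float, float]]:
    th = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return list(zip(aspect * np.cos(th), np.sin(th)))


def _circle_ring(n: int = 720) -> list[tuple[float, float]]:
    th = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return list(zip(np.cos(th), np.sin(th)))


def _triangle_ring() -> list[tuple[float, float]]:
    # equilateral, one vertex pointing north
    th = np.radians([90.0, 210.0, 330.0])
    return list(zip(np.cos(th), np.sin(th)))


def _star_ring(n_points: int = 5, inner_ratio: float = 0.5) -> list[tuple[float, float]]:
    ring = []
    for i in range(2 * n_points):
        r = 1.0 if i % 2 == 0 else inner_ratio
        a = math.pi / 2 + i * math.pi / n_points
        ring.append((r * math.cos(a), r * math.sin(a)))
    return ring


def _angle_ring() -> list[tuple[float, float]]:
    # L-shaped hexagon, arm width one third of arm length
    return [(0, 0), (3, 0), (3, 1), (1, 1), (1, 3), (0, 3)]


def _irregular_ring() -> list[tuple[float, float]]:
    # fixed 12-vertex concave outline (two deep bays, one spur)
    return [
        (0.0, 0.0), (4.0, -1.0), (7.0, 1.0), (5.5, 3.0), (8.0, 4.5),
        (6.5, 7.0), (3.5, 5.5), (2.5, 8.0), (0.5, 6.5), (1.5, 4.0),
        (-1.5, 3.5), (-0.5, 1.5),
    ]


_BASE_RINGS = {
    "ellipse": _ellipse_ring,
    "star": _star_ring,
    "triangle": _triangle_ring,
    "angle": _angle_ring,
    "circle": _circle_ring,
    "irregular": _irregular_ring,
}


def make_virtual_territory(
    shape: str | Polygon | Sequence,
    true_area: float | None = None,
    central_scale: float = 0.3,
) -> Territory:
    """Construct a virtual territory scaled to an exact true area.

    Parameters
    ----------
    shape
        One of the stock shape names (``ellipse``, ``star``, ``triangle``,
        ``angle``, ``circle``, ``irregular``) or a custom simple polygon /
        exterior ring.
    true_area
        Target area of the outer polygon.  Defaults to the stock value for
        named shapes and is required for custom polygons.
    central_scale
        Linear scale of the central area relative to the outer polygon,
        applied about the outer centroid (default 0.3).
    """
    if not 0.0 < central_scale < 1.0:
        raise ValueError("central_scale must be in (0, 1)")
    if isinstance(shape, str):
        name = shape.lower()
        if name not in _BASE_RINGS:
            raise ValueError(f"unknown shape {shape!r}; choose from {sorted(_BASE_RINGS)}")
        base = make_polygon(_BASE_RINGS[name]())
        if true_area is None:
            true_area = DEFAULT_TRUE_AREAS[name]
    else:
        name = "custom"
        base = shape if isinstance(shape, Polygon) else Polygon(shape)
        if not base.is_valid:
            raise InvalidGeometryError("custom polygon is not simple/valid")
        base = make_polygon(base.exterior.coords)
        if true_area is None:
            raise ValueError("true_area is required for custom polygons")
    if true_area <= 0:
        raise ValueError("true_area must be positive")

    factor = math.sqrt(true_area / base.area)
    c = base.centroid
    outer = affinity.scale(base, xfact=factor, yfact=factor, origin=c)
    central = _scaled_central(outer, central_scale)
    return Territory(outer=outer, central=central, true_area=float(true_area),
                     shape_name=name)


def _scaled_central(outer: Polygon, central_scale: float) -> Polygon:
    """Shrunken copy of the outer polygon anchored at its centroid, or — for
    shapes whose centroid falls outside (e.g. an L) — at the pole of
    inaccessibility, so the central area always sits inside the outer one."""
    central = affinity.scale(outer, xfact=central_scale, yfact=central_scale,
                             origin=outer.centroid)
    if outer.contains(central):
        return central
    from shapely.ops import polylabel

    anchor = polylabel(outer, tolerance=1e-3 * math.sqrt(outer.area))
    central = affinity.scale(outer, xfact=central_scale, yfact=central_scale,
                             origin=anchor)
    if not outer.contains(central):
        raise InvalidGeometryError(
            "cannot place a scaled central area inside this outline; "
            "reduce central_scale or supply a custom central polygon"
        )
    return central


# ---------------------------------------------------------------------------
# Point placement and trial pairing
# ---------------------------------------------------------------------------

def sample_central_points(
    territory: Territory, n: int, rng: np.random.Generator
) -> np.ndarray:
    """``n`` points uniform over the central area, by rejection sampling
    from its bounding box.  Reproducible under a fixed generator state."""
    if n == 0:
        return np.empty((0, 2))
    if n < 0:
        raise ValueError("n must be non-negative")
    minx, miny, maxx, maxy = territory.central.bounds
    out = np.empty((n, 2))
    got = 0
    # acceptance rate = area / bbox area; draw in batches
    batch = max(64, int(2.5 * n))
    while got < n:
        cand = rng.uniform((minx, miny), (maxx, maxy), size=(batch, 2))
        inside = shapely.contains_xy(territory.central, cand[:, 0], cand[:, 1])
        cand = cand[inside]
        take = min(n - got, len(cand))
        out[got : got + take] = cand[:take]
        got += take
    return out


def place_edge_points(territory: Territory, n: int = 360) -> np.ndarray:
    """``n`` points on the outer edge at equal angular intervals about the
    centroid of the central area (bearing i * 360/n, 0 = north)."""
    if 360 % n != 0:
        raise ValueError("n must divide 360 for equiangular placement")
    c = territory.central.centroid
    origin = Point2(c.x, c.y)
    step = 360.0 / n
    pts = [
        ray_outermost_intersection(territory.outer, origin, i * step)
        for i in range(n)
    ]
    return as_point_array(pts)


def pair_trials(
    centrals: np.ndarray,
    edges: np.ndarray,
    rng: np.random.Generator,
    directions: Sequence[float] | None = None,
    individual: str = "sim",
) -> TrialSet:
    """Pair central and edge points into trials by a uniform random bijection.

    Each edge point is used exactly once; its bearing index becomes the
    trial direction (``directions`` defaults to i * 360/n for edge point i).
    """
    centrals = as_point_array(centrals)
    edges = as_point_array(edges)
    if len(centrals) != len(edges):
        raise ValueError("need equal numbers of central and edge points")
    n = len(edges)
    if directions is None:
        directions = [i * 360.0 / n for i in range(n)]
    perm = rng.permutation(n)
    trials = [
        Trial(
            individual=individual,
            direction=float(directions[i]),
            start=Point2(*centrals[perm[i]]),
            end=Point2(*edges[i]),
            responded=True,
        )
        for i in range(n)
    ]
    return TrialSet(trials, n_directions=n)


def simulate_trialset(
    territory: Territory, seed: int | np.random.Generator, n: int = 360
) -> TrialSet:
    """Convenience: full simulated trial set for one territory (``n`` random
    central starts paired with ``n`` equiangular edge endpoints)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    centrals = sample_central_points(territory, n, rng)
    edges = place_edge_points(territory, n)
    return pair_trials(centrals, edges, rng)


def enumerate_equiangular_subsets(
    n_directions: int = 360, k: int | None = None
) -> list[tuple[int, ...]]:
    """Equiangular direction subsets of size ``k`` within ``n_directions``.

    The subset at offset ``o`` is {o, o + n/k, o + 2n/k, ...}; there are
    ``n_directions // k`` such subsets and together they partition the
    directions.  With ``k=None``, subsets for every divisor in
    :data:`DIVISORS_OF_360` are returned (810 in total for 360 directions).
    """
    if k is None:
        return [
            s for kk in DIVISORS_OF_360
            for s in enumerate_equiangular_subsets(n_directions, kk)
        ]
    if k <= 0 or n_directions % k != 0:
        raise ValueError(f"k={k} does not divide n_directions={n_directions}")
    step = n_directions // k
    return [tuple(o + j * step for j in range(k)) for o in range(step)]


# ---------------------------------------------------------------------------
# Synthetic cohort ("frog-like" fixture) generator
# ---------------------------------------------------------------------------

@dataclass
class FixtureIndividual:
    """One synthetic territory holder with a 12-direction trial set."""

    territory: Territory
    trials: TrialSet
    calling_points: np.ndarray  # (m, 2) calling positions in the central area


def generate_fixture_individuals(
    n_individuals: int,
    arena: Polygon,
    rng: np.random.Generator,
    nonresponse_prob: float = 0.04,
    n_calling: int = 15,
    area_range: tuple[float, float] = (60.0, 420.0),
    max_tries: int = 2000,
) -> list[FixtureIndividual]:
    """Synthetic stand-in for a field cohort of territorial males.

    Places non-overlapping elliptical territories of varied size and
    orientation inside ``arena``; for each, draws calling positions in the
    central area and runs 12 intrusion trials at every 30 degrees in the
    semi-random field order, with independent non-response probability
    (default 4%, the order of magnitude seen in playback fieldwork where a
    territory simply does not extend in a tested direction).  Non-responding
    trials keep their start point and have no endpoint.
    """
    from .protocol import schedule_directions  # local import avoids a cycle

    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    validate_polygon(arena)
    placed: list[Territory] = []
    out: list[FixtureIndividual] = []
    minx, miny, maxx, maxy = arena.bounds
    tries = 0
    while len(placed) < n_individuals:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n_individuals} non-overlapping territories "
                f"in the arena after {max_tries} attempts"
            )
        area = float(rng.uniform(*area_range))
        aspect = float(rng.uniform(1.0, 2.0))
        angle = float(rng.uniform(0.0, 180.0))
        base = make_polygon(_ellipse_ring(aspect=aspect, n=180))
        base = affinity.rotate(base, angle, origin="centroid")
        base = affinity.scale(base, *(math.sqrt(area / base.area),) * 2,
                              origin="centroid")
        cx = rng.uniform(minx, maxx)
        cy = rng.uniform(miny, maxy)
        c = base.centroid
        cand = affinity.translate(base, cx - c.x, cy - c.y)
        if not arena.contains(cand):
            continue
        if any(cand.intersects(t.outer) for t in placed):
            continue
        outer = make_polygon(cand.exterior.coords)
        central = affinity.scale(outer, 0.3, 0.3, origin=outer.centroid)
        terr = Territory(outer=outer, central=central, true_area=outer.area,
                         shape_name="fixture-ellipse")
        placed.append(terr)

        ident = f"ind{len(placed):02d}"
        calling = sample_central_points(terr, n_calling, rng)
        directions = schedule_directions(rng)
        trials = []
        for d in directions:
            start = Point2(*calling[rng.integers(0, n_calling)])
            if rng.random() < nonresponse_prob:
                trials.append(Trial(ident, float(d), start, None, False))
            else:
                end = ray_outermost_intersection(terr.outer, start, float(d))
                trials.append(Trial(ident, float(d), start, end, True))
        out.append(
            FixtureIndividual(
                territory=terr,
                trials=TrialSet(trials, n_directions=12),
                calling_points=calling,
            )
        )
    return out
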