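"""Parametric utilization distributions: bivariate normal kernel densities.

Implements fixed and adaptive bivariate normal kernel density estimates on a
regular grid, with the normal-reference (href) and least-squares
cross-validation (LSCV) bandwidth selectors, and probability-volume isopleth
extraction by marching squares.

The href rule used here is the Worton normal-reference form

    h = sqrt((s_x^2 + s_y^2) / 2) * n^(-1/6)

with s the marginal sample standard deviations.  GIS plug-ins that claim
the same selectors are known to disagree numerically, so the exact constant
is fixed and logged with every run.  LSCV minimises the closed-form
least-squares score over pairwise distances; for the clumped, bimodal point
patterns produced by intrusion experiments LSCV often drives h to the edge
of its search interval — that failure is reported via a flag rather than
hidden, since erratic LSCV behaviour on such patterns is precisely what
makes parametric kernels unsuitable as territory area estimators.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import shapely
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import pdist
from shapely.geometry import MultiPolygon, Polygon

from .geometry import as_point_array

logger = logging.getLogger(__name__)

DEFAULT_LEVELS: tuple[int, ...] = (1, 5, 10, 15, 20, 25, 30, 35, 40, 45, 50,
                                   55, 60, 65, 70, 75, 80, 85, 90, 95, 99)


@dataclass(frozen=True)
class KernelConfig:
    """Smoothing configuration: bandwidth, fixed/adaptive mode, selector."""

    h: float
    mode: str = "fixed"  # "fixed" | "adaptive"
    selector: str = "MANUAL"  # "HREF" | "LSCV" | "MANUAL"

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError("bandwidth h must be positive")
        if self.mode not in ("fixed", "adaptive"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class UDGrid:
    """A discretized utilization density on a regular grid.

    ``values[iy, ix]`` is the density at cell centre
    ``(x0 + ix*cell, y0 + iy*cell)``.
    """

    x0: float
    y0: float
    cell: float
    values: np.ndarray  # (ny, nx)

    @property
    def total_mass(self) -> float:
        return float(self.values.sum() * self.cell**2)

    @property
    def xs(self) -> np.ndarray:
        return self.x0 + self.cell * np.arange(self.values.shape[1])

    @property
    def ys(self) -> np.ndarray:
        return self.y0 + self.cell * np.arange(self.values.shape[0])


@dataclass
class IsoplethSet:
    """Ordered percentage isopleths of a utilization distribution."""

    levels: list[float]
    geoms: dict[float, shapely.Geometry]

    def area(self, level: float) -> float:
        return float(self.geoms[level].area)

    def areas(self) -> dict[float, float]:
        return {lv: self.area(lv) for lv in self.levels}

    def nesting_violations(self, rel_tol: float = 0.01) -> list[tuple[float, float]]:
        """Pairs of consecutive levels (p, q), p < q, where the p-isopleth
        spills outside the q-isopleth by more than ``rel_tol`` of its own
        area.  Isopleths are raster-derived polylines, so hairline overlaps
        below this tolerance are discretization noise, not real violations.
        """
        bad = []
        lv = sorted(self.levels)
        for p, q in zip(lv, lv[1:]):
            inner, outer = self.geoms[p], self.geoms[q]
            if inner.is_empty:
                continue
            overflow = inner.difference(outer).area
            if overflow > rel_tol * inner.area + 1e-12:
                bad.append((p, q))
        return bad


def href_bandwidth(points) -> float:
    """Normal-reference bandwidth sqrt((s_x^2+s_y^2)/2) * n^(-1/6)."""
    pts = as_point_array(points)
    n = len(pts)
    if n < 2:
        raise ValueError("need at least 2 points")
    sx, sy = pts.std(axis=0, ddof=1)
    if sx == 0 and sy == 0:
        raise ValueError("zero variance: all points identical")
    return float(math.sqrt((sx**2 + sy**2) / 2.0) * n ** (-1.0 / 6.0))


def lscv_score(points, h: float) -> float:
    """Closed-form least-squares cross-validation score M(h).

    M(h) = int f_hat^2 - (2/n) sum_i f_hat_{-i}(X_i), evaluated exactly via
    the Gaussian convolution identity over pairwise squared distances.
    """
    pts = as_point_array(points)
    n = len(pts)
    d2 = pdist(pts, "sqeuclidean")
    s4 = np.exp(-d2 / (4.0 * h * h)).sum()  # over unordered pairs
    s2 = np.exp(-d2 / (2.0 * h * h)).sum()
    integral_f2 = (n + 2.0 * s4) / (4.0 * math.pi * h * h * n * n)
    loo_sum = 2.0 * s2 / (2.0 * math.pi * h * h * (n - 1))  # sum_i f_{-i}(X_i)
    return float(integral_f2 - (2.0 / n) * loo_sum)


def lscv_bandwidth(
    points, interval: tuple[float, float] | None = None, n_grid: int = 60
) -> tuple[float, bool]:
    """LSCV bandwidth with a boundary-failure flag.

    Searches ``interval`` (default [href/20, 2*href]) by a coarse
    logarithmic grid followed by bounded scalar minimisation.  The flag is
    True when the minimiser lies on the interval boundary — the known LSCV
    failure mode on tightly clumped or duplicate-heavy patterns — in which
    case the boundary value is returned rather than raising.
    """
    pts = as_point_array(points)
    if len(pts) < 5:
        raise ValueError("LSCV needs at least 5 points")
    if interval is None:
        href = href_bandwidth(pts)
        interval = (href / 20.0, 2.0 * href)
    lo, hi = interval
    hs = np.geomspace(lo, hi, n_grid)
    scores = np.array([lscv_score(pts, h) for h in hs])
    i = int(np.argmin(scores))
    if i in (0, n_grid - 1):
        h = float(hs[i])
        logger.info("LSCV minimiser on search boundary: h=%.6g", h)
        return h, True
    res = minimize_scalar(
        lambda h: lscv_score(pts, h),
        bounds=(hs[i - 1], hs[i + 1]),
        method="bounded",
        options={"xatol": 1e-8 * hi},
    )
    h = float(res.x)
    on_boundary = h <= lo * 1.001 or h >= hi * 0.999
    return h, bool(on_boundary)


def _adaptive_bandwidths(pts: np.ndarray, h: float) -> np.ndarray:
    """Per-point bandwidths h_i = h * (pilot(X_i)/g)^(-1/2), pilot fixed at href."""
    pilot_h = href_bandwidth(pts)
    pilot = _eval_fixed(pts, pts, pilot_h)
    g = float(np.exp(np.mean(np.log(pilot))))
    return h * (pilot / g) ** (-0.5)


def _eval_fixed(xy: np.ndarray, pts: np.ndarray, h: float) -> np.ndarray:
    """Fixed-kernel density of ``pts`` evaluated at rows of ``xy``."""
    n = len(pts)
    out = np.zeros(len(xy))
    norm = 1.0 / (2.0 * math.pi * h * h * n)
    step = max(1, int(4e6 // max(n, 1)))
    for s in range(0, len(xy), step):
        block = xy[s : s + step]
        d2 = ((block[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
        out[s : s + step] = norm * np.exp(-d2 / (2.0 * h * h)).sum(axis=1)
    return out


def _eval_adaptive(xy: np.ndarray, pts: np.ndarray, hi: np.ndarray) -> np.ndarray:
    n = len(pts)
    out = np.zeros(len(xy))
    step = max(1, int(4e6 // max(n, 1)))
    inv2h2 = 1.0 / (2.0 * hi * hi)
    norms = 1.0 / (2.0 * math.pi * hi * hi * n)
    for s in range(0, len(xy), step):
        block = xy[s : s + step]
        d2 = ((block[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
        out[s : s + step] = (norms[None, :] * np.exp(-d2 * inv2h2[None, :])).sum(axis=1)
    return out


def kde_density(
    points,
    config: KernelConfig,
    grid_n: int = 256,
    pad_sigmas: float = 3.5,
    min_mass: float = 0.99,
) -> UDGrid:
    """Bivariate normal kernel density on a regular grid.

    The grid covers the data bounding box padded by ``pad_sigmas`` times the
    largest bandwidth and is expanded automatically until the enclosed
    probability mass reaches ``min_mass``.
    """
    pts = as_point_array(points)
    if len(pts) < 1:
        raise ValueError("need at least one point")
    h = config.h
    if config.mode == "adaptive" and len(pts) >= 2:
        his = _adaptive_bandwidths(pts, h)
    else:
        his = None
    hmax = h if his is None else float(his.max())

    pad = pad_sigmas * hmax
    for _attempt in range(6):
        minx, miny = pts.min(axis=0) - pad
        maxx, maxy = pts.max(axis=0) + pad
        cell = max(maxx - minx, maxy - miny) / (grid_n - 1)
        if cell > h:
            logger.warning("grid cell %.3g coarser than bandwidth %.3g", cell, h)
        xs = minx + cell * np.arange(grid_n)
        ys = miny + cell * np.arange(grid_n)
        gx, gy = np.meshgrid(xs, ys)
        xy = np.column_stack([gx.ravel(), gy.ravel()])
        if his is None:
            vals = _eval_fixed(xy, pts, h)
        else:
            vals = _eval_adaptive(xy, pts, his)
        grid = UDGrid(x0=float(minx), y0=float(miny), cell=float(cell),
                      values=vals.reshape(grid_n, grid_n))
        if grid.total_mass >= min_mass:
            return grid
        pad *= 1.6  # expand and retry
    return grid  # pragma: no cover - 3.5 sigma padding essentially always suffices


def kde_isopleth(grid: UDGrid, p: float) -> shapely.Geometry:
    """Smallest density level set containing ``p`` percent of the mass.

    Cells are ranked by density; the threshold is the density at which the
    accumulated mass reaches p% of the grid's total, and the contour at that
    threshold is traced by marching squares with sub-cell interpolation.
    """
    from skimage import measure

    if not 0 < p < 100:
        raise ValueError(
            "isopleth percentage must be in (0, 100); a 100% isopleth is "
            "impossible for a parametric kernel"
        )
    vals = grid.values
    flat = np.sort(vals.ravel())[::-1]
    cmass = np.cumsum(flat) * grid.cell**2
    target = (p / 100.0) * grid.total_mass
    idx = int(np.searchsorted(cmass, target))
    idx = min(idx, len(flat) - 1)
    threshold = float(flat[idx])
    contours = measure.find_contours(vals, threshold)
    rings = []
    for c in contours:
        if len(c) < 3:
            continue
        xy = np.column_stack([grid.x0 + c[:, 1] * grid.cell,
                              grid.y0 + c[:, 0] * grid.cell])
        rings.append(xy)
    return _assemble_rings(rings)


def _assemble_rings(rings: Sequence[np.ndarray]) -> shapely.Geometry:
    """Build polygons from closed contour rings with even-odd hole nesting."""
    polys = []
    for r in rings:
        if not np.allclose(r[0], r[-1]):
            r = np.vstack([r, r[0]])
        p = Polygon(r)
        if not p.is_valid:
            p = p.buffer(0)
        if not p.is_empty:
            polys.append(p)
    if not polys:
        return Polygon()
    polys.sort(key=lambda g: g.area, reverse=True)
    shells: list[Polygon] = []
    holes_for: list[list] = []
    for p in polys:
        rep = p.representative_point()
        depth = sum(1 for s in shells if s.covers(rep))
        if depth % 2 == 0:
            shells.append(p)
            holes_for.append([])
        else:
            # hole in the smallest shell that contains it
            owner = min(
                (i for i, s in enumerate(shells) if s.covers(rep)),
                key=lambda i: shells[i].area,
            )
            holes_for[owner].append(p.exterior)
    out = [Polygon(s.exterior, hs) for s, hs in zip(shells, holes_for)]
    geom = out[0] if len(out) == 1 else MultiPolygon(out)
    if not geom.is_valid:
        geom = geom.buffer(0)
    return geom


def kde_isopleth_set(grid: UDGrid, levels: Sequence[float] = DEFAULT_LEVELS) -> IsoplethSet:
    levels = sorted(levels)
    return IsoplethSet(levels=list(levels),
                       geoms={lv: kde_isopleth(grid, lv) for lv in levels})
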