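"""Benchmarking machinery for territory estimators on virtual territories.

Quantifies estimator behaviour the way a simulation study would: percent of
true area recovered, area-accumulation curves over exhaustively enumerated
equiangular trial subsets (mean and SD over all offsets per trial count k),
the smallest trial count from which the rank order of territories is stable,
per-step relative changes in mean area, and coverage statistics of an
isopleth family against a reference hull.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import hulls, kernels, locoh
from .geometry import as_point_array
from .simulate import (
    DIVISORS_OF_360,
    Territory,
    TrialSet,
    enumerate_equiangular_subsets,
)

#: estimator label -> area of a point pattern.  Polygon estimators are
#: evaluated at their full extension, parametric kernels at the 95% isocline.
_ESTIMATORS: dict[str, Callable[[np.ndarray], float]] = {}


def _register(name: str):
    def deco(fn):
        _ESTIMATORS[name] = fn
        return fn
    return deco


@_register("MCP")
def _area_mcp(pts: np.ndarray) -> float:
    return hulls.mcp(pts).area


@_register("DH")
def _area_dh(pts: np.ndarray) -> float:
    return hulls.detailed_hull(pts, lam=hulls.AUTO).area


@_register("LoCoH")
def _area_locoh(pts: np.ndarray) -> float:
    k = locoh.mshc_select_k(pts)
    return float(locoh.k_locoh(pts, k).full_union.area)


def _kernel_area(pts: np.ndarray, selector: str, mode: str) -> float:
    if selector == "HREF":
        h = kernels.href_bandwidth(pts)
    else:
        h, _flag = kernels.lscv_bandwidth(pts)
    grid = kernels.kde_density(
        pts, kernels.KernelConfig(h=h, mode=mode, selector=selector), grid_n=128
    )
    return float(kernels.kde_isopleth(grid, 95).area)


@_register("KDE-HREF-f")
def _area_kde_href_f(pts: np.ndarray) -> float:
    return _kernel_area(pts, "HREF", "fixed")


@_register("KDE-HREF-a")
def _area_kde_href_a(pts: np.ndarray) -> float:
    return _kernel_area(pts, "HREF", "adaptive")


@_register("KDE-LSCV-f")
def _area_kde_lscv_f(pts: np.ndarray) -> float:
    return _kernel_area(pts, "LSCV", "fixed")


def estimator_area(points, estimator: str) -> float:
    """Area assigned to a point pattern by a named estimator."""
    if estimator not in _ESTIMATORS:
        raise ValueError(
            f"unknown estimator {estimator!r}; choose from {sorted(_ESTIMATORS)}"
        )
    return float(_ESTIMATORS[estimator](as_point_array(points)))


def percent_of_true(estimate_area: float, territory: Territory) -> float:
    """Estimate as a percentage of the territory's true area (unrounded;
    round to integer for table display)."""
    if territory.true_area <= 0:
        raise ValueError("true_area must be positive")
    return 100.0 * estimate_area / territory.true_area


def subset_points(trials: TrialSet, directions: Sequence[int]) -> np.ndarray:
    """Start+end points of the trials whose directions are in the subset."""
    return trials.for_directions(directions).points()


def accumulation_table(
    territory: Territory,
    trials: TrialSet,
    estimator: str,
    ks: Sequence[int] = DIVISORS_OF_360,
) -> pd.DataFrame:
    """Mean and SD of estimated area over all equiangular offsets, per k.

    Columns: k, n_offsets, mean_area, sd_area, percent_of_true (of the mean).
    """
    rows = []
    for k in ks:
        areas = [
            estimator_area(subset_points(trials, sub), estimator)
            for sub in enumerate_equiangular_subsets(trials.n_directions, k)
        ]
        areas = np.asarray(areas)
        rows.append(
            {
                "k": k,
                "n_offsets": len(areas),
                "mean_area": areas.mean(),
                "sd_area": areas.std(ddof=0) if len(areas) > 1 else 0.0,
                "percent_of_true": percent_of_true(areas.mean(), territory),
            }
        )
    return pd.DataFrame(rows)


def rank_stability(series: Mapping[str, Mapping[int, float]]) -> int:
    """Smallest trial count k* from which the area rank order is invariant.

    ``series`` maps unit id -> {k: area}.  The reference ordering is the one
    at the largest common k; ties in area are broken by unit id.  Returns
    the smallest k such that every k' >= k reproduces the reference order.
    """
    units = sorted(series)
    if len(units) < 2:
        raise ValueError("need at least two units to rank")
    ks = sorted(set.intersection(*(set(series[u]) for u in units)))
    if not ks:
        raise ValueError("no common trial counts across units")

    def order(k: int) -> tuple:
        return tuple(sorted(units, key=lambda u: (series[u][k], u)))

    reference = order(ks[-1])
    k_star = ks[-1]
    for k in reversed(ks):
        if order(k) == reference:
            k_star = k
        else:
            break
    return k_star


@dataclass(frozen=True)
class StepwiseChange:
    """Per-step percent changes of a mean-area series over increasing k."""

    ks: tuple[int, ...]
    changes: tuple[float, ...]  # change at step i: ks[i] -> ks[i+1]
    last_exceeding: int | None  # k after the last step with |change| > threshold
    threshold: float


def stepwise_change(
    means: Sequence[float], ks: Sequence[int] | None = None, threshold: float = 2.0
) -> StepwiseChange:
    """Relative change of mean area between consecutive trial counts.

    ``last_exceeding`` is the k reached by the last step whose absolute
    change exceeds ``threshold`` percent (None when no step does).
    """
    means = np.asarray(means, dtype=float)
    if (means <= 0).any():
        raise ValueError("mean areas must be positive")
    if ks is None:
        ks = list(range(len(means)))
    changes = 100.0 * np.diff(means) / means[:-1]
    exceeding = [i for i, c in enumerate(changes) if abs(c) > threshold]
    last = ks[exceeding[-1] + 1] if exceeding else None
    return StepwiseChange(
        ks=tuple(ks), changes=tuple(float(c) for c in changes),
        last_exceeding=last, threshold=threshold,
    )


def isopleth_coverage_stats(
    isopleths: kernels.IsoplethSet, reference: hulls.HullEstimate, tol: float = 1e-9
) -> tuple[float | None, float | None]:
    """At which isopleth level a reference hull is matched and covered.

    Returns ``(area_equality_level, full_overlap_level)``: the smallest
    level whose isopleth area reaches the reference area, and the smallest
    level whose isopleth fully contains the reference polygon (None if a
    level is never reached).  Containment is stricter than area, so
    ``full_overlap_level >= area_equality_level`` whenever both exist.
    """
    area_level = None
    overlap_level = None
    for lv in sorted(isopleths.levels):
        geom = isopleths.geoms[lv]
        if area_level is None and geom.area >= reference.area - tol:
            area_level = lv
        if overlap_level is None and geom.buffer(tol).covers(reference.polygon):
            overlap_level = lv
        if area_level is not None and overlap_level is not None:
            break
    return area_level, overlap_level
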