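"""CSV and GeoJSON input/output for trials, territories and estimator output.

CSV is the canonical trial format (field teams work in spreadsheets);
GeoJSON (RFC 7946) is canonical for all geometry.  Every written artifact
embeds the run configuration (seed, resolved parameters, software version)
in its metadata so a run is reproducible from its outputs alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import shapely
from shapely.geometry import mapping as geo_mapping
from shapely.geometry import shape as geo_shape

from . import __version__
from .geometry import Point2
from .simulate import Territory, Trial, TrialSet

TRIALS_COLUMNS = [
    "individual", "direction_deg", "start_x", "start_y", "end_x", "end_y",
    "responded",
]


class SchemaError(ValueError):
    """A required column is missing from a trial table."""


class RowError(ValueError):
    """A specific row of a trial table cannot be parsed."""


@dataclass
class RunConfig:
    """Run parameters that accompany every artifact file."""

    seed: int | None = None
    params: dict = field(default_factory=dict)

    def metadata(self) -> dict:
        return {
            "software": f"territoria {__version__}",
            "seed": self.seed,
            **self.params,
        }


def write_trials_csv(trials: TrialSet, path) -> None:
    rows = []
    for t in trials.trials:
        rows.append(
            {
                "individual": t.individual,
                "direction_deg": t.direction,
                "start_x": t.start.x,
                "start_y": t.start.y,
                "end_x": t.end.x if t.end is not None else "",
                "end_y": t.end.y if t.end is not None else "",
                "responded": t.responded,
            }
        )
    pd.DataFrame(rows, columns=TRIALS_COLUMNS).to_csv(path, index=False)


def read_trials_csv(path, n_directions: int | None = None) -> TrialSet:
    """Parse a trial table; blank end coordinates with responded=false are
    non-responses.  Missing columns raise :class:`SchemaError`; malformed
    rows raise :class:`RowError` naming the offending line."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TRIALS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    trials: list[Trial] = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        responded = str(row["responded"]).strip().lower() in ("true", "1", "yes")
        try:
            start = Point2(float(row["start_x"]), float(row["start_y"]))
        except ValueError as exc:
            raise RowError(f"line {line}: non-numeric start coordinate") from exc
        end_blank = row["end_x"].strip() == "" and row["end_y"].strip() == ""
        if responded and end_blank:
            raise RowError(f"line {line}: responded=true but no end coordinates")
        if responded:
            try:
                end = Point2(float(row["end_x"]), float(row["end_y"]))
            except ValueError as exc:
                raise RowError(f"line {line}: non-numeric end coordinate") from exc
        else:
            end = None
        try:
            direction = float(row["direction_deg"])
        except ValueError as exc:
            raise RowError(f"line {line}: non-numeric direction") from exc
        trials.append(
            Trial(individual=row["individual"], direction=direction,
                  start=start, end=end, responded=responded)
        )
    if n_directions is None:
        n_directions = max(
            (len([t for t in trials if t.individual == ind])
             for ind in {t.individual for t in trials}),
            default=0,
        )
    return TrialSet(trials, n_directions=n_directions)


def feature(geom, properties: Mapping | None = None) -> dict:
    if isinstance(geom, (Point2, tuple)):
        geom = shapely.Point(*geom)
    if not geom.is_valid:
        name = (properties or {}).get("name", "<unnamed>")
        raise ValueError(f"invalid geometry for feature {name!r}")
    return {
        "type": "Feature",
        "geometry": geo_mapping(geom),
        "properties": dict(properties or {}),
    }


def write_geojson(features: Iterable[dict], path, config: RunConfig | None = None) -> None:
    collection = {
        "type": "FeatureCollection",
        "features": list(features),
        "metadata": (config or RunConfig()).metadata(),
    }
    Path(path).write_text(json.dumps(collection, indent=1))


def read_geojson(path) -> dict:
    return json.loads(Path(path).read_text())


def read_geojson_geometries(path) -> list[tuple[shapely.Geometry, dict]]:
    """(geometry, properties) pairs from a GeoJSON FeatureCollection."""
    data = read_geojson(path)
    feats = data["features"] if data.get("type") == "FeatureCollection" else [data]
    return [(geo_shape(f["geometry"]), f.get("properties", {})) for f in feats]


def territory_features(territory: Territory) -> list[dict]:
    common = {"shape": territory.shape_name, "true_area": territory.true_area}
    return [
        feature(territory.outer, {**common, "role": "outer"}),
        feature(territory.central, {**common, "role": "central"}),
    ]


def isopleth_features(isopleths, extra: Mapping | None = None) -> list[dict]:
    return [
        feature(isopleths.geoms[lv], {"level": lv, **(extra or {})})
        for lv in isopleths.levels
        if not isopleths.geoms[lv].is_empty
    ]


def hull_feature(estimate, extra: Mapping | None = None) -> dict:
    props = {"method": estimate.method, **estimate.params, **(extra or {})}
    return feature(estimate.polygon, props)


def linkset_features(links) -> list[dict]:
    feats = []
    for ln in links.links:
        geom = shapely.LineString([tuple(ln.source), tuple(ln.target)])
        if ln.kind == "identity":  # zero-length: represent as a point
            geom = shapely.Point(*ln.source)
        feats.append(feature(geom, {"kind": ln.kind}))
    return feats


def points_features(points, role: str = "point") -> list[dict]:
    return [feature(shapely.Point(*p), {"role": role}) for p in points]
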