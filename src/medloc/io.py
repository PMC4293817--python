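"""Readers and writers for the package's file formats.

Segments travel as GeoJSON LineString FeatureCollections (properties:
``category``, optional ``length_km``) or CSV with WKT geometry; stations
and cities as GeoJSON Points or CSV. Solution tables are tidy CSV; selected
allocations export as GeoJSON supplying lines (city -> facility) for map
display. The synthetic generator writes these same formats, acting as their
reference producer.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from shapely import wkt as shapely_wkt
from shapely.geometry import LineString, Point, mapping, shape

from .errors import InputError
from .metrics import DemandSite, aggregate_hospitals
from .network import Station, TransportSegment

__all__ = [
    "read_segments_geojson", "write_segments_geojson",
    "read_segments_csv", "write_segments_csv",
    "read_stations", "write_stations_geojson",
    "read_cities_csv", "write_cities_csv",
    "read_hospitals_csv", "write_hospitals_csv",
    "save_instance", "load_instance",
    "supplying_lines_geojson", "write_manifest",
]


def read_segments_geojson(path) -> list[TransportSegment]:
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise InputError(f"{path}: expected a GeoJSON FeatureCollection")
    out = []
    for k, feat in enumerate(gj.get("features", [])):
        geom = shape(feat["geometry"])
        if geom.geom_type != "LineString":
            raise InputError(f"{path}: feature {k} is not a LineString")
        props = feat.get("properties") or {}
        if "category" not in props:
            raise InputError(f"{path}: feature {k} has no 'category' property")
        out.append(
            TransportSegment(
                id=str(feat.get("id", props.get("id", f"seg{k + 1}"))),
                polyline=tuple(geom.coords),
                category=props["category"],
                length_km=props.get("length_km"),
            )
        )
    return out


def write_segments_geojson(segments, path) -> None:
    features = [
        {
            "type": "Feature",
            "id": s.id,
            "geometry": mapping(LineString(s.polyline)),
            "properties": {"category": s.category, "length_km": s.length_km},
        }
        for s in segments
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_segments_csv(path) -> list[TransportSegment]:
    df = pd.read_csv(path)
    required = {"id", "wkt", "category"}
    if not required <= set(df.columns):
        raise InputError(f"{path}: segment CSV needs columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        geom = shapely_wkt.loads(row["wkt"])
        length = row.get("length_km")
        out.append(
            TransportSegment(
                id=str(row["id"]),
                polyline=tuple(geom.coords),
                category=row["category"],
                length_km=None if pd.isna(length) else float(length),
            )
        )
    return out


def write_segments_csv(segments, path) -> None:
    pd.DataFrame(
        {
            "id": [s.id for s in segments],
            "wkt": [LineString(s.polyline).wkt for s in segments],
            "category": [s.category for s in segments],
            "length_km": [s.length_km for s in segments],
        }
    ).to_csv(path, index=False)


def read_stations(path) -> list[Station]:
    path = Path(path)
    if path.suffix.lower() in (".geojson", ".json"):
        with open(path) as fh:
            gj = json.load(fh)
        out = []
        for k, feat in enumerate(gj.get("features", [])):
            geom = shape(feat["geometry"])
            props = feat.get("properties") or {}
            out.append(
                Station(
                    id=str(feat.get("id", props.get("id", f"st{k + 1}"))),
                    lon=geom.x, lat=geom.y,
                )
            )
        return out
    df = pd.read_csv(path)
    return [
        Station(id=str(r["id"]), lon=float(r["lon"]), lat=float(r["lat"]))
        for _, r in df.iterrows()
    ]


def write_stations_geojson(stations, path) -> None:
    features = [
        {
            "type": "Feature",
            "id": s.id,
            "geometry": mapping(Point(s.lon, s.lat)),
            "properties": {"id": s.id},
        }
        for s in stations
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_cities_csv(path) -> list[DemandSite]:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"id", "lon", "lat", "population"}
    if not required <= set(df.columns):
        raise InputError(f"{path}: city CSV needs columns {sorted(required)}")
    return [
        DemandSite(
            id=str(r["id"]), name=str(r.get("name", r["id"])),
            lon=float(r["lon"]), lat=float(r["lat"]),
            population=float(r["population"]),
        )
        for _, r in df.iterrows()
    ]


def write_cities_csv(cities, path) -> None:
    pd.DataFrame(
        {
            "id": [c.id for c in cities],
            "name": [c.name for c in cities],
            "lon": [c.lon for c in cities],
            "lat": [c.lat for c in cities],
            "population": [c.population for c in cities],
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_hospitals_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"id", "city_id", "beds", "ksd", "ptr", "btr"}
    if not required <= set(df.columns):
        raise InputError(f"{path}: hospital CSV needs columns {sorted(required)}")
    return df


def write_hospitals_csv(hospitals: pd.DataFrame, path) -> None:
    hospitals.to_csv(path, index=False, float_format="%.17g")


def save_instance(instance, directory) -> None:
    """Write an instance as cities.csv, hospitals.csv, segments.geojson,
    stations.geojson and params.json inside ``directory``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_cities_csv(instance.cities, d / "cities.csv")
    write_hospitals_csv(instance.hospitals, d / "hospitals.csv")
    write_segments_geojson(instance.segments, d / "segments.geojson")
    write_stations_geojson(instance.stations, d / "stations.geojson")
    with open(d / "params.json", "w") as fh:
        json.dump({"seed": instance.seed, "params": instance.params}, fh, indent=1)


def load_instance(directory):
    from .synthetic import SyntheticInstance

    d = Path(directory)
    cities = read_cities_csv(d / "cities.csv")
    hospitals = read_hospitals_csv(d / "hospitals.csv")
    segments = read_segments_geojson(d / "segments.geojson")
    stations = read_stations(d / "stations.geojson")
    meta = {"seed": None, "params": {}}
    if (d / "params.json").exists():
        with open(d / "params.json") as fh:
            meta = json.load(fh)
    return SyntheticInstance(
        cities=cities,
        hospitals=hospitals,
        facilities=aggregate_hospitals(hospitals, cities),
        segments=segments,
        stations=stations,
        seed=meta.get("seed"),
        params=meta.get("params", {}),
    )


def supplying_lines_geojson(assignment, cities, facilities, path=None) -> dict:
    """GeoJSON LineStrings from each city to its assigned facility."""
    city_pos = {c.id: (c.lon, c.lat) for c in cities}
    fac_pos = {f.id: (f.lon, f.lat) for f in facilities}
    features = []
    for i, j in sorted(assignment.items(), key=lambda kv: str(kv[0])):
        if i not in city_pos or j not in fac_pos:
            raise InputError(f"assignment pair ({i!r}, {j!r}) has no coordinates")
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(LineString([city_pos[i], fac_pos[j]])),
                "properties": {"city": str(i), "facility": str(j)},
            }
        )
    gj = {"type": "FeatureCollection", "features": features}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(gj, fh)
    return gj


def write_manifest(path, *, config, seed, extra=None) -> None:
    """JSON run manifest: configuration, seed and package version."""
    from dataclasses import asdict

    from . import __version__

    doc = {
        "medloc_version": __version__,
        "seed": seed,
        "config": asdict(config),
    }
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, default=str)
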