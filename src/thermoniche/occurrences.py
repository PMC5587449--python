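"""Occurrence-record curation: reading, deduplication, thinning, range filtering.

Museum and aggregator records (e.g. GBIF downloads) arrive as one row per
specimen.  Analyses downstream operate on *unique localities*: records
sharing exact coordinates collapse to one, optionally thinned so that no two
retained localities lie closer than a distance threshold, and optionally
clipped to expert range polygons.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from shapely.geometry import Point, shape
from shapely.geometry.base import BaseGeometry

from .errors import ConfigurationError, EmptyInputError, GeometryError, ParameterError

EARTH_RADIUS_KM = 6371.0

#: decimal places used when comparing coordinates for duplication; absorbs
#: float noise introduced by CSV round-trips without merging distinct sites
COORD_DECIMALS = 6


@dataclass(frozen=True)
class LocalityRecord:
    """A single georeferenced occurrence of one species."""

    species: str
    longitude: float
    latitude: float
    source_id: str | None = None

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("species must be non-empty")
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} outside [-180, 180]")


@dataclass
class LocalitySet:
    """Unique localities for one species, in order of first occurrence."""

    species: str
    localities: list[LocalityRecord]

    @property
    def n(self) -> int:
        return len(self.localities)

    def __iter__(self):
        return iter(self.localities)

    def __len__(self) -> int:
        return len(self.localities)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": [r.species for r in self.localities],
                "longitude": [r.longitude for r in self.localities],
                "latitude": [r.latitude for r in self.localities],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class LoadReport:
    """Row-level accounting for :func:`load_records`."""

    n_read: int = 0
    n_kept: int = 0
    n_skipped: int = 0
    skipped_rows: list[int] = field(default_factory=list)


_DEFAULT_COLUMNS = {"species": "species", "longitude": "longitude", "latitude": "latitude"}


def load_records(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    *,
    delimiter: str = ",",
) -> tuple[list[LocalityRecord], LoadReport]:
    """Read occurrence records from a delimited text file.

    Parameters
    ----------
    path:
        CSV/TSV file with a header row.
    column_map:
        Maps the canonical field names ``species``, ``longitude``,
        ``latitude`` (and optionally ``source_id``) to the file's column
        names. Defaults to identity.

    Returns
    -------
    records, report:
        Rows with unparsable or out-of-range coordinates are skipped, not
        fatal — the report counts them.
    """
    cols = dict(_DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep=delimiter)
    if df.empty:
        raise EmptyInputError(f"no records in {path}")
    for canonical in ("species", "longitude", "latitude"):
        if cols[canonical] not in df.columns:
            raise ConfigurationError(
                f"column {cols[canonical]!r} (for {canonical}) not found in {path}; "
                f"available: {list(df.columns)}"
            )
    id_col = cols.get("source_id")
    report = LoadReport(n_read=len(df))
    records: list[LocalityRecord] = []
    for idx, row in df.iterrows():
        try:
            rec = LocalityRecord(
                species=str(row[cols["species"]]),
                longitude=float(row[cols["longitude"]]),
                latitude=float(row[cols["latitude"]]),
                source_id=(
                    str(row[id_col]) if id_col and id_col in df.columns else None
                ),
            )
        except (ValueError, TypeError):
            report.n_skipped += 1
            report.skipped_rows.append(int(idx))
            continue
        records.append(rec)
    report.n_kept = len(records)
    return records, report


def _coord_key(rec: LocalityRecord) -> tuple[float, float]:
    return (round(rec.longitude, COORD_DECIMALS), round(rec.latitude, COORD_DECIMALS))


def deduplicate(records: Iterable[LocalityRecord]) -> LocalitySet:
    """Collapse records sharing exact coordinates into single localities.

    Order of first occurrence is preserved. All records must belong to one
    species.
    """
    records = list(records)
    if not records:
        raise EmptyInputError("no records to deduplicate")
    species = records[0].species
    for rec in records:
        if rec.species != species:
            raise ValueError(
                f"mixed species: {rec.species!r} vs {species!r}; deduplicate per species"
            )
    seen: set[tuple[float, float]] = set()
    unique: list[LocalityRecord] = []
    for rec in records:
        key = _coord_key(rec)
        if key not in seen:
            seen.add(key)
            unique.append(rec)
    return LocalitySet(species=species, localities=unique)


def haversine_km(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    """Great-circle distance in km on a sphere of radius 6371 km."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlmb = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlmb / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def thin_by_distance(locset: LocalitySet, min_km: float = 1.0) -> LocalitySet:
    """Greedy spatial thinning in input order.

    A locality is dropped when it lies strictly within ``min_km``
    (great-circle) of any already-retained locality, so points at least
    ``min_km`` apart are always both kept.
    """
    if min_km <= 0:
        raise ParameterError("min_km must be > 0")
    retained: list[LocalityRecord] = []
    for rec in locset:
        if all(
            haversine_km(rec.longitude, rec.latitude, kept.longitude, kept.latitude) >= min_km
            for kept in retained
        ):
            retained.append(rec)
    return LocalitySet(species=locset.species, localities=retained)


def _as_geometries(polygons) -> list[BaseGeometry]:
    """Accept a shapely geometry, GeoJSON mapping, GeoJSON file path, or a list."""
    if isinstance(polygons, BaseGeometry):
        geoms = [polygons]
    elif isinstance(polygons, (str, Path)):
        with open(polygons) as fh:
            gj = json.load(fh)
        return _as_geometries(gj)
    elif isinstance(polygons, Mapping):
        t = polygons.get("type")
        if t == "FeatureCollection":
            geoms = [shape(f["geometry"]) for f in polygons["features"]]
        elif t == "Feature":
            geoms = [shape(polygons["geometry"])]
        else:
            geoms = [shape(polygons)]
    elif isinstance(polygons, Sequence):
        geoms = []
        for p in polygons:
            geoms.extend(_as_geometries(p))
        return geoms
    else:
        raise GeometryError(f"unsupported polygon input: {type(polygons)!r}")
    for g in geoms:
        if not g.is_valid:
            raise GeometryError("invalid range geometry")
    return geoms


def filter_by_range(locset: LocalitySet, polygons) -> LocalitySet:
    """Keep localities inside or on the boundary of any range polygon.

    ``polygons`` may be a shapely geometry, a GeoJSON mapping or file path,
    or a sequence of these. Coordinates are assumed geographic (WGS84), the
    same CRS as the polygons.
    """
    geoms = _as_geometries(polygons)
    kept = [
        rec
        for rec in locset
        if any(g.covers(Point(rec.longitude, rec.latitude)) for g in geoms)
    ]
    return LocalitySet(species=locset.species, localities=kept)
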