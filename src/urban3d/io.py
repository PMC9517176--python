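"""Plain-text geodata formats: GeoJSON feature collections and ASCII rasters.

Geometry lives in planar metres on a local grid; no CRS handling. Vector
layers are GeoJSON; the PM2.5 surface is an ESRI ASCII grid (.asc), a
single-band plain-text raster with a no-data value of −9999.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import LineString, Polygon, mapping, shape

__all__ = [
    "Parcel",
    "Road",
    "Raster",
    "SchemaError",
    "read_geojson",
    "write_geojson",
    "read_parcels",
    "write_parcels",
    "read_roads",
    "write_roads",
    "read_ascii_grid",
    "write_ascii_grid",
]

NODATA = -9999.0


class SchemaError(ValueError):
    """A file violated the expected schema (names the file, record, field)."""


@dataclass
class Parcel:
    """A land-use parcel: polygon plus land-use class."""

    geometry: Polygon
    land_use: str
    parcel_id: Optional[str] = None


@dataclass
class Road:
    """A road polyline with class 'main' or 'secondary'."""

    geometry: LineString
    road_class: str


def _round_coords(obj, ndigits: int = 3):
    if isinstance(obj, (list, tuple)):
        return [_round_coords(o, ndigits) for o in obj]
    if isinstance(obj, float):
        return round(obj, ndigits)
    return obj


def write_geojson(path: str | Path, geometries: Sequence, properties: Sequence[dict]) -> None:
    """Write a FeatureCollection; deterministic (sorted keys, mm precision)."""
    features = []
    for geom, props in zip(geometries, properties):
        gm = mapping(geom)
        gm = {"type": gm["type"], "coordinates": _round_coords(gm["coordinates"])}
        features.append({"type": "Feature", "geometry": gm, "properties": props})
    fc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(fc, sort_keys=True, separators=(",", ":")) + "\n")


def read_geojson(path: str | Path) -> list[tuple]:
    """Read a FeatureCollection into (shapely geometry, properties) pairs.

    Invalid geometry raises :class:`SchemaError` naming the record index.
    """
    path = Path(path)
    data = json.loads(path.read_text())
    if data.get("type") != "FeatureCollection":
        raise SchemaError(f"{path}: not a FeatureCollection")
    out = []
    for i, feat in enumerate(data.get("features", [])):
        try:
            geom = shape(feat["geometry"])
        except Exception as exc:  # noqa: BLE001 - reported with context
            raise SchemaError(f"{path}: record {i}: bad geometry ({exc})") from exc
        if not geom.is_valid:
            raise SchemaError(f"{path}: record {i}: invalid geometry")
        out.append((geom, feat.get("properties", {}) or {}))
    return out


def _require_prop(props: dict, key: str, path, i: int):
    if key not in props:
        raise SchemaError(f"{path}: record {i}: missing property {key!r}")
    return props[key]


def write_parcels(path: str | Path, parcels: Sequence[Parcel]) -> None:
    write_geojson(
        path,
        [p.geometry for p in parcels],
        [{"land_use": p.land_use, "parcel_id": p.parcel_id} for p in parcels],
    )


def read_parcels(path: str | Path) -> list[Parcel]:
    out = []
    for i, (geom, props) in enumerate(read_geojson(path)):
        out.append(
            Parcel(
                geometry=geom,
                land_use=_require_prop(props, "land_use", path, i),
                parcel_id=props.get("parcel_id"),
            )
        )
    return out


def write_roads(path: str | Path, roads: Sequence[Road]) -> None:
    write_geojson(
        path,
        [r.geometry for r in roads],
        [{"road_class": r.road_class} for r in roads],
    )


def read_roads(path: str | Path) -> list[Road]:
    out = []
    for i, (geom, props) in enumerate(read_geojson(path)):
        cls = _require_prop(props, "road_class", path, i)
        if cls not in ("main", "secondary"):
            raise SchemaError(f"{path}: record {i}: road_class must be main|secondary")
        out.append(Road(geometry=geom, road_class=cls))
    return out


@dataclass
class Raster:
    """A single-band raster on a regular grid, lower-left anchored.

    ``values`` has shape (nrows, ncols) with row 0 at the TOP (north), as in
    the ASCII-grid convention; ``nodata`` cells carry :data:`NODATA`.
    """

    values: np.ndarray
    x0: float  # lower-left corner x (m)
    y0: float  # lower-left corner y (m)
    cellsize: float
    nodata: float = NODATA

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(xs, ys) meshgrid of cell centres, same shape as ``values``."""
        xs = self.x0 + (np.arange(self.ncols) + 0.5) * self.cellsize
        ys = self.y0 + (self.nrows - np.arange(self.nrows) - 0.5) * self.cellsize
        return np.meshgrid(xs, ys)

    def mask(self) -> np.ndarray:
        return self.values != self.nodata


def write_ascii_grid(path: str | Path, raster: Raster) -> None:
    lines = [
        f"ncols {raster.ncols}",
        f"nrows {raster.nrows}",
        f"xllcorner {raster.x0:.3f}",
        f"yllcorner {raster.y0:.3f}",
        f"cellsize {raster.cellsize:.3f}",
        f"NODATA_value {raster.nodata:g}",
    ]
    for row in raster.values:
        lines.append(" ".join(f"{v:.6g}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_ascii_grid(path: str | Path) -> Raster:
    path = Path(path)
    lines = path.read_text().splitlines()
    header: dict[str, float] = {}
    idx = 0
    for idx, line in enumerate(lines):
        key, _, val = line.partition(" ")
        if key.lower() in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"):
            header[key.lower()] = float(val)
        else:
            break
    try:
        ncols, nrows = int(header["ncols"]), int(header["nrows"])
    except KeyError as exc:
        raise SchemaError(f"{path}: missing header field {exc}") from exc
    values = np.array([[float(v) for v in line.split()] for line in lines[idx : idx + nrows]])
    if values.shape != (nrows, ncols):
        raise SchemaError(f"{path}: grid shape {values.shape} != header ({nrows},{ncols})")
    return Raster(
        values=values,
        x0=header["xllcorner"],
        y0=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata=header.get("nodata_value", NODATA),
    )
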