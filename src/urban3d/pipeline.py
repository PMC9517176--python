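"""End-to-end pipeline: simulate → zones → indices → LUR → surface → zonal
stats → GWR, with a checksum manifest, resumable stages and YAML config.

A single master seed fans out to stage-specific seeds by fixed offsets (see
:mod:`urban3d.synthetic_city`), so a run is reproducible file-for-file and
each stage is independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import gwr as gwr_mod
from . import lur as lur_mod
from . import stats as stats_mod
from .io import (
    Raster,
    read_ascii_grid,
    read_geojson,
    read_parcels,
    read_roads,
    write_ascii_grid,
    write_geojson,
)
from .landscape3d import Building, SampleArea, index_vector
from .synthetic_city import CityConfig, ZoneTypeSpec, generate_city, write_city
from .zoning import ZONE_TYPES, FunctionZone, identify_zones, zone_summary

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("urban3d.pipeline")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Configuration of a full run; round-trips losslessly through YAML."""

    city: CityConfig = field(default_factory=CityConfig)
    radii: tuple[int, ...] = lur_mod.DEFAULT_RADII
    alpha: float = 0.10
    r_cut: float = 0.6
    enforce_signs: str = "buffered"
    split_seed: int = 0
    kernel: str = "gaussian"
    resolution: float = 500.0
    smax_global: bool = False

    _CITY_KEYS = (
        "width_m", "height_m", "n_mixed_candidates", "n_sites", "n_months",
        "noise_sd", "noise_rel", "met_scale", "background_cell_m", "seed",
    )

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["radii"] = list(self.radii)
        d["city"] = {k: getattr(self.city, k) for k in self._CITY_KEYS}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__ if not f.startswith("_")}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        city_raw = raw.pop("city", {}) or {}
        unknown_city = set(city_raw) - set(cls._CITY_KEYS)
        if unknown_city:
            raise ValueError(f"unknown city config keys: {sorted(unknown_city)}")
        if "radii" in raw:
            raw["radii"] = tuple(raw["radii"])
        return cls(city=CityConfig(**city_raw), **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _buildings_from_geojson(path: Path) -> list[Building]:
    out = []
    for geom, props in read_geojson(path):
        out.append(
            Building(
                footprint=geom,
                floors=int(props["floors"]),
                use_class=props["use_class"],
                zone_id=props.get("zone_id"),
            )
        )
    return out


def _zones_from_geojson(path: Path) -> list[FunctionZone]:
    out = []
    for geom, props in read_geojson(path):
        out.append(
            FunctionZone(
                zone_id=props["zone_id"],
                zone_type=props["zone_type"],
                polygon=geom,
                area_km2=props.get("area_km2", geom.area / 1e6),
            )
        )
    return out


def compute_indices(
    zones: list[FunctionZone], buildings: list[Building], smax_global: bool = False
) -> pd.DataFrame:
    """Index vector of every zone; buildings matched by zone_id, falling back
    to footprint-centroid containment."""
    by_zone: dict[str, list[Building]] = {}
    unmatched: list[Building] = []
    zone_ids = {z.zone_id for z in zones}
    for b in buildings:
        if b.zone_id in zone_ids:
            by_zone.setdefault(b.zone_id, []).append(b)
        else:
            unmatched.append(b)
    rows = []
    for z in zones:
        members = by_zone.get(z.zone_id, [])
        if unmatched:
            members = members + [
                b for b in unmatched if z.polygon.contains(b.footprint.centroid)
            ]
        if not members:
            continue
        area = SampleArea(buildings=members, polygon=z.polygon)
        iv = index_vector(area, smax_global=smax_global)
        rows.append({"zone_id": z.zone_id, "zone_type": z.zone_type, **iv.as_dict()})
    return pd.DataFrame(rows)


def run_gwr_by_zone_type(
    indices: pd.DataFrame,
    zone_pm25: pd.DataFrame,
    zones: list[FunctionZone],
    kernel: str = "gaussian",
    moran_seed: int = 0,
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Per zone type: predictor selection, bandwidth, GWR fit, Moran check."""
    centroids = {z.zone_id: (z.polygon.centroid.x, z.polygon.centroid.y) for z in zones}
    merged = indices.merge(zone_pm25[["zone_id", "PM25"]], on="zone_id")
    index_cols = ["H_bar", "E_vol", "L", "LHR", "S_div", "E_uni"]
    tables: dict[str, pd.DataFrame] = {}
    summary: dict = {}
    for ztype in ZONE_TYPES:
        sub = merged[merged["zone_type"] == ztype]
        if len(sub) < 5:
            continue
        predictors = gwr_mod.select_gwr_predictors(sub[index_cols], sub["PM25"])
        coords = np.array([centroids[z] for z in sub["zone_id"]])
        X = sub[predictors].to_numpy(dtype=float)
        y = sub["PM25"].to_numpy(dtype=float)
        bw = gwr_mod.select_bandwidth(coords, y, X, kernel=kernel)
        fit = gwr_mod.fit_gwr(coords, y, X, bw, kernel=kernel, variable_names=predictors)
        moran = gwr_mod.morans_i(fit.std_residuals, coords, seed=moran_seed)
        df = fit.coefficients_frame()
        df.insert(0, "zone_id", sub["zone_id"].to_numpy())
        tables[ztype] = df
        summary[ztype] = {
            "predictors": predictors,
            "bandwidth": bw,
            "r2": fit.r2,
            "adj_r2": fit.adj_r2,
            "morans_i": moran.I,
            "morans_expected": moran.expected,
            "morans_p": moran.p_value,
            "credible": bool(moran.p_value > 0.05),
        }
    return tables, summary


def run_pipeline(
    config: Optional[PipelineConfig] = None,
    out_dir: str | Path = "results",
    seed: Optional[int] = None,
    resume: bool = False,
) -> dict[str, str]:
    """Execute all stages; returns the manifest (relative path → sha256).

    With ``resume=True`` a stage is skipped when all its outputs exist and
    its inputs still match the stored manifest checksums; deleting an
    intermediate file therefore regenerates only that stage and everything
    downstream.
    """
    config = config or PipelineConfig()
    if seed is not None:
        config.city.seed = seed
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest_path = out / "manifest.json"
    old_manifest: dict[str, str] = {}
    if resume and manifest_path.exists():
        old_manifest = json.loads(manifest_path.read_text())

    def fresh(inputs: list[str], outputs: list[str]) -> bool:
        """True when the stage can be skipped under --resume."""
        if not resume:
            return False
        for o in outputs:
            if not (out / o).exists() or old_manifest.get(o) != _sha256(out / o):
                return False
        for i in inputs:
            if old_manifest.get(i) != _sha256(out / i):
                return False
        return True

    def log_stage(stage: str, skipped: bool = False) -> None:
        log.info(
            "stage=%s time=%s skipped=%s seed=%s",
            stage, time.strftime("%Y-%m-%dT%H:%M:%S"), skipped, config.city.seed,
        )

    stages: list[tuple[str, list[str], list[str]]] = [
        ("simulate", [], ["parcels.geojson", "candidates.geojson", "buildings.geojson",
                          "roads.geojson", "panel.csv", "truth.json"]),
        ("zones", ["parcels.geojson", "candidates.geojson"],
         ["zones.geojson", "zones_summary.csv"]),
        ("indices", ["zones.geojson", "buildings.geojson"], ["indices.csv"]),
        ("lur", ["panel.csv", "parcels.geojson", "roads.geojson"], ["model.json"]),
        ("surface", ["model.json", "parcels.geojson", "roads.geojson"], ["pm25.asc"]),
        ("stats", ["indices.csv", "pm25.asc", "zones.geojson"],
         ["zone_pm25.csv", "anova.csv", "lsd.csv", "correlations.csv"]),
        ("gwr", ["indices.csv", "zone_pm25.csv", "zones.geojson"], ["gwr_summary.json"]),
    ]

    index_cols = ["H_bar", "E_vol", "L", "LHR", "S_div", "E_uni"]
    produced: list[str] = []
    for stage, inputs, outputs in stages:
        if fresh(inputs, outputs):
            log_stage(stage, skipped=True)
            produced.extend(outputs)
            continue
        try:
            if stage == "simulate":
                city = generate_city(config.city)
                write_city(city, out)
            elif stage == "zones":
                parcels = read_parcels(out / "parcels.geojson")
                cands = read_geojson(out / "candidates.geojson")
                zones = identify_zones(
                    parcels,
                    [g for g, _ in cands],
                    [p["zone_id"] for _, p in cands],
                )
                write_geojson(
                    out / "zones.geojson",
                    [z.polygon for z in zones],
                    [{"zone_id": z.zone_id, "zone_type": z.zone_type,
                      "area_km2": round(z.area_km2, 6)} for z in zones],
                )
                zone_summary(zones).to_csv(
                    out / "zones_summary.csv", index=False, float_format="%.6g"
                )
            elif stage == "indices":
                zones = _zones_from_geojson(out / "zones.geojson")
                buildings = _buildings_from_geojson(out / "buildings.geojson")
                compute_indices(zones, buildings, config.smax_global).to_csv(
                    out / "indices.csv", index=False, float_format="%.10g"
                )
            elif stage == "lur":
                panel = pd.read_csv(out / "panel.csv")
                parcels = read_parcels(out / "parcels.geojson")
                roads = read_roads(out / "roads.geojson")
                model = lur_mod.build_lur(
                    panel, parcels, roads,
                    radii=config.radii, alpha=config.alpha, r_cut=config.r_cut,
                    enforce_signs=config.enforce_signs,
                    met_scale=config.city.met_scale, split_seed=config.split_seed,
                )
                model.to_json(out / "model.json")
            elif stage == "surface":
                model = lur_mod.LURModel.from_json(out / "model.json")
                parcels = read_parcels(out / "parcels.geojson")
                roads = read_roads(out / "roads.geojson")
                raster = lur_mod.predict_surface(
                    model, parcels, roads,
                    bounds=config.city.bounds, resolution=config.resolution,
                )
                write_ascii_grid(out / "pm25.asc", raster)
            elif stage == "stats":
                raster = read_ascii_grid(out / "pm25.asc")
                zones = _zones_from_geojson(out / "zones.geojson")
                indices = pd.read_csv(out / "indices.csv")
                zp = pd.DataFrame(
                    {
                        "zone_id": [z.zone_id for z in zones],
                        "zone_type": [z.zone_type for z in zones],
                        "PM25": [
                            stats_mod.zonal_mean_pm25(
                                raster, z.polygon, z.zone_id, centroid_fallback=True
                            )
                            for z in zones
                        ],
                    }
                )
                zp.to_csv(out / "zone_pm25.csv", index=False, float_format="%.10g")
                merged = indices.merge(zp[["zone_id", "PM25"]], on="zone_id")
                groups = [
                    merged.loc[merged["zone_type"] == t, "PM25"].to_numpy()
                    for t in ZONE_TYPES
                ]
                labels = list(ZONE_TYPES)
                stats_mod.one_way_anova(groups).as_frame().to_csv(
                    out / "anova.csv", index=False, float_format="%.10g"
                )
                stats_mod.lsd_posthoc(groups, labels).to_csv(
                    out / "lsd.csv", index=False, float_format="%.10g"
                )
                corr_rows = []
                for t in ZONE_TYPES:
                    sub = merged[merged["zone_type"] == t]
                    for col in index_cols:
                        try:
                            r, p = stats_mod.pearson_r(sub[col], sub["PM25"])
                        except ValueError:
                            r, p = float("nan"), float("nan")
                        corr_rows.append({"zone_type": t, "index": col, "r": r, "p": p})
                pd.DataFrame(corr_rows).to_csv(
                    out / "correlations.csv", index=False, float_format="%.10g"
                )
            elif stage == "gwr":
                zones = _zones_from_geojson(out / "zones.geojson")
                indices = pd.read_csv(out / "indices.csv")
                zp = pd.read_csv(out / "zone_pm25.csv")
                tables, summary = run_gwr_by_zone_type(
                    indices, zp, zones, kernel=config.kernel,
                    moran_seed=config.city.seed,
                )
                for ztype, df in tables.items():
                    path = out / f"gwr_{ztype}.csv"
                    df.to_csv(path, index=False, float_format="%.10g")
                    produced.append(path.name)
                (out / "gwr_summary.json").write_text(
                    json.dumps(summary, indent=2, sort_keys=True) + "\n"
                )
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        log_stage(stage)
        produced.extend(outputs)

    produced.extend(sorted(p.name for p in out.glob("gwr_*.csv")))
    manifest = {name: _sha256(out / name) for name in dict.fromkeys(produced)}
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
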