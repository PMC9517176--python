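"""Land-use regression (LUR) modelling of PM2.5.

The LUR workflow, in the Henderson et al. tradition:

1. **Buffer extraction** — around every monitoring site, circular buffers at
   seven radii (500–5000 m) are intersected with the land-use mosaic and the
   road network; each variable family (VEG, INDU, WAT, RAR, POP for area
   shares; MROAD, SROAD, TAL for road length per buffer area) is instantiated
   at every radius and named ``<FAMILY><radius>`` (e.g. ``VEG5000``).
2. **Screening** — within each family the member most correlated (Pearson)
   with PM2.5 is kept; the kept variables are then ranked by |r| and, walking
   down the ranking, any variable correlated above |r| = 0.6 with an already
   accepted one is dropped. Meteorological variables are singleton families.
3. **Stepwise removal** — a multiple linear regression is refit repeatedly,
   removing every variable whose two-sided t-test has p > 0.10 (90%
   confidence) and, for buffered variables, any coefficient whose sign
   contradicts the assumed direction, until no removal occurs.
4. **Validation** — a random 75/25 split gives a mean absolute error rate and
   RMSE; the fitted equation evaluated on a grid of cell-centre buffers gives
   the PM2.5 surface.

Meteorological covariates are standardized before entering the design:
``x' = met_scale · (x − mean) / sd`` with population statistics from the
panel, ``met_scale`` = 0.1 by default. Printed-magnitude coefficients on
this scale produce realistic monthly swings; the transform is stored on the
fitted model so predictions and simulations share it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from shapely.geometry import Point, Polygon, box
from shapely.ops import unary_union

from .io import NODATA, Parcel, Raster, Road

__all__ = [
    "DEFAULT_RADII",
    "MET_VARS",
    "MET_SCALE",
    "ASSUMED_SIGNS",
    "LURModel",
    "build_landuse_unions",
    "build_road_unions",
    "extract_buffer_variables",
    "predictor_table",
    "prepare_design",
    "screen_variables",
    "fit_lur",
    "cross_validate",
    "build_lur",
    "predict_surface",
]

DEFAULT_RADII: tuple[int, ...] = (500, 1000, 1500, 2000, 3000, 4000, 5000)

#: land-use classes aggregated by each area-share family
LANDUSE_FAMILY_CLASSES = {
    "VEG": ("ecological", "water"),  # ecological area: forest, water, etc.
    "INDU": ("industrial",),
    "WAT": ("water",),
    "RAR": ("arable",),
    "POP": ("residential",),  # residential land share as population proxy
}

ROAD_FAMILY_CLASSES = {
    "MROAD": ("main",),
    "SROAD": ("secondary",),
    "TAL": ("main", "secondary"),
}

#: unbuffered monthly meteorological covariates
MET_VARS = ("PRS", "PRS_Sea", "WIN", "TEM", "RHU", "PRE_1h")

#: default scale of the standardized meteorological covariates
MET_SCALE = 0.1

#: a-priori direction of association with PM2.5 for each variable family
ASSUMED_SIGNS = {
    "MROAD": +1,
    "SROAD": +1,
    "TAL": +1,
    "VEG": -1,
    "INDU": +1,
    "WAT": -1,
    "RAR": -1,
    "POP": +1,
    "PRS": -1,
    "PRS_Sea": -1,
    "WIN": -1,
    "TEM": -1,
    "RHU": -1,
    "PRE_1h": -1,
}

_QUAD_SEGS = 32  # circle discretization for buffers


def variable_family(name: str) -> str:
    """Family of a predictor name: ``VEG5000`` → ``VEG``; met vars are their
    own singleton family."""
    if name in MET_VARS:
        return name
    stem = name.rstrip("0123456789")
    if stem in LANDUSE_FAMILY_CLASSES or stem in ROAD_FAMILY_CLASSES:
        return stem
    raise ValueError(f"unrecognised predictor name: {name!r}")


def build_landuse_unions(parcels: Sequence[Parcel]) -> dict:
    """Dissolve the parcel mosaic into one geometry per family."""
    by_class: dict[str, list] = {}
    for p in parcels:
        by_class.setdefault(p.land_use, []).append(p.geometry)
    unions = {}
    for family, classes in LANDUSE_FAMILY_CLASSES.items():
        geoms = [g for cls in classes for g in by_class.get(cls, [])]
        unions[family] = unary_union(geoms) if geoms else None
    return unions


def build_road_unions(roads: Sequence[Road]) -> dict:
    by_class: dict[str, list] = {}
    for r in roads:
        by_class.setdefault(r.road_class, []).append(r.geometry)
    unions = {}
    for family, classes in ROAD_FAMILY_CLASSES.items():
        geoms = [g for cls in classes for g in by_class.get(cls, [])]
        unions[family] = unary_union(geoms) if geoms else None
    return unions


def extract_buffer_variables(
    site: Point,
    landuse_unions: dict,
    road_unions: dict,
    radii: Sequence[int] = DEFAULT_RADII,
) -> dict[str, float]:
    """Buffer predictors at one site: area shares and road densities.

    Shares are intersection area / buffer area; road densities are
    intersected length / buffer area (m per m²). Empty intersections give 0.
    The values depend only on the dissolved class geometry, so the parcel
    tessellation is irrelevant.
    """
    out: dict[str, float] = {}
    for r in radii:
        buf = site.buffer(r, quad_segs=_QUAD_SEGS)
        barea = buf.area
        for family, geom in landuse_unions.items():
            val = 0.0 if geom is None else geom.intersection(buf).area / barea
            out[f"{family}{r}"] = val
        for family, geom in road_unions.items():
            val = 0.0 if geom is None else geom.intersection(buf).length / barea
            out[f"{family}{r}"] = val
    return out


def predictor_table(
    sites: pd.DataFrame,
    parcels: Sequence[Parcel],
    roads: Sequence[Road],
    radii: Sequence[int] = DEFAULT_RADII,
) -> pd.DataFrame:
    """Buffer predictors for every site; index = site_id.

    ``sites`` needs columns site_id, x, y.
    """
    lu = build_landuse_unions(parcels)
    rd = build_road_unions(roads)
    rows = {}
    for _, row in sites.iterrows():
        rows[row["site_id"]] = extract_buffer_variables(Point(row["x"], row["y"]), lu, rd, radii)
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("site_id")


def met_statistics(panel: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """Population mean and SD of each meteorological column in the panel."""
    stats = {}
    for var in MET_VARS:
        if var in panel.columns:
            col = panel[var].to_numpy(dtype=float)
            stats[var] = (float(col.mean()), float(col.std()))
    return stats


def transform_met(
    values: pd.DataFrame | dict,
    met_stats: dict[str, tuple[float, float]],
    met_scale: float = MET_SCALE,
):
    """Apply the shared standardization ``met_scale · (x − mean)/sd``."""
    if isinstance(values, dict):
        return {
            var: met_scale * (v - met_stats[var][0]) / met_stats[var][1]
            for var, v in values.items()
            if var in met_stats
        }
    out = values.copy()
    for var, (mu, sd) in met_stats.items():
        if var in out.columns and sd > 0:
            out[var] = met_scale * (out[var] - mu) / sd
    return out


def prepare_design(
    panel: pd.DataFrame,
    predictors: pd.DataFrame,
    met_scale: float = MET_SCALE,
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Assemble the regression design from the panel and site predictors.

    Returns (X, y, met_stats): X holds the buffered variables (joined by
    site_id) plus standardized meteorology; y is PM25.
    """
    if "PM25" not in panel.columns:
        raise ValueError("panel has no PM25 column")
    met_stats = met_statistics(panel)
    X = predictors.loc[panel["site_id"]].reset_index(drop=True)
    met = transform_met(panel[list(met_stats)], met_stats, met_scale).reset_index(drop=True)
    X = pd.concat([X, met], axis=1)
    y = panel["PM25"].reset_index(drop=True)
    return X, y, met_stats


def screen_variables(
    y: pd.Series | np.ndarray,
    X: pd.DataFrame,
    r_cut: float = 0.6,
) -> list[str]:
    """Two-stage correlation screening.

    Stage 1 keeps, per variable family, the member with largest |Pearson r|
    against the response. Stage 2 ranks the keepers by |r| and greedily drops
    any variable whose |pairwise r| with an already accepted variable exceeds
    ``r_cut``. Constant columns are excluded with a warning.
    """
    y = np.asarray(y, dtype=float)
    usable = []
    for col in X.columns:
        if np.std(X[col].to_numpy(dtype=float)) <= 0:
            warnings.warn(f"predictor {col!r} is constant; excluded from screening")
            continue
        usable.append(col)
    r = {
        col: float(np.corrcoef(X[col].to_numpy(dtype=float), y)[0, 1])
        for col in usable
    }
    # stage 1: family winners
    winners: dict[str, str] = {}
    for col in usable:
        fam = variable_family(col)
        if fam not in winners or abs(r[col]) > abs(r[winners[fam]]):
            winners[fam] = col
    ranked = sorted(winners.values(), key=lambda c: abs(r[c]), reverse=True)
    # stage 2: cross-family collinearity pruning
    accepted: list[str] = []
    for col in ranked:
        xc = X[col].to_numpy(dtype=float)
        collinear = any(
            abs(np.corrcoef(xc, X[a].to_numpy(dtype=float))[0, 1]) > r_cut for a in accepted
        )
        if not collinear:
            accepted.append(col)
    return accepted


@dataclass
class LURModel:
    """A fitted land-use regression model."""

    intercept: float
    coefficients: dict[str, float]
    r2: float
    adj_r2: float
    pvalues: dict[str, float] = field(default_factory=dict)
    cv_mae_rate: Optional[float] = None
    cv_rmse: Optional[float] = None
    met_stats: dict[str, tuple[float, float]] = field(default_factory=dict)
    met_scale: float = MET_SCALE
    n_obs: int = 0
    settings: dict = field(default_factory=dict)

    @property
    def variables(self) -> list[str]:
        return list(self.coefficients)

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        """Evaluate on a design already on the model's (transformed) scale."""
        yhat = np.full(len(X), self.intercept, dtype=float)
        for var, beta in self.coefficients.items():
            yhat += beta * X[var].to_numpy(dtype=float)
        return yhat

    def to_json(self, path: str | Path) -> None:
        payload = {
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "pvalues": self.pvalues,
            "cv_mae_rate": self.cv_mae_rate,
            "cv_rmse": self.cv_rmse,
            "met_stats": {k: list(v) for k, v in self.met_stats.items()},
            "met_scale": self.met_scale,
            "n_obs": self.n_obs,
            "settings": self.settings,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "LURModel":
        d = json.loads(Path(path).read_text())
        d["met_stats"] = {k: tuple(v) for k, v in d.get("met_stats", {}).items()}
        return cls(**d)


def _sign_enforced_vars(variables: Sequence[str], mode: str) -> set[str]:
    if mode == "off":
        return set()
    if mode == "all":
        return set(variables)
    if mode == "buffered":
        return {v for v in variables if v not in MET_VARS}
    raise ValueError(f"enforce_signs must be off|buffered|all, got {mode!r}")


def fit_lur(
    y: pd.Series | np.ndarray,
    X: pd.DataFrame,
    variables: Sequence[str],
    alpha: float = 0.10,
    enforce_signs: str = "buffered",
) -> LURModel:
    """Iterative stepwise removal until every retained variable is significant.

    Each pass fits OLS on the current variable set and removes all variables
    with two-sided p > ``alpha`` plus (for sign-enforced variables) any whose
    coefficient contradicts the assumed direction; stops when a pass removes
    nothing. If everything is removed the result is an intercept-only model.
    """
    y = np.asarray(y, dtype=float)
    current = list(variables)
    enforced = _sign_enforced_vars(variables, enforce_signs)
    res = None
    for _ in range(len(current) + 1):
        if not current:
            break
        design = sm.add_constant(X[current].to_numpy(dtype=float))
        res = sm.OLS(y, design).fit()
        pvals = dict(zip(current, res.pvalues[1:]))
        coefs = dict(zip(current, res.params[1:]))
        # NaN p (exact fit, zero residual variance) counts as not significant
        removals = {v for v, p in pvals.items() if p > alpha or np.isnan(p)}
        if res.ssr <= 1e-16 * len(y) * np.var(y):
            # numerically perfect fit: t-statistics are noise ratios; drop
            # variables whose standardized contribution is negligible
            sy = np.std(y)
            removals |= {
                v for v in current
                if abs(coefs[v]) * np.std(X[v].to_numpy(dtype=float)) < 1e-8 * sy
            }
        removals |= {
            v
            for v in current
            if v in enforced and np.sign(coefs[v]) != ASSUMED_SIGNS[variable_family(v)]
        }
        if not removals:
            break
        current = [v for v in current if v not in removals]
    if not current:
        mean = float(np.mean(y))
        return LURModel(
            intercept=mean,
            coefficients={},
            r2=0.0,
            adj_r2=0.0,
            n_obs=len(y),
            settings={"alpha": alpha, "enforce_signs": enforce_signs, "empty_model": True},
        )
    return LURModel(
        intercept=float(res.params[0]),
        coefficients={v: float(c) for v, c in zip(current, res.params[1:])},
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        pvalues={v: float(p) for v, p in zip(current, res.pvalues[1:])},
        n_obs=len(y),
        settings={"alpha": alpha, "enforce_signs": enforce_signs},
    )


def cross_validate(
    y: pd.Series | np.ndarray,
    X: pd.DataFrame,
    variables: Sequence[str],
    split_seed: int = 0,
    train_fraction: float = 0.75,
) -> tuple[float, float]:
    """Hold-out validation: fit on a random 75%, score the remaining 25%.

    Returns (mean absolute error rate, RMSE). Holdout records with y = 0 are
    skipped in the error-rate mean with a warning.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 8:
        raise ValueError("need at least 8 records for a 75/25 split")
    rng = np.random.default_rng(split_seed)
    order = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    train, test = order[:n_train], order[n_train:]
    cols = list(variables)
    design = sm.add_constant(X[cols].to_numpy(dtype=float)[train]) if cols else np.ones((len(train), 1))
    res = sm.OLS(y[train], design).fit()
    test_design = (
        sm.add_constant(X[cols].to_numpy(dtype=float)[test], has_constant="add")
        if cols
        else np.ones((len(test), 1))
    )
    yhat = test_design @ res.params
    err = yhat - y[test]
    rmse = float(np.sqrt(np.mean(err**2)))
    nonzero = y[test] != 0
    if not np.all(nonzero):
        warnings.warn("holdout contains zero PM2.5 values; skipped in MAE rate")
    mae_rate = float(np.mean(np.abs(err[nonzero]) / y[test][nonzero]))
    return mae_rate, rmse


def build_lur(
    panel: pd.DataFrame,
    parcels: Sequence[Parcel],
    roads: Sequence[Road],
    sites: Optional[pd.DataFrame] = None,
    radii: Sequence[int] = DEFAULT_RADII,
    alpha: float = 0.10,
    r_cut: float = 0.6,
    enforce_signs: str = "buffered",
    met_scale: float = MET_SCALE,
    split_seed: int = 0,
) -> LURModel:
    """The full LUR chain: extract → screen → stepwise fit → cross-validate.

    ``panel`` needs site_id, month, x, y, PM25 and the meteorological
    columns; site coordinates are taken from ``sites`` (site_id, x, y) or
    deduplicated from the panel.
    """
    if sites is None:
        sites = panel[["site_id", "x", "y"]].drop_duplicates("site_id")
    predictors = predictor_table(sites, parcels, roads, radii)
    X, y, met_stats = prepare_design(panel, predictors, met_scale)
    retained = screen_variables(y, X, r_cut=r_cut)
    model = fit_lur(y, X, retained, alpha=alpha, enforce_signs=enforce_signs)
    model.met_stats = met_stats
    model.met_scale = met_scale
    model.settings.update({"radii": list(radii), "r_cut": r_cut, "split_seed": split_seed})
    mae_rate, rmse = cross_validate(y, X, model.variables, split_seed=split_seed)
    model.cv_mae_rate, model.cv_rmse = mae_rate, rmse
    return model


def predict_surface(
    model: LURModel,
    parcels: Sequence[Parcel],
    roads: Sequence[Road],
    bounds: tuple[float, float, float, float],
    resolution: float = 100.0,
    met_values: Optional[dict[str, float]] = None,
    region: Optional[Polygon] = None,
) -> Raster:
    """Evaluate the fitted equation on a grid of cell-centre buffers.

    Buffered predictors are extracted at each cell centre; meteorological
    terms use ``met_values`` (raw units, transformed with the model's stored
    statistics) or contribute zero (the panel mean) when omitted. Cells whose
    centre falls outside ``region`` (default: the bounding rectangle) are
    no-data.
    """
    xmin, ymin, xmax, ymax = bounds
    if region is None:
        region = box(xmin, ymin, xmax, ymax)
    ncols = max(int(np.ceil((xmax - xmin) / resolution)), 1)
    nrows = max(int(np.ceil((ymax - ymin) / resolution)), 1)

    buffered_vars = [v for v in model.variables if v not in MET_VARS]
    met_vars = [v for v in model.variables if v in MET_VARS]
    met_term = 0.0
    if met_vars:
        transformed = (
            transform_met(met_values, model.met_stats, model.met_scale) if met_values else {}
        )
        met_term = sum(model.coefficients[v] * transformed.get(v, 0.0) for v in met_vars)

    lu = build_landuse_unions(parcels)
    rd = build_road_unions(roads)
    values = np.full((nrows, ncols), NODATA, dtype=float)
    for i in range(nrows):
        cy = ymin + (nrows - i - 0.5) * resolution
        for j in range(ncols):
            cx = xmin + (j + 0.5) * resolution
            centre = Point(cx, cy)
            if not region.contains(centre):
                continue
            val = model.intercept + met_term
            for var in buffered_vars:
                fam = variable_family(var)
                radius = float(var[len(fam):])
                buf = centre.buffer(radius, quad_segs=_QUAD_SEGS)
                geom = lu.get(fam) if fam in LANDUSE_FAMILY_CLASSES else rd.get(fam)
                if geom is None:
                    x = 0.0
                elif fam in LANDUSE_FAMILY_CLASSES:
                    x = geom.intersection(buf).area / buf.area
                else:
                    x = geom.intersection(buf).length / buf.area
                val += model.coefficients[var] * x
            values[i, j] = val
    return Raster(values=values, x0=xmin, y0=ymin, cellsize=resolution)
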