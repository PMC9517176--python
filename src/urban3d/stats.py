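"""Zonal statistics and classical inference for the zone-level analysis.

Covers zonal mean PM2.5 from the predicted surface, one-way ANOVA across
the four zone types, Fisher's LSD pairwise comparisons (no multiplicity
adjustment, per the LSD procedure), and Pearson correlations between
landscape indices and zonal PM2.5.

With a one-way layout the Type III decomposition coincides with the
standard between/within split, also for unbalanced group sizes, so the
plain decomposition is computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from shapely import contains_xy
from shapely.geometry import Polygon

from .io import Raster

__all__ = [
    "AnovaTable",
    "zonal_mean_pm25",
    "one_way_anova",
    "lsd_posthoc",
    "pearson_r",
]


@dataclass(frozen=True)
class AnovaTable:
    """One-way ANOVA decomposition."""

    ss_between: float
    ss_within: float
    ss_total: float
    df_between: int
    df_within: int
    ms_between: float
    ms_within: float
    F: float
    p: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": ["between", "within", "total"],
                "sum_of_squares": [self.ss_between, self.ss_within, self.ss_total],
                "df": [self.df_between, self.df_within, self.df_between + self.df_within],
                "mean_square": [self.ms_between, self.ms_within, np.nan],
                "F": [self.F, np.nan, np.nan],
                "p": [self.p, np.nan, np.nan],
            }
        )


def zonal_mean_pm25(
    raster: Raster, zone: Polygon, zone_id: str = "?", centroid_fallback: bool = False
) -> float:
    """Mean of raster cells whose centres fall inside the zone polygon.

    A zone smaller than one cell may contain no centre; by default that is
    an error naming the zone, with ``centroid_fallback=True`` the value of
    the cell containing the zone centroid is returned instead.
    """
    xs, ys = raster.cell_centers()
    inside = contains_xy(zone, xs.ravel(), ys.ravel()).reshape(xs.shape)
    valid = inside & raster.mask()
    if not np.any(valid):
        if centroid_fallback:
            c = zone.centroid
            j = int(np.clip((c.x - raster.x0) / raster.cellsize, 0, raster.ncols - 1))
            i = int(np.clip(raster.nrows - 1 - (c.y - raster.y0) / raster.cellsize,
                            0, raster.nrows - 1))
            if raster.values[i, j] != raster.nodata:
                return float(raster.values[i, j])
        raise ValueError(f"zone {zone_id}: no raster cell centres inside polygon")
    return float(raster.values[valid].mean())


def _check_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrays):
        if len(g) < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
    return arrays


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaTable:
    """Standard one-way decomposition; F = MS_between / MS_within."""
    arrays = _check_groups(groups)
    allv = np.concatenate(arrays)
    grand = allv.mean()
    ss_between = float(sum(len(g) * (g.mean() - grand) ** 2 for g in arrays))
    ss_within = float(sum(np.sum((g - g.mean()) ** 2) for g in arrays))
    df_between = len(arrays) - 1
    df_within = len(allv) - len(arrays)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0:
        f_stat = 0.0 if ss_between == 0 else float("inf")
    else:
        f_stat = ms_between / ms_within
    p = float(sps.f.sf(f_stat, df_between, df_within)) if np.isfinite(f_stat) else 0.0
    return AnovaTable(
        ss_between=ss_between,
        ss_within=ss_within,
        ss_total=ss_between + ss_within,
        df_between=df_between,
        df_within=df_within,
        ms_between=ms_between,
        ms_within=ms_within,
        F=f_stat,
        p=p,
    )


def lsd_posthoc(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Fisher's LSD pairwise comparisons after one-way ANOVA.

    For each ordered pair (I, J): mean difference, pooled standard error
    sqrt(MS_within (1/n_I + 1/n_J)), and two-sided p from t with the
    within-group degrees of freedom. Mean differences are antisymmetric.
    """
    arrays = _check_groups(groups)
    if labels is None:
        labels = [f"group_{i}" for i in range(len(arrays))]
    table = one_way_anova(groups)
    rows = []
    for i, j in combinations(range(len(arrays)), 2):
        diff = float(arrays[i].mean() - arrays[j].mean())
        se = float(np.sqrt(table.ms_within * (1 / len(arrays[i]) + 1 / len(arrays[j]))))
        if se == 0:
            p = 1.0 if diff == 0 else 0.0
        else:
            t = diff / se
            p = float(2 * sps.t.sf(abs(t), table.df_within))
        for a, b, dd in ((i, j, diff), (j, i, -diff)):
            rows.append(
                {
                    "group_i": labels[a],
                    "group_j": labels[b],
                    "mean_difference": dd,
                    "std_error": se,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("pearson_r needs two equal-length samples of n >= 3")
    if np.std(x) <= 0 or np.std(y) <= 0:
        raise ValueError("pearson_r undefined for constant input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
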