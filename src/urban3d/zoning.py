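"""Identification of urban land-function zones from parcel composition.

A land-function zone is a limited area whose function is dominated by one
land-use type. Candidate polygons are classified from the area shares of the
land-use classes inside them: residential, commercial and educational zones
require their class to exceed 50% of the candidate area; industrial zones
require more than 40% industrial land. Candidates meeting no rule (mixed
areas) are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd
from shapely.geometry import Polygon

__all__ = [
    "ZONE_TYPES",
    "DOMINANCE_THRESHOLDS",
    "ZoneComposition",
    "FunctionZone",
    "classify_zone",
    "identify_zones",
    "zone_summary",
]

ZONE_TYPES = ("industrial", "educational", "residential", "commercial")

#: strict lower bounds on the dominant-class area share
DOMINANCE_THRESHOLDS = {
    "residential": 0.50,
    "commercial": 0.50,
    "educational": 0.50,
    "industrial": 0.40,
}

_SHARE_SUM_TOL = 1e-9


@dataclass
class ZoneComposition:
    """Land-use area shares of one candidate polygon."""

    shares: Mapping[str, float]
    polygon: Optional[Polygon] = None

    def __post_init__(self) -> None:
        for cls, share in self.shares.items():
            if share < 0:
                raise ValueError(f"negative share for class {cls!r}: {share}")
        if sum(self.shares.values()) > 1.0 + _SHARE_SUM_TOL:
            raise ValueError("shares sum to more than 1")


@dataclass
class FunctionZone:
    """A classified land-function zone."""

    zone_id: str
    zone_type: str
    polygon: Polygon
    area_km2: float
    buildings: list = field(default_factory=list)
    mean_pm25: Optional[float] = None


def classify_zone(comp: ZoneComposition | Mapping[str, float]) -> Optional[str]:
    """Classify a candidate by its dominance rule; ``None`` if no rule holds.

    Residential/commercial/educational need a strict majority (>50%);
    industrial needs >40%. When several rules fire the largest share wins;
    an exact tie yields ``None`` (conservative: the function is not distinct).
    """
    if not isinstance(comp, ZoneComposition):
        comp = ZoneComposition(shares=comp)
    winners = [
        (comp.shares.get(ztype, 0.0), ztype)
        for ztype, thr in DOMINANCE_THRESHOLDS.items()
        if comp.shares.get(ztype, 0.0) > thr
    ]
    if not winners:
        return None
    winners.sort(reverse=True)
    if len(winners) > 1 and winners[0][0] == winners[1][0]:
        return None
    return winners[0][1]


def _composition(candidate: Polygon, parcels: Sequence) -> dict[str, float]:
    """Area share of each land-use class inside a candidate polygon."""
    shares: dict[str, float] = {}
    area = candidate.area
    if area <= 0:
        raise ValueError("candidate polygon has zero area")
    for p in parcels:
        geom = p.geometry
        if not geom.intersects(candidate):
            continue
        inter = geom.intersection(candidate).area
        if inter > 0:
            shares[p.land_use] = shares.get(p.land_use, 0.0) + inter / area
    return shares


def identify_zones(
    parcels: Sequence,
    candidates: Sequence[Polygon],
    candidate_ids: Optional[Sequence[str]] = None,
) -> list[FunctionZone]:
    """Classify candidate polygons against the parcel mosaic.

    ``parcels`` is any sequence of objects with ``geometry`` (shapely) and
    ``land_use`` (str) attributes. Candidates whose composition satisfies no
    dominance rule are dropped. Invalid candidate geometry raises with the
    candidate id.
    """
    if candidate_ids is None:
        candidate_ids = [f"zone_{i:03d}" for i in range(len(candidates))]
    zones: list[FunctionZone] = []
    for cid, cand in zip(candidate_ids, candidates):
        if cand.is_empty or not cand.is_valid:
            raise ValueError(f"invalid candidate geometry: {cid}")
        comp = ZoneComposition(shares=_composition(cand, parcels), polygon=cand)
        ztype = classify_zone(comp)
        if ztype is None:
            continue
        zones.append(
            FunctionZone(
                zone_id=cid,
                zone_type=ztype,
                polygon=cand,
                area_km2=cand.area / 1e6,
            )
        )
    return zones


def zone_summary(zones: Sequence[FunctionZone]) -> pd.DataFrame:
    """Per-type count and min/max/mean area (km²), one row per zone type."""
    rows = []
    for ztype in ZONE_TYPES:
        areas = [z.area_km2 for z in zones if z.zone_type == ztype]
        if not areas:
            continue
        rows.append(
            {
                "zone_type": ztype,
                "number": len(areas),
                "max_km2": max(areas),
                "min_km2": min(areas),
                "mean_km2": sum(areas) / len(areas),
            }
        )
    return pd.DataFrame(rows, columns=["zone_type", "number", "max_km2", "min_km2", "mean_km2"])
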