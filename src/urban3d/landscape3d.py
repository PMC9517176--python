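"""Three-dimensional landscape pattern metrics for built form.

A sample area (in practice a land-function zone) is reduced to the set of
buildings it contains, each building to a (footprint area, height) pair.
Heights are estimated from floor counts using standard storey heights
(2.8 m for ordinary buildings, 5.0 m for industrial plants) and binned into
eight height categories, from bungalows to super high-rise.

Six indices summarise the vertical landscape of a sample area:

========================  =======================================================
height density   ``H̄``    arithmetic mean building height (m)
volume density   ``E_v``  filled-volume fraction  Σ V_i / (H_max · S)
spatial dispersion ``L``  coefficient of variation of heights (population SD / H̄)
fluctuation      ``LHR``  height range  H_max − H_min  (m)
building diversity ``S``  Shannon entropy of footprint-area shares across the
                          height categories (nats)
building uniformity ``E`` that entropy as a percentage of its maximum ln(m)
========================  =======================================================

Volumes are footprint area × height, i.e. the top contour of every building
is taken to coincide with its footprint (rectangular-prism buildings).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from shapely.geometry import Polygon

__all__ = [
    "FLOOR_HEIGHT_STANDARD",
    "FLOOR_HEIGHT_PLANT",
    "HEIGHT_CATEGORIES",
    "N_HEIGHT_CATEGORIES",
    "Building",
    "SampleArea",
    "IndexVector",
    "estimate_height",
    "classify_height",
    "height_density",
    "volume_density",
    "spatial_dispersion",
    "fluctuation",
    "building_diversity",
    "building_uniformity",
    "index_vector",
]

#: storey height of an ordinary (house-type) building, metres
FLOOR_HEIGHT_STANDARD = 2.8
#: storey height of an industrial plant building, metres
FLOOR_HEIGHT_PLANT = 5.0

#: the eight height categories as (name, lower bound m, upper bound m).
#: The printed bounds enumerate attained heights (multiples of the storey
#: heights), so consecutive intervals leave gaps (e.g. 15.0–19.6 m); heights
#: falling in a gap are assigned to the category with the nearest interval
#: endpoint (ties go to the lower category).
HEIGHT_CATEGORIES: tuple[tuple[str, float, float], ...] = (
    ("bungalow", 2.8, 5.0),
    ("low_rise", 5.6, 10.0),
    ("multistory", 11.2, 15.0),
    ("high_rise", 19.6, 28.0),
    ("high_rise_1", 30.8, 50.4),
    ("high_rise_2", 53.2, 70.0),
    ("high_rise_3", 73.2, 98.0),
    ("super_high_rise", 100.0, math.inf),
)

N_HEIGHT_CATEGORIES = len(HEIGHT_CATEGORIES)


def estimate_height(floors: int, use_class: str) -> float:
    """Estimate a building's height (m) from its floor count.

    Industrial (plant) buildings use 5.0 m per floor, everything else 2.8 m.
    """
    if floors < 1:
        raise ValueError(f"floors must be >= 1, got {floors}")
    per_floor = FLOOR_HEIGHT_PLANT if use_class == "industrial" else FLOOR_HEIGHT_STANDARD
    return floors * per_floor


def classify_height(height: float) -> str:
    """Assign a height (m) to one of the eight height categories.

    Heights inside a printed interval (bounds inclusive) take that category;
    heights above 100 m are super high-rise; heights in an inter-interval gap
    take the category with the nearest interval endpoint, ties resolved to
    the lower category.
    """
    if not height > 0:
        raise ValueError(f"height must be positive, got {height}")
    for name, lo, hi in HEIGHT_CATEGORIES:
        if lo <= height <= hi:
            return name
    # gap (or below the first interval): nearest endpoint, ties -> lower
    best_name, best_dist = HEIGHT_CATEGORIES[0][0], math.inf
    for name, lo, hi in HEIGHT_CATEGORIES:
        for endpoint in (lo, hi):
            if not math.isfinite(endpoint):
                continue
            d = abs(height - endpoint)
            if d < best_dist - 1e-12:
                best_name, best_dist = name, d
    return best_name


@dataclass
class Building:
    """A building: footprint polygon (or plain area), floor count, use class.

    Height, volume and height category are derived on construction and kept
    consistent with the classification rule.
    """

    footprint: Polygon | float
    floors: int
    use_class: str = "residential"
    zone_id: Optional[str] = None
    height: float = field(init=False)
    volume: float = field(init=False)
    category: str = field(init=False)

    def __post_init__(self) -> None:
        self.height = estimate_height(self.floors, self.use_class)
        self.volume = self.footprint_area * self.height
        self.category = classify_height(self.height)

    @property
    def footprint_area(self) -> float:
        if isinstance(self.footprint, (int, float)):
            return float(self.footprint)
        return self.footprint.area


@dataclass
class SampleArea:
    """A polygonal sample area with its member buildings."""

    buildings: Sequence[Building]
    polygon: Optional[Polygon] = None
    area: Optional[float] = None  # m²; derived from polygon if absent

    def __post_init__(self) -> None:
        if self.area is None:
            if self.polygon is None:
                raise ValueError("SampleArea needs a polygon or an explicit area")
            self.area = self.polygon.area
        if not self.area > 0:
            raise ValueError("sample area must be positive")

    @property
    def n(self) -> int:
        return len(self.buildings)

    def heights(self) -> np.ndarray:
        return np.array([b.height for b in self.buildings], dtype=float)

    def _require_members(self) -> None:
        if self.n < 1:
            raise ValueError("sample area contains no buildings")


@dataclass(frozen=True)
class IndexVector:
    """The six 3D landscape indices of one sample area."""

    height_density: float  # H̄, m
    volume_density: float  # E_vol, fraction
    spatial_dispersion: float  # L, dimensionless CV
    fluctuation: float  # LHR, m
    building_diversity: float  # S_div, nats
    building_uniformity: float  # E_uni, percent

    def as_dict(self) -> dict[str, float]:
        return {
            "H_bar": self.height_density,
            "E_vol": self.volume_density,
            "L": self.spatial_dispersion,
            "LHR": self.fluctuation,
            "S_div": self.building_diversity,
            "E_uni": self.building_uniformity,
        }


def height_density(area: SampleArea) -> float:
    """Mean building height H̄ (m)."""
    area._require_members()
    return float(np.mean(area.heights()))


def volume_density(area: SampleArea) -> float:
    """Filled-volume fraction Σ V_i / (H_max · S)."""
    area._require_members()
    hmax = float(np.max(area.heights()))
    total_volume = float(sum(b.volume for b in area.buildings))
    return total_volume / (hmax * area.area)


def spatial_dispersion(area: SampleArea) -> float:
    """Coefficient of variation of heights (population SD / mean)."""
    area._require_members()
    h = area.heights()
    return float(np.std(h) / np.mean(h))


def fluctuation(area: SampleArea) -> float:
    """Height range H_max − H_min (m)."""
    area._require_members()
    h = area.heights()
    return float(np.max(h) - np.min(h))


def _category_shares(buildings: Iterable[Building]) -> np.ndarray:
    """Footprint-area share of each height category present (nonzero only)."""
    shares: dict[str, float] = {}
    total = 0.0
    for b in buildings:
        a = b.footprint_area
        shares[b.category] = shares.get(b.category, 0.0) + a
        total += a
    if total <= 0:
        raise ValueError("total footprint area is zero")
    return np.array([v / total for v in shares.values() if v > 0], dtype=float)


def building_diversity(area: SampleArea) -> float:
    """Shannon entropy −Σ P_i ln P_i of footprint-area shares across height
    categories (nats); categories with zero share contribute nothing."""
    area._require_members()
    p = _category_shares(area.buildings)
    return float(-np.sum(p * np.log(p)))


def building_uniformity(area: SampleArea, smax_global: bool = False) -> float:
    """Diversity as a percentage of its maximum, (S_div / ln m) × 100.

    ``m`` is the number of height categories present in the sample; with
    ``smax_global=True`` the fixed scheme size ln(8) is used instead. A
    single-category sample has uniformity 0 by convention.
    """
    area._require_members()
    p = _category_shares(area.buildings)
    m = N_HEIGHT_CATEGORIES if smax_global else len(p)
    if m < 2:
        return 0.0
    s = float(-np.sum(p * np.log(p)))
    return s / math.log(m) * 100.0


def index_vector(area: SampleArea, smax_global: bool = False) -> IndexVector:
    """All six indices of one sample area."""
    if area.n < 1:
        raise ValueError("cannot compute indices for a building-free sample area")
    return IndexVector(
        height_density=height_density(area),
        volume_density=volume_density(area),
        spatial_dispersion=spatial_dispersion(area),
        fluctuation=fluctuation(area),
        building_diversity=building_diversity(area),
        building_uniformity=building_uniformity(area, smax_global=smax_global),
    )
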