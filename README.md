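# urban3d

Three-dimensional building-morphology metrics of urban land-function zones,
land-use-regression (LUR) PM2.5 surfaces, and geographically weighted
regression (GWR) of zone morphology against PM2.5 — packaged as a fully
reproducible pipeline driven by a synthetic-city generator, so every stage
runs end-to-end with no external data.

## Who this is for

Researchers in urban air-quality epidemiology and landscape ecology who want
to study how the *vertical* form of a city — building heights, volumes, and
their diversity within functional districts — relates to fine-particulate
(PM2.5) exposure, and who need a tested, seedable implementation of the full
chain: function-zone identification → 3D landscape indices → LUR exposure
surface → zonal statistics → local (GWR) regression.

## The models

**Function zones.** A land-function zone is a limited area dominated by one
land-use type: residential, commercial and educational zones require their
class to exceed 50% of the area, industrial zones more than 40%.

**Six 3D landscape indices** per zone (buildings reduced to footprint area
and height; height = floors × 2.8 m, or × 5.0 m for industrial plants;
heights binned into 8 categories from bungalow to super high-rise):

| index | formula |
|---|---|
| height density | H̄ = Σ Hᵢ / n |
| volume density | E = Σ Vᵢ / (H_max · S) |
| spatial dispersion | L = √(Σ(Hᵢ − H̄)²/n) / H̄ |
| fluctuation | LHR = H_max − H_min |
| building diversity | S = −Σ Pᵢ ln Pᵢ (footprint-area shares over height categories) |
| building uniformity | E = S / ln m × 100% |

**LUR.** PM2.5 at 16 monitoring sites × 12 months is regressed on buffer
covariates (land-use shares and road densities at 500–5000 m) and monthly
meteorology: per-family correlation screening, cross-family pruning at
|r| > 0.6, then iterative removal of variables insignificant at the 90%
level. The fitted equation evaluated on a grid of cell-centre buffers gives
the PM2.5 surface.

**GWR.** Zonal mean PM2.5 is regressed on the two least-collinear, most
correlated indices per zone type with local weighted least squares,
y_i = β₀(uᵢ,vᵢ) + Σ_k β_k(uᵢ,vᵢ)x_ik + εᵢ, Gaussian kernel, AICc-selected
bandwidth; spatial randomness of the standardized residuals is checked with
Moran's I (expected value −1/(n−1), permutation p).

## Worked example

```bash
urban3d run-all --seed 1 --out results/
```

runs simulate → zones → indices → LUR → surface → zonal stats → GWR and
writes a checksum manifest. Selected output from a run at seed 1:

`results/zones_summary.csv` — the synthetic city carries 61 function zones
with the study's per-type counts and area statistics:

```
zone_type,number,max_km2,min_km2,mean_km2
industrial,16,2.31773,0.406489,0.783256
educational,14,2.24303,0.457518,1.03066
residential,18,1.06097,0.505916,0.69872
commercial,13,0.46383,0.321717,0.377066
```

`results/model.json` — the LUR chain recovers the generating equation
(intercept 41.308, VEG5000 −5.921, PRE_1h +40.316, PRS_Sea −26.102,
INDU500 +4.088) from the noisy panel:

```
intercept 41.296, coefficients {INDU500: 4.106, PRE_1h: 40.309,
PRS_Sea: -26.095, VEG5000: -5.906}
```

meaning: each unit of ecological share within 5 km lowers predicted PM2.5 by
~5.9 µg/m³, industrial share within 500 m raises it by ~4.1 µg/m³, and the
standardized precipitation / sea-level-pressure terms carry the seasonal
variation. `results/pm25.asc` is the predicted surface (µg/m³, ASCII grid),
and `results/gwr_summary.json` reports per-zone-type GWR fit, bandwidth and
the Moran's I residual check.

As a library:

```python
from urban3d import CityConfig, generate_city, build_lur

city = generate_city(CityConfig(seed=1))
model = build_lur(city.panel, city.parcels, city.roads)
print(model.intercept, model.coefficients)
```

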