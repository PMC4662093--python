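# geocov

Computation of GIS-derived covariates at point sites for air-pollution
exposure prediction (land-use-regression style): eight categories of
geographic variables — traffic, demographic characteristics, land use,
transportation facilities, physical geography, emissions, vegetation and
altitude — evaluated at monitoring-site locations via nearest-feature
distances, circular-buffer statistics with areal weighting, and raster
extraction.

All geometry is planar Euclidean in a single projected, meter-based
coordinate system; geographic (degree) inputs are rejected at load time
with instructions to reproject. Vector layers travel as GeoJSON, rasters
as ESRI ASCII grids, tables as CSV.

## What it computes

| Category | Variables |
| --- | --- |
| traffic | distance to nearest road per class (ALL / MR1 / MR2); clipped road-length sums per class × buffer radius × weighting (length, length×lanes, length×lanes×width); registered vehicles of the containing district |
| demographic | areal-weighted census counts (uniform within-polygon density) per attribute × radius |
| land use | per-class area proportion of the buffer (12 classes) |
| transport | distance to nearest rail station, subway station, bus stop, airport, major port (> 10 000 vessels/year) |
| physical | distance to nearest river, coastline, and the derived northern border line |
| emissions | areal-weighted totals of 7 pollutants from a 1-km emission grid, 3/15/30 km buffers |
| vegetation | annual mean/min/max of a 36-composite index stack; pooled August median over 3 years |
| altitude | site elevation; % of DEM cells on a 30 m-wide ring (1 or 5 km) more than 20/50 m above/below the site |

MR1 = national + metropolitan-city highways; MR2 = MR1 plus local roads
with strictly more than six lanes (threshold configurable). Road
segments are clipped at the buffer boundary before summing; buffer discs
are 256-vertex polygons (area deficit ≈ 0.01%). Empty buffer sums are 0;
failed lookups (site in no district, empty target layer) are missing —
the two are kept distinct through to the output CSV.

## CLI

```sh
# generate a synthetic scene (all layer types, closed-form ground truth)
geocov synth --seed 1 --out scene/

# list the expanded variable catalog (310 variables by default)
geocov catalog --config scene/config.yaml

# compute the sites x variables table
geocov compute --config scene/config.yaml --out covariates.csv [--format long|wide]
```

The config YAML names every layer path, the attribute schema, radii
presets, the width table and thresholds; `geocov synth` writes a
complete, ready-to-run scene directory including its config.

## Library

```python
from geocov.synthetic import SceneSpec, generate_scene
from geocov.catalog import build_default_catalog
from geocov.pipeline import compute_covariates

scene = generate_scene(SceneSpec(seed=1))
table = compute_covariates(scene.sites, scene.bundle, build_default_catalog())
table.to_wide_csv("covariates.csv")
```

Individual operations live in `geocov.proximity` (nearest distances,
road classification, width assignment, border derivation),
`geocov.buffers` (road sums, areal weighting, land-use proportions,
emission aggregation), and `geocov.rasters` (band-ratio vegetation
index, cell extraction, stack summaries, ring relative elevation).

## Testing notes

The test suite checks every operation against independent oracles:
dense point sampling for distances and clipped road lengths,
Monte-Carlo point sampling for areal-weighted and proportion values,
index arithmetic for raster extraction, plus property tests (class
nesting, radius monotonicity, proportion completeness, rigid-motion
invariance, determinism) — many on seeded synthetic scenes whose
expected values are closed forms.
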