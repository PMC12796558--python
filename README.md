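# krillscape

A reusable, tested pipeline linking acoustically derived euphausiid and
hake densities to spatial biomass hotspots and multispecies
co-occurrence:

1. **acoustics** — dB-difference classification of dual-frequency
   (120−38 kHz) MVBS echograms (10.0–16.3 dB window, 40-ping × 10-m
   cells) and NASC echo-integration into 0.5-nmi transect bins;
2. **sdm** — spatiotemporal Tweedie GAMMs: penalized-spline covariate
   effects, a time-invariant spatial field plus AR1-correlated
   spatiotemporal fields on a k-means knot mesh (barycentric
   interpolation), year intercepts, Laplace-approximate maximum
   marginal likelihood, AIC selection, convergence diagnostics and
   conditional/marginal r² decomposition;
3. **hotspots** — Moran's-I-correlogram neighborhood calibration,
   Getis-Ord Gi\* Z-scores (pooled across years), 90th-percentile
   hotspot masks, percentage overlap, per-cell co-occurrence and
   100-km latitude-binned hotspot areas;
4. **rda** — redundancy analysis (constrained ordination) of species
   Z-scores on environmental covariates, from first principles;
5. **synthetic** — generators for every input (Matérn random fields,
   AR1 field stacks, Tweedie transect surveys, dual-frequency
   echograms with planted krill, multi-species surfaces with designed
   hotspot overlap) so the whole pipeline is testable offline;
6. **grids / pipeline** — grid algebra (area-weighted regridding,
   temporal/spatial truncation, covariate extraction), YAML-driven
   end-to-end orchestration with manifests and structured logs.

## CLI

```sh
krillscape run --demo --out artifacts/           # full synthetic workflow
krillscape simulate --config sim.yaml --out dir/
krillscape preprocess --sv38 f38.csv --sv120 f120.csv \
    --low 10.0 --high 16.3 --depth 50 300 --bin 0.5 --out nasc.csv
krillscape fit --obs obs.csv --knots 100 --spatial --out fit.json
krillscape hotspots --pred pred.csv --percentile 90 --out mask.csv
krillscape overlap --a euph_mask.csv --b hake_mask.csv
krillscape cooccur --masks m1.csv --masks m2.csv ... --out cooccur.csv
krillscape rda --y z.csv --x env.csv --out rda.json
```

File formats are documented in `docs/formats.md`.

## Library use

```python
import pandas as pd
from krillscape.sdm import ModelSpec, fit, predict, r2_decompose

obs = pd.read_csv("obs.csv")
spec = ModelSpec(
    smooth_terms=(("sst_may", 3), ("stratification_aug", 3)),
    year_factor=True,
    include_spatial_field=True,
    include_spatiotemporal_ar1=True,
    n_knots=800,
)
result = fit(obs, spec, compute_se=True)
print(result.aic, result.rho, result.tweedie_p)
```
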