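# File formats

All products are plain text. Coordinates are planar kilometres
(UTM-style eastings/northings); no geodesy is performed. Grid cells are
half-open `[lo, hi)` in both axes, 0-based, row-major with cell (0, 0)
at the origin corner and centers at `origin + (i + 0.5) * cell_km`.

## ObservationTable (CSV)

Headered CSV with one row per 0.5-nmi transect bin:

| column | meaning |
| ------ | ------- |
| `x_km`, `y_km` | bin midpoint, projected km |
| `year`  | integer survey year |
| `nasc`  | nautical area scattering coefficient, m² nmi⁻² (≥ 0) |
| *(others)* | covariate columns, e.g. `sst_aug`, `depth` |

## GridStack (CSV with gridspec header)

First line embeds the geometry:

```
# gridspec: {"x0_km": 0.0, "y0_km": 0.0, "cell_km": 3.0, "n_x": 30, "n_y": 30, "projection": "planar-km"}
layer,year,row,col,x_km,y_km,value
```

One row per (layer, year, cell); missing cells are simply absent and
read back as NaN. Layer names carry month tags as suffixes when
relevant (`sst_may`, `sst_aug`).

## Hotspot masks (CSV with gridspec header)

Same `# gridspec:` header followed by `row,col` pairs of hotspot cells.

## Echograms (CSV matrix, CLI `preprocess` input)

CSV matrix of Sv (dB re 1 m⁻¹): first column is depth (m, strictly
increasing), header row is cumulative along-track distance (nmi),
one column per ping.

## Pipeline artifacts

`krillscape run` writes per-stage products plus `manifest.json`
(sha256 per file) and `pipeline.log`. Exit codes: 0 ok, 2 config
error, 3 stage failure.
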