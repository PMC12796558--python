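"""Plain-text readers/writers for the pipeline's data products.

Formats (documented in docs/formats.md):

* ObservationTable — headered CSV: x_km, y_km, year, nasc, covariates.
* GridStack — long CSV (layer, year, row, col, x_km, y_km, value) with
  the grid geometry embedded as a ``# gridspec: {...}`` comment line.
* masks — CSV of hotspot cell indices (row, col) with the same header.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import GridSpec, GridStack
from .hotspots import HotspotMask

__all__ = [
    "read_observations",
    "write_observations",
    "read_grid_stack",
    "write_grid_stack",
    "read_mask",
    "write_mask",
    "sha256_of",
]

_REQUIRED_OBS_COLS = ("x_km", "y_km", "year", "nasc")


def write_observations(obs: pd.DataFrame, path) -> None:
    missing = [c for c in _REQUIRED_OBS_COLS if c not in obs.columns]
    if missing:
        raise ValueError(f"observation table missing columns {missing}")
    obs.to_csv(path, index=False)


def read_observations(path) -> pd.DataFrame:
    obs = pd.read_csv(path)
    missing = [c for c in _REQUIRED_OBS_COLS if c not in obs.columns]
    if missing:
        raise ValueError(f"observation table {path} missing columns {missing}")
    return obs


def _spec_header(spec: GridSpec) -> str:
    payload = {
        "x0_km": spec.x0_km,
        "y0_km": spec.y0_km,
        "cell_km": spec.cell_km,
        "n_x": spec.n_x,
        "n_y": spec.n_y,
        "projection": spec.projection,
    }
    return f"# gridspec: {json.dumps(payload)}\n"


def _read_spec_header(path) -> tuple[GridSpec, int]:
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("# gridspec:"):
        raise ValueError(f"{path} lacks a '# gridspec:' header line")
    return GridSpec(**json.loads(first.split(":", 1)[1])), 1


def write_grid_stack(stack: GridStack, path) -> None:
    spec = stack.spec
    centers = spec.cell_centers()
    rows, cols = np.divmod(np.arange(spec.n_cells), spec.n_x)
    frames = []
    for layer, arr in stack.data.items():
        for t, year in enumerate(stack.years):
            vals = arr[t].ravel()
            keep = np.isfinite(vals)
            frames.append(
                pd.DataFrame(
                    {
                        "layer": layer,
                        "year": year,
                        "row": rows[keep],
                        "col": cols[keep],
                        "x_km": centers[keep, 0],
                        "y_km": centers[keep, 1],
                        "value": vals[keep],
                    }
                )
            )
    buf = _io.StringIO()
    pd.concat(frames, ignore_index=True).to_csv(buf, index=False)
    with open(path, "w") as fh:
        fh.write(_spec_header(spec))
        fh.write(buf.getvalue())


def read_grid_stack(path) -> GridStack:
    spec, skip = _read_spec_header(path)
    tbl = pd.read_csv(path, skiprows=skip)
    years = sorted(tbl["year"].unique().tolist())
    data = {}
    for layer, sub in tbl.groupby("layer"):
        arr = np.full((len(years), spec.n_y, spec.n_x), np.nan)
        t = np.searchsorted(years, sub["year"].to_numpy())
        arr[t, sub["row"].to_numpy(), sub["col"].to_numpy()] = sub["value"].to_numpy()
        data[str(layer)] = arr
    return GridStack(spec, years, data)


def write_mask(mask: HotspotMask, spec: GridSpec, path) -> None:
    cells = np.asarray(mask.cells, dtype=bool)
    r, c = np.nonzero(cells)
    with open(path, "w") as fh:
        fh.write(_spec_header(spec))
        pd.DataFrame({"row": r, "col": c}).to_csv(fh, index=False)


def read_mask(path) -> tuple[HotspotMask, GridSpec]:
    spec, skip = _read_spec_header(path)
    tbl = pd.read_csv(path, skiprows=skip)
    cells = np.zeros(spec.shape, dtype=bool)
    cells[tbl["row"].to_numpy(), tbl["col"].to_numpy()] = True
    return HotspotMask(cells, cell_km=spec.cell_km), spec


def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
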