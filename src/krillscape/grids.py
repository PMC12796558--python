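"""Regular projected grids and the algebra the pipeline needs.

All coordinates are planar kilometres (UTM-style eastings/northings); a
projection tag travels with each grid but no reprojection is ever done.
Cells are half-open ``[lo, hi)`` in both axes, 0-based, with cell (0, 0)
at the origin corner and centers at ``origin + (i + 0.5) * cell_km``.
The half-open convention lives in :func:`GridSpec.cell_index` and is the
single lookup used by extraction, regridding and mask algebra.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GridSpec",
    "GridField",
    "GridStack",
    "regrid_mean",
    "mean_across_years",
    "truncate_to_common",
    "extract_covariates_at_obs",
    "derive_stratification",
]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular planar grid.

    Values on the grid are stored row-major with shape ``(n_y, n_x)``:
    axis 0 indexes northings (rows), axis 1 eastings (columns).
    """

    x0_km: float
    y0_km: float
    cell_km: float
    n_x: int
    n_y: int
    projection: str = "planar-km"

    def __post_init__(self) -> None:
        if self.cell_km <= 0:
            raise ValueError("cell_km must be positive")
        if self.n_x < 1 or self.n_y < 1:
            raise ValueError("grid must have at least one cell per axis")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_y, self.n_x)

    @property
    def n_cells(self) -> int:
        return self.n_x * self.n_y

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return (
            self.x0_km,
            self.x0_km + self.n_x * self.cell_km,
            self.y0_km,
            self.y0_km + self.n_y * self.cell_km,
        )

    def x_centers(self) -> np.ndarray:
        return self.x0_km + (np.arange(self.n_x) + 0.5) * self.cell_km

    def y_centers(self) -> np.ndarray:
        return self.y0_km + (np.arange(self.n_y) + 0.5) * self.cell_km

    def cell_centers(self) -> np.ndarray:
        """(n_cells, 2) array of (x, y) centers in row-major cell order."""
        xx, yy = np.meshgrid(self.x_centers(), self.y_centers())
        return np.column_stack([xx.ravel(), yy.ravel()])

    def cell_index(self, x, y):
        """Map points to (row, col) under the half-open cell convention.

        Returns integer arrays; points outside the extent get index -1
        in the offending axis.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0_km) / self.cell_km).astype(int)
        row = np.floor((y - self.y0_km) / self.cell_km).astype(int)
        col = np.where((col >= 0) & (col < self.n_x), col, -1)
        row = np.where((row >= 0) & (row < self.n_y), row, -1)
        return row, col

    def contains(self, x, y) -> np.ndarray:
        row, col = self.cell_index(x, y)
        return (row >= 0) & (col >= 0)


@dataclass
class GridField:
    """A single layer of values on a :class:`GridSpec` (NaN = missing)."""

    spec: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.spec.shape}"
            )

    def copy(self) -> "GridField":
        return GridField(self.spec, self.values.copy())


@dataclass
class GridStack:
    """Per-year (and optionally per-layer) fields on a shared grid.

    ``data`` maps layer name -> (n_years, n_y, n_x) array aligned with
    ``years``.  A bare single-variable stack uses layer name "value".
    """

    spec: GridSpec
    years: list[int]
    data: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.years = [int(y) for y in self.years]
        for name, arr in self.data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (len(self.years), *self.spec.shape):
                raise ValueError(
                    f"layer {name!r} has shape {arr.shape}, expected "
                    f"{(len(self.years), *self.spec.shape)}"
                )
            self.data[name] = arr

    @property
    def layers(self) -> list[str]:
        return list(self.data)

    def year_index(self, year: int) -> int:
        try:
            return self.years.index(int(year))
        except ValueError:
            raise KeyError(f"year {year} not in stack years {self.years}") from None

    def field(self, layer: str, year: int) -> GridField:
        return GridField(self.spec, self.data[layer][self.year_index(year)])

    def subset_years(self, years_subset) -> "GridStack":
        idx = [self.year_index(y) for y in years_subset]
        return GridStack(
            self.spec,
            [self.years[i] for i in idx],
            {k: v[idx] for k, v in self.data.items()},
        )


# ---------------------------------------------------------------------------
# grid algebra


def _overlap_operator(fine: GridSpec, coarse: GridSpec, axis: str) -> np.ndarray:
    """1-D matrix of overlap lengths between fine and coarse cells."""
    if axis == "x":
        f0, fn, fc = fine.x0_km, fine.n_x, fine.cell_km
        c0, cn, cc = coarse.x0_km, coarse.n_x, coarse.cell_km
    else:
        f0, fn, fc = fine.y0_km, fine.n_y, fine.cell_km
        c0, cn, cc = coarse.y0_km, coarse.n_y, coarse.cell_km
    fe = f0 + np.arange(fn + 1) * fc
    ce = c0 + np.arange(cn + 1) * cc
    lo = np.maximum(ce[:-1, None], fe[None, :-1])
    hi = np.minimum(ce[1:, None], fe[None, 1:])
    return np.clip(hi - lo, 0.0, None)  # (coarse, fine)


def regrid_mean(fine: GridField, coarse: GridSpec) -> GridField:
    """Area-weighted mean of fine cells within each coarse cell.

    Missing fine cells are excluded from the weighting; a coarse cell
    with no valid overlap is missing.  Conserves the valid-area-weighted
    mean of the field.
    """
    if coarse.cell_km < fine.spec.cell_km:
        raise ValueError("coarse cell size must be >= fine cell size")
    wx = _overlap_operator(fine.spec, coarse, "x")  # (Cx, Fx)
    wy = _overlap_operator(fine.spec, coarse, "y")  # (Cy, Fy)
    if wx.sum() == 0 or wy.sum() == 0:
        raise ValueError("grids do not overlap")
    vals = fine.values
    valid = np.isfinite(vals)
    v0 = np.where(valid, vals, 0.0)
    num = wy @ v0 @ wx.T
    den = wy @ valid.astype(float) @ wx.T
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / den, np.nan)
    return GridField(coarse, out)


def mean_across_years(stack: GridStack, years_subset=None, layer: str = "value") -> GridField:
    """Cell-wise mean over the requested years, skipping missing years."""
    if years_subset is None:
        years_subset = stack.years
    years_subset = list(years_subset)
    if not years_subset:
        raise ValueError("years_subset is empty")
    sub = stack.subset_years(years_subset)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        out = np.nanmean(sub.data[layer], axis=0)
    return GridField(stack.spec, out)


def truncate_to_common(datasets: list[GridStack]) -> list[GridStack]:
    """Intersect stacks in time and space before any averaging.

    Temporal rule: restrict every stack to the year set of the stack
    with the fewest years (intersection must be non-empty).  Spatial
    rule: cells missing (all-NaN across layers/years) in any dataset
    are masked to missing in all.  All stacks must share a grid spec.
    Idempotent.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two datasets to truncate")
    spec = datasets[0].spec
    for ds in datasets[1:]:
        if ds.spec != spec:
            raise ValueError("all datasets must share a grid spec (regrid first)")
    shortest = min(datasets, key=lambda d: len(d.years))
    common_years = [y for y in shortest.years if all(y in d.years for d in datasets)]
    if not common_years:
        raise ValueError("temporal intersection of datasets is empty")
    subs = [d.subset_years(common_years) for d in datasets]
    surveyed = np.ones(spec.shape, dtype=bool)
    for d in subs:
        covered = np.zeros(spec.shape, dtype=bool)
        for arr in d.data.values():
            covered |= np.isfinite(arr).any(axis=0)
        surveyed &= covered
    if not surveyed.any():
        raise ValueError("spatial intersection of datasets is empty")
    out = []
    for d in subs:
        data = {k: np.where(surveyed[None, :, :], v, np.nan) for k, v in d.data.items()}
        out.append(GridStack(spec, d.years, data))
    return out


def extract_covariates_at_obs(
    stack: GridStack,
    obs: pd.DataFrame,
    month_tag: str | None = None,
    x_col: str = "x_km",
    y_col: str = "y_km",
    year_col: str = "year",
) -> pd.DataFrame:
    """Attach each observation the covariates of its containing cell.

    Layers are matched by ``month_tag`` when given (layer names look
    like ``"sst_may"``); the resulting columns keep the tagged layer
    name.  Out-of-extent observations are dropped with a logged count.
    """
    if month_tag is not None:
        layers = [ly for ly in stack.layers if ly.endswith(f"_{month_tag}")]
        if not layers:
            raise KeyError(f"no layer with month tag {month_tag!r} in stack {stack.layers}")
    else:
        layers = stack.layers
    row, col = stack.spec.cell_index(obs[x_col].to_numpy(), obs[y_col].to_numpy())
    inside = (row >= 0) & (col >= 0)
    n_dropped = int((~inside).sum())
    if n_dropped:
        logger.warning("extract_covariates_at_obs: dropped %d out-of-extent observations", n_dropped)
    out = obs.loc[inside].copy()
    row, col = row[inside], col[inside]
    yi = np.array([stack.year_index(y) for y in out[year_col].to_numpy()])
    for ly in layers:
        out[ly] = stack.data[ly][yi, row, col]
    return out


def derive_stratification(density_50m: GridField, density_surface: GridField) -> GridField:
    """Cell-wise water-column stratification proxy: rho(50 m) - rho(0 m)."""
    if density_50m.spec != density_surface.spec:
        raise ValueError("fields are not co-registered")
    return GridField(density_50m.spec, density_50m.values - density_surface.values)
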