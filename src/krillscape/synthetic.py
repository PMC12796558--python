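"""Synthetic survey and ocean-field generators with known ground truth.

Everything downstream of raw data collection is testable against these:
Matern-correlated latent fields, AR1 year-to-year field stacks, Tweedie
transect surveys on 0.5-nmi bins, dual-frequency echograms with planted
krill cells, and multi-species biomass surfaces with designed hotspot
overlap.  All generators are pure functions of (arguments, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.linalg import cholesky
from scipy.special import kv

from .acoustics import EchogramGrid
from .grids import GridField, GridSpec, GridStack
from .hotspots import HotspotMask
from .tweedie import tweedie_rvs

NMI_KM = 1.852
BIN_NMI = 0.5
BIN_KM = BIN_NMI * NMI_KM  # 0.926 km per half-nautical-mile bin

__all__ = [
    "SimulationConfig",
    "TransectLayout",
    "matern_correlation",
    "simulate_matern_grf",
    "simulate_ar1_fields",
    "simulate_survey",
    "simulate_dual_frequency_echogram",
    "plant_hotspot_surfaces",
    "BIN_KM",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a full synthetic survey scenario."""

    grid_extent: tuple[float, float, float, float]  # x_min, x_max, y_min, y_max (km)
    cell_km: float = 3.0
    years: tuple[int, ...] = tuple(range(2007, 2019))
    matern_range_km: float = 30.0
    sigma_spatial: float = 1.0
    sigma_st: float = 0.8
    rho_ar1: float = 0.5
    tweedie_p: float = 1.5
    tweedie_phi: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        x_min, x_max, y_min, y_max = self.grid_extent
        for span, name in ((x_max - x_min, "x"), (y_max - y_min, "y")):
            if span <= 0:
                raise ValueError(f"empty grid extent along {name}")
            if abs(round(span / self.cell_km) - span / self.cell_km) > 1e-9:
                raise ValueError(f"cell_km must divide the {name} extent")
        if not (1.0 < self.tweedie_p < 2.0):
            raise ValueError("tweedie_p must lie strictly in (1, 2)")
        if not abs(self.rho_ar1) < 1:
            raise ValueError("|rho_ar1| must be < 1")
        if self.sigma_spatial < 0 or self.sigma_st < 0:
            raise ValueError("field SDs must be nonnegative")
        if self.tweedie_phi <= 0:
            raise ValueError("tweedie_phi must be positive")

    def grid(self) -> GridSpec:
        x_min, x_max, y_min, y_max = self.grid_extent
        return GridSpec(
            x0_km=x_min,
            y0_km=y_min,
            cell_km=self.cell_km,
            n_x=int(round((x_max - x_min) / self.cell_km)),
            n_y=int(round((y_max - y_min) / self.cell_km)),
        )


def matern_correlation(d, range_km: float) -> np.ndarray:
    """Matern correlation with smoothness nu = 1.

    Parametrized so that correlation ~ 0.14 at ``d = range_km``
    (kappa = sqrt(8 * nu) / range, the usual SPDE range convention).
    """
    if range_km <= 0:
        raise ValueError("range_km must be positive")
    d = np.asarray(d, dtype=float)
    kappa = np.sqrt(8.0) / range_km
    x = kappa * d
    with np.errstate(invalid="ignore"):
        c = np.where(x > 0, x * kv(1, np.where(x > 0, x, 1.0)), 1.0)
    return np.clip(c, 0.0, 1.0)


@lru_cache(maxsize=8)
def _matern_chol(grid: GridSpec, range_km: float) -> np.ndarray:
    """Lower Cholesky factor of the Matern correlation over cell centers."""
    pts = grid.cell_centers()
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    c = matern_correlation(d, range_km)
    c[np.diag_indices_from(c)] = 1.0 + 1e-8  # jitter for numerical PD
    return cholesky(c, lower=True)


def simulate_matern_grf(grid: GridSpec, range_km: float, sigma: float, seed: int) -> GridField:
    """Zero-mean Gaussian random field with Matern (nu=1) covariance."""
    if range_km <= 0:
        raise ValueError("range_km must be positive")
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if grid.n_cells < 4:
        raise ValueError("grid must have at least 4 cells")
    if sigma == 0:
        return GridField(grid, np.zeros(grid.shape))
    rng = np.random.default_rng(seed)
    chol = _matern_chol(grid, float(range_km))
    z = sigma * (chol @ rng.standard_normal(grid.n_cells))
    return GridField(grid, z.reshape(grid.shape))


def simulate_ar1_fields(
    grid: GridSpec, years, rho: float, sigma_st: float, seed: int, range_km: float = 30.0
) -> GridStack:
    """One zero-mean Matern field per year with AR1 year-to-year
    correlation ``rho`` and stationary marginal SD ``sigma_st``."""
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1 for a stationary AR1 process")
    years = [int(y) for y in years]
    shape = (len(years), *grid.shape)
    if sigma_st == 0:
        return GridStack(grid, years, {"value": np.zeros(shape)})
    rng = np.random.default_rng(seed)
    chol = _matern_chol(grid, float(range_km))
    out = np.empty(shape)
    innov = sigma_st * (chol @ rng.standard_normal((grid.n_cells, len(years)))).T
    out[0] = innov[0].reshape(grid.shape)
    for t in range(1, len(years)):
        out[t] = rho * out[t - 1] + np.sqrt(1.0 - rho**2) * innov[t].reshape(grid.shape)
    return GridStack(grid, years, {"value": out})


@dataclass
class TransectLayout:
    """Survey bin midpoints: arrays of x, y (km) and year per bin."""

    x_km: np.ndarray
    y_km: np.ndarray
    year: np.ndarray

    def __post_init__(self) -> None:
        self.x_km = np.asarray(self.x_km, dtype=float)
        self.y_km = np.asarray(self.y_km, dtype=float)
        self.year = np.asarray(self.year, dtype=int)
        if not (self.x_km.shape == self.y_km.shape == self.year.shape):
            raise ValueError("x, y and year must align")

    @property
    def n_bins(self) -> int:
        return self.x_km.size

    @classmethod
    def parallel(
        cls,
        grid: GridSpec,
        years,
        spacing_km: float = 10.0,
        bin_km: float = BIN_KM,
    ) -> "TransectLayout":
        """East-west parallel transects every ``spacing_km``, binned at
        0.5-nmi (0.926 km) intervals, repeated every year."""
        x_min, x_max, y_min, y_max = grid.extent
        ys = np.arange(y_min + spacing_km / 2, y_max, spacing_km)
        xs = np.arange(x_min + bin_km / 2, x_max, bin_km)
        xx, yy = np.meshgrid(xs, ys)
        x1, y1 = xx.ravel(), yy.ravel()
        years = [int(y) for y in years]
        return cls(
            np.tile(x1, len(years)),
            np.tile(y1, len(years)),
            np.repeat(years, x1.size),
        )


def simulate_survey(
    truth: GridStack,
    transects: TransectLayout,
    p: float,
    phi: float,
    seed: int,
    layer: str = "value",
) -> "pd.DataFrame":
    """Draw one Tweedie observation per transect bin from the response-
    scale truth surface (mean looked up at the bin's containing cell).

    Bins outside the grid are dropped with a logged count.  Returns an
    observation table with columns ``x_km, y_km, year, nasc``.
    """
    import logging

    import pandas as pd

    grid = truth.spec
    row, col = grid.cell_index(transects.x_km, transects.y_km)
    inside = (row >= 0) & (col >= 0)
    n_dropped = int((~inside).sum())
    if n_dropped:
        logging.getLogger(__name__).warning(
            "simulate_survey: dropped %d bins outside the grid", n_dropped
        )
    x, y, yr = transects.x_km[inside], transects.y_km[inside], transects.year[inside]
    row, col = row[inside], col[inside]
    yi = np.array([truth.year_index(v) for v in yr])
    mu = truth.data[layer][yi, row, col]
    if np.any(~(mu > 0)):
        raise ValueError("truth surface must be strictly positive on the response scale")
    rng = np.random.default_rng(seed)
    obs = tweedie_rvs(mu, p, phi, rng)
    return pd.DataFrame({"x_km": x, "y_km": y, "year": yr, "nasc": obs})


def simulate_dual_frequency_echogram(
    krill_mask: np.ndarray,
    db_diff_target: float,
    noise_sd: float,
    seed: int,
    background_sv38: float = -80.0,
    krill_sv38: float = -75.0,
    background_diff: float = 0.0,
    window_pings: int = 40,
    window_depth_m: float = 10.0,
    sample_dz_m: float = 1.0,
    ping_spacing_nmi: float = 0.0025,
    low_db: float = 10.0,
    high_db: float = 16.3,
) -> tuple[EchogramGrid, EchogramGrid]:
    """Fine-resolution 38/120 kHz echograms with planted krill cells.

    ``krill_mask`` marks MVBS-resolution cells (depth-window rows by
    40-ping columns).  Each marked cell gets a 120-38 difference of
    ``db_diff_target`` plus N(0, noise_sd) noise (one draw per MVBS
    cell, so classification operates on exactly the planted values);
    background cells get ``background_diff``, which must lie outside the
    classification window.
    """
    if not (low_db <= db_diff_target <= high_db):
        raise ValueError("db_diff_target must lie inside the classification window")
    if low_db <= background_diff <= high_db:
        raise ValueError("background_diff must lie outside the classification window")
    mask = np.asarray(krill_mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("krill_mask must be 2-D (depth cells x ping cells)")
    rng = np.random.default_rng(seed)
    n_dc, n_pc = mask.shape
    diff = np.where(mask, db_diff_target + noise_sd * rng.standard_normal(mask.shape), background_diff)
    sv38_cell = np.where(mask, krill_sv38, background_sv38)

    rows_per_cell = int(round(window_depth_m / sample_dz_m))
    sv38 = np.repeat(np.repeat(sv38_cell, rows_per_cell, axis=0), window_pings, axis=1)
    sv120 = np.repeat(np.repeat(sv38_cell + diff, rows_per_cell, axis=0), window_pings, axis=1)
    depth = (np.arange(n_dc * rows_per_cell) + 0.5) * sample_dz_m
    track = np.arange(n_pc * window_pings) * ping_spacing_nmi
    return (
        EchogramGrid(sv38, depth, track, 38.0),
        EchogramGrid(sv120, depth, track, 120.0),
    )


def _ribbon_cells(grid: GridSpec, row0: int, height: int, start: int, size: int) -> np.ndarray:
    """Boolean mask for a column-major run of ``size`` cells inside the
    band of rows [row0, row0+height), starting at linear offset
    ``start`` (column-by-column ordering within the band)."""
    mask = np.zeros(grid.shape, dtype=bool)
    band = np.zeros((height, grid.n_x), dtype=bool)
    flat = band.ravel(order="F")
    flat[start : start + size] = True
    mask[row0 : row0 + height, :] = flat.reshape((height, grid.n_x), order="F")
    return mask


def plant_hotspot_surfaces(
    n_species: int,
    overlap_design: dict[tuple[int, int], float] | float,
    grid: GridSpec,
    seed: int,
    hotspot_cells: int | None = None,
    mu_background: float = 1.0,
    mu_hotspot: float = 10.0,
    years=(2018,),
    noise_sd: float = 0.0,
) -> tuple[list[GridStack], list[HotspotMask]]:
    """Multi-species response surfaces with designed hotspot overlap.

    ``overlap_design`` gives target union overlap |A∩B|/|A∪B| per
    species pair (a bare float means the (0, 1) pair).  Hotspots are
    equal-sized compact ribbons placed along a shared row band; species
    i+1 is offset from species i so consecutive-pair targets are met
    exactly up to integer rounding (intersection within one cell).
    Designs that cannot be realized this way raise, naming the violated
    pair.  Optional lognormal noise roughens the surfaces.
    """
    if n_species < 1:
        raise ValueError("need at least one species")
    if isinstance(overlap_design, (int, float)):
        overlap_design = {(0, 1): float(overlap_design)}
    for (i, j), jac in overlap_design.items():
        if not (0 <= i < n_species and 0 <= j < n_species and i != j):
            raise ValueError(f"bad species pair {(i, j)}")
        if not (0.0 <= jac <= 1.0):
            raise ValueError(f"overlap for pair {(i, j)} must be in [0, 1]")

    s = hotspot_cells if hotspot_cells is not None else max(int(0.05 * grid.n_cells), 16)
    height = min(max(int(round(np.sqrt(s))), 1), grid.n_y)
    band_cells = height * grid.n_x
    row0 = (grid.n_y - height) // 2

    # consecutive-pair offsets from designed Jaccard: |A∩B| = J*2s/(1+J)
    offsets = [0]
    for i in range(1, n_species):
        jac = overlap_design.get((i - 1, i), overlap_design.get((i, i - 1), 0.0))
        inter = int(round(2.0 * s * jac / (1.0 + jac)))
        offsets.append(offsets[-1] + (s - inter))
    if offsets[-1] + s > band_cells:
        raise ValueError(
            f"infeasible design: species {n_species - 1} needs offset {offsets[-1]} + "
            f"{s} cells but the band holds {band_cells}"
        )

    # verify every designed pair against the realized run intersections
    for (i, j), jac in overlap_design.items():
        realized_inter = max(0, s - abs(offsets[i] - offsets[j]))
        designed_inter = int(round(2.0 * s * jac / (1.0 + jac)))
        if abs(realized_inter - designed_inter) > 1:
            raise ValueError(
                f"infeasible design for pair {(i, j)}: realized intersection "
                f"{realized_inter} cells vs designed {designed_inter}"
            )

    rng = np.random.default_rng(seed)
    years = [int(y) for y in years]
    stacks, masks = [], []
    for i in range(n_species):
        cells = _ribbon_cells(grid, row0, height, offsets[i], s)
        mu = np.where(cells, mu_hotspot, mu_background).astype(float)
        arr = np.empty((len(years), *grid.shape))
        for t in range(len(years)):
            layer = mu.copy()
            if noise_sd > 0:
                layer = layer * np.exp(noise_sd * rng.standard_normal(grid.shape) - noise_sd**2 / 2)
            arr[t] = layer
        stacks.append(GridStack(grid, years, {"value": arr}))
        masks.append(HotspotMask(cells, percentile=None, cell_km=grid.cell_km))
    return stacks, masks
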