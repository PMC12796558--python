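"""Spatial clustering statistics: global Moran's I, distance-band
correlograms for neighborhood calibration, Getis-Ord Gi* Z-scores,
percentile hotspot masks, and overlap / co-occurrence summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

__all__ = [
    "ZField",
    "HotspotMask",
    "OverlapReport",
    "morans_i",
    "morans_i_moments",
    "correlogram",
    "choose_neighborhood",
    "gi_star",
    "pooled_gi_star_by_year",
    "hotspot_mask",
    "overlap_percentage",
    "cooccurrence_percent",
    "binned_hotspot_area",
]


@dataclass
class ZField:
    """Gi* Z-scores per cell (or per cell-year stacked along axis 0)."""

    z: np.ndarray
    pooled_mean: float
    pooled_sd: float
    neighborhood_km: float

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.pooled_sd <= 0:
            raise ValueError("pooled_sd must be positive")


@dataclass
class HotspotMask:
    """Boolean hotspot cells with the percentile rule that produced them."""

    cells: np.ndarray
    percentile: float | None = None
    cell_km: float | None = None

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=bool)

    @property
    def area_km2(self) -> float:
        if self.cell_km is None:
            raise ValueError("cell_km unknown; cannot compute area")
        return float(self.cells.sum()) * self.cell_km**2


@dataclass
class OverlapReport:
    pct_overlap: float
    area_a_only: float
    area_b_only: float
    area_both: float
    by_year: dict[int, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Moran's I


def _as_weight_matrix(weights):
    if sp.issparse(weights):
        w = weights.tocsr().astype(float)
    else:
        w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weights must be a square matrix")
    return w


def morans_i(values, weights) -> float:
    """Global Moran's I with an arbitrary (zero-diagonal) weight matrix,
    dense or sparse.

    I = (N / sum_ij w_ij) * sum_ij w_ij (x_i - xbar)(x_j - xbar)
        / sum_i (x_i - xbar)^2
    """
    x = np.asarray(values, dtype=float).ravel()
    w = _as_weight_matrix(weights)
    if x.size < 3:
        raise ValueError("need at least 3 cells")
    if x.size != w.shape[0]:
        raise ValueError("values and weights disagree in size")
    s0 = w.sum()
    if s0 == 0:
        raise ValueError("total weight is zero")
    d = x - x.mean()
    denom = (d**2).sum()
    if denom == 0:
        raise ValueError("Moran's I is undefined for a constant field")
    cross = float(d @ (w @ d))
    return float(x.size / s0 * cross / denom)


def morans_i_moments(weights) -> tuple[float, float]:
    """(E[I], SD[I]) under the normality null hypothesis (Cliff-Ord)."""
    w = _as_weight_matrix(weights)
    n = w.shape[0]
    s0 = w.sum()
    if sp.issparse(w):
        wt = w + w.T
        s1 = 0.5 * wt.multiply(wt).sum()
        sums = np.asarray(w.sum(axis=1)).ravel() + np.asarray(w.sum(axis=0)).ravel()
    else:
        s1 = 0.5 * ((w + w.T) ** 2).sum()
        sums = w.sum(axis=1) + w.sum(axis=0)
    s2 = (sums**2).sum()
    e_i = -1.0 / (n - 1)
    var = (n**2 * s1 - n * s2 + 3 * s0**2) / (s0**2 * (n**2 - 1)) - e_i**2
    return e_i, float(np.sqrt(max(var, 0.0)))


def _band_weights(coords: np.ndarray, lo: float, hi: float) -> sp.csr_matrix:
    """Sparse binary weights for pairs with lo < d <= hi (zero diagonal)."""
    tree = cKDTree(coords)
    dmat = tree.sparse_distance_matrix(tree, hi, output_type="coo_matrix")
    keep = (dmat.data > lo) & (dmat.data <= hi) & (dmat.row != dmat.col)
    n = coords.shape[0]
    return sp.csr_matrix(
        (np.ones(int(keep.sum())), (dmat.row[keep], dmat.col[keep])), shape=(n, n)
    )


def correlogram(values, coords, distance_bins) -> list[dict]:
    """Moran's I per distance band with its null moments.

    ``distance_bins`` is a sequence of increasing band edges
    ``[d0, d1, ...]``; band k uses pairs with d_k < distance <= d_{k+1}
    (the first band starts at d0, typically 0).  Returns one dict per
    band: ``{"lo", "hi", "i", "e_i", "sd_i", "n_pairs"}``.
    """
    x = np.asarray(values, dtype=float).ravel()
    coords = np.asarray(coords, dtype=float)
    edges = np.asarray(distance_bins, dtype=float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("distance_bins must be increasing with >= 2 edges")
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        w = _band_weights(coords, lo, hi)
        n_pairs = int(w.sum())
        if n_pairs == 0:
            out.append({"lo": lo, "hi": hi, "i": np.nan, "e_i": np.nan, "sd_i": np.nan, "n_pairs": 0})
            continue
        e_i, sd_i = morans_i_moments(w)
        out.append(
            {
                "lo": float(lo),
                "hi": float(hi),
                "i": morans_i(x, w),
                "e_i": e_i,
                "sd_i": sd_i,
                "n_pairs": n_pairs,
            }
        )
    return out


def choose_neighborhood(correlogram_rows: list[dict]) -> float:
    """Neighborhood distance from a correlogram: the upper edge of the
    last band before the first band whose I has decayed to the null
    (I <= E[I] + 2*SD[I]).

    If the first band already fails the criterion, returns its upper
    edge with a warning; if no band fails, returns the largest edge
    with a warning.
    """
    rows = [r for r in correlogram_rows if r["n_pairs"] > 0]
    if not rows:
        raise ValueError("empty correlogram")
    for k, r in enumerate(rows):
        if r["i"] <= r["e_i"] + 2.0 * r["sd_i"]:
            if k == 0:
                warnings.warn(
                    "autocorrelation already decayed in the first distance band; "
                    "using its upper edge as the neighborhood"
                )
                return float(r["hi"])
            return float(rows[k - 1]["hi"])
    warnings.warn("no distance band shows decay; using the largest band edge")
    return float(rows[-1]["hi"])


# ---------------------------------------------------------------------------
# Getis-Ord


def gi_star(
    values,
    coords,
    neighborhood_km: float,
    pooled: tuple[float, float] | None = None,
    include_self: bool = True,
) -> ZField:
    """Getis-Ord Z-scores with binary distance-band weights.

    Per cell i, with w_ij = 1 for d(i, j) <= neighborhood_km (self
    included under the Gi* convention, the default):

        Z_i = (sum_j w_ij x_j - xbar W_i)
              / (S * sqrt((N sum_j w_ij^2 - W_i^2) / (N - 1)))

    where xbar and S are the mean and SD over all cells — or the
    supplied ``pooled`` (mean, sd) when standardizing across years.
    Missing values are excluded from sums and get Z = NaN.
    """
    if neighborhood_km <= 0:
        raise ValueError("neighborhood_km must be positive")
    x = np.asarray(values, dtype=float).ravel()
    coords = np.asarray(coords, dtype=float)
    valid = np.isfinite(x)
    xv = x[valid]
    cv = coords[valid]
    n = xv.size
    if n < 2 or np.unique(xv).size < 2 and pooled is None:
        raise ValueError("need >= 2 distinct values")
    if pooled is None:
        xbar = float(xv.mean())
        s = float(xv.std(ddof=0))
    else:
        xbar, s = float(pooled[0]), float(pooled[1])
    if s <= 0:
        raise ValueError("zero standard deviation; Gi* undefined")

    tree = cKDTree(cv)
    neighbor_lists = tree.query_ball_tree(tree, neighborhood_km)
    z = np.full(x.size, np.nan)
    zv = np.empty(n)
    for i, nbrs in enumerate(neighbor_lists):
        nbrs = list(nbrs)
        if not include_self:
            nbrs = [j for j in nbrs if j != i]
        w_i = float(len(nbrs))  # binary weights: W_i = sum w_ij = sum w_ij^2
        num = xv[nbrs].sum() - xbar * w_i
        den = s * np.sqrt((n * w_i - w_i**2) / (n - 1)) if n > 1 else np.nan
        zv[i] = num / den if den > 0 else 0.0
    z[valid] = zv
    return ZField(z.reshape(np.shape(values)), xbar, s, float(neighborhood_km))


def pooled_gi_star_by_year(
    values_by_year: dict[int, np.ndarray],
    coords,
    neighborhood_km: float,
    include_self: bool = True,
) -> dict[int, ZField]:
    """Gi* per year with mean/SD pooled over all cell-years, so Z-scores
    are comparable between years."""
    years = sorted(values_by_year)
    if len(years) < 2:
        warnings.warn("single year supplied; falling back to plain gi_star")
        y = years[0]
        return {y: gi_star(values_by_year[y], coords, neighborhood_km, include_self=include_self)}
    pooled_vals = np.concatenate(
        [np.asarray(values_by_year[y], dtype=float).ravel() for y in years]
    )
    pooled_vals = pooled_vals[np.isfinite(pooled_vals)]
    pooled = (float(pooled_vals.mean()), float(pooled_vals.std(ddof=0)))
    return {
        y: gi_star(values_by_year[y], coords, neighborhood_km, pooled=pooled, include_self=include_self)
        for y in years
    }


# ---------------------------------------------------------------------------
# hotspot masks and summaries


def hotspot_mask(
    zfield: ZField | np.ndarray,
    percentile: float = 0.90,
    cell_km: float | None = None,
) -> HotspotMask:
    """Cells with Z at or above the ``percentile`` quantile of all
    (finite) Z values.  Ties at the threshold are included.
    """
    z = zfield.z if isinstance(zfield, ZField) else np.asarray(zfield, dtype=float)
    finite = z[np.isfinite(z)]
    if finite.size < 10:
        raise ValueError("need >= 10 cells for a percentile hotspot mask")
    thr = np.quantile(finite, percentile)
    if finite.min() == finite.max():
        warnings.warn("all Z values tie at the threshold; every cell flagged")
    with np.errstate(invalid="ignore"):
        cells = np.where(np.isfinite(z), z >= thr, False)
    return HotspotMask(cells, percentile=percentile, cell_km=cell_km)


def _mask_array(m) -> np.ndarray:
    return m.cells if isinstance(m, HotspotMask) else np.asarray(m, dtype=bool)


def overlap_percentage(mask_a, mask_b, cell_km: float = 1.0) -> OverlapReport:
    """Percentage overlap 100 * |A∩B| / |A∪B| plus area breakdown."""
    a = _mask_array(mask_a)
    b = _mask_array(mask_b)
    if a.shape != b.shape:
        raise ValueError("masks are not co-registered")
    both = int((a & b).sum())
    union = int((a | b).sum())
    if union == 0:
        warnings.warn("both masks empty; overlap defined as 0%")
        pct = 0.0
    else:
        pct = 100.0 * both / union
    cell_area = cell_km**2
    return OverlapReport(
        pct_overlap=float(pct),
        area_a_only=float((a & ~b).sum()) * cell_area,
        area_b_only=float((b & ~a).sum()) * cell_area,
        area_both=float(both) * cell_area,
    )


def cooccurrence_percent(masks: list, surveyed: list | None = None) -> np.ndarray:
    """Per cell: 100 * (species hot) / (species analyzed).

    ``surveyed`` optionally gives per-species boolean coverage; cells
    outside the common surveyed area come back NaN.
    """
    if not masks:
        raise ValueError("empty species list")
    arrs = [_mask_array(m) for m in masks]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("masks are not on a common grid")
    hot = np.sum(arrs, axis=0).astype(float)
    pct = 100.0 * hot / len(arrs)
    if surveyed is not None:
        common = np.logical_and.reduce([_mask_array(s) for s in surveyed])
        pct = np.where(common, pct, np.nan)
    return pct


def binned_hotspot_area(
    mask,
    northings_km: np.ndarray,
    cell_km: float,
    northing_bin_km: float = 100.0,
    comask=None,
) -> dict:
    """Hotspot area per northing bin (bins aligned to multiples of
    ``northing_bin_km``); bin totals sum to the overall mask area.

    Returns {"bins": lower edges, "area_km2": per-bin areas[, "co_area_km2"]}.
    """
    cells = _mask_array(mask).ravel()
    y = np.asarray(northings_km, dtype=float).ravel()
    if y.size != cells.size:
        raise ValueError("northings must align with mask cells")
    lo = np.floor(y.min() / northing_bin_km) * northing_bin_km
    hi = np.floor(y.max() / northing_bin_km) * northing_bin_km
    edges = np.arange(lo, hi + northing_bin_km, northing_bin_km)
    idx = np.floor((y - lo) / northing_bin_km).astype(int)
    cell_area = cell_km**2
    areas = np.zeros(edges.size)
    np.add.at(areas, idx[cells], cell_area)
    out = {"bins": edges, "area_km2": areas}
    if comask is not None:
        co = (_mask_array(mask) & _mask_array(comask)).ravel()
        co_areas = np.zeros(edges.size)
        np.add.at(co_areas, idx[co], cell_area)
        out["co_area_km2"] = co_areas
    return out
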