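"""Knot meshes for the reduced-rank spatial random fields.

Knots are either k-means centroids of the observation coordinates or a
greedy minimum-spacing thinning ("cutoff").  Values at arbitrary points
are obtained by barycentric interpolation on the Delaunay triangulation
of the knots — weights are nonnegative and sum to 1; points outside the
hull snap to their nearest knot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.spatial import Delaunay, cKDTree

__all__ = ["KnotMesh", "select_knots", "select_knots_by_cutoff"]


@dataclass
class KnotMesh:
    knot_coords: np.ndarray  # (m, 2)
    triangulation: Delaunay | None = field(default=None, repr=False)
    _tree: cKDTree | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.knot_coords = np.asarray(self.knot_coords, dtype=float)
        if self.knot_coords.ndim != 2 or self.knot_coords.shape[1] != 2:
            raise ValueError("knot_coords must be (m, 2)")
        if self.triangulation is None and self.n_knots >= 3:
            try:
                self.triangulation = Delaunay(self.knot_coords)
            except Exception:  # degenerate (collinear) knot sets
                self.triangulation = None
        if self._tree is None:
            self._tree = cKDTree(self.knot_coords)

    @property
    def n_knots(self) -> int:
        return self.knot_coords.shape[0]

    def interpolation_weights(self, points) -> csr_matrix:
        """Sparse (n_points, n_knots) operator mapping knot values to
        points; rows sum to 1, entries in [0, 1]."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        n = pts.shape[0]
        rows, cols, vals = [], [], []
        if self.triangulation is not None:
            simplex = self.triangulation.find_simplex(pts)
        else:
            simplex = np.full(n, -1)
        inside = simplex >= 0
        if inside.any():
            tri = self.triangulation
            s = simplex[inside]
            t = tri.transform[s]
            bary = np.einsum("ijk,ik->ij", t[:, :2, :], pts[inside] - t[:, 2, :])
            w = np.column_stack([bary, 1.0 - bary.sum(axis=1)])
            w = np.clip(w, 0.0, 1.0)
            w /= w.sum(axis=1, keepdims=True)
            verts = tri.simplices[s]
            idx = np.where(inside)[0]
            rows.append(np.repeat(idx, 3))
            cols.append(verts.ravel())
            vals.append(w.ravel())
        if (~inside).any():
            idx = np.where(~inside)[0]
            _, nearest = self._tree.query(pts[idx])
            rows.append(idx)
            cols.append(np.atleast_1d(nearest))
            vals.append(np.ones(idx.size))
        rows = np.concatenate(rows) if rows else np.array([], dtype=int)
        cols = np.concatenate(cols) if cols else np.array([], dtype=int)
        vals = np.concatenate(vals) if vals else np.array([], dtype=float)
        return csr_matrix((vals, (rows, cols)), shape=(n, self.n_knots))

    def min_spacing(self) -> float:
        if self.n_knots < 2:
            return np.inf
        d, _ = self._tree.query(self.knot_coords, k=2)
        return float(d[:, 1].min())


def select_knots(coords, n_knots: int, seed: int = 0) -> KnotMesh:
    """K-means centroids of the observation coordinates as knots."""
    from sklearn.cluster import KMeans

    coords = np.unique(np.asarray(coords, dtype=float), axis=0)
    if n_knots > coords.shape[0]:
        raise ValueError(
            f"n_knots={n_knots} exceeds the {coords.shape[0]} distinct coordinates"
        )
    if n_knots == coords.shape[0]:
        return KnotMesh(coords)
    km = KMeans(n_clusters=n_knots, random_state=seed, n_init=5)
    km.fit(coords)
    return KnotMesh(km.cluster_centers_)


def select_knots_by_cutoff(coords, cutoff_km: float) -> KnotMesh:
    """Greedy thinning: keep each point only if it is at least
    ``cutoff_km`` away from every knot accepted so far."""
    if cutoff_km <= 0:
        raise ValueError("cutoff_km must be positive")
    coords = np.unique(np.asarray(coords, dtype=float), axis=0)
    kept: list[np.ndarray] = []
    for pt in coords:
        if all(np.hypot(*(pt - q)) >= cutoff_km for q in kept):
            kept.append(pt)
    return KnotMesh(np.array(kept))
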