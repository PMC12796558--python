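"""Redundancy analysis (constrained ordination) from first principles.

RDA is the PCA of the fitted values of a multivariate linear regression
of the (centered) response matrix Y on the (centered) constraint matrix
X.  Scores default to the type-2 (correlation) biplot scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = ["RDAResult", "rda_fit", "rda_axis_interpretation"]


@dataclass
class RDAResult:
    eigenvalues: np.ndarray  # constrained-axis variances, descending
    species_scores: np.ndarray  # species x axes
    site_scores: np.ndarray  # cells x axes
    biplot_scores: np.ndarray  # covariates x axes
    prop_constrained: float  # constrained variance / total variance
    total_variance: float
    species_names: list[str] | None = None
    covariate_names: list[str] | None = None

    @property
    def n_axes(self) -> int:
        return int(self.eigenvalues.size)


def _center_scale(m: np.ndarray, scale: bool) -> np.ndarray:
    m = m - m.mean(axis=0)
    if scale:
        sd = m.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("constant column cannot be standardized")
        m = m / sd
    return m


def rda_fit(
    y: np.ndarray,
    x: np.ndarray,
    scale_y: bool = True,
    scale_x: bool = True,
    scaling: int = 2,
    species_names: list[str] | None = None,
    covariate_names: list[str] | None = None,
) -> RDAResult:
    """Fit an RDA of responses ``y`` (cells x species) on constraints
    ``x`` (cells x covariates).

    Both matrices are centered (and by default standardized).  The
    fitted values ``Yhat = X (X'X)^-1 X' Y`` are eigendecomposed via
    their SVD; eigenvalues are variances of the constrained axes
    (divisor n-1).  ``scaling=1`` gives distance (site-focused) scores,
    ``scaling=2`` correlation (species-focused) scores.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.ndim != 2 or x.ndim != 2 or y.shape[0] != x.shape[0]:
        raise ValueError("y and x must be 2-D with matching row counts")
    if not (np.isfinite(y).all() and np.isfinite(x).all()):
        raise ValueError("missing values must be removed before RDA")
    n = y.shape[0]
    if n <= x.shape[1]:
        raise ValueError("need more rows than constraints")

    yc = _center_scale(y, scale_y)
    xc = _center_scale(x, scale_x)

    rank_x = np.linalg.matrix_rank(xc)
    if rank_x < xc.shape[1]:
        # identify dependent columns by rank-revealing QR pivots
        _, _, piv = scipy.linalg.qr(xc, pivoting=True)
        dep = sorted(piv[rank_x:])
        names = (
            [covariate_names[i] for i in dep] if covariate_names is not None else list(dep)
        )
        raise ValueError(f"constraint matrix is rank-deficient; dependent columns: {names}")

    beta, *_ = np.linalg.lstsq(xc, yc, rcond=None)
    yhat = xc @ beta

    u, sing, vt = np.linalg.svd(yhat, full_matrices=False)
    eig = sing**2 / (n - 1)
    keep = eig > max(eig.max(), 1.0) * 1e-12 if eig.size else np.array([], dtype=bool)
    # cap axes at the rank of the constrained space
    n_axes = min(int(keep.sum()), rank_x, y.shape[1])
    u, sing, vt = u[:, :n_axes], sing[:n_axes], vt[:n_axes]
    eig = eig[:n_axes]

    total_var = float((yc**2).sum() / (n - 1))
    prop = float(eig.sum() / total_var) if total_var > 0 else 0.0

    if scaling == 1:
        species = vt.T  # unit-length species axes, sites carry the variance
        sites = u * sing / np.sqrt(n - 1)
    elif scaling == 2:
        species = vt.T * np.sqrt(eig)  # species scaled by axis SD
        sites = u
    else:
        raise ValueError("scaling must be 1 or 2")

    # biplot scores: correlations of constraints with the site ordination
    site_lc = u  # linear-combination site scores, unit norm per axis
    with np.errstate(invalid="ignore", divide="ignore"):
        bip = np.array(
            [
                [
                    _safe_corr(xc[:, k], site_lc[:, a])
                    for a in range(n_axes)
                ]
                for k in range(xc.shape[1])
            ]
        )

    return RDAResult(
        eigenvalues=eig,
        species_scores=species,
        site_scores=sites,
        biplot_scores=bip,
        prop_constrained=prop,
        total_variance=total_var,
        species_names=species_names,
        covariate_names=covariate_names,
    )


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def rda_axis_interpretation(result: RDAResult, axis: int) -> list[tuple[str, float]]:
    """Covariates ranked by |biplot score| on ``axis`` (0-based), with
    their signed loadings."""
    if not (0 <= axis < result.n_axes):
        raise ValueError(f"axis {axis} out of range; result has {result.n_axes} axes")
    loadings = result.biplot_scores[:, axis]
    names = result.covariate_names or [f"x{k}" for k in range(loadings.size)]
    order = np.argsort(-np.abs(loadings))
    return [(names[k], float(loadings[k])) for k in order]
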