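"""Spatiotemporal Tweedie random-field GAMM.

The model for density y at location s in year t is

    y ~ Tweedie(mu, p, phi),  log mu = X(s,t) beta + w(s) + e_t(s) + b_t

with penalized-spline covariate effects in X (random-effect wiggle
representation), a time-invariant spatial field w, AR1-correlated
spatiotemporal fields e_t, and an optional year random intercept b_t.
Fields live on a knot mesh (k-means or cutoff-thinned) with Matern
(nu = 1) covariance between knots, projected to observations by
barycentric interpolation — a predictive-process stand-in for the
SPDE/GMRF construction used by sdmTMB-style frameworks.

Estimation maximizes the Laplace-approximate marginal likelihood over
(beta, variance/correlation/dispersion parameters) with all random
effects integrated out; the inner problem is convex because the Tweedie
negative log-likelihood is convex in the log-mean for 1 < p < 2.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
from scipy.interpolate import BSpline
from scipy.optimize import minimize

from .grids import GridStack
from .mesh import KnotMesh, select_knots, select_knots_by_cutoff
from .synthetic import matern_correlation
from .tweedie import tweedie_deviance_weights, tweedie_logpdf

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "SDMFit",
    "R2Report",
    "fit",
    "predict",
    "check_convergence",
    "aic_select",
    "r2_decompose",
    "concurvity_screen",
    "tweedie_logpdf",
]

_P_LO, _P_HI = 1.01, 1.99
_ETA_CLIP = 30.0


# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class ModelSpec:
    """Structure of one candidate model.

    ``smooth_terms`` is a list of (covariate, basis dimension k) pairs;
    each smooth contributes a fixed linear column plus k - 2 penalized
    wiggle coefficients whose variance is estimated.  Exactly one of
    ``n_knots`` / ``cutoff_km`` may be set when any field is requested.
    """

    response: str = "nasc"
    smooth_terms: tuple[tuple[str, int], ...] = ()
    linear_terms: tuple[str, ...] = ()
    year_factor: bool = False
    year_random_intercept: bool = False
    include_spatial_field: bool = False
    include_spatiotemporal_ar1: bool = False
    n_knots: int | None = None
    cutoff_km: float | None = None
    range_km_init: float = 30.0
    name: str = "model"

    def __post_init__(self) -> None:
        for cov, k in self.smooth_terms:
            if k < 3:
                raise ValueError(f"smooth for {cov!r} needs basis dimension k >= 3")
        wants_mesh = self.include_spatial_field or self.include_spatiotemporal_ar1
        if wants_mesh and (self.n_knots is None) == (self.cutoff_km is None):
            raise ValueError("set exactly one of n_knots / cutoff_km when fields are on")


@dataclass
class _Smooth:
    """Penalized B-spline basis in its mixed-model reparametrization."""

    name: str
    k: int
    degree: int
    knots: np.ndarray  # full knot vector
    u_pen: np.ndarray  # (k, k-2) penalized-range transform, scaled
    x_lo: float
    x_hi: float
    x_mean: float

    @classmethod
    def build(cls, x: np.ndarray, name: str, k: int) -> "_Smooth":
        degree = min(3, k - 1)
        n_interior = k - degree - 1
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi <= lo:
            raise ValueError(f"covariate {name!r} is constant; cannot build a smooth")
        if n_interior > 0:
            qs = np.quantile(x, np.linspace(0, 1, n_interior + 2)[1:-1])
        else:
            qs = np.array([])
        t = np.r_[[lo] * (degree + 1), qs, [hi] * (degree + 1)]
        # second-difference penalty on the k coefficients
        d2 = np.diff(np.eye(k), n=2, axis=0)
        s_pen = d2.T @ d2
        evals, evecs = np.linalg.eigh(s_pen)
        pos = evals > 1e-10
        u_pen = evecs[:, pos] / np.sqrt(evals[pos])
        return cls(name, k, degree, t, u_pen, lo, hi, float(np.mean(x)))

    def design(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(fixed linear column, penalized wiggle design) at points x."""
        xc = np.clip(np.asarray(x, dtype=float), self.x_lo, self.x_hi)
        b = BSpline.design_matrix(xc, self.knots, self.degree).toarray()
        z = b @ self.u_pen
        return (np.asarray(x, dtype=float) - self.x_mean), z

    @property
    def rank(self) -> int:
        return self.u_pen.shape[1]


def _ar1_precision(t: int, rho: float) -> np.ndarray:
    """Precision of a unit-marginal-variance AR1 chain of length t."""
    q = np.zeros((t, t))
    if t == 1:
        q[0, 0] = 1.0
        return q
    idx = np.arange(t)
    q[idx, idx] = 1.0 + rho**2
    q[0, 0] = q[-1, -1] = 1.0
    q[idx[:-1], idx[1:]] = -rho
    q[idx[1:], idx[:-1]] = -rho
    return q / (1.0 - rho**2)


# ---------------------------------------------------------------------------
# design assembly


@dataclass
class _Design:
    """Everything needed to build X and the random-effect blocks for the
    training data or any prediction table."""

    spec: ModelSpec
    years: list[int]
    smooths: list[_Smooth]
    mesh: KnotMesh | None
    beta_names: list[str]
    corr_knots: np.ndarray | None = None  # cached knot distance matrix

    def fixed_matrix(self, tbl: pd.DataFrame) -> np.ndarray:
        cols = [np.ones(len(tbl))]
        if self.spec.year_factor:
            yr = tbl["year"].to_numpy()
            for y in self.years[1:]:
                cols.append((yr == y).astype(float))
        for name in self.spec.linear_terms:
            cols.append(tbl[name].to_numpy(dtype=float))
        for sm in self.smooths:
            lin, _ = sm.design(tbl[sm.name].to_numpy(dtype=float))
            cols.append(lin)
        return np.column_stack(cols)

    def random_blocks(self, tbl: pd.DataFrame) -> list[tuple[str, sp.csr_matrix]]:
        """Ordered (block name, design matrix) pairs; block order fixes
        the layout of the stacked random-effect vector."""
        n = len(tbl)
        t = len(self.years)
        blocks: list[tuple[str, sp.csr_matrix]] = []
        for sm in self.smooths:
            _, z = sm.design(tbl[sm.name].to_numpy(dtype=float))
            blocks.append((f"smooth:{sm.name}", sp.csr_matrix(z)))
        if self.spec.year_random_intercept:
            yr = tbl["year"].to_numpy()
            rows = np.arange(n)
            cols = np.array([self.years.index(y) for y in yr])
            z = sp.csr_matrix((np.ones(n), (rows, cols)), shape=(n, t))
            blocks.append(("year_intercept", z))
        if self.mesh is not None:
            a = self.mesh.interpolation_weights(tbl[["x_km", "y_km"]].to_numpy())
            if self.spec.include_spatial_field:
                blocks.append(("spatial", a))
            if self.spec.include_spatiotemporal_ar1:
                m = self.mesh.n_knots
                yr = tbl["year"].to_numpy()
                yi = np.array([self.years.index(y) for y in yr])
                a_coo = a.tocoo()
                cols = a_coo.col + yi[a_coo.row] * m
                z = sp.csr_matrix((a_coo.data, (a_coo.row, cols)), shape=(n, m * t))
                blocks.append(("spatiotemporal", z))
        return blocks


def _build_design(obs: pd.DataFrame, spec: ModelSpec, seed: int = 0) -> _Design:
    years = sorted(int(y) for y in obs["year"].unique()) if "year" in obs else [0]
    if spec.include_spatiotemporal_ar1 and len(years) < 2:
        raise ValueError("AR1 spatiotemporal fields need observations from >= 2 years")
    smooths = [
        _Smooth.build(obs[cov].to_numpy(dtype=float), cov, k) for cov, k in spec.smooth_terms
    ]
    mesh = None
    if spec.include_spatial_field or spec.include_spatiotemporal_ar1:
        coords = obs[["x_km", "y_km"]].to_numpy()
        if spec.n_knots is not None:
            mesh = select_knots(coords, spec.n_knots, seed=seed)
        else:
            mesh = select_knots_by_cutoff(coords, spec.cutoff_km)
        if mesh.n_knots < 3:
            raise ValueError("mesh is singular: fewer than 3 knots")
    beta_names = ["(intercept)"]
    if spec.year_factor:
        beta_names += [f"year_{y}" for y in years[1:]]
    beta_names += list(spec.linear_terms)
    beta_names += [f"{sm.name}_linear" for sm in smooths]
    design = _Design(spec, years, smooths, mesh, beta_names)
    if mesh is not None:
        kc = mesh.knot_coords
        design.corr_knots = np.linalg.norm(kc[:, None, :] - kc[None, :, :], axis=-1)
    return design


# ---------------------------------------------------------------------------
# parameter transforms


def _theta_layout(spec: ModelSpec, smooths: list[_Smooth]) -> list[str]:
    names = [f"log_sigma_smooth:{sm.name}" for sm in smooths]
    if spec.year_random_intercept:
        names.append("log_sigma_year")
    if spec.include_spatial_field:
        names.append("log_sigma_spatial")
    if spec.include_spatiotemporal_ar1:
        names += ["log_sigma_st", "atanh_rho"]
    if spec.include_spatial_field or spec.include_spatiotemporal_ar1:
        names.append("log_range")
    names += ["logit_p", "log_phi"]
    return names


def _p_from_logit(t: float) -> float:
    return _P_LO + (_P_HI - _P_LO) / (1.0 + np.exp(-t))


def _logit_from_p(p: float) -> float:
    frac = (p - _P_LO) / (_P_HI - _P_LO)
    frac = min(max(frac, 1e-6), 1 - 1e-6)
    return float(np.log(frac / (1 - frac)))


_NATURAL_TRANSFORMS = {
    "log": np.exp,
    "atanh": np.tanh,
    "logit": _p_from_logit,
}


def _natural(name: str, value: float) -> float:
    kind = name.split("_", 1)[0]
    return float(_NATURAL_TRANSFORMS[kind](value))


# ---------------------------------------------------------------------------
# the Laplace objective


class _LaplaceNLL:
    """Negative Laplace-approximate marginal log-likelihood.

    psi = [beta, theta]; random effects are profiled out by an inner
    Newton solve (convex).  The inner mode is cached and warm-started
    between evaluations, which makes finite-difference outer gradients
    cheap.
    """

    def __init__(self, y: np.ndarray, design: _Design, tbl: pd.DataFrame):
        self.y = y
        self.design = design
        self.spec = design.spec
        self.x = design.fixed_matrix(tbl)
        self.blocks = design.random_blocks(tbl)
        self.block_dims = [z.shape[1] for _, z in self.blocks]
        self.d = int(sum(self.block_dims))
        self.z = sp.hstack([z for _, z in self.blocks]).tocsr() if self.blocks else None
        self.theta_names = _theta_layout(self.spec, design.smooths)
        self.n_beta = self.x.shape[1]
        self._u_cache = np.zeros(self.d)

    # -- precision assembly -------------------------------------------------
    def _precision(self, theta: dict[str, float]) -> tuple[np.ndarray, float]:
        """(dense Q over all blocks, log det Q) for natural-scale theta."""
        q = np.zeros((self.d, self.d))
        logdet = 0.0
        off = 0
        t_years = len(self.design.years)
        corr = None
        corr_logdet = corr_inv = None
        if self.design.corr_knots is not None and (
            self.spec.include_spatial_field or self.spec.include_spatiotemporal_ar1
        ):
            corr = matern_correlation(self.design.corr_knots, theta["range_km"])
            corr[np.diag_indices_from(corr)] += 1e-6
            cf = sla.cho_factor(corr, lower=True)
            corr_logdet = 2.0 * np.log(np.diag(cf[0])).sum()
            corr_inv = sla.cho_solve(cf, np.eye(corr.shape[0]))
        for (name, _), dim in zip(self.blocks, self.block_dims):
            sl = slice(off, off + dim)
            if name.startswith("smooth:"):
                s2 = theta[f"sigma_smooth:{name[7:]}"] ** 2
                q[sl, sl] = np.eye(dim) / s2
                logdet += -dim * np.log(s2)
            elif name == "year_intercept":
                s2 = theta["sigma_year"] ** 2
                q[sl, sl] = np.eye(dim) / s2
                logdet += -dim * np.log(s2)
            elif name == "spatial":
                s2 = theta["sigma_spatial"] ** 2
                q[sl, sl] = corr_inv / s2
                logdet += -dim * np.log(s2) - corr_logdet
            elif name == "spatiotemporal":
                s2 = theta["sigma_st"] ** 2
                rho = theta["rho"]
                qt = _ar1_precision(t_years, rho)
                m = dim // t_years
                q[sl, sl] = np.kron(qt, corr_inv) / s2
                logdet += (
                    -dim * np.log(s2)
                    - t_years * corr_logdet
                    - m * (t_years - 1) * np.log(1.0 - rho**2)
                )
            off += dim
        return q, logdet

    def natural_theta(self, theta_vec: np.ndarray) -> dict[str, float]:
        out: dict[str, float] = {}
        for name, val in zip(self.theta_names, theta_vec):
            if name.startswith("log_sigma_smooth:"):
                out[f"sigma_smooth:{name[17:]}"] = float(np.exp(val))
            elif name == "log_sigma_year":
                out["sigma_year"] = float(np.exp(val))
            elif name == "log_sigma_spatial":
                out["sigma_spatial"] = float(np.exp(val))
            elif name == "log_sigma_st":
                out["sigma_st"] = float(np.exp(val))
            elif name == "atanh_rho":
                out["rho"] = float(np.tanh(val))
            elif name == "log_range":
                out["range_km"] = float(np.exp(val))
            elif name == "logit_p":
                out["p"] = _p_from_logit(val)
            elif name == "log_phi":
                out["phi"] = float(np.exp(val))
        return out

    # -- inner problem ------------------------------------------------------
    def _eta(self, beta: np.ndarray, u: np.ndarray) -> np.ndarray:
        eta = self.x @ beta
        if self.z is not None and self.d:
            eta = eta + self.z @ u
        return np.clip(eta, -_ETA_CLIP, _ETA_CLIP)

    def _neg_loglik_obs(self, eta: np.ndarray, p: float, phi: float) -> float:
        mu = np.exp(eta)
        return -float(np.sum(tweedie_logpdf(self.y, mu, p, phi)))

    def _inner_mode(
        self, beta: np.ndarray, theta: dict[str, float], q: np.ndarray
    ) -> tuple[np.ndarray, float, np.ndarray]:
        """Newton solve for the random-effect mode; returns
        (u_hat, g(u_hat), cholesky factor of H)."""
        p, phi = theta["p"], theta["phi"]
        u = self._u_cache.copy()

        def g_val(u_):
            return self._neg_loglik_obs(self._eta(beta, u_), p, phi) + 0.5 * u_ @ q @ u_

        g = g_val(u)
        chol = None
        for _ in range(100):
            eta = self._eta(beta, u)
            mu = np.exp(eta)
            score, _ = tweedie_deviance_weights(self.y, mu, p, phi)
            # true negative second derivative wrt eta (nonnegative for 1<p<2)
            w = ((2.0 - p) * mu ** (2.0 - p) + (p - 1.0) * self.y * mu ** (1.0 - p)) / phi
            grad = -(self.z.T @ score) + q @ u
            zw = self.z.multiply(w[:, None]).tocsr()
            h = (self.z.T @ zw).toarray() + q
            try:
                chol = sla.cho_factor(h, lower=True)
            except sla.LinAlgError:
                h += 1e-8 * np.eye(self.d)
                chol = sla.cho_factor(h, lower=True)
            if np.max(np.abs(grad)) < 1e-8:
                break
            step = -sla.cho_solve(chol, grad)
            alpha, g_new = 1.0, g
            for _ in range(30):
                g_new = g_val(u + alpha * step)
                if g_new <= g + 1e-12:
                    break
                alpha *= 0.5
            if g_new > g:
                break  # no descent possible at machine precision
            u = u + alpha * step
            g = g_new
        self._u_cache = u
        return u, g, chol

    # -- outer objective ----------------------------------------------------
    def value(self, psi: np.ndarray) -> float:
        beta = psi[: self.n_beta]
        theta = self.natural_theta(psi[self.n_beta :])
        if self.d == 0:
            return self._neg_loglik_obs(self._eta(beta, np.zeros(0)), theta["p"], theta["phi"])
        q, logdet_q = self._precision(theta)
        u, g, chol = self._inner_mode(beta, theta, q)
        logdet_h = 2.0 * np.log(np.diag(chol[0])).sum()
        return g - 0.5 * logdet_q + 0.5 * logdet_h

    def mode(self, psi: np.ndarray) -> np.ndarray:
        beta = psi[: self.n_beta]
        theta = self.natural_theta(psi[self.n_beta :])
        if self.d == 0:
            return np.zeros(0)
        q, _ = self._precision(theta)
        u, _, _ = self._inner_mode(beta, theta, q)
        return u


# ---------------------------------------------------------------------------
# fit result


@dataclass
class SDMFit:
    spec: ModelSpec
    design: _Design = dc_field(repr=False, default=None)
    beta: np.ndarray = None
    beta_names: list[str] = None
    theta: dict[str, float] = None
    u_blocks: dict[str, np.ndarray] = dc_field(repr=False, default=None)
    loglik: float = np.nan
    aic: float = np.nan
    n_params: int = 0
    gradient_max: float = np.nan
    hessian_pd: bool = False
    converged: bool = False
    psi_hat: np.ndarray = dc_field(repr=False, default=None)
    psi_names: list[str] = None
    psi_cov: np.ndarray | None = dc_field(repr=False, default=None)
    n_obs: int = 0

    # convenient natural-scale accessors -----------------------------------
    @property
    def tweedie_p(self) -> float:
        return self.theta["p"]

    @property
    def tweedie_phi(self) -> float:
        return self.theta["phi"]

    @property
    def rho(self) -> float:
        return self.theta.get("rho", np.nan)

    @property
    def sigma_spatial(self) -> float:
        return self.theta.get("sigma_spatial", np.nan)

    @property
    def sigma_st(self) -> float:
        return self.theta.get("sigma_st", np.nan)

    @property
    def sigma_year(self) -> float:
        return self.theta.get("sigma_year", np.nan)

    @property
    def range_km(self) -> float:
        return self.theta.get("range_km", np.nan)

    @property
    def mu_intercept(self) -> float:
        return float(np.exp(self.beta[0]))

    def field_sds(self) -> dict[str, float]:
        return {
            k: v
            for k, v in self.theta.items()
            if k in ("sigma_spatial", "sigma_st")
        }

    def wald_interval(self, param: str, level: float = 0.95) -> tuple[float, float]:
        """CI for a natural-scale parameter by transforming the Wald
        interval of its unconstrained transform (monotone maps)."""
        if self.psi_cov is None:
            raise ValueError("fit was run without standard errors")
        from scipy.stats import norm

        idx = self.psi_names.index(_transform_name(param, self.psi_names))
        se = float(np.sqrt(max(self.psi_cov[idx, idx], 0.0)))
        zq = norm.ppf(0.5 + level / 2)
        lo_t, hi_t = self.psi_hat[idx] - zq * se, self.psi_hat[idx] + zq * se
        name = self.psi_names[idx]
        lo, hi = _natural_of(name, lo_t), _natural_of(name, hi_t)
        return (min(lo, hi), max(lo, hi))


def _transform_name(param: str, psi_names: list[str]) -> str:
    aliases = {
        "p": "logit_p",
        "phi": "log_phi",
        "rho": "atanh_rho",
        "sigma_st": "log_sigma_st",
        "sigma_spatial": "log_sigma_spatial",
        "sigma_year": "log_sigma_year",
        "range_km": "log_range",
    }
    name = aliases.get(param, param)
    if name not in psi_names:
        raise KeyError(f"unknown parameter {param!r}; have {psi_names}")
    return name


def _natural_of(name: str, value: float) -> float:
    if name == "logit_p":
        return _p_from_logit(value)
    if name == "atanh_rho":
        return float(np.tanh(value))
    if name.startswith("log_"):
        return float(np.exp(value))
    return float(value)  # fixed-effect coefficient


# ---------------------------------------------------------------------------
# fitting


def fit(
    obs: pd.DataFrame,
    spec: ModelSpec,
    seed: int = 0,
    compute_se: bool = False,
    maxiter: int = 300,
) -> SDMFit:
    """Maximum Laplace-approximate marginal likelihood fit.

    Non-convergence (fixed-effect gradient >= 0.01 or a non-PD outer
    Hessian when requested) is flagged on the returned fit rather than
    raised; degenerate fields (SD < 0.01) are caught downstream by
    :func:`check_convergence`.
    """
    y = obs[spec.response].to_numpy(dtype=float)
    if np.any(y < 0):
        raise ValueError("response must be nonnegative")
    design = _build_design(obs, spec, seed=seed)
    nll = _LaplaceNLL(y, design, obs)

    psi0 = np.zeros(nll.n_beta + len(nll.theta_names))
    psi0[0] = np.log(max(y.mean(), 1e-3))
    range_init = spec.range_km_init
    bounds: list[tuple[float | None, float | None]] = [(None, None)] * psi0.size
    if design.mesh is not None and "log_range" in nll.theta_names:
        # a correlation range shorter than the knot spacing lets the
        # mesh degenerate into iid per-knot noise; bound it below by the
        # median nearest-neighbor spacing (predictive-process validity)
        from scipy.spatial import cKDTree

        d, _ = cKDTree(design.mesh.knot_coords).query(design.mesh.knot_coords, k=2)
        r_min = max(float(np.median(d[:, 1])), 1e-3)
        span = np.ptp(design.mesh.knot_coords, axis=0).max()
        r_max = max(10.0 * span, 2 * r_min)
        range_init = min(max(range_init, 1.05 * r_min), 0.95 * r_max)
        bounds[nll.n_beta + nll.theta_names.index("log_range")] = (
            np.log(r_min),
            np.log(r_max),
        )
    theta0 = {
        "logit_p": _logit_from_p(1.5),
        "log_phi": 0.0,
        "log_range": np.log(range_init),
    }
    for i, name in enumerate(nll.theta_names):
        psi0[nll.n_beta + i] = theta0.get(name, np.log(0.5))

    res = minimize(
        nll.value,
        psi0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-6, "eps": 1e-6},
    )
    # polish: restarting clears the quasi-Newton history and drives the
    # fixed-effect gradient below the 0.01 convergence threshold
    res2 = minimize(
        nll.value,
        res.x,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 100, "ftol": 1e-14, "gtol": 1e-5, "eps": 1e-6},
    )
    if res2.fun <= res.fun:
        res = res2
    psi = res.x
    theta = nll.natural_theta(psi[nll.n_beta :])
    u = nll.mode(psi)
    u_blocks: dict[str, np.ndarray] = {}
    off = 0
    for (name, _), dim in zip(nll.blocks, nll.block_dims):
        u_blocks[name] = u[off : off + dim]
        off += dim

    # gradient with respect to fixed effects, central differences
    grad_beta = np.empty(nll.n_beta)
    h = 1e-5
    for j in range(nll.n_beta):
        e = np.zeros_like(psi)
        e[j] = h
        grad_beta[j] = (nll.value(psi + e) - nll.value(psi - e)) / (2 * h)
    gradient_max = float(np.max(np.abs(grad_beta)))

    psi_names = list(design.beta_names) + list(nll.theta_names)
    n_params = len(psi_names)
    loglik = -float(res.fun)
    fit_out = SDMFit(
        spec=spec,
        design=design,
        beta=psi[: nll.n_beta].copy(),
        beta_names=list(design.beta_names),
        theta=theta,
        u_blocks=u_blocks,
        loglik=loglik,
        aic=-2.0 * loglik + 2.0 * n_params,
        n_params=n_params,
        gradient_max=gradient_max,
        hessian_pd=True,
        converged=bool(res.success) and gradient_max < 0.01,
        psi_hat=psi.copy(),
        psi_names=psi_names,
        n_obs=len(obs),
    )

    if compute_se:
        hess = _fd_hessian(nll.value, psi)
        evals = np.linalg.eigvalsh(hess)
        fit_out.hessian_pd = bool(evals.min() > 0)
        if fit_out.hessian_pd:
            fit_out.psi_cov = np.linalg.inv(hess)
        else:
            # pseudo-inverse keeps intervals usable on flat directions
            fit_out.psi_cov = np.linalg.pinv(hess)
        fit_out.converged = fit_out.converged and fit_out.hessian_pd
    return fit_out


def _fd_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    k = x.size
    hess = np.empty((k, k))
    f0 = f(x)
    fp = np.empty(k)
    for i in range(k):
        e = np.zeros(k)
        e[i] = h
        fp[i] = f(x + e)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h
        hess[i, i] = (f(x + 2 * ei) - 2 * fp[i] + f0) / h**2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h
            fij = f(x + ei + ej)
            hess[i, j] = hess[j, i] = (fij - fp[i] - fp[j] + f0) / h**2
    return hess


# ---------------------------------------------------------------------------
# diagnostics / selection


def check_convergence(fit_result: SDMFit) -> dict:
    """The three convergence checks: fixed-effect gradient < 0.01,
    positive-definite Hessian, and no degenerate field (SD < 0.01)."""
    reasons = []
    if not (fit_result.gradient_max < 0.01):
        reasons.append("gradient")
    if not fit_result.hessian_pd:
        reasons.append("hessian")
    for name, sd in fit_result.field_sds().items():
        if sd < 0.01:
            reasons.append(f"degenerate field ({name})")
    return {"passed": not reasons, "reasons": reasons, "gradient_max": fit_result.gradient_max}


def aic_select(candidates: list[SDMFit]) -> pd.DataFrame:
    """Rank converged fits by AIC; delta relative to the best.

    Ties break by fewer parameters, then by spec name.  Non-converged
    candidates are excluded with a warning.
    """
    rows = []
    for f in candidates:
        if not check_convergence(f)["passed"]:
            warnings.warn(f"excluding non-converged candidate {f.spec.name!r} from AIC ranking")
            continue
        rows.append(
            {"name": f.spec.name, "aic": f.aic, "n_params": f.n_params, "loglik": f.loglik}
        )
    if not rows:
        raise ValueError("no converged candidates")
    tbl = pd.DataFrame(rows).sort_values(["aic", "n_params", "name"]).reset_index(drop=True)
    tbl["delta_aic"] = tbl["aic"] - tbl["aic"].iloc[0]
    return tbl


def concurvity_screen(covariate_table: pd.DataFrame, r2_threshold: float = 0.7) -> list[tuple[str, ...]]:
    """Maximal covariate subsets whose all pairwise r^2 stay below the
    threshold.  Constant covariates are excluded with a warning."""
    cols = list(covariate_table.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 covariates")
    usable = []
    for c in cols:
        if covariate_table[c].std() == 0:
            warnings.warn(f"covariate {c!r} is constant; correlation undefined, excluded")
        else:
            usable.append(c)
    r = covariate_table[usable].corr().to_numpy() ** 2
    n = len(usable)
    compatible = {(i, j) for i in range(n) for j in range(n) if i != j and r[i, j] < r2_threshold}

    maximal: list[tuple[str, ...]] = []
    # enumerate maximal admissible subsets (covariate counts are small)
    for size in range(n, 0, -1):
        for combo in itertools.combinations(range(n), size):
            ok = all((i, j) in compatible for i, j in itertools.combinations(combo, 2))
            if ok and not any(set(combo) <= set(m) for m in maximal):
                maximal.append(combo)
    return [tuple(usable[i] for i in combo) for combo in maximal]


# ---------------------------------------------------------------------------
# prediction / r2


def _predict_table(fit_result: SDMFit, tbl: pd.DataFrame) -> np.ndarray:
    """Link-scale prediction for a table with x_km, y_km, year and all
    covariates the spec references."""
    design = fit_result.design
    for cov, _ in design.spec.smooth_terms:
        if cov not in tbl:
            raise KeyError(f"missing covariate {cov!r} in prediction table")
    for cov in design.spec.linear_terms:
        if cov not in tbl:
            raise KeyError(f"missing covariate {cov!r} in prediction table")
    eta = design.fixed_matrix(tbl) @ fit_result.beta
    for name, z in design.random_blocks(tbl):
        eta = eta + z @ fit_result.u_blocks[name]
    return eta


def predict(fit_result: SDMFit, grid: GridStack, years=None) -> GridStack:
    """Predict over a covariate grid stack for the requested years.

    Returns a stack with ``link`` and ``response`` layers; response =
    exp(link).  Raises KeyError naming any missing covariate layer.
    """
    if years is None:
        years = [y for y in grid.years if y in fit_result.design.years]
    years = [int(y) for y in years]
    spec_cov = [c for c, _ in fit_result.spec.smooth_terms] + list(fit_result.spec.linear_terms)
    for cov in spec_cov:
        if cov not in grid.layers:
            raise KeyError(f"missing covariate layer {cov!r} in prediction grid")
    centers = grid.spec.cell_centers()
    shape = grid.spec.shape
    link = np.empty((len(years), *shape))
    for t, yr in enumerate(years):
        tbl = pd.DataFrame(
            {"x_km": centers[:, 0], "y_km": centers[:, 1], "year": yr}
        )
        for cov in spec_cov:
            tbl[cov] = grid.data[cov][grid.year_index(yr)].ravel()
        link[t] = _predict_table(fit_result, tbl).reshape(shape)
    return GridStack(
        grid.spec, years, {"link": link, "response": np.exp(link)}
    )


def fitted_values(fit_result: SDMFit, obs: pd.DataFrame, conditional: bool = True) -> np.ndarray:
    """Response-scale fitted values at the observations; with
    ``conditional=False`` the random fields (and year random intercept)
    are zeroed, leaving the covariate-only (marginal) prediction."""
    design = fit_result.design
    eta = design.fixed_matrix(obs) @ fit_result.beta
    for name, z in design.random_blocks(obs):
        if not conditional and name in ("spatial", "spatiotemporal", "year_intercept"):
            continue
        eta = eta + z @ fit_result.u_blocks[name]
    return np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))


@dataclass
class R2Report:
    conditional_r2: float
    marginal_r2: float
    spatiotemporal_r2: float


def r2_decompose(fit_result: SDMFit, obs: pd.DataFrame, offset: float = 0.01) -> R2Report:
    """r^2 of observed vs predicted density, both as log(x + offset).

    Conditional uses the full prediction; marginal zeroes the random
    fields; the spatiotemporal share is their difference.
    """
    y = obs[fit_result.spec.response].to_numpy(dtype=float)
    if np.var(y) == 0:
        raise ValueError("zero-variance observations; r^2 undefined")
    ly = np.log(y + offset)
    cond = _log_r2(ly, np.log(fitted_values(fit_result, obs, True) + offset))
    marg = _log_r2(ly, np.log(fitted_values(fit_result, obs, False) + offset))
    return R2Report(cond, marg, max(cond - marg, 0.0))


def _log_r2(a: np.ndarray, b: np.ndarray) -> float:
    if np.var(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)
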