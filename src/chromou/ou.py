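"""Ornstein-Uhlenbeck and Brownian-motion trait models on a phylogeny.

The response (log chromosome number) is modeled as an OU process pulled
toward primary optima with selection strength ``alpha``; the two reported
natural parameters are the phylogenetic half-life ``t_half = ln2 / alpha``
(time to lose half the ancestral influence, in tree heights) and the
stationary variance ``v_y = sigma_y^2 / (2 alpha)``.  On a unit-height
ultrametric tree the tip covariance is

    V_ij = v_y * (1 - exp(-2 alpha s_ij)) * exp(-alpha d_ij)

with ``s`` the shared time to the MRCA and ``d`` the patristic distance;
``alpha -> 0`` with ``sigma^2 = 2 alpha v_y`` held fixed recovers the BM
covariance ``sigma^2 * s``.  Per-species observation variance is added to
the diagonal.

Fitting follows the classic two-level scheme: regression coefficients by
generalized least squares at fixed (t_half, v_y), and (t_half, v_y) by
profile maximum likelihood — a log-spaced grid over t_half with the
stationary variance maximized at each grid point (closed form when there
is no observation variance, bounded 1-D search otherwise).  The support
region is the set of half-lives within two log-likelihood units of the
maximum; estimates sitting at the top of the grid are reported as
infinite (Brownian-like).

For a continuous predictor the design column is attenuated by
``rho(alpha) = 1 - (1 - exp(-alpha T)) / (alpha T)``; the *optimal*
regression slope (evolution free of ancestral influence) is the fitted
coefficient, and the *phylogenetic* (across-species) slope is ``rho``
times it, hence never steeper.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import linalg, optimize

from .phylo import Phylogeny, TimeMatrices, time_matrices
from .regimes import RegimePainting, regime_weights
from .selection import aicc as _aicc

__all__ = [
    "GridConfig",
    "OUParams",
    "ModelSpec",
    "OUFitResult",
    "ou_covariance",
    "bm_covariance",
    "add_observation_variance",
    "rho_factor",
    "design_matrix",
    "gls_fit",
    "fit_model",
    "r_squared",
]

LN2 = math.log(2.0)
_LOG2PI = math.log(2.0 * math.pi)

MODEL_KINDS = ("intercept_ou", "brownian", "continuous_ou", "categorical_ou", "ancova_ou")


@dataclass(frozen=True)
class GridConfig:
    """Log-spaced profile grid over the phylogenetic half-life.

    Defaults: 64 points in [0.01, 100] tree heights.  The stationary
    variance is maximized at each grid point within
    [1e-8, ``v_max_factor`` * var(y)].
    """

    n_points: int = 64
    t_half_min: float = 0.01
    t_half_max: float = 100.0
    v_max_factor: float = 100.0
    v_tol: float = 1e-8

    def values(self) -> np.ndarray:
        if not (0 < self.t_half_min < self.t_half_max):
            raise ValueError("need 0 < t_half_min < t_half_max")
        return np.geomspace(self.t_half_min, self.t_half_max, self.n_points)


@dataclass(frozen=True)
class OUParams:
    """Half-life / stationary-variance parameterization of the OU process."""

    t_half: float
    v_y: float
    sigma2_bm: Optional[float] = None

    @property
    def alpha(self) -> float:
        return LN2 / self.t_half

    @property
    def sigma2_drift(self) -> float:
        """sigma_y^2 = 2 * alpha * v_y."""
        return 2.0 * self.alpha * self.v_y


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: model kind, predictor name(s), response name."""

    kind: str
    predictors: tuple = ()
    response: str = "2n"

    def __post_init__(self):
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind: {self.kind!r}")
        if self.kind == "continuous_ou" and len(self.predictors) != 1:
            raise ValueError("continuous_ou takes exactly one predictor")
        if self.kind == "categorical_ou" and len(self.predictors) != 1:
            raise ValueError("categorical_ou takes exactly one painted predictor")

    @property
    def name(self) -> str:
        if self.kind == "intercept_ou":
            return "(single-equilibrium O-U)"
        if self.kind == "brownian":
            return "(Brownian motion)"
        return "+".join(self.predictors)


@dataclass
class OUFitResult:
    """A fitted model: parameters, support region, coefficients, fit stats."""

    spec: ModelSpec
    t_half: float                      # np.inf when the MLE sits at the grid top
    v_y: Optional[float]
    sigma2_bm: Optional[float]
    support_lo: Optional[float]
    support_hi: Optional[float]        # np.inf when the region touches the grid top
    coefficients: list                 # (name, estimate, SE) triples
    rho: Optional[float]
    b_optimal: Optional[float]
    b_phylogenetic: Optional[float]
    loglik: float
    n: int
    k_params: int
    aicc: float
    r2: float
    grid: Optional[GridConfig] = None
    grid_t_half: Optional[np.ndarray] = None
    grid_loglik: Optional[np.ndarray] = None
    boundary_warning: Optional[str] = None

    def to_dict(self) -> dict:
        """Flat serializable summary (Table-style column vocabulary)."""
        def _num(x):
            if x is None:
                return None
            return "inf" if np.isinf(x) else float(x)

        d = {
            "model": self.spec.name,
            "kind": self.spec.kind,
            "response": self.spec.response,
            "n": self.n,
            "t_half": _num(self.t_half),
            "support_lo": _num(self.support_lo),
            "support_hi": _num(self.support_hi),
            "v_y": _num(self.v_y),
            "sigma2_bm": _num(self.sigma2_bm),
            "rho": _num(self.rho),
            "b_optimal": _num(self.b_optimal),
            "b_phylogenetic": _num(self.b_phylogenetic),
            "loglik": float(self.loglik),
            "k_params": self.k_params,
            "AICc": float(self.aicc),
            "R2": float(self.r2),
        }
        for name, est, se in self.coefficients:
            d[name] = float(est)
            d[f"{name}_se"] = float(se)
        return d

    def format_t_half(self) -> str:
        """Half-life with support region, table style (inf prints as the symbol)."""
        if self.t_half is None:
            return "-"
        t = "∞" if np.isinf(self.t_half) else f"{self.t_half:.2f}"
        if self.support_lo is None:
            return t
        hi = "∞" if np.isinf(self.support_hi) else f"{self.support_hi:.2f}"
        return f"{t} ({self.support_lo:.2f}-{hi})"


# ---------------------------------------------------------------------------
# covariances

def ou_covariance(tm: TimeMatrices, t_half: float, v_y: float) -> np.ndarray:
    """Stationary OU tip covariance on an ultrametric tree."""
    if not (np.isfinite(t_half) and t_half > 0):
        raise ValueError("t_half must be positive and finite")
    if not (np.isfinite(v_y) and v_y > 0):
        raise ValueError("v_y must be positive")
    alpha = LN2 / t_half
    if not np.isfinite(alpha):
        raise ValueError("non-finite alpha")
    return v_y * _ou_correlation(tm, alpha)


def _ou_correlation(tm: TimeMatrices, alpha: float) -> np.ndarray:
    """OU covariance at v_y = 1 (pure correlation-structure factor)."""
    with np.errstate(under="ignore"):
        A = -np.expm1(-2.0 * alpha * tm.shared_time) * np.exp(-alpha * tm.distance)
    return A


def bm_covariance(tm: TimeMatrices, sigma2: float) -> np.ndarray:
    """Brownian-motion tip covariance sigma^2 * shared_time."""
    if not (np.isfinite(sigma2) and sigma2 > 0):
        raise ValueError("sigma2 must be positive")
    return sigma2 * tm.shared_time


def add_observation_variance(V: np.ndarray, me: Sequence[float]) -> np.ndarray:
    """Add per-tip observation variance to the model covariance diagonal."""
    me = np.asarray(me, dtype=float)
    if np.any(me < 0):
        raise ValueError("observation variances must be non-negative")
    if me.shape != (V.shape[0],):
        raise ValueError("me length does not match covariance dimension")
    return V + np.diag(me)


def rho_factor(alpha: float, T: float = 1.0) -> float:
    """Attenuation of the optimal slope into the phylogenetic slope.

    rho = 1 - (1 - exp(-alpha T)) / (alpha T); strictly increasing in
    alpha, -> 0 as alpha -> 0 (pure inertia) and -> 1 as alpha -> inf
    (instant adaptation).
    """
    if not (np.isfinite(alpha) and alpha > 0):
        raise ValueError("alpha must be positive")
    aT = alpha * T
    return float(1.0 + np.expm1(-aT) / aT)


# ---------------------------------------------------------------------------
# design and GLS

def design_matrix(
    spec: ModelSpec,
    alpha: Optional[float],
    tree: Optional[Phylogeny] = None,
    painting: Optional[RegimePainting] = None,
    predictor: Optional[np.ndarray] = None,
    n: Optional[int] = None,
) -> np.ndarray:
    """Design matrix for a model at selection strength ``alpha``.

    intercept/BM: a column of ones.  Continuous: ``[1, rho(alpha) * x]``.
    Categorical: the regime weight matrix ``W(alpha)``.  ANCOVA:
    ``[W(alpha), rho(alpha) * x]``.
    """
    if spec.kind in ("intercept_ou", "brownian"):
        if n is None:
            n = tree.n_tips
        return np.ones((n, 1))
    if spec.kind == "continuous_ou":
        x = np.asarray(predictor, dtype=float)
        if n is not None and len(x) != n:
            raise ValueError("predictor length mismatch")
        return np.column_stack([np.ones(len(x)), rho_factor(alpha) * x])
    W = regime_weights(painting, tree, alpha).W
    if spec.kind == "categorical_ou":
        return W
    # ancova_ou
    x = np.asarray(predictor, dtype=float)
    if len(x) != W.shape[0]:
        raise ValueError("predictor length mismatch")
    return np.column_stack([W, rho_factor(alpha) * x])


def _coef_names(spec: ModelSpec, painting: Optional[RegimePainting]) -> list:
    if spec.kind in ("intercept_ou", "brownian"):
        return ["intercept"]
    if spec.kind == "continuous_ou":
        return ["intercept", f"slope_{spec.predictors[0]}"]
    names = [f"theta_{s}" for s in painting.states]
    if spec.kind == "ancova_ou":
        names.append(f"slope_{spec.predictors[-1]}")
    return names


def gls_fit(X: np.ndarray, y: np.ndarray, V: np.ndarray):
    """Generalized least squares with a Gaussian profile log-likelihood.

    Returns ``(beta, se, loglik)`` where ``beta = (X' V^-1 X)^-1 X' V^-1 y``
    and the log-likelihood is the multivariate normal density of the
    residuals under covariance ``V``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    try:
        c_and_low = linalg.cho_factor(V, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError("covariance matrix is not positive definite") from exc
    L = c_and_low[0]
    Xw = linalg.solve_triangular(L, X, lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)
    XtX = Xw.T @ Xw
    # rank check with named collinear columns
    _, R, piv = linalg.qr(Xw, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(Xw.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    if diag.size and diag[-1] <= tol:
        bad = sorted(int(piv[k]) for k in range(len(diag)) if diag[k] <= tol)
        raise ValueError(f"design matrix is rank deficient; collinear column(s): {bad}")
    beta = linalg.solve(XtX, Xw.T @ yw, assume_a="pos")
    r = yw - Xw @ beta
    q = float(r @ r)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    loglik = -0.5 * (n * _LOG2PI + logdet + q)
    cov = linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    return beta, se, loglik


def _profile_point(A, X, y, me, v_bounds, v_tol):
    """Profile log-likelihood over v_y at one correlation structure A.

    With no observation variance the profile is available in closed form
    (v_hat = r' A^-1 r / n); otherwise a bounded Brent search is used.
    Returns (loglik, v_hat) or (-inf, nan) if A is numerically singular.
    """
    n = len(y)
    if me is None or not np.any(me):
        try:
            L = linalg.cho_factor(A, lower=True)[0]
        except linalg.LinAlgError:
            return -np.inf, np.nan
        Xw = linalg.solve_triangular(L, X, lower=True)
        yw = linalg.solve_triangular(L, y, lower=True)
        beta, *_ = linalg.lstsq(Xw, yw)
        r = yw - Xw @ beta
        q = float(r @ r)
        if q <= 0:
            return -np.inf, np.nan
        v = max(q / n, 1e-300)
        logdetA = 2.0 * float(np.sum(np.log(np.diag(L))))
        ll = -0.5 * (n * _LOG2PI + n * math.log(v) + logdetA + n)
        return ll, v

    def negll(v):
        V = v * A + np.diag(me)
        try:
            L = linalg.cho_factor(V, lower=True)[0]
        except linalg.LinAlgError:
            return 1e300
        Xw = linalg.solve_triangular(L, X, lower=True)
        yw = linalg.solve_triangular(L, y, lower=True)
        beta, *_ = linalg.lstsq(Xw, yw)
        r = yw - Xw @ beta
        q = float(r @ r)
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        return 0.5 * (n * _LOG2PI + logdet + q)

    res = optimize.minimize_scalar(
        negll, bounds=v_bounds, method="bounded", options={"xatol": v_tol}
    )
    return -float(res.fun), float(res.x)


def _final_fit(A_or_V, X, y, me, v_hat, is_bm=False):
    """Coefficients and SEs at the maximized variance parameters."""
    V = A_or_V if is_bm else v_hat * A_or_V
    if me is not None and np.any(me):
        V = V + np.diag(np.asarray(me, dtype=float))
    return gls_fit(X, y, V), V


def r_squared(X: np.ndarray, y: np.ndarray, V: np.ndarray) -> float:
    """GLS R^2 against an intercept-only null using the model's own V.

    R^2 = 1 - (r' V^-1 r) / (r0' V^-1 r0), clipped to [0, 1].
    """
    L = linalg.cho_factor(V, lower=True)[0]
    yw = linalg.solve_triangular(L, y, lower=True)
    Xw = linalg.solve_triangular(L, np.asarray(X, dtype=float), lower=True)
    ones_w = linalg.solve_triangular(L, np.ones(len(y)), lower=True)
    beta, *_ = linalg.lstsq(Xw, yw)
    q = float(np.sum((yw - Xw @ beta) ** 2))
    b0 = float(ones_w @ yw) / float(ones_w @ ones_w)
    q0 = float(np.sum((yw - ones_w * b0) ** 2))
    if q0 <= 1e-300:
        raise ValueError("degenerate null residuals: response has no GLS variance")
    return float(np.clip(1.0 - q / q0, 0.0, 1.0))


# ---------------------------------------------------------------------------
# full model fit

def fit_model(
    tree: Phylogeny,
    y: np.ndarray,
    me: Optional[np.ndarray],
    spec: ModelSpec,
    painting: Optional[RegimePainting] = None,
    predictor: Optional[np.ndarray] = None,
    grid: GridConfig = GridConfig(),
    tm: Optional[TimeMatrices] = None,
) -> OUFitResult:
    """Maximum-likelihood fit of one model on a unit-height tree.

    ``y`` and ``me`` are aligned with ``tree.tip_labels``.  OU-family models
    profile the likelihood over the half-life grid; the Brownian model
    maximizes over its rate directly.  A half-life whose MLE sits at the
    top of the grid is reported as infinite; a support region touching the
    grid top gets an infinite upper bound; an MLE at the *bottom* of the
    grid is flagged in ``boundary_warning``.
    """
    n = tree.n_tips
    if n < 3:
        raise ValueError("need at least 3 tips to fit a model")
    tree.assert_ultrametric()
    if abs(tree.height - 1.0) > 1e-6:
        raise ValueError("fit_model expects a unit-height tree; scale it first")
    y = np.asarray(y, dtype=float)
    if y.shape != (n,):
        raise ValueError("response length does not match the number of tips")
    me_arr = None
    if me is not None:
        me_arr = np.asarray(me, dtype=float)
        if np.any(me_arr < 0):
            raise ValueError("negative observation variance")
        if not np.any(me_arr):
            me_arr = None
    if tm is None:
        tm = time_matrices(tree)

    if spec.kind == "brownian":
        return _fit_brownian(tm, y, me_arr, spec, grid)

    if spec.kind in ("categorical_ou", "ancova_ou") and painting is None:
        raise ValueError(f"{spec.kind} requires a regime painting")
    if spec.kind in ("continuous_ou", "ancova_ou") and predictor is None:
        raise ValueError(f"{spec.kind} requires predictor values")

    thalf = grid.values()
    v_hi = max(grid.v_max_factor * float(np.var(y)), 1e-6)
    lls = np.full(len(thalf), -np.inf)
    vs = np.full(len(thalf), np.nan)
    for i, t in enumerate(thalf):
        alpha = LN2 / t
        A = _ou_correlation(tm, alpha)
        try:
            X = design_matrix(
                spec, alpha, tree=tree, painting=painting, predictor=predictor, n=n
            )
            lls[i], vs[i] = _profile_point(A, X, y, me_arr, (1e-8, v_hi), grid.v_tol)
        except (ValueError, linalg.LinAlgError):
            lls[i] = -np.inf
    if not np.any(np.isfinite(lls)):
        raise ValueError("likelihood not finite anywhere on the half-life grid")
    ll_max = float(np.max(lls))
    # ties on a flat profile resolve toward the smallest half-life (the
    # weakest phylogenetic-effect claim consistent with the data)
    imax = int(np.flatnonzero(lls >= ll_max - 1e-9)[0])
    support_lo, support_hi = _support_bounds(thalf, lls, ll_max - 2.0)
    at_top = imax == len(thalf) - 1
    t_hat = np.inf if at_top else float(thalf[imax])
    warning = None
    if imax == 0:
        warning = (
            "half-life MLE at the lower grid boundary: no resolvable "
            "phylogenetic effect at this grid resolution"
        )

    alpha_hat = LN2 / float(thalf[imax])
    A = _ou_correlation(tm, alpha_hat)
    X = design_matrix(
        spec, alpha_hat, tree=tree, painting=painting, predictor=predictor, n=n
    )
    v_hat = float(vs[imax])
    (beta, se, loglik), V = _final_fit(A, X, y, me_arr, v_hat)
    names = _coef_names(spec, painting)
    rho = b_opt = b_phy = None
    coefficients = list(zip(names, beta.tolist(), se.tolist()))
    if spec.kind in ("continuous_ou", "ancova_ou"):
        rho = rho_factor(alpha_hat)
        b_opt = float(beta[-1])
        b_phy = rho * b_opt
        # report the slope on the phylogenetic (across-species) scale
        sname = names[-1]
        coefficients[-1] = (sname, b_phy, rho * float(se[-1]))
    k = 2 + len(names)
    r2 = 0.0 if spec.kind == "intercept_ou" else r_squared(X, y, V)
    return OUFitResult(
        spec=spec,
        t_half=t_hat,
        v_y=v_hat,
        sigma2_bm=None,
        support_lo=support_lo,
        support_hi=support_hi,
        coefficients=coefficients,
        rho=rho,
        b_optimal=b_opt,
        b_phylogenetic=b_phy,
        loglik=loglik,
        n=n,
        k_params=k,
        aicc=_aicc(loglik, k, n),
        r2=r2,
        grid=grid,
        grid_t_half=thalf,
        grid_loglik=lls,
        boundary_warning=warning,
    )


def _support_bounds(thalf, lls, threshold):
    """Two-log-likelihood-unit support interval for the half-life.

    Endpoints are interpolated (linearly in log half-life) between the
    last grid point outside the region and the first inside, so the
    interval is nearly independent of grid resolution.  An endpoint at
    the top of the grid is reported as infinite.
    """
    inside = np.flatnonzero(lls >= threshold)
    lo_i, hi_i = int(inside[0]), int(inside[-1])
    log_t = np.log(thalf)

    def _cross(i_out, i_in):
        if not np.isfinite(lls[i_out]) or lls[i_in] - lls[i_out] < 1e-12:
            return float(thalf[i_in])
        frac = (threshold - lls[i_out]) / (lls[i_in] - lls[i_out])
        return float(np.exp(log_t[i_out] + frac * (log_t[i_in] - log_t[i_out])))

    lo = float(thalf[0]) if lo_i == 0 else _cross(lo_i - 1, lo_i)
    if hi_i == len(thalf) - 1:
        hi = np.inf
    else:
        hi = _cross(hi_i + 1, hi_i)
    return lo, hi


def _fit_brownian(tm, y, me_arr, spec, grid):
    n = len(y)
    S = tm.shared_time
    X = np.ones((n, 1))
    if me_arr is None:
        L = linalg.cho_factor(S, lower=True)[0]
        Xw = linalg.solve_triangular(L, X, lower=True)
        yw = linalg.solve_triangular(L, y, lower=True)
        beta, *_ = linalg.lstsq(Xw, yw)
        q = float(np.sum((yw - Xw @ beta) ** 2))
        s2_hat = max(q / n, 1e-300)
    else:
        def negll(log_s2):
            s2 = math.exp(log_s2)
            V = s2 * S + np.diag(me_arr)
            try:
                Lf = linalg.cho_factor(V, lower=True)[0]
            except linalg.LinAlgError:
                return 1e300
            Xw = linalg.solve_triangular(Lf, X, lower=True)
            yw = linalg.solve_triangular(Lf, y, lower=True)
            b, *_ = linalg.lstsq(Xw, yw)
            qq = float(np.sum((yw - Xw @ b) ** 2))
            logdet = 2.0 * float(np.sum(np.log(np.diag(Lf))))
            return 0.5 * (n * _LOG2PI + logdet + qq)

        v0 = max(float(np.var(y)), 1e-8)
        res = optimize.minimize_scalar(
            negll,
            bounds=(math.log(v0) - 20.0, math.log(v0) + 20.0),
            method="bounded",
            options={"xatol": 1e-10},
        )
        s2_hat = math.exp(float(res.x))
    (beta, se, loglik), V = _final_fit(s2_hat * S, X, y, me_arr, None, is_bm=True)
    k = 2
    return OUFitResult(
        spec=spec,
        t_half=None,
        v_y=None,
        sigma2_bm=float(s2_hat),
        support_lo=None,
        support_hi=None,
        coefficients=[("intercept", float(beta[0]), float(se[0]))],
        rho=None,
        b_optimal=None,
        b_phylogenetic=None,
        loglik=loglik,
        n=n,
        k_params=k,
        aicc=_aicc(loglik, k, n),
        r2=0.0,
        grid=grid,
    )
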