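"""Spatial mixed models with Matérn covariance.

Generalized linear mixed models with a spatially correlated site-level
random effect:

    g(E[y_i]) = x_i' beta + b_i,      b ~ N(0, lambda * C(nu, rho))

where ``C`` is the Matérn correlation matrix over site coordinates,

    corr(d) = 2^(1-nu) / Gamma(nu) * (rho d)^nu * K_nu(rho d),

with smoothness ``nu``, inverse range ``rho`` (1/m, multiplying distance),
and random-effect variance ``lambda``.  Families: binomial with logit
link (presence/absence) and Gamma with log link (nitrate, shape estimated
by ML).

Estimation is Laplace-approximate maximum likelihood: an inner Newton
solve for the latent site effects and fixed effects given the covariance
parameters, an outer derivative-free search over the log-transformed
covariance parameters, and a final re-maximization of the fixed effects
against the Laplace objective itself (the joint mode alone attenuates
fixed effects when each site contributes a single binary observation).
Inference is Wald, with SEs from the penalized joint Hessian at the mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm

from .errors import DegenerateResponseError, FitError, StygoscaleError

log = logging.getLogger(__name__)

NU_BOUNDS = (0.05, 10.0)
LAMBDA_BOUNDS = (1e-8, 1e4)
RHO_BOUNDS = (1e-8, 10.0)
Z95 = norm.ppf(0.975)


# --------------------------------------------------------------------------
# Matérn correlation
# --------------------------------------------------------------------------
def matern_correlation(d, nu: float, rho: float):
    """Matérn correlation at distance ``d`` (meters).

    ``corr(d) = 2^(1-nu)/Gamma(nu) * (rho d)^nu * K_nu(rho d)`` with
    ``corr(0) = 1``; strictly decreasing in ``d``.  ``nu = 0.5`` gives
    ``exp(-rho d)``.
    """
    if nu <= 0 or rho <= 0:
        raise StygoscaleError("nu and rho must be positive")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise StygoscaleError("distances must be non-negative")
    x = rho * d
    small = x < 1e-10
    xs = np.where(small, 1.0, x)  # avoid 0*inf in the masked branch
    with np.errstate(over="ignore", invalid="ignore"):
        val = (2.0 ** (1.0 - nu) / special.gamma(nu)) * xs**nu * special.kv(nu, xs)
    val = np.where(small, 1.0, val)
    val = np.nan_to_num(val, nan=0.0)  # kv underflow at very large x
    out = np.clip(val, 0.0, 1.0)
    return out if out.ndim else float(out)


def matern_matrix(coords: np.ndarray, nu: float, rho: float,
                  jitter: float = 1e-8,
                  condensed_d: np.ndarray | None = None) -> np.ndarray:
    """Matérn correlation matrix over site coordinates, jittered on the
    diagonal for positive definiteness.

    ``condensed_d`` lets callers reuse precomputed ``pdist`` distances
    (the Bessel-K evaluation dominates fit time, so it is done once per
    unique pair).
    """
    if condensed_d is None:
        condensed_d = pdist(np.asarray(coords, dtype=float))
    C = squareform(matern_correlation(condensed_d, nu, rho))
    C[np.diag_indices_from(C)] = 1.0 + jitter
    return C


@dataclass
class MaternParams:
    """Matérn smoothness, inverse range (1/m), and random-effect variance."""

    nu: float
    rho: float
    lam: float


# --------------------------------------------------------------------------
# Families (natural-parameter derivatives with respect to the linear predictor)
# --------------------------------------------------------------------------
class _BinomialLogit:
    name = "binomial"
    n_extra_params = 0

    @staticmethod
    def loglik(y, eta, shape=None):
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))

    @staticmethod
    def score_eta(y, eta, shape=None):
        return y - special.expit(eta)

    @staticmethod
    def weight_eta(y, eta, shape=None):
        p = special.expit(eta)
        return np.maximum(p * (1.0 - p), 1e-10)

    @staticmethod
    def link(mu):
        return special.logit(mu)


class _GammaLog:
    """Gamma with log link; ``shape`` is the Gamma shape (1/dispersion)."""

    name = "gamma"
    n_extra_params = 1

    @staticmethod
    def loglik(y, eta, shape):
        a = shape
        e = np.exp(np.clip(-eta, -700, 700))
        return float(
            np.sum(a * np.log(a) - special.gammaln(a) + (a - 1.0) * np.log(y)
                   - a * eta - a * y * e)
        )

    @staticmethod
    def score_eta(y, eta, shape):
        e = np.exp(np.clip(-eta, -700, 700))
        return shape * (y * e - 1.0)

    @staticmethod
    def weight_eta(y, eta, shape):
        e = np.exp(np.clip(-eta, -700, 700))
        return np.maximum(shape * y * e, 1e-10)

    @staticmethod
    def link(mu):
        return np.log(mu)


_FAMILIES = {"binomial": _BinomialLogit, "gamma": _GammaLog}


# --------------------------------------------------------------------------
# Fit container
# --------------------------------------------------------------------------
@dataclass
class SpatialFit:
    """One fitted spatial mixed model.

    ``terms`` has one row per fixed effect with columns ``estimate, se, t,
    ci_low, ci_high, p``.  ``aic`` counts the fixed effects plus the three
    covariance parameters (and the Gamma shape where applicable).
    """

    family: str
    terms: pd.DataFrame
    matern: MaternParams
    loglik: float
    aic: float
    n_obs: int
    converged: bool
    gamma_shape: float | None = None
    latent: np.ndarray | None = None
    # data references so the fit can be refit during model selection
    design: pd.DataFrame | None = field(default=None, repr=False)
    response: np.ndarray | None = field(default=None, repr=False)
    coords: np.ndarray | None = field(default=None, repr=False)

    def predict_eta(self, X: np.ndarray) -> np.ndarray:
        """Population-level linear predictor (random effect at 0)."""
        return np.asarray(X) @ self.terms["estimate"].to_numpy()


def _inner_newton(X, y, L, lam, fam, shape, beta0, v0, tol=1e-8, maxit=50):
    """Maximize the penalized log-likelihood jointly over (beta, v).

    The random effect is parameterized as ``b = L v`` with
    ``v ~ N(0, lam I)`` (L the Cholesky factor of the Matérn correlation),
    so the penalty is ``v'v / (2 lam)``.
    """
    p = X.shape[1]
    n = len(y)
    beta = beta0.copy()
    v = v0.copy()
    eta = X @ beta + L @ v
    pen = fam.loglik(y, eta, shape) - 0.5 * v @ v / lam
    converged = False
    for _ in range(maxit):
        g = fam.score_eta(y, eta, shape)
        w = fam.weight_eta(y, eta, shape)
        grad = np.concatenate([X.T @ g, L.T @ g - v / lam])
        WX = X * w[:, None]
        WL = L * w[:, None]
        H = np.empty((p + n, p + n))
        H[:p, :p] = X.T @ WX
        H[:p, p:] = X.T @ WL
        H[p:, :p] = H[:p, p:].T
        H[p:, p:] = L.T @ WL
        H[p:, p:][np.diag_indices(n)] += 1.0 / lam
        try:
            step = cho_solve(cho_factor(H, lower=True), grad)
        except np.linalg.LinAlgError:
            H[np.diag_indices(p + n)] += 1e-6
            step = np.linalg.solve(H, grad)
        t = 1.0
        improved = False
        while t > 1e-10:
            nb = beta + t * step[:p]
            nv = v + t * step[p:]
            neta = X @ nb + L @ nv
            npen = fam.loglik(y, neta, shape) - 0.5 * nv @ nv / lam
            if np.isfinite(npen) and npen >= pen:
                improved = True
                break
            t *= 0.5
        if not improved:
            break
        delta = npen - pen
        beta, v, eta, pen = nb, nv, neta, npen
        if delta < tol * (1.0 + abs(pen)):
            converged = True
            break
    return beta, v, eta, pen, converged


def _newton_v(X, y, L, lam, fam, shape, beta, v0, tol=1e-10, maxit=50):
    """Maximize the penalized log-likelihood over the latent ``v`` only."""
    n = len(y)
    v = v0.copy()
    eta = X @ beta + L @ v
    pen = fam.loglik(y, eta, shape) - 0.5 * v @ v / lam
    for _ in range(maxit):
        g = fam.score_eta(y, eta, shape)
        w = fam.weight_eta(y, eta, shape)
        grad = L.T @ g - v / lam
        A = L.T @ (L * w[:, None])
        A[np.diag_indices(n)] += 1.0 / lam
        try:
            step = cho_solve(cho_factor(A, lower=True), grad)
        except np.linalg.LinAlgError:
            A[np.diag_indices(n)] += 1e-6
            step = np.linalg.solve(A, grad)
        t = 1.0
        npen = -np.inf
        while t > 1e-10:
            nv = v + t * step
            neta = X @ beta + L @ nv
            npen = fam.loglik(y, neta, shape) - 0.5 * nv @ nv / lam
            if np.isfinite(npen) and npen >= pen:
                break
            t *= 0.5
        if npen < pen:
            break
        delta = npen - pen
        v, eta, pen = nv, neta, npen
        if delta < tol * (1.0 + abs(pen)):
            break
    return v, eta


def _profile_beta(X, y, L, lam, fam, shape, beta0, v0):
    """Maximize the Laplace marginal likelihood over the fixed effects.

    The joint (beta, v) mode systematically attenuates fixed effects for
    binary responses (one observation per latent effect), so the reported
    beta re-maximizes the Laplace objective itself, with the inner Newton
    mode taken over v alone at each candidate beta.
    """
    state = {"v": v0.copy()}

    def neglap(beta):
        v, eta = _newton_v(X, y, L, lam, fam, shape, beta, state["v"])
        state["v"] = v
        return -_laplace_loglik(X, y, L, lam, fam, shape, beta, v, eta)

    res = optimize.minimize(neglap, beta0, method="Nelder-Mead",
                            options={"xatol": 1e-7, "fatol": 1e-9,
                                     "maxfev": 400 * max(len(beta0), 1)})
    beta = res.x
    v, eta = _newton_v(X, y, L, lam, fam, shape, beta, state["v"])
    return beta, v, eta


def _laplace_loglik(X, y, L, lam, fam, shape, beta, v, eta):
    """Laplace-approximate marginal log-likelihood at the joint mode."""
    n = len(y)
    ll = fam.loglik(y, eta, shape)
    w = fam.weight_eta(y, eta, shape)
    A = L.T @ (L * w[:, None])
    A[np.diag_indices(n)] += 1.0 / lam
    try:
        cA = cholesky(A, lower=True)
    except np.linalg.LinAlgError:
        return -np.inf
    logdetA = 2.0 * np.sum(np.log(np.diag(cA)))
    return ll - 0.5 * v @ v / lam - 0.5 * n * np.log(lam) - 0.5 * logdetA


def fit_spatial_glmm(
    design,
    response,
    coords,
    family: str = "binomial",
    lambda_fix: float | None = None,
    start: dict | None = None,
    maxiter_outer: int = 1000,
    tol_outer: float = 1e-6,
    jitter: float = 1e-8,
    jitter_coords: bool = True,
) -> SpatialFit:
    """Laplace-approximate ML fit of a spatial GLMM.

    Parameters
    ----------
    design
        Fixed-effect matrix as a DataFrame (columns are term names) or
        ndarray; include an ``Intercept`` column explicitly.
    response
        Response vector (0/1 for binomial, positive for gamma).
    coords
        ``(n, 2)`` planar site coordinates in meters.  Duplicated
        coordinates are jittered by 1 m (logged).
    family
        ``"binomial"`` (logit) or ``"gamma"`` (log link).
    lambda_fix
        Fix the random-effect variance instead of estimating it (used for
        degenerate-limit checks; ``lambda -> 0`` recovers the plain GLM).
    """
    if isinstance(design, pd.DataFrame):
        terms = list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        terms = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(response, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n, p = X.shape
    if n < 30:
        raise FitError(f"need at least 30 observations for a spatial fit, got {n}")
    if len(y) != n or coords.shape != (n, 2):
        raise FitError("design, response, and coords lengths disagree")
    if family not in _FAMILIES:
        raise FitError(f"unknown family {family!r}")
    if np.linalg.matrix_rank(X) < p:
        raise FitError("singular fixed-effect design")
    fam = _FAMILIES[family]
    if family == "binomial" and y.min() == y.max():
        raise DegenerateResponseError("single-class response")
    if family == "gamma" and np.any(y <= 0):
        raise FitError("gamma response must be strictly positive")

    # jitter exact duplicate coordinates by 1 m
    if jitter_coords:
        _, inv, counts = np.unique(coords, axis=0, return_inverse=True,
                                   return_counts=True)
        if counts.max() > 1:
            dup = counts[inv] > 1
            rng = np.random.default_rng(0)
            coords = coords.copy()
            coords[dup] += rng.uniform(-0.5, 0.5, size=(int(dup.sum()), 2))
            log.info("jittered %d duplicated coordinates by <=1 m",
                     int(dup.sum()))

    # starting values from the non-spatial GLM
    sm_fam = (sm.families.Binomial() if family == "binomial"
              else sm.families.Gamma(link=sm.families.links.Log()))
    import warnings as _warnings
    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            glm_res = sm.GLM(y, X, family=sm_fam).fit()
        beta0 = np.asarray(glm_res.params, dtype=float)
        disp = float(glm_res.pearson_chi2) / max(n - p, 1)
    except (ValueError, np.linalg.LinAlgError):
        # e.g. a constant gamma response; fall back to an intercept guess
        beta0 = np.zeros(p)
        has_const = np.all(X == X[0:1, :], axis=0)
        mu0 = float(np.mean(y))
        eta0 = fam.link(min(max(mu0, 1e-6), 1 - 1e-6)) if family == "binomial" \
            else np.log(max(mu0, 1e-12))
        if has_const.any():
            beta0[np.argmax(has_const)] = eta0 / X[0, np.argmax(has_const)]
        disp = float(np.var(y) / max(np.mean(y) ** 2, 1e-12)) or 1.0
    shape0 = float(np.clip(1.0 / max(disp, 1e-3), 0.1, 1e3)) \
        if family == "gamma" else None

    D = pdist(coords)
    med_d = float(np.median(D[D > 0])) if np.any(D > 0) else 1.0
    start = start or {}
    lam0 = float(start.get("lam", 0.5))
    nu0 = float(start.get("nu", 1.0))
    rho0 = float(start.get("rho", 2.0 / med_d))
    shape0 = float(start.get("shape", shape0)) if family == "gamma" else None

    state = {"beta": beta0, "v": np.zeros(n), "inner_ok": True}
    cache: dict[tuple[float, float], np.ndarray] = {}
    dcond = pdist(coords)

    def chol_corr(nu, rho):
        key = (round(float(nu), 12), round(float(rho), 12))
        if key not in cache:
            if len(cache) > 64:
                cache.clear()
            C = matern_matrix(coords, nu, rho, jitter=jitter, condensed_d=dcond)
            cache[key] = cholesky(C, lower=True)
        return cache[key]

    def unpack(theta):
        i = 0
        if lambda_fix is None:
            lam = np.exp(theta[i]); i += 1
        else:
            lam = lambda_fix
        nu = np.exp(theta[i]); i += 1
        rho = np.exp(theta[i]); i += 1
        shape = np.exp(theta[i]) if family == "gamma" else None
        return lam, nu, rho, shape

    def neg_marginal(theta):
        lam, nu, rho, shape = unpack(theta)
        if not (NU_BOUNDS[0] <= nu <= NU_BOUNDS[1]):
            return 1e10 + abs(np.log(nu)) ** 2
        if not (LAMBDA_BOUNDS[0] <= lam <= LAMBDA_BOUNDS[1]):
            return 1e10 + abs(np.log(lam)) ** 2
        if not (RHO_BOUNDS[0] <= rho <= RHO_BOUNDS[1]):
            return 1e10 + abs(np.log(rho)) ** 2
        try:
            L = chol_corr(nu, rho)
        except np.linalg.LinAlgError:
            return 1e10
        beta, v, eta, _, ok = _inner_newton(
            X, y, L, lam, fam, shape, state["beta"], state["v"]
        )
        ml = _laplace_loglik(X, y, L, lam, fam, shape, beta, v, eta)
        if not np.isfinite(ml):
            return 1e10
        state["beta"], state["v"] = beta, v
        state["inner_ok"] = ok
        return -ml

    theta0 = []
    if lambda_fix is None:
        theta0.append(np.log(lam0))
    theta0 += [np.log(nu0), np.log(rho0)]
    if family == "gamma":
        theta0.append(np.log(shape0))
    theta0 = np.array(theta0)

    res = optimize.minimize(
        neg_marginal, theta0, method="Nelder-Mead",
        options={"maxfev": maxiter_outer, "fatol": tol_outer, "xatol": 1e-4},
    )
    lam, nu, rho, shape = unpack(res.x)
    L = chol_corr(nu, rho)
    beta, v, eta, _, inner_ok = _inner_newton(
        X, y, L, lam, fam, shape, state["beta"], state["v"], maxit=100
    )
    # re-estimate the fixed effects against the Laplace objective proper
    beta, v, eta = _profile_beta(X, y, L, lam, fam, shape, beta, v)
    loglik = _laplace_loglik(X, y, L, lam, fam, shape, beta, v, eta)

    # Wald SEs from the penalized joint Hessian
    w = fam.weight_eta(y, eta, shape)
    WX = X * w[:, None]
    WL = L * w[:, None]
    H = np.empty((p + n, p + n))
    H[:p, :p] = X.T @ WX
    H[:p, p:] = X.T @ WL
    H[p:, :p] = H[:p, p:].T
    H[p:, p:] = L.T @ WL
    H[p:, p:][np.diag_indices(n)] += 1.0 / lam
    try:
        cov = cho_solve(cho_factor(H, lower=True), np.eye(p + n))
        se = np.sqrt(np.maximum(np.diag(cov)[:p], 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)

    tvals = beta / se
    pvals = 2.0 * norm.sf(np.abs(tvals))
    table = pd.DataFrame(
        {
            "estimate": beta,
            "se": se,
            "t": tvals,
            "ci_low": beta - Z95 * se,
            "ci_high": beta + Z95 * se,
            "p": pvals,
        },
        index=pd.Index(terms, name="term"),
    )
    k_cov = (3 if lambda_fix is None else 2) + fam.n_extra_params
    aic = -2.0 * loglik + 2.0 * (p + k_cov)
    converged = bool(res.success) and inner_ok and np.isfinite(loglik)
    if not converged:
        log.warning("spatial GLMM flagged non-converged: outer=%s inner=%s",
                    res.success, inner_ok)
    return SpatialFit(
        family=family,
        terms=table,
        matern=MaternParams(nu=float(nu), rho=float(rho), lam=float(lam)),
        loglik=float(loglik),
        aic=float(aic),
        n_obs=n,
        converged=converged,
        gamma_shape=(float(shape) if shape is not None else None),
        latent=L @ v,
        design=pd.DataFrame(X, columns=terms),
        response=y,
        coords=coords,
    )


def stepwise_backward_aic(fit: SpatialFit, candidate_terms=None,
                          protected=("Intercept",), **fit_kwargs):
    """Backward elimination by AIC on a fitted spatial model.

    Repeatedly drops the single candidate term whose removal most lowers
    the AIC, refitting the covariance parameters at every candidate
    removal, until no removal lowers it.  The intercept and the spatial
    random effect are never dropped.  Returns ``(selected_fit, trace)``
    where ``trace`` lists the elimination steps.
    """
    if fit.design is None:
        raise FitError("fit does not carry its data; refit with fit_spatial_glmm")
    if not fit.converged:
        raise FitError("full model did not converge")
    current = fit
    candidates = list(candidate_terms
                      if candidate_terms is not None
                      else [t for t in fit.design.columns if t not in protected])
    trace = [{"step": 0, "dropped": None, "aic": fit.aic,
              "terms": list(fit.design.columns)}]
    step = 0
    while candidates:
        step += 1
        best_drop, best_fit = None, None
        for term in candidates:
            reduced = current.design.drop(columns=[term])
            try:
                cand = fit_spatial_glmm(
                    reduced, current.response, current.coords,
                    family=current.family, **fit_kwargs,
                )
            except StygoscaleError:
                continue
            if not cand.converged:
                log.info("refit without %r did not converge; term retained", term)
                continue
            if cand.aic < current.aic - 1e-9 and (
                best_fit is None or cand.aic < best_fit.aic
            ):
                best_drop, best_fit = term, cand
        if best_drop is None:
            break
        current = best_fit
        candidates.remove(best_drop)
        trace.append({"step": step, "dropped": best_drop, "aic": current.aic,
                      "terms": list(current.design.columns)})
    return current, trace


def autocorrelation_range(fit_or_params, threshold: float = 0.05) -> float:
    """Distance (m) at which the fitted Matérn correlation falls to
    ``threshold``, found by bisection."""
    if threshold <= 0:
        raise StygoscaleError("threshold must be positive")
    mp = fit_or_params.matern if isinstance(fit_or_params, SpatialFit) else fit_or_params
    if threshold >= 1.0:
        return 0.0
    f = lambda d: matern_correlation(d, mp.nu, mp.rho) - threshold
    hi = 1.0 / mp.rho
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e12:
            raise StygoscaleError("correlation never falls below threshold")
    return float(optimize.bisect(f, 0.0, hi, xtol=max(1e-6 * hi, 1e-9)))


# --------------------------------------------------------------------------
# The study's two model surfaces
# --------------------------------------------------------------------------
def nitrate_models(
    sites: pd.DataFrame,
    proportions: pd.DataFrame,
    size: float = 600.0,
    buffer_type: str = "catchment",
    classes=("forest", "pasture", "crop"),
    **fit_kwargs,
) -> dict[str, SpatialFit]:
    """Gamma log-link spatial models of nitrate vs each major land use.

    One single-covariate model per class (coverage % from the chosen
    buffer size and type); slopes are per percentage point.
    """
    nit = sites.dropna(subset=["nitrate_mg_l"])
    if len(nit) < 30:
        raise FitError(
            f"only {len(nit)} sites carry nitrate; need >= 30. "
            "Provide more nitrate measurements or simulate more sites."
        )
    sub = proportions[
        (proportions["size_m"] == size)
        & (proportions["buffer_type"] == buffer_type)
    ]
    out = {}
    for cls in classes:
        prop = sub[sub["class"] == cls].set_index("site_id")["proportion"]
        merged = nit.set_index("site_id").join(prop.rename("prop"), how="inner")
        design = pd.DataFrame(
            {"Intercept": 1.0, cls: merged["prop"].to_numpy() * 100.0}
        )
        out[cls] = fit_spatial_glmm(
            design,
            merged["nitrate_mg_l"].to_numpy(),
            merged[["x", "y"]].to_numpy(),
            family="gamma",
            **fit_kwargs,
        )
    return out


def final_presence_model(
    sites: pd.DataFrame,
    covariates: pd.DataFrame,
    gradient_col: str = "land_use",
    **fit_kwargs,
):
    """Full presence model (gradient + covariates), then backward AIC.

    ``covariates`` must carry ``site_id`` and the forest-agriculture
    gradient (0-100) in ``gradient_col``; remaining numeric columns are
    additional covariates.  Returns ``(selected_fit, trace, full_fit)``.
    """
    merged = sites.set_index("site_id").join(
        covariates.set_index("site_id"), how="inner"
    )
    cov_cols = [c for c in covariates.columns if c != "site_id"]
    design = pd.DataFrame({"Intercept": np.ones(len(merged))},
                          index=merged.index)
    for c in cov_cols:
        design[c] = merged[c].to_numpy(dtype=float)
    if merged[cov_cols].isna().any().any():
        raise FitError("covariate columns contain missing values")
    full = fit_spatial_glmm(
        design.reset_index(drop=True),
        merged["presence"].to_numpy(),
        merged[["x", "y"]].to_numpy(),
        family="binomial",
        **fit_kwargs,
    )
    selected, trace = stepwise_backward_aic(full, **fit_kwargs)
    return selected, trace, full


def format_fit_report(fit: SpatialFit, title: str = "Spatial mixed model") -> str:
    """Plain-text coefficient table in the style of the study's Table 1."""
    lines = [title, "=" * len(title), f"family: {fit.family}", ""]
    lines.append(f"{'term':<22}{'Est':>10}{'SE':>10}{'t':>8}"
                 f"{'95% CI':>22}{'p':>10}")
    for term, row in fit.terms.iterrows():
        ci = f"{row.ci_low:.4g}, {row.ci_high:.4g}"
        lines.append(
            f"{term:<22}{row.estimate:>10.4g}{row.se:>10.4g}{row.t:>8.2f}"
            f"{ci:>22}{row.p:>10.3g}"
        )
    lines.append("")
    lines.append(f"nu, rho       {fit.matern.nu:.3g}, {fit.matern.rho:.3g}")
    lines.append(f"lambda        {fit.matern.lam:.3g}")
    if fit.gamma_shape is not None:
        lines.append(f"Gamma shape   {fit.gamma_shape:.3g}")
    lines.append(f"logLik        {fit.loglik:.3f}")
    lines.append(f"AIC           {fit.aic:.2f}")
    lines.append(f"N obs         {fit.n_obs}")
    return "\n".join(lines)


def simulate_glmm_response(
    X, coords, beta, lam, nu, rho, family="binomial", shape=5.0, seed=0
):
    """Draw a response from the spatial GLMM itself (for recovery studies)."""
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    coords = np.asarray(coords, dtype=float)
    C = matern_matrix(coords, nu, rho)
    L = cholesky(C, lower=True)
    b = np.sqrt(lam) * (L @ rng.standard_normal(len(coords)))
    eta = X @ np.asarray(beta, dtype=float) + b
    if family == "binomial":
        return (rng.uniform(size=len(eta)) < special.expit(eta)).astype(int)
    mu = np.exp(eta)
    return rng.gamma(shape, mu / shape)
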