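"""Random-intercept multilevel logistic regression and per-cell prediction.

The outcome model is

    logit(p_ij) = x_ij' beta + z_i' eta + mu_i,    mu_i ~ N(0, sigma_mu^2)

where ``x_ij`` dummy-codes the individual-level stratification factors of
respondent j in area i, ``z_i`` holds continuous area-level covariates,
and ``mu_i`` is an area (e.g. county) random intercept.  The fit is
unweighted maximum likelihood: the random intercept is integrated out of
the marginal likelihood with adaptive Gauss-Hermite quadrature, which is
exact-to-quadrature because the random-effect structure makes the
integral one-dimensional per area.

Respondents sharing (area, cell) are collapsed to binomial rows before
optimisation, so the likelihood cost scales with the number of distinct
cells, not respondents.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, log_expit, logsumexp

from .core import (
    AreaCovariates,
    AreaEstimate,
    FittingError,
    InputError,
    CellPredictions,
    StratificationScheme,
    SurveyDataset,
)

__all__ = [
    "ModelSpec",
    "GlmmFit",
    "cell_design",
    "fit_multilevel_logistic",
    "predict_cell_probabilities",
    "compare_models",
]

_SQRT2 = np.sqrt(2.0)
_LOG_SIGMA_MIN = np.log(1e-6)  # effectively sigma = 0 at the boundary
_LOG_SIGMA_MAX = np.log(20.0)


@dataclass(frozen=True)
class ModelSpec:
    """Which terms enter the regression.

    ``fixed`` names the scheme factors used as dummy-coded fixed effects
    (first declared level of each factor is the reference);
    ``area_covariates`` names continuous area-level covariates; with
    ``random_intercept=False`` the area effect is instead a set of fixed
    area-indicator dummies (first sampled area as reference), the
    fixed-effect model variant.
    """

    fixed: tuple[str, ...]
    area_covariates: tuple[str, ...] = ()
    random_intercept: bool = True

    def __init__(
        self,
        fixed: Sequence[str],
        area_covariates: Sequence[str] = (),
        random_intercept: bool = True,
    ):
        object.__setattr__(self, "fixed", tuple(fixed))
        object.__setattr__(self, "area_covariates", tuple(area_covariates))
        object.__setattr__(self, "random_intercept", bool(random_intercept))

    def validate(self, scheme: StratificationScheme, covariates: AreaCovariates) -> None:
        for f in self.fixed:
            if f not in scheme.factor_names:
                raise InputError(f"model factor {f!r} not in scheme {scheme.factor_names}")
        for z in self.area_covariates:
            if z not in covariates.data.columns:
                raise InputError(
                    f"area covariate {z!r} not found; available: {list(covariates.data.columns)}"
                )


def cell_design(
    scheme: StratificationScheme, fixed: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Dummy-coded design matrix over all scheme cells (intercept first).

    The reference for each factor is its first declared level; rows follow
    the canonical cell order.
    """
    cells = scheme.cell_frame()
    cols = [np.ones(len(cells))]
    names = ["(Intercept)"]
    for f in fixed:
        levels = scheme.levels(f)
        for lv in levels[1:]:
            cols.append((cells[f].to_numpy() == lv).astype(float))
            names.append(f"{f}[{lv}]")
    return np.column_stack(cols), names


@dataclass
class GlmmFit:
    """Fitted multilevel logistic model.

    ``beta`` covers the intercept and factor dummies (order in
    ``x_names``); ``eta`` the area-level covariates (``z_names``);
    ``sigma_mu`` the random-intercept SD; ``mu`` the per-sampled-area
    posterior-mode random effects (area fixed effects when
    ``spec.random_intercept`` is False).
    """

    spec: ModelSpec
    beta: np.ndarray
    eta: np.ndarray
    sigma_mu: float
    mu: dict[str, float]
    loglik: float
    converged: bool
    n_iter: int
    x_names: list[str]
    z_names: list[str]
    quadrature_points: int = 15
    se: dict[str, float] | None = None
    message: str = ""
    survey_signature: str = ""
    n_obs: int = 0

    def summary_frame(self) -> pd.DataFrame:
        terms = self.x_names + self.z_names
        est = np.concatenate([self.beta, self.eta])
        ses = [self.se.get(t) if self.se else None for t in terms]
        return pd.DataFrame({"term": terms, "estimate": est, "se": ses})

    def metadata(self) -> dict:
        return {
            "sigma_mu": self.sigma_mu,
            "loglik": self.loglik,
            "iterations": self.n_iter,
            "converged": self.converged,
            "quadrature_points": self.quadrature_points,
            "message": self.message,
        }


def _survey_signature(survey: SurveyDataset) -> str:
    h = hashlib.sha256()
    h.update(pd.util.hash_pandas_object(survey.data, index=False).values.tobytes())
    return h.hexdigest()[:16]


class _AgqProblem:
    """Aggregated-binomial marginal likelihood with adaptive GH quadrature."""

    def __init__(
        self,
        row_area: np.ndarray,
        X: np.ndarray,
        s: np.ndarray,
        n: np.ndarray,
        n_areas: int,
        n_quad: int,
    ):
        order = np.argsort(row_area, kind="stable")
        self.row_area = row_area[order]
        self.X = X[order]
        self.s = s[order]
        self.n = n[order]
        self.n_areas = n_areas
        self.starts = np.searchsorted(self.row_area, np.arange(n_areas))
        t, w = np.polynomial.hermite.hermgauss(n_quad)
        self.t = t
        self.logw_t2 = np.log(w) + t**2
        self._mode_cache = np.zeros(n_areas)

    # ---- inner (per-area) log joint in u --------------------------------
    def _data_terms(self, eta_lin: np.ndarray) -> np.ndarray:
        """Per-row binomial log-likelihood terms; eta_lin is (R,) or (R,K)."""
        if eta_lin.ndim == 1:
            s, n = self.s, self.n
        else:
            s, n = self.s[:, None], self.n[:, None]
        return s * log_expit(eta_lin) + (n - s) * log_expit(-eta_lin)

    def _segsum(self, rows: np.ndarray) -> np.ndarray:
        return np.add.reduceat(rows, self.starts, axis=0)

    def modes(self, xb: np.ndarray, sigma: float, u0: np.ndarray | None = None):
        """Posterior modes and curvatures of the inner log joint, by Newton."""
        u = np.zeros(self.n_areas) if u0 is None else u0.copy()
        inv_s2 = 1.0 / sigma**2
        for _ in range(100):
            p = expit(xb + u[self.row_area])
            g = self._segsum(self.s - self.n * p) - u * inv_s2
            h = -self._segsum(self.n * p * (1.0 - p)) - inv_s2
            step = -g / h
            # inner objective is strictly concave; damp oversized steps
            step = np.clip(step, -4.0, 4.0)
            u = u + step
            if np.abs(g).max() < 1e-10 * (1.0 + inv_s2):
                break
        p = expit(xb + u[self.row_area])
        h = -self._segsum(self.n * p * (1.0 - p)) - inv_s2
        return u, np.sqrt(-1.0 / h)

    # ---- marginal log-likelihood and gradient ---------------------------
    def loglik_grad(self, theta: np.ndarray, want_grad: bool = True):
        coef, log_sigma = theta[:-1], theta[-1]
        sigma = np.exp(log_sigma)
        xb = self.X @ coef
        u_hat, scale = self.modes(xb, sigma, self._mode_cache)
        self._mode_cache = u_hat.copy()

        U = u_hat[:, None] + _SQRT2 * scale[:, None] * self.t[None, :]  # (A, K)
        ETA = xb[:, None] + U[self.row_area]  # (R, K)
        ll_data = self._segsum(self._data_terms(ETA))  # (A, K)
        log_prior = -0.5 * U**2 / sigma**2 - log_sigma - 0.5 * np.log(2 * np.pi)
        L = self.logw_t2[None, :] + ll_data + log_prior  # (A, K)
        ll_area = logsumexp(L, axis=1) + 0.5 * np.log(2.0) + np.log(scale)
        ll = float(ll_area.sum())
        if not want_grad:
            return ll, None

        # gradient with quadrature nodes held fixed: the dependence of the
        # computed value on (u_hat, scale) is pure quadrature error, so the
        # omitted terms vanish at the rate of the quadrature itself
        Pi = np.exp(L - logsumexp(L, axis=1, keepdims=True))  # node weights, rows sum to 1
        P = expit(ETA)
        row_w = ((self.s[:, None] - self.n[:, None] * P) * Pi[self.row_area]).sum(axis=1)
        g_coef = self.X.T @ row_w
        g_logsig = float((Pi * (U**2 / sigma**2 - 1.0)).sum())
        return ll, np.concatenate([g_coef, [g_logsig]])

    def neg_loglik_grad(self, theta: np.ndarray):
        ll, g = self.loglik_grad(theta)
        return -ll, -g


def _aggregate(
    survey: SurveyDataset,
    covariates: AreaCovariates,
    spec: ModelSpec,
    scheme: StratificationScheme,
):
    """Collapse respondents to binomial (area, cell) rows with design matrix."""
    areas = survey.area_ids
    area_index = {a: i for i, a in enumerate(areas)}
    a_idx = survey.data["area_id"].astype(str).map(area_index).to_numpy()
    cells = survey.cell_ids
    key = a_idx * scheme.n_cells + cells
    uniq, inv = np.unique(key, return_inverse=True)
    s = np.bincount(inv, weights=survey.data["y"].to_numpy(dtype=float))
    n = np.bincount(inv).astype(float)
    row_area = (uniq // scheme.n_cells).astype(np.int64)
    row_cell = (uniq % scheme.n_cells).astype(np.int64)

    Xcell, x_names = cell_design(scheme, spec.fixed)
    Z = covariates.matrix(areas, spec.area_covariates)
    X = np.column_stack([Xcell[row_cell], Z[row_area]]) if spec.area_covariates else Xcell[
        row_cell
    ]
    return areas, row_area, X, s, n, x_names, list(spec.area_covariates)


def fit_multilevel_logistic(
    survey: SurveyDataset,
    covariates: AreaCovariates,
    spec: ModelSpec,
    scheme: StratificationScheme | None = None,
    quadrature_points: int = 15,
    tol: float = 1e-8,
    max_iter: int = 500,
    start: np.ndarray | None = None,
    compute_se: bool = True,
) -> GlmmFit:
    """Maximum-likelihood fit of the random-intercept logistic model.

    The marginal likelihood (random intercept integrated out by adaptive
    Gauss-Hermite quadrature with ``quadrature_points`` nodes per area) is
    maximised over (beta, eta, log sigma_mu) by L-BFGS-B.  Every
    respondent counts once: survey weights, if present, are ignored.

    Raises
    ------
    FittingError
        On complete separation (diverging coefficients) or failure to
        converge within ``max_iter`` iterations.
    """
    scheme = scheme or survey.scheme
    spec.validate(scheme, covariates)
    if "weight" in survey.data.columns:
        import warnings

        warnings.warn(
            "survey weights present but ignored: the model is fitted unweighted",
            UserWarning,
            stacklevel=2,
        )
    areas, row_area, X, s, n, x_names, z_names = _aggregate(survey, covariates, spec, scheme)
    p_x = len(x_names)
    signature = _survey_signature(survey)

    if not spec.random_intercept:
        return _fit_fixed_effect(
            areas, row_area, X, s, n, x_names, z_names, spec, signature, survey.n
        )

    prob = _AgqProblem(row_area, X, s, n, len(areas), quadrature_points)
    if start is None:
        theta0 = np.zeros(X.shape[1] + 1)
        ybar = min(max(s.sum() / n.sum(), 1e-3), 1 - 1e-3)
        theta0[0] = np.log(ybar / (1 - ybar))
        theta0[-1] = np.log(0.5)
    else:
        theta0 = np.asarray(start, dtype=float)
    bounds = [(None, None)] * X.shape[1] + [(_LOG_SIGMA_MIN, _LOG_SIGMA_MAX)]
    res = minimize(
        prob.neg_loglik_grad,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-6, "maxcor": 25},
    )
    theta = res.x
    ll, grad = prob.loglik_grad(theta)
    gmax = float(np.abs(grad[:-1]).max())  # sigma may sit on its bound
    if not np.isfinite(ll) or np.abs(theta[:-1]).max() > 30.0:
        raise FittingError(
            f"fit diverged (possible complete separation): max |coef| = "
            f"{np.abs(theta[:-1]).max():.2f}, loglik = {ll}"
        )
    converged = bool(res.success) or gmax < 1e-3
    if not converged:
        raise FittingError(
            f"optimizer failed to converge in {res.nit} iterations: {res.message}; "
            f"max |gradient| = {gmax:.3g}"
        )

    sigma = float(np.exp(theta[-1]))
    if sigma <= 2e-6:
        sigma = 0.0
    xb = X @ theta[:-1]
    u_hat, _ = prob.modes(xb, max(sigma, 1e-6))
    se = None
    if compute_se:
        se_vals = _numerical_se(prob, theta)
        se = dict(zip(x_names + z_names, se_vals[: len(x_names) + len(z_names)]))
    return GlmmFit(
        spec=spec,
        beta=theta[:p_x].copy(),
        eta=theta[p_x : p_x + len(z_names)].copy(),
        sigma_mu=sigma,
        mu={a: float(u) for a, u in zip(areas, u_hat)},
        loglik=float(ll),
        converged=True,
        n_iter=int(res.nit),
        x_names=x_names,
        z_names=z_names,
        quadrature_points=quadrature_points,
        se=se,
        message=str(res.message),
        survey_signature=signature,
        n_obs=survey.n,
    )


def _numerical_se(prob: _AgqProblem, theta: np.ndarray) -> np.ndarray:
    """Observed-information SEs via central differences of the gradient."""
    k = len(theta)
    H = np.zeros((k, k))
    for j in range(k):
        h = 1e-5 * (1.0 + abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        _, gp = prob.loglik_grad(tp)
        _, gm = prob.loglik_grad(tm)
        H[:, j] = (gp - gm) / (2 * h)
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(-H)
        d = np.diag(cov).copy()
        d[d < 0] = np.nan
        return np.sqrt(d)
    except np.linalg.LinAlgError:
        return np.full(k, np.nan)


def _fit_fixed_effect(
    areas, row_area, X, s, n, x_names, z_names, spec, signature, n_obs
) -> GlmmFit:
    """Ordinary logistic fit with area-indicator dummies (no random effect)."""
    import statsmodels.api as sm

    A = len(areas)
    dummies = np.zeros((len(row_area), A - 1))
    for i in range(1, A):
        dummies[row_area == i, i - 1] = 1.0
    exog = np.column_stack([X, dummies])
    endog = np.column_stack([s, n - s])
    try:
        glm = sm.GLM(endog, exog, family=sm.families.Binomial())
        res = glm.fit(maxiter=200, tol=1e-10)
    except Exception as exc:  # pragma: no cover - statsmodels failure paths vary
        raise FittingError(f"fixed-effect logistic fit failed: {exc}") from exc
    coef = np.asarray(res.params)
    if not np.isfinite(coef).all() or np.abs(coef).max() > 30.0:
        raise FittingError("fixed-effect fit diverged (possible complete separation)")
    p_x = len(x_names)
    p_z = len(z_names)
    mu = {areas[0]: 0.0}
    for i in range(1, A):
        mu[areas[i]] = float(coef[p_x + p_z + i - 1])
    se_all = np.asarray(res.bse)
    se = dict(zip(x_names + z_names, se_all[: p_x + p_z]))
    return GlmmFit(
        spec=spec,
        beta=coef[:p_x],
        eta=coef[p_x : p_x + p_z],
        sigma_mu=0.0,
        mu=mu,
        loglik=float(res.llf),
        converged=bool(res.converged) if hasattr(res, "converged") else True,
        n_iter=int(getattr(res, "fit_history", {}).get("iteration", 0) or 0),
        x_names=x_names,
        z_names=z_names,
        quadrature_points=0,
        se=se,
        message="fixed-effect (area dummy) fit",
        survey_signature=signature,
        n_obs=n_obs,
    )


def predict_cell_probabilities(
    fit: GlmmFit,
    scheme: StratificationScheme,
    covariates: AreaCovariates,
    target_areas: Sequence[str],
    re_policy: str = "conditional_blup",
    marginal_points: int = 41,
    mu_override: Mapping[str, float] | None = None,
) -> CellPredictions:
    """Predicted outcome probability for every cell of every target area.

    ``re_policy`` selects the area random-effect contribution mu*:

    - ``conditional_blup``: the area's posterior mode when the area was
      sampled, otherwise 0 (the BLUP of an unobserved group);
    - ``conditional_zero``: 0 for every area;
    - ``marginal``: posterior mode for sampled areas; for unsampled areas
      the population-averaged probability
      ``int expit(x'b + z'e + u) N(u; 0, sigma^2) du`` by Gauss-Hermite
      quadrature, which differs from plugging in mu = 0 because the
      inverse logit is nonlinear.

    ``mu_override`` forces mu* for the named areas regardless of policy
    (used by the bootstrap to draw the unobserved random effect of
    unsampled areas).
    """
    if re_policy not in ("conditional_blup", "conditional_zero", "marginal"):
        raise InputError(f"unknown re_policy {re_policy!r}")
    Xcell, _ = cell_design(scheme, fit.spec.fixed)
    base = Xcell @ fit.beta  # (n_cells,)
    t, w = np.polynomial.hermite.hermgauss(marginal_points)
    wn = w / np.sqrt(np.pi)

    probs: dict[str, np.ndarray] = {}
    for a in target_areas:
        a = str(a)
        z_shift = float(
            covariates.vector(a, fit.z_names) @ fit.eta
        ) if fit.z_names else 0.0
        lin = base + z_shift
        sampled = a in fit.mu
        if mu_override is not None and a in mu_override:
            probs[a] = expit(lin + float(mu_override[a]))
            continue
        if re_policy == "conditional_zero":
            mu_star = 0.0
        elif sampled:
            mu_star = fit.mu[a]
        else:
            mu_star = 0.0
        if re_policy == "marginal" and not sampled and fit.sigma_mu > 0:
            nodes = _SQRT2 * fit.sigma_mu * t  # N(0, sigma^2) draws at GH nodes
            probs[a] = expit(lin[:, None] + nodes[None, :]) @ wn
        else:
            probs[a] = expit(lin + mu_star)
    return CellPredictions(scheme, probs)


def compare_models(
    fits: Sequence[tuple[str, GlmmFit]],
    estimates: dict[str, Sequence[AreaEstimate]],
    direct: dict[str, float] | None = None,
    direct_ci: dict[str, tuple[float, float]] | None = None,
) -> dict:
    """Side-by-side comparison of area estimates from several model specs.

    Returns a report with each model's cross-area range (rendered like
    ``"52.5-73.1%"``), a per-area estimate table, and, when direct
    estimates are supplied, MSE/MAD/correlations against them via
    :func:`mrrake.validation.compare_estimates`.
    """
    from .validation import compare_estimates

    if len(fits) < 2:
        raise InputError("compare_models needs at least two fitted specs")
    signatures = {f.survey_signature for _, f in fits}
    if len(signatures) > 1:
        raise InputError("models were fitted on different surveys; comparison is meaningless")
    names = [name for name, _ in fits]
    missing = [n for n in names if n not in estimates]
    if missing:
        raise InputError(f"no estimates supplied for models {missing}")

    table = pd.DataFrame(
        {name: {e.area_id: 100 * e.estimate for e in estimates[name]} for name in names}
    ).sort_index()
    ranges = {}
    for name in names:
        lo, hi = table[name].min(), table[name].max()
        ranges[name] = f"{lo:.1f}–{hi:.1f}%"
    report: dict = {"range": ranges, "table": table}
    if direct is not None:
        report["validation"] = {}
        for name in names:
            model_pct = {a: v for a, v in table[name].items()}
            direct_pct = {str(k): float(v) for k, v in direct.items()}
            report["validation"][name] = compare_estimates(model_pct, direct_pct, direct_ci)
    return report
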