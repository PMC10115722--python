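"""Full-information maximum marginal likelihood (FIML) estimation.

Fits the unidimensional graded response model (2PL when K = 2) and the
complete-independence null model by maximizing the grouped multinomial
likelihood

    L(theta) ∝ prod_c pi_c(theta)^{p_c},

where ``pi_c`` is the marginal probability of response pattern ``c``.  The
substantive model is fitted with the EM algorithm of the Bock-Aitkin type:
the E-step computes the posterior weight of each observed pattern over the
quadrature nodes; the M-step maximizes each item's expected complete-data
log-likelihood.  Intercept ordering for K > 2 is maintained through the
reparameterization alpha_k = alpha_{k-1} - exp(gamma_k), so the M-step is
unconstrained.

The full-information G2 and X2 statistics are available for short tests
where the K^n contingency table can be enumerated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from .data import ResponseData
from .irt_core import (
    ItemParameters,
    category_curves,
    enumerate_pattern_distribution,
)
from .quadrature import QuadratureGrid
from .results import FitStatistics

__all__ = [
    "FittedModel",
    "fit_grm_em",
    "fit_null_model",
    "g2_statistic",
    "x2_statistic",
    "marginal_loglik",
]

SLOPE_CAP = 20.0


@dataclass(frozen=True)
class FittedModel:
    """A fitted IRT model with its log-likelihood and bookkeeping."""

    params: ItemParameters
    loglik: float
    n_iterations: int
    converged: bool
    model_kind: str  # "substantive" | "null"
    dim_theta: int


def _check_categories(data: ResponseData) -> None:
    counts = data.category_counts()
    if counts.min() == 0:
        i, k = np.argwhere(counts == 0)[0]
        raise ValueError(
            f"item {i + 1} has no observed responses in category {k}; "
            "collapse categories before fitting (no silent re-coding is done)"
        )


def marginal_loglik(
    params: ItemParameters, patterns: np.ndarray, counts: np.ndarray, grid: QuadratureGrid
) -> float:
    """Grouped marginal log-likelihood sum_c n_c log pi_c(theta)."""
    logp = np.log(np.clip(category_curves(params, grid.nodes), 1e-300, None))
    ll = np.zeros((patterns.shape[0], grid.n_nodes))
    for i in range(params.n_items):
        ll += logp[i, patterns[:, i], :]
    m = special.logsumexp(ll + np.log(grid.weights)[None, :], axis=1)
    return float(counts @ m)


def _e_step(params, patterns, counts, grid):
    """Posterior-weighted expected category counts r[i, k, q] and loglik."""
    logp = np.log(np.clip(category_curves(params, grid.nodes), 1e-300, None))
    ll = np.zeros((patterns.shape[0], grid.n_nodes))
    for i in range(params.n_items):
        ll += logp[i, patterns[:, i], :]
    a = ll + np.log(grid.weights)[None, :]
    m = special.logsumexp(a, axis=1)
    post = np.exp(a - m[:, None])
    w = counts[:, None] * post  # (P, Q)
    n, K = params.n_items, params.K
    r = np.empty((n, K, grid.n_nodes))
    if K == 2:
        u = patterns.astype(float)
        r[:, 1, :] = u.T @ w
        r[:, 0, :] = w.sum(axis=0)[None, :] - r[:, 1, :]
    else:
        for i in range(n):
            for k in range(K):
                r[i, k, :] = w[patterns[:, i] == k].sum(axis=0)
    return r, float(counts @ m)


def _m_step_2pl(r, x, slopes, intercepts, estimate_slopes, inner_tol=1e-9, max_inner=50):
    """Vectorized per-item Newton updates for the 2PL expected log-likelihood.

    The expected complete-data log-likelihood is concave in (alpha, beta),
    so safeguarded Newton with step halving converges; all items are updated
    simultaneously.
    """
    a = intercepts[:, 0].copy()
    b = slopes[:, 0].copy()
    r1 = r[:, 1, :]
    t = r[:, 0, :] + r1

    def ell(av, bv):
        z = av[:, None] + bv[:, None] * x[None, :]
        # r1*log(C) + r0*log(1-C) = r1*z - t*log(1+exp(z))
        return (r1 * z).sum(axis=1) - (t * np.logaddexp(0.0, z)).sum(axis=1)

    cur = ell(a, b)
    for _ in range(max_inner):
        z = a[:, None] + b[:, None] * x[None, :]
        c = special.expit(z)
        resid = r1 - t * c
        wgt = t * c * (1.0 - c)
        g_a = resid.sum(axis=1)
        g_b = (resid * x[None, :]).sum(axis=1)
        h_aa = wgt.sum(axis=1)
        h_ab = (wgt * x[None, :]).sum(axis=1)
        h_bb = (wgt * x[None, :] ** 2).sum(axis=1)
        if estimate_slopes:
            det = h_aa * h_bb - h_ab**2
            det = np.where(det <= 0, np.inf, det)
            da = (h_bb * g_a - h_ab * g_b) / det
            db = (h_aa * g_b - h_ab * g_a) / det
        else:
            da = g_a / np.where(h_aa <= 0, np.inf, h_aa)
            db = np.zeros_like(da)
        if max(np.abs(da).max(), np.abs(db).max()) < inner_tol:
            break
        step = np.ones_like(da)
        for _half in range(30):
            na, nb = a + step * da, b + step * db
            new = ell(na, nb)
            bad = new < cur - 1e-12
            if not bad.any():
                break
            step[bad] *= 0.5
        a, b = a + step * da, b + step * db
        cur = ell(a, b)
    if estimate_slopes and np.abs(b).max() > SLOPE_CAP:
        warnings.warn("slope estimate capped at |beta| <= 20", stacklevel=3)
        b = np.clip(b, -SLOPE_CAP, SLOPE_CAP)
    return b[:, None], a[:, None]


def _pack_item(beta, alpha, estimate_slopes):
    gamma = np.log(-np.diff(alpha)) if alpha.size > 1 else np.empty(0)
    head = [beta, alpha[0]] if estimate_slopes else [alpha[0]]
    return np.concatenate([np.asarray(head, float), gamma])


def _unpack_item(x, K, beta_fixed, estimate_slopes):
    if estimate_slopes:
        beta, a1, gamma = x[0], x[1], x[2:]
    else:
        beta, a1, gamma = beta_fixed, x[0], x[1:]
    alpha = np.empty(K - 1)
    alpha[0] = a1
    if K > 2:
        alpha[1:] = a1 - np.cumsum(np.exp(gamma))
    return beta, alpha


def _item_objective(x, r_i, nodes_x, K, beta_fixed, estimate_slopes):
    """Negative expected log-likelihood and gradient for one graded item."""
    beta, alpha = _unpack_item(x, K, beta_fixed, estimate_slopes)
    z = alpha[:, None] + beta * nodes_x[None, :]  # (K-1, Q)
    c = special.expit(z)
    full = np.vstack([np.ones_like(nodes_x), c, np.zeros_like(nodes_x)])
    p = np.clip(full[:-1] - full[1:], 1e-12, None)  # (K, Q)
    obj = -(r_i * np.log(p)).sum()
    # d(obj)/dC_k: C_k enters P_k with +1 and P_{k-1} with -1
    ratio = r_i / p
    dc = (ratio[:-1] - ratio[1:]) * c * (1.0 - c)  # (K-1, Q)
    g_alpha = dc.sum(axis=1)
    g_beta = (dc * nodes_x[None, :]).sum(axis=1).sum()
    # chain to (a1, gamma): alpha_k = a1 - sum_{j<=k} exp(gamma_j)
    g_a1 = g_alpha.sum()
    grad = []
    if estimate_slopes:
        grad.append(g_beta)
    grad.append(g_a1)
    if K > 2:
        gamma = x[(2 if estimate_slopes else 1):]
        # d alpha_k / d gamma_j = -exp(gamma_j) for k >= j (k, j are 1-based among 2..K-1)
        tail = np.cumsum(g_alpha[::-1])[::-1][1:]  # sum_{k>=j} g_alpha_k for j=2..K-1
        grad.extend(-np.exp(gamma) * tail)
    return obj, np.asarray(grad)


def _m_step_graded(r, nodes_x, params, estimate_slopes):
    n, K = params.n_items, params.K
    slopes = params.slopes.copy()
    intercepts = params.intercepts.copy()
    for i in range(n):
        x0 = _pack_item(slopes[i, 0], intercepts[i], estimate_slopes)
        bounds = None
        if estimate_slopes:
            bounds = [(-SLOPE_CAP, SLOPE_CAP)] + [(None, None)] * (x0.size - 1)
        res = optimize.minimize(
            _item_objective,
            x0,
            args=(r[i], nodes_x, K, slopes[i, 0], estimate_slopes),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 100, "ftol": 1e-12, "gtol": 1e-10},
        )
        beta, alpha = _unpack_item(res.x, K, slopes[i, 0], estimate_slopes)
        slopes[i, 0] = beta
        intercepts[i] = alpha
    return slopes, intercepts


def fit_null_model(data: ResponseData, smoothing: float = 0.0) -> FittedModel:
    """Closed-form fit of the complete-independence (zero-factor) model.

    Each intercept is the logit of the observed proportion of responses at
    or above category k; there are no slopes and no latent variables.
    """
    counts = data.category_counts().astype(float)
    if smoothing:
        counts = counts + smoothing
    N_eff = counts.sum(axis=1, keepdims=True)
    cum = np.cumsum(counts[:, ::-1], axis=1)[:, ::-1]  # counts of U >= k
    cum_prop = cum[:, 1:] / N_eff
    if np.any(cum_prop <= 0) or np.any(cum_prop >= 1):
        raise ValueError(
            "an observed cumulative proportion is 0 or 1; the logit is infinite. "
            "Pass a positive smoothing constant or collapse categories."
        )
    intercepts = special.logit(cum_prop)
    cat_prop = np.clip(counts / N_eff, 1e-300, None)
    loglik = float((data.category_counts() * np.log(cat_prop)).sum())
    params = ItemParameters(
        slopes=np.zeros((data.n_items, 1)), intercepts=intercepts, K=data.K
    )
    return FittedModel(
        params=params,
        loglik=loglik,
        n_iterations=0,
        converged=True,
        model_kind="null",
        dim_theta=data.n_items * (data.K - 1),
    )


def fit_grm_em(
    data: ResponseData,
    grid: QuadratureGrid | None = None,
    tol: float = 1e-4,
    max_iter: int = 2000,
    start: ItemParameters | None = None,
    estimate_slopes: bool = True,
) -> FittedModel:
    """Fit the unidimensional GRM (2PL for K = 2) by Bock-Aitkin EM.

    Start values are deterministic: unit slopes and intercepts from the
    null-model closed form.  Convergence is declared when the largest
    absolute parameter change falls below ``tol``.  Non-convergence at
    ``max_iter`` yields a flagged result, not an exception.
    """
    _check_categories(data)
    if grid is None:
        grid = QuadratureGrid.normal()
    if grid.n_dim != 1:
        raise ValueError("fit_grm_em fits a unidimensional model; grid must be 1-D")
    patterns, counts = data.grouped()
    counts = counts.astype(float)
    if data.n_respondents < data.n_items * (data.K - 1) + data.n_items:
        warnings.warn("fewer respondents than free parameters", stacklevel=2)

    if start is None:
        null = fit_null_model(data)
        params = ItemParameters(
            slopes=np.ones((data.n_items, 1)) if estimate_slopes else np.zeros((data.n_items, 1)),
            intercepts=null.params.intercepts,
            K=data.K,
        )
    else:
        params = start
    x = grid.nodes[:, 0]

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        r, _ = _e_step(params, patterns, counts, grid)
        if data.K == 2:
            slopes, intercepts = _m_step_2pl(
                r, x, params.slopes, params.intercepts, estimate_slopes
            )
        else:
            slopes, intercepts = _m_step_graded(r, x, params, estimate_slopes)
        delta = max(
            np.abs(slopes - params.slopes).max(),
            np.abs(intercepts - params.intercepts).max(),
        )
        params = ItemParameters(slopes=slopes, intercepts=intercepts, K=data.K)
        if delta < tol:
            converged = True
            break
    loglik = marginal_loglik(params, patterns, counts, grid)
    dim_theta = data.n_items * (data.K - 1) + (data.n_items if estimate_slopes else 0)
    return FittedModel(
        params=params,
        loglik=loglik,
        n_iterations=it,
        converged=converged,
        model_kind="substantive" if estimate_slopes else "null",
        dim_theta=dim_theta,
    )


def _full_cell_proportions(data: ResponseData) -> np.ndarray:
    n, K = data.n_items, data.K
    idx = np.zeros(data.n_respondents, dtype=np.int64)
    for i in range(n):
        idx = idx * K + data.codes[:, i]
    return np.bincount(idx, minlength=K**n) / data.n_respondents


def _full_info_stat(
    data: ResponseData, fitted: FittedModel, grid: QuadratureGrid | None, kind: str
) -> FitStatistics:
    if grid is None:
        grid = QuadratureGrid.normal()
    dist = enumerate_pattern_distribution(fitted.params, grid)
    p_obs = _full_cell_proportions(data)
    pi = dist.probs
    N = data.n_respondents
    if kind == "G2":
        mask = p_obs > 0
        value = 2.0 * N * float(p_obs[mask] @ np.log(p_obs[mask] / pi[mask]))
    else:
        value = N * float(((p_obs - pi) ** 2 / pi).sum())
    df = dist.n_cells - 1 - fitted.dim_theta
    return FitStatistics.from_value(value, df, N, kind)


def g2_statistic(data: ResponseData, fitted: FittedModel, grid=None) -> FitStatistics:
    """Likelihood-ratio G2 over the full contingency table (small n only)."""
    return _full_info_stat(data, fitted, grid, "G2")


def x2_statistic(data: ResponseData, fitted: FittedModel, grid=None) -> FitStatistics:
    """Pearson X2 over the full contingency table (small n only)."""
    return _full_info_stat(data, fitted, grid, "X2")
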