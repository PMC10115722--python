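"""Limited-information goodness of fit: margins, M2, RMSEA, and TLIRT.

Full-information statistics collapse under the sparseness of the K^n
contingency table, so model fit is assessed from the first- and
second-order margins instead.  With ``e2`` the vector of marginal
residuals (observed minus model-implied moments), the M2 statistic is the
quadratic form

    M2 = N e2' [ Xi2^{-1} - Xi2^{-1} D2 (D2' Xi2^{-1} D2)^{-1} D2' Xi2^{-1} ] e2,

where ``Xi2`` is the asymptotic covariance of the sample moments and
``D2`` the Jacobian of the model moments with respect to the free
parameters.  Under exact fit M2 is asymptotically chi-square with
``s - dim(theta)`` degrees of freedom, ``s`` the number of moments.

The moment basis is cumulative: indicators 1{U_i >= k} for the univariate
block and products 1{U_i >= k} 1{U_j >= l} for item pairs i < j.  For
K = 2 this is the standard dichotomous margin vector of length
n + n(n-1)/2; any nonsingular linear transform of the basis leaves M2
unchanged.

The derived indices are the RMSEA, sqrt(max(0, (M2 - df) / (df N))), with
a confidence interval from inverting the noncentral chi-square CDF, and
the Tucker-Lewis index for IRT,

    TLIRT = (X0/df0 - Xm/dfm) / (X0/df0 - 1),

comparing the substantive model's per-degree-of-freedom fit against the
complete-independence null.  TLIRT is deliberately not clamped to (0, 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import linalg, optimize, stats

from .data import ResponseData
from .fiml import FittedModel
from .irt_core import ItemParameters, cumulative_curves
from .quadrature import QuadratureGrid
from .results import FitStatistics

__all__ = [
    "MarginalMoments",
    "observed_margins",
    "model_margins",
    "margin_jacobian",
    "margin_covariance",
    "m2_statistic",
    "n_moments",
    "rmsea_from_chi2",
    "rmsea_confidence_interval",
    "tlirt",
]


# ---------------------------------------------------------------------------
# moment bookkeeping


@dataclass(frozen=True)
class _MarginStructure:
    """Fixed index maps for the moment vector of an (n, K) design.

    Univariate moments are the flattened curve rows a = i(K-1) + (k-1),
    items ascending, categories ascending.  Bivariate moments run over
    pairs i < j in lexicographic order, row-major over the category pair
    (k of item i, l of item j).
    """

    n: int
    K: int
    row_a: np.ndarray  # (s2,) curve-row index of the first member of each product
    row_b: np.ndarray  # (s2,) curve-row index of the second member
    item_a: np.ndarray  # (s2,) item of row_a
    item_b: np.ndarray  # (s2,) item of row_b

    @property
    def s1(self) -> int:
        return self.n * (self.K - 1)

    @property
    def s2(self) -> int:
        return self.row_a.size

    @property
    def s(self) -> int:
        return self.s1 + self.s2


@lru_cache(maxsize=32)
def _margin_structure(n: int, K: int) -> _MarginStructure:
    m = K - 1
    row_a, row_b, item_a, item_b = [], [], [], []
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(m):
                for l in range(m):
                    row_a.append(i * m + k)
                    row_b.append(j * m + l)
                    item_a.append(i)
                    item_b.append(j)
    return _MarginStructure(
        n=n,
        K=K,
        row_a=np.asarray(row_a, dtype=np.int64),
        row_b=np.asarray(row_b, dtype=np.int64),
        item_a=np.asarray(item_a, dtype=np.int64),
        item_b=np.asarray(item_b, dtype=np.int64),
    )


def n_moments(n: int, K: int) -> int:
    """Length s of the order-2 moment vector: n(K-1) + C(n,2)(K-1)^2."""
    return n * (K - 1) + (n * (n - 1) // 2) * (K - 1) ** 2


@lru_cache(maxsize=8)
def _covariance_corrections(n: int, K: int):
    """Index arrays fixing E[m_a m_b] for moment pairs with shared items.

    The outer-product quadrature is only valid when the two moments touch
    disjoint item sets; overlapping products collapse by
    1{U >= k} 1{U >= l} = 1{U >= max(k, l)}, so each correction is a
    product of at most three cumulative curves.  Returns (ia, ib, rows)
    with ``rows`` of shape (n_corr, 3) indexing an extended curve matrix
    whose last row is all ones (padding).
    """
    st = _margin_structure(n, K)
    m = K - 1
    dummy = st.s1  # index of the all-ones padding row

    # moment -> tuple of (item, cat) pairs; cat is 1-based cumulative level
    members = []
    for i in range(n):
        for k in range(1, K):
            members.append(((i, k),))
    for r in range(st.s2):
        i, j = st.item_a[r], st.item_b[r]
        members.append(
            ((int(i), int(st.row_a[r]) - int(i) * m + 1), (int(j), int(st.row_b[r]) - int(j) * m + 1))
        )

    by_item: dict[int, list[int]] = {i: [] for i in range(n)}
    for idx, mem in enumerate(members):
        for (i, _k) in mem:
            by_item[i].append(idx)

    seen = set()
    ia, ib, rows = [], [], []
    for i in range(n):
        lst = by_item[i]
        for p in range(len(lst)):
            for q in range(p + 1, len(lst)):
                a, b = lst[p], lst[q]
                if (a, b) in seen:
                    continue
                seen.add((a, b))
                merged: dict[int, int] = {}
                for (it, k) in members[a] + members[b]:
                    merged[it] = max(merged.get(it, 0), k)
                rr = [it * m + (k - 1) for it, k in sorted(merged.items())]
                while len(rr) < 3:
                    rr.append(dummy)
                ia.append(a)
                ib.append(b)
                rows.append(rr)
    return (
        np.asarray(ia, dtype=np.int64),
        np.asarray(ib, dtype=np.int64),
        np.asarray(rows, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# moments


@dataclass(frozen=True)
class MarginalMoments:
    """Stacked first- and second-order margins in the fixed ordering."""

    uni: np.ndarray
    bi: np.ndarray

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.uni, self.bi])


def observed_margins(data: ResponseData) -> MarginalMoments:
    """Sample proportions of the cumulative moment basis."""
    st = _margin_structure(data.n_items, data.K)
    z = np.empty((data.n_respondents, st.s1))
    for i in range(data.n_items):
        for k in range(1, data.K):
            z[:, i * (data.K - 1) + (k - 1)] = data.codes[:, i] >= k
    uni = z.mean(axis=0)
    zz = (z.T @ z) / data.n_respondents
    bi = zz[st.row_a, st.row_b]
    return MarginalMoments(uni=uni, bi=bi)


def _curve_rows(params: ItemParameters, grid: QuadratureGrid) -> np.ndarray:
    """Cumulative curves flattened to (n(K-1), Q)."""
    cum = cumulative_curves(params, grid.nodes)
    n, m, q = cum.shape
    return cum.reshape(n * m, q)


def model_margins(params: ItemParameters, grid: QuadratureGrid) -> MarginalMoments:
    """Model-implied moments by quadrature; never enumerates K^n cells."""
    st = _margin_structure(params.n_items, params.K)
    cc = _curve_rows(params, grid)
    uni = cc @ grid.weights
    bi = (cc[st.row_a] * cc[st.row_b]) @ grid.weights
    return MarginalMoments(uni=uni, bi=bi)


def margin_jacobian(
    params: ItemParameters, grid: QuadratureGrid, free: str = "all"
) -> np.ndarray:
    """Jacobian of the moment vector with respect to the free parameters.

    Columns are item-major: for ``free="all"`` each item contributes its
    slope column(s) followed by its K-1 intercept columns; for
    ``free="intercepts"`` (the null model) only the intercept columns.
    """
    n, K, D = params.n_items, params.K, params.n_dim
    m = K - 1
    st = _margin_structure(n, K)
    cc = _curve_rows(params, grid)
    dc = cc * (1.0 - cc)
    w = grid.weights
    with_slopes = free == "all"
    per_item = (D if with_slopes else 0) + m
    J = np.zeros((st.s, n * per_item))
    for i in range(n):
        base = i * per_item
        if with_slopes:
            for d in range(D):
                col = base + d
                xd = grid.nodes[:, d]
                for k in range(m):
                    a = i * m + k
                    J[a, col] = (dc[a] * xd) @ w
                for mask, other in (
                    (st.item_a == i, st.row_b),
                    (st.item_b == i, st.row_a),
                ):
                    idx = np.nonzero(mask)[0]
                    own = st.row_a if other is st.row_b else st.row_b
                    J[st.s1 + idx, col] = (dc[own[idx]] * xd[None, :] * cc[other[idx]]) @ w
        for k in range(m):
            a = i * m + k
            col = base + (D if with_slopes else 0) + k
            J[a, col] = dc[a] @ w
            for own, other, mask in (
                (st.row_a, st.row_b, st.row_a == a),
                (st.row_b, st.row_a, st.row_b == a),
            ):
                idx = np.nonzero(mask)[0]
                J[st.s1 + idx, col] = (dc[a][None, :] * cc[other[idx]]) @ w
    return J


def margin_covariance(params: ItemParameters, grid: QuadratureGrid) -> np.ndarray:
    """Asymptotic covariance Xi2 of the sample moments under the model.

    Entries are E[m_a m_b] - E[m_a] E[m_b]; cross-expectations involve
    joint cumulative moments of up to four distinct items, computed by
    quadrature with the overlap corrections of
    :func:`_covariance_corrections`.
    """
    n, K = params.n_items, params.K
    st = _margin_structure(n, K)
    cc = _curve_rows(params, grid)
    w = grid.weights
    rows = np.vstack([cc, cc[st.row_a] * cc[st.row_b]])  # (s, Q)
    mu = rows @ w
    e = (rows * w[None, :]) @ rows.T
    ia, ib, corr_rows = _covariance_corrections(n, K)
    cc_ext = np.vstack([cc, np.ones((1, grid.n_nodes))])
    if ia.size:
        vals = (cc_ext[corr_rows[:, 0]] * cc_ext[corr_rows[:, 1]] * cc_ext[corr_rows[:, 2]]) @ w
        e[ia, ib] = vals
        e[ib, ia] = vals
    np.fill_diagonal(e, mu)  # indicator^2 = indicator
    xi = e - np.outer(mu, mu)
    return xi


# ---------------------------------------------------------------------------
# M2 and derived indices


def _chol_solve(xi: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    try:
        c = linalg.cho_factor(xi, check_finite=False)
    except linalg.LinAlgError:
        jitter = 1e-10 * np.mean(np.diag(xi))
        warnings.warn("Xi2 not positive definite; adding 1e-10 ridge", stacklevel=3)
        c = linalg.cho_factor(xi + jitter * np.eye(xi.shape[0]), check_finite=False)
    return linalg.cho_solve(c, rhs, check_finite=False)


def m2_statistic(
    data: ResponseData, fitted: FittedModel, grid: QuadratureGrid | None = None
) -> FitStatistics:
    """The M2 limited-information statistic for a FIML-fitted model.

    df = s - dim(theta), with s = n(K-1) + C(n,2)(K-1)^2 moments; for the
    null model dim(theta) = n(K-1).
    """
    if grid is None:
        grid = QuadratureGrid.normal()
    params = fitted.params
    free = "all" if fitted.model_kind == "substantive" else "intercepts"
    e2 = observed_margins(data).vector - model_margins(params, grid).vector
    xi = margin_covariance(params, grid)
    delta = margin_jacobian(params, grid, free=free)
    xi_inv_e = _chol_solve(xi, e2)
    xi_inv_d = _chol_solve(xi, delta)
    a = delta.T @ xi_inv_d
    rhs = delta.T @ xi_inv_e
    rank = np.linalg.matrix_rank(a, rtol=1e-8)
    if rank < a.shape[0]:
        warnings.warn(
            f"Jacobian cross-product rank {rank} < {a.shape[0]}; using pseudo-inverse "
            "and reducing df by the rank deficit",
            stacklevel=2,
        )
        middle = rhs @ (np.linalg.pinv(a, rcond=1e-8) @ rhs)
    else:
        middle = rhs @ linalg.solve(a, rhs, assume_a="pos")
    value = max(data.n_respondents * float(e2 @ xi_inv_e - middle), 0.0)
    s = n_moments(data.n_items, data.K)
    df = s - rank
    return FitStatistics.from_value(value, df, data.n_respondents, "M2")


def rmsea_from_chi2(stat: FitStatistics) -> float:
    """RMSEA point estimate sqrt(max(0, (X - df) / (df N)))."""
    if stat.df <= 0 or stat.N <= 0:
        raise ValueError("RMSEA requires df > 0 and N > 0")
    return float(np.sqrt(max(0.0, (stat.value - stat.df) / (stat.df * stat.N))))


def _ncx2_cdf(x: float, df: int, lam: float) -> float:
    if lam <= 0:
        return float(stats.chi2.cdf(x, df))
    return float(stats.ncx2.cdf(x, df, lam))


def rmsea_confidence_interval(stat: FitStatistics, level: float = 0.90):
    """Confidence interval for RMSEA from the noncentral chi-square.

    The bounds invert the noncentral chi-square CDF in the noncentrality
    lambda: F(value; df, lam_L) = 1 - (1-level)/2 and
    F(value; df, lam_U) = (1-level)/2, with each RMSEA bound
    sqrt(lam / (N df)) and the lower bound clamped at 0.
    """
    if stat.df <= 0 or stat.N <= 0:
        raise ValueError("RMSEA requires df > 0 and N > 0")
    x, df, N = stat.value, stat.df, stat.N
    lo_target = (1.0 + level) / 2.0
    hi_target = (1.0 - level) / 2.0

    def solve(target: float) -> float:
        # F is decreasing in lambda; F(x; df, 0) is the central CDF
        if _ncx2_cdf(x, df, 0.0) < target:
            return 0.0
        hi = max(2.0 * (x - df), 10.0)
        while _ncx2_cdf(x, df, hi) > target:
            hi *= 2.0
            if hi > 1e10:
                break
        return float(
            optimize.brentq(lambda lam: _ncx2_cdf(x, df, lam) - target, 0.0, hi, xtol=1e-8)
        )

    lam_l = solve(lo_target)
    lam_u = solve(hi_target)
    return (
        float(np.sqrt(max(lam_l, 0.0) / (N * df))),
        float(np.sqrt(max(lam_u, 0.0) / (N * df))),
    )


def tlirt(stat_m: FitStatistics, stat_0: FitStatistics) -> float:
    """Tucker-Lewis index for IRT from a substantive and a null statistic.

    The ratio is returned raw -- sample values may fall outside (0, 1).
    """
    if stat_m.df <= 0 or stat_0.df <= 0:
        raise ValueError("both statistics need positive degrees of freedom")
    ratio_0 = stat_0.value / stat_0.df
    ratio_m = stat_m.value / stat_m.df
    denom = ratio_0 - 1.0
    if denom == 0.0:
        raise ZeroDivisionError(
            "null-model chi-square/df equals 1: the null model already fits "
            "and the incremental index is undefined"
        )
    return float((ratio_0 - ratio_m) / denom)
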