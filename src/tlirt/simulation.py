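"""Monte Carlo machinery: generating conditions and replication summaries.

Three data-generating regimes are supported for a 30-item graded test:

* ``null`` -- the fitted unidimensional GRM is correct.
* ``misspec1`` -- an independent-cluster two-factor model (items 1-15 on
  factor 1, items 16-30 on factor 2) with latent correlation .8; the
  fitted model remains unidimensional.
* ``misspec2`` -- the two-factor structure is further perturbed by the
  Tucker-Koopman-Linn (TKL) procedure: 50 random "minor factor" loading
  columns with geometrically decaying spread (each column's SD 80% of the
  preceding one) are appended in the common-factor metric, each item's
  minor-factor variance is rescaled so the minor factors absorb 10% of
  the item's unique variance (the classic TKL error proportion), the
  uniqueness shrinks accordingly so each item's total variance stays 1,
  and the result is mapped back to IRT slopes.  This injects pervasive
  model error that no low-dimensional IRT model can absorb.

Item parameters follow the location-step construction: slopes cycle
(1.0, 1.5, 2.0), locations run -1.0(0.5)1.0, steps (1.2, 0.4, -0.4, -1.2)
for K = 5, and items 16-30 duplicate items 1-15.

Each replication generates responses, fits the unidimensional model and
the complete-independence null by FIML, computes M2 for both, and records
the RMSEA and TLIRT.  Per-replication seeds are derived from the master
seed by a counter-based scheme, so conditions are reproducible and safe
to parallelize.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as slinalg
from scipy import special

from .data import ResponseData
from .fiml import fit_grm_em, fit_null_model
from .irt_core import ItemParameters, LocationStepParameters, location_step_to_intercepts
from .limited_info import m2_statistic, rmsea_from_chi2, tlirt
from .quadrature import QuadratureGrid

__all__ = [
    "LOGISTIC_SCALING",
    "SimulationCondition",
    "LoadingMatrix",
    "ConditionSummary",
    "generating_parameters",
    "generate_responses",
    "misspec1_parameters",
    "slopes_to_loadings",
    "loadings_to_slopes",
    "tkl_perturb",
    "run_condition",
    "run_replication",
    "render_tables",
]

#: logistic-to-probit scaling constant used only in loading transforms
LOGISTIC_SCALING = 1.702

_SLOPE_CYCLE = (1.0, 1.5, 2.0)
_LOCATIONS = (-1.0, -0.5, 0.0, 0.5, 1.0)
_STEPS_K5 = (1.2, 0.4, -0.4, -1.2)


def generating_parameters(K: int, n_items: int = 30) -> ItemParameters:
    """Generating item parameters for the 30-item test (K = 2 or 5)."""
    if K not in (2, 5):
        raise ValueError("generating design defines K = 2 or K = 5")
    slopes = []
    intercepts = []
    base = []
    for loc in _LOCATIONS:
        for beta in _SLOPE_CYCLE:
            base.append((beta, loc))
    for item in range(n_items):
        beta, loc = base[item % len(base)]
        steps = np.asarray(_STEPS_K5) if K == 5 else np.zeros(1)
        if K == 2:
            _, alpha = location_step_to_intercepts(
                LocationStepParameters(slope=beta, location=loc, steps=np.zeros(1)), K=2
            )
        else:
            _, alpha = location_step_to_intercepts(
                LocationStepParameters(slope=beta, location=loc, steps=steps), K=K
            )
        slopes.append([beta])
        intercepts.append(alpha)
    return ItemParameters(slopes=np.asarray(slopes), intercepts=np.asarray(intercepts), K=K)


def misspec1_parameters(K: int, n_items: int = 30, latent_corr: float = 0.8):
    """Two-factor independent-cluster generating model with correlated factors.

    The first half of the items loads only on factor 1 and the second half
    only on factor 2, with the same slopes and intercepts as the
    unidimensional design.  Returns ``(params, latent_cov)``.
    """
    uni = generating_parameters(K, n_items)
    half = n_items // 2
    slopes = np.zeros((n_items, 2))
    slopes[:half, 0] = uni.slopes[:half, 0]
    slopes[half:, 1] = uni.slopes[half:, 0]
    latent_cov = np.array([[1.0, latent_corr], [latent_corr, 1.0]])
    return ItemParameters(slopes=slopes, intercepts=uni.intercepts, K=K), latent_cov


def generate_responses(
    params: ItemParameters, latent_cov: np.ndarray, N: int, seed
) -> ResponseData:
    """Draw N respondents: eta ~ MVN(0, latent_cov), categories from the GRM."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    latent_cov = np.atleast_2d(np.asarray(latent_cov, dtype=float))
    try:
        chol = np.linalg.cholesky(latent_cov)
    except np.linalg.LinAlgError:
        # positive semidefinite boundary (e.g. latent correlation exactly 1)
        vals, vecs = np.linalg.eigh(latent_cov)
        if vals.min() < -1e-10:
            raise ValueError("latent covariance must be positive semidefinite") from None
        chol = vecs * np.sqrt(np.clip(vals, 0.0, None))
    eta = rng.standard_normal((N, params.n_dim)) @ chol.T
    lin = eta @ params.slopes.T  # (N, n)
    cum = special.expit(params.intercepts[None, :, :] + lin[:, :, None])  # (N, n, K-1)
    u = rng.random((N, params.n_items))
    codes = (u[:, :, None] < cum).sum(axis=2)
    return ResponseData(codes=codes, K=params.K)


# ---------------------------------------------------------------------------
# loading metric and the TKL perturbation


@dataclass(frozen=True)
class LoadingMatrix:
    """Item loadings in the common-factor (probit) metric.

    ``loadings`` is items x factors with the major columns first;
    ``thresholds`` are the probit-metric category thresholds;
    ``uniqueness`` completes each item's unit variance:
    communality + uniqueness = 1.
    """

    loadings: np.ndarray
    thresholds: np.ndarray
    uniqueness: np.ndarray
    n_major: int
    minor_column_sds: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def communality(self) -> np.ndarray:
        return (self.loadings**2).sum(axis=1)


def slopes_to_loadings(params: ItemParameters) -> LoadingMatrix:
    """Convert logistic slopes/intercepts to factor loadings/thresholds.

    With x = beta/c (c = 1.702), lambda = x / sqrt(1 + |x|^2) and the
    uniqueness is 1 - |lambda|^2; thresholds are
    tau = -alpha sqrt(uniqueness) / c.
    """
    x = params.slopes / LOGISTIC_SCALING
    denom = np.sqrt(1.0 + (x**2).sum(axis=1))
    loadings = x / denom[:, None]
    uniqueness = 1.0 - (loadings**2).sum(axis=1)
    thresholds = -params.intercepts * np.sqrt(uniqueness)[:, None] / LOGISTIC_SCALING
    return LoadingMatrix(
        loadings=loadings,
        thresholds=thresholds,
        uniqueness=uniqueness,
        n_major=params.n_dim,
    )


def loadings_to_slopes(lm: LoadingMatrix, K: int) -> ItemParameters:
    """Inverse of :func:`slopes_to_loadings` (exact round trip)."""
    if np.any(lm.communality >= 1.0):
        raise ValueError("item communality >= 1; loadings are not admissible")
    root_u = np.sqrt(lm.uniqueness)
    slopes = LOGISTIC_SCALING * lm.loadings / root_u[:, None]
    intercepts = -LOGISTIC_SCALING * lm.thresholds / root_u[:, None]
    return ItemParameters(slopes=slopes, intercepts=intercepts, K=K)


def tkl_perturb(
    major: LoadingMatrix,
    n_minor: int = 50,
    decay: float = 0.8,
    minor_prop: float = 0.10,
    seed=None,
) -> LoadingMatrix:
    """Append TKL minor-factor loadings to a major loading structure.

    Minor loadings are drawn normal with mean 0; successive columns have
    standard deviations ``decay`` times the preceding column (first column
    SD 1 -- only relative scales matter).  Each item's minor row is then
    rescaled so the minor factors absorb exactly ``minor_prop`` of that
    item's unique variance (the TKL model-error proportion), and the
    uniqueness shrinks by the same amount so the item's total variance
    stays 1; the major loadings are untouched.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = major.loadings.shape[0]
    if minor_prop == 0.0:
        return LoadingMatrix(
            loadings=np.hstack([major.loadings, np.zeros((n, n_minor))]),
            thresholds=major.thresholds,
            uniqueness=major.uniqueness,
            n_major=major.n_major,
            minor_column_sds=decay ** np.arange(n_minor),
        )
    if not (0.0 < minor_prop < 1.0):
        raise ValueError("minor_prop must lie in [0, 1)")
    h2_major = major.communality
    if np.any(h2_major >= 1.0):
        raise ValueError("major communality must stay below 1")
    minor_var = minor_prop * (1.0 - h2_major)
    sds = decay ** np.arange(n_minor)
    raw = rng.standard_normal((n, n_minor)) * sds[None, :]
    row_var = (raw**2).sum(axis=1)
    if np.any(row_var == 0):
        raise ValueError("degenerate minor draw; cannot scale to the target variance")
    minor = raw * np.sqrt(minor_var / row_var)[:, None]
    uniqueness = 1.0 - h2_major - minor_var
    return LoadingMatrix(
        loadings=np.hstack([major.loadings, minor]),
        thresholds=major.thresholds,
        uniqueness=uniqueness,
        n_major=major.n_major,
        minor_column_sds=sds,
    )


# ---------------------------------------------------------------------------
# replication harness


@dataclass(frozen=True)
class SimulationCondition:
    """One cell of the simulation design."""

    condition_kind: str  # "null" | "misspec1" | "misspec2"
    K: int
    N: int
    reps: int
    seed: int
    n_items: int = 30
    latent_corr: float = 0.8
    n_minor: int = 50
    minor_decay: float = 0.8
    minor_prop: float = 0.10
    cutoffs: tuple = (0.96, 0.97, 0.98, 0.99)
    alphas: tuple = (0.01, 0.05, 0.10)

    def __post_init__(self):
        if self.condition_kind not in ("null", "misspec1", "misspec2"):
            raise ValueError(f"unknown condition {self.condition_kind!r}")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")


@dataclass(frozen=True)
class ConditionSummary:
    """Replication summary for one condition cell.

    Intervals are empirical 5th/95th percentiles across replications.
    """

    condition_kind: str
    K: int
    N: int
    reps: int
    n_converged: int
    m2_mean: float
    m2_var: float
    rejection_rates: dict
    rmsea_mean: float
    rmsea_interval: tuple
    tlirt_mean: float
    tlirt_interval: tuple
    cutoff_rates: dict
    df_m: int
    df_0: int

    def to_dict(self) -> dict:
        d = {
            "condition": self.condition_kind,
            "K": self.K,
            "N": self.N,
            "reps": self.reps,
            "n_converged": self.n_converged,
            "df_m": self.df_m,
            "df_0": self.df_0,
            "m2_mean": self.m2_mean,
            "m2_var": self.m2_var,
            "rmsea_mean": self.rmsea_mean,
            "rmsea_lo": self.rmsea_interval[0],
            "rmsea_hi": self.rmsea_interval[1],
            "tlirt_mean": self.tlirt_mean,
            "tlirt_lo": self.tlirt_interval[0],
            "tlirt_hi": self.tlirt_interval[1],
        }
        for a, r in self.rejection_rates.items():
            d[f"reject_{a}"] = r
        for c, r in self.cutoff_rates.items():
            d[f"cutoff_{c}"] = r
        return d


def _generating_model(cond: SimulationCondition, rng: np.random.Generator):
    """Generating parameters and latent covariance for one replication."""
    if cond.condition_kind == "null":
        params = generating_parameters(cond.K, cond.n_items)
        return params, np.eye(1)
    params2, cov2 = misspec1_parameters(cond.K, cond.n_items, cond.latent_corr)
    if cond.condition_kind == "misspec1":
        return params2, cov2
    # misspec2: TKL perturbation drawn fresh each replication
    major = slopes_to_loadings(params2)
    perturbed = tkl_perturb(
        major,
        n_minor=cond.n_minor,
        decay=cond.minor_decay,
        minor_prop=cond.minor_prop,
        seed=rng,
    )
    params = loadings_to_slopes(perturbed, cond.K)
    latent_cov = slinalg.block_diag(cov2, np.eye(cond.n_minor))
    return params, latent_cov


def run_replication(cond: SimulationCondition, rep: int, grid: QuadratureGrid | None = None):
    """Run one replication of a condition; returns a flat record dict."""
    if grid is None:
        grid = QuadratureGrid.normal()
    rng = np.random.default_rng([cond.seed, rep])
    params, latent_cov = _generating_model(cond, rng)
    data = generate_responses(params, latent_cov, cond.N, rng)
    fitted = fit_grm_em(data, grid=grid)
    null = fit_null_model(data)
    stat_m = m2_statistic(data, fitted, grid)
    stat_0 = m2_statistic(data, null, grid)
    return {
        "rep": rep,
        "M2_m": stat_m.value,
        "df_m": stat_m.df,
        "p_m": stat_m.p,
        "M2_0": stat_0.value,
        "df_0": stat_0.df,
        "p_0": stat_0.p,
        "rmsea": rmsea_from_chi2(stat_m),
        "tlirt": tlirt(stat_m, stat_0),
        "converged": fitted.converged,
        "n_iterations": fitted.n_iterations,
    }


def run_condition(
    cond: SimulationCondition,
    grid: QuadratureGrid | None = None,
    progress=None,
):
    """Run all replications of a condition.

    Returns ``(summary, records)`` where ``records`` is a per-replication
    DataFrame (persisted by the CLI for audit).  Replications whose EM fit
    failed to converge are recorded but excluded from the summary.
    """
    if grid is None:
        grid = QuadratureGrid.normal()
    records = []
    for rep in range(cond.reps):
        records.append(run_replication(cond, rep, grid))
        if progress is not None:
            progress(rep)
    frame = pd.DataFrame.from_records(records)
    ok = frame[frame["converged"]]
    n_failed = int((~frame["converged"]).sum())
    if n_failed:
        warnings.warn(f"{n_failed} replication(s) did not converge; excluded", stacklevel=2)
    m2 = ok["M2_m"].to_numpy()
    tl = ok["tlirt"].to_numpy()
    rm = ok["rmsea"].to_numpy()
    summary = ConditionSummary(
        condition_kind=cond.condition_kind,
        K=cond.K,
        N=cond.N,
        reps=cond.reps,
        n_converged=int(len(ok)),
        m2_mean=float(m2.mean()),
        m2_var=float(m2.var(ddof=1)) if len(ok) > 1 else float("nan"),
        rejection_rates={a: float((ok["p_m"] < a).mean()) for a in cond.alphas},
        rmsea_mean=float(rm.mean()),
        rmsea_interval=(float(np.percentile(rm, 5)), float(np.percentile(rm, 95))),
        tlirt_mean=float(tl.mean()),
        tlirt_interval=(float(np.percentile(tl, 5)), float(np.percentile(tl, 95))),
        cutoff_rates={c: float((tl < c).mean()) for c in cond.cutoffs},
        df_m=int(ok["df_m"].iloc[0]) if len(ok) else 0,
        df_0=int(ok["df_0"].iloc[0]) if len(ok) else 0,
    )
    return summary, frame


def render_tables(summaries) -> pd.DataFrame:
    """Arrange condition summaries as a table in the style of the study.

    One row per (condition, K, N) cell: M2 mean and variance, rejection
    rates, RMSEA and TLIRT means with their empirical 90% intervals, and
    the TLIRT-cutoff rejection rates.
    """
    if not summaries:
        raise ValueError("need at least one summary")
    rows = [s.to_dict() for s in summaries]
    frame = pd.DataFrame.from_records(rows)
    return frame


def format_interval(lo: float, hi: float, decimals: int = 3) -> str:
    return f"({lo:.{decimals}f}, {hi:.{decimals}f})"
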