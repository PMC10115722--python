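"""Item response functions and marginal pattern probabilities.

The graded response model (GRM) expresses the probability of an ordered
category response through cumulative two-parameter logistic curves

    P(U_i >= k | eta) = 1 / (1 + exp(-(alpha_ik + beta_i' eta))),

for k = 1..K-1, with the boundary conventions P(U_i >= 0) = 1 and
P(U_i >= K) = 0, so that

    P(U_i = k | eta) = P(U_i >= k | eta) - P(U_i >= k+1 | eta).

For K = 2 this is exactly the 2PL model.  Responses are conditionally
independent given eta; the marginal probability of an n-item response
pattern is the integral of the product of the item terms against the
latent prior, approximated here on a :class:`~tlirt.quadrature.QuadratureGrid`.

Category codes are 0-based throughout.  Response patterns are ordered
lexicographically with item 1 varying slowest, i.e. from (0,...,0) to
(K-1,...,K-1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quadrature import QuadratureGrid

__all__ = [
    "ItemParameters",
    "LocationStepParameters",
    "PatternDistribution",
    "OrderedThresholdError",
    "category_probabilities",
    "location_step_to_intercepts",
    "intercepts_to_location_step",
    "pattern_probability",
    "enumerate_pattern_distribution",
    "cumulative_curves",
    "category_curves",
]

ENUMERATION_LIMIT = 10**6


class OrderedThresholdError(ValueError):
    """Raised when item intercepts are not strictly decreasing in k."""


@dataclass(frozen=True)
class ItemParameters:
    """Slope-intercept parameters for an n-item GRM with K categories.

    Attributes
    ----------
    slopes : ndarray, shape (n, D)
        Item slopes beta_i on the logistic metric.
    intercepts : ndarray, shape (n, K-1)
        Item intercepts alpha_ik, strictly decreasing in k within each item
        so the cumulative curves are properly ordered.
    K : int
        Number of response categories per item (>= 2).
    """

    slopes: np.ndarray
    intercepts: np.ndarray
    K: int

    def __post_init__(self):
        slopes = np.atleast_2d(np.asarray(self.slopes, dtype=float))
        intercepts = np.atleast_2d(np.asarray(self.intercepts, dtype=float))
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if intercepts.shape[1] != self.K - 1:
            raise ValueError(
                f"expected {self.K - 1} intercepts per item, got {intercepts.shape[1]}"
            )
        if slopes.shape[0] != intercepts.shape[0]:
            raise ValueError("slopes and intercepts must agree on the number of items")
        if self.K > 2 and not np.all(np.diff(intercepts, axis=1) < 0):
            raise OrderedThresholdError(
                "intercepts must be strictly decreasing in k within every item"
            )
        object.__setattr__(self, "slopes", slopes)
        object.__setattr__(self, "intercepts", intercepts)

    @property
    def n_items(self) -> int:
        return self.slopes.shape[0]

    @property
    def n_dim(self) -> int:
        return self.slopes.shape[1]

    def to_json(self, path) -> None:
        payload = {
            "K": self.K,
            "D": self.n_dim,
            "items": [
                {"slopes": list(map(float, s)), "intercepts": list(map(float, a))}
                for s, a in zip(self.slopes, self.intercepts)
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ItemParameters":
        with open(path) as fh:
            payload = json.load(fh)
        slopes = np.array([it["slopes"] for it in payload["items"]], dtype=float)
        intercepts = np.array([it["intercepts"] for it in payload["items"]], dtype=float)
        return cls(slopes=slopes, intercepts=intercepts, K=int(payload["K"]))

    def to_frame(self) -> pd.DataFrame:
        cols = {"item": np.arange(1, self.n_items + 1)}
        for d in range(self.n_dim):
            cols[f"slope_{d + 1}"] = self.slopes[:, d]
        for k in range(self.K - 1):
            cols[f"intercept_{k + 1}"] = self.intercepts[:, k]
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, K: int) -> "ItemParameters":
        slope_cols = sorted(
            (c for c in df.columns if c.startswith("slope_")),
            key=lambda c: int(c.split("_")[1]),
        )
        icpt_cols = [f"intercept_{k + 1}" for k in range(K - 1)]
        return cls(
            slopes=df[slope_cols].to_numpy(float),
            intercepts=df[icpt_cols].to_numpy(float),
            K=K,
        )


@dataclass(frozen=True)
class LocationStepParameters:
    """Location-step parameterization of one graded item.

    The linear predictor ``alpha_ik + beta_i eta`` is rewritten as
    ``beta_i (eta - b_i + d_k)``: ``b_i`` is the overall item location and
    the steps ``d_k`` describe the category boundaries, constrained to sum
    to zero for identification.  ``b_ik = b_i - d_k`` is the traditional
    graded difficulty, so ``alpha_ik = -beta_i * b_ik``.
    """

    slope: float
    location: float
    steps: np.ndarray

    def __post_init__(self):
        steps = np.atleast_1d(np.asarray(self.steps, dtype=float))
        if steps.size and abs(steps.sum()) > 1e-8:
            raise ValueError("step parameters must sum to 0 for identification")
        object.__setattr__(self, "steps", steps)

    @property
    def K(self) -> int:
        return self.steps.size + 1


def location_step_to_intercepts(p: LocationStepParameters, K: int | None = None):
    """Convert (slope, location, steps) to slope-intercept form for one item.

    Returns ``(slope, intercepts)`` with ``alpha_ik = -beta_i (b_i - d_k)``.
    For K = 2 the step term vanishes and ``alpha_i1 = -beta_i b_i``.
    """
    if K is None:
        K = p.K
    if p.steps.size != K - 1:
        raise ValueError(f"expected {K - 1} steps, got {p.steps.size}")
    graded_difficulty = p.location - p.steps
    intercepts = -p.slope * graded_difficulty
    return p.slope, intercepts


def intercepts_to_location_step(slope: float, intercepts: np.ndarray) -> LocationStepParameters:
    """Inverse of :func:`location_step_to_intercepts` for one item.

    Requires a nonzero slope: with ``beta_i = 0`` the location is undefined.
    """
    if slope == 0:
        raise ZeroDivisionError("location is undefined for a zero slope")
    b_ik = -np.asarray(intercepts, dtype=float) / slope
    location = b_ik.mean()
    steps = location - b_ik
    return LocationStepParameters(slope=slope, location=location, steps=steps)


def cumulative_curves(params: ItemParameters, nodes: np.ndarray) -> np.ndarray:
    """Cumulative response curves P(U_i >= k | eta) on a node set.

    Returns an array of shape ``(n, K-1, Q)``.
    """
    nodes = np.atleast_2d(np.asarray(nodes, dtype=float))
    lin = params.slopes @ nodes.T  # (n, Q)
    z = params.intercepts[:, :, None] + lin[:, None, :]
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-z))


def category_curves(params: ItemParameters, nodes: np.ndarray) -> np.ndarray:
    """Category probabilities P(U_i = k | eta), shape ``(n, K, Q)``."""
    cum = cumulative_curves(params, nodes)
    n, _, q = cum.shape
    full = np.empty((n, params.K + 1, q))
    full[:, 0, :] = 1.0
    full[:, 1:-1, :] = cum
    full[:, -1, :] = 0.0
    return full[:, :-1, :] - full[:, 1:, :]


def category_probabilities(params: ItemParameters, item: int, eta) -> np.ndarray:
    """P(U_item = k | eta) for k = 0..K-1 at a single latent point."""
    eta = np.atleast_1d(np.asarray(eta, dtype=float))
    probs = category_curves(params, eta[None, :])[item, :, 0]
    return probs


def _pattern_likelihood(params: ItemParameters, patterns: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    """Conditional probability of each pattern at each node, shape (P, Q)."""
    pcat = category_curves(params, nodes)  # (n, K, Q)
    patterns = np.atleast_2d(patterns)
    out = np.ones((patterns.shape[0], pcat.shape[2]))
    for i in range(params.n_items):
        out *= pcat[i, patterns[:, i], :]
    return out


def pattern_probability(params: ItemParameters, pattern, grid: QuadratureGrid) -> float:
    """Marginal probability of one response pattern by quadrature."""
    pattern = np.asarray(pattern, dtype=int)
    if pattern.min() < 0 or pattern.max() >= params.K:
        raise ValueError("pattern codes must be in 0..K-1")
    lik = _pattern_likelihood(params, pattern[None, :], grid.nodes)
    return float((lik @ grid.weights)[0])


@dataclass(frozen=True)
class PatternDistribution:
    """All ``C = K**n`` response-pattern probabilities in lexicographic order."""

    patterns: np.ndarray  # (C, n) int
    probs: np.ndarray  # (C,)

    @property
    def n_cells(self) -> int:
        return self.probs.size


def all_patterns(n_items: int, K: int) -> np.ndarray:
    """All K**n patterns, lexicographic with item 1 slowest."""
    idx = np.arange(K**n_items)
    cols = []
    for i in range(n_items):
        cols.append((idx // K ** (n_items - 1 - i)) % K)
    return np.column_stack(cols).astype(int)


def enumerate_pattern_distribution(
    params: ItemParameters, grid: QuadratureGrid, limit: int = ENUMERATION_LIMIT
) -> PatternDistribution:
    """Enumerate the full multinomial cell distribution.

    Only feasible for small n; refuses if ``K**n`` exceeds ``limit``.  Used
    for full-information statistics and as an oracle for the
    limited-information machinery.
    """
    n, K = params.n_items, params.K
    n_cells = K**n
    if n_cells > limit:
        raise ValueError(
            f"K^n = {n_cells} exceeds the enumeration limit {limit}; "
            "use limited-information statistics (M2) for long tests"
        )
    pcat = category_curves(params, grid.nodes)  # (n, K, Q)
    lik = np.ones((1, grid.n_nodes))
    for i in range(n):
        lik = (lik[:, None, :] * pcat[i][None, :, :]).reshape(-1, grid.n_nodes)
    probs = lik @ grid.weights
    return PatternDistribution(patterns=all_patterns(n, K), probs=probs)
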