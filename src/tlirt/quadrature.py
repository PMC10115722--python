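"""Quadrature grids for marginalizing over the latent trait distribution.

The marginal probability of a response pattern is an integral of the
conditional (locally independent) pattern probability against the latent
prior ``g(eta)``.  Following common IRT software practice the prior is
discretized on a rectangular grid of equally spaced nodes, with weights
proportional to the multivariate normal density at the nodes and
renormalized to sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["QuadratureGrid"]


@dataclass(frozen=True)
class QuadratureGrid:
    """A discretized latent prior ``g(eta)``.

    Attributes
    ----------
    nodes : ndarray, shape (Q, D)
        Latent-variable evaluation points.
    weights : ndarray, shape (Q,)
        Nonnegative prior weights summing to one.
    cov : ndarray, shape (D, D)
        Latent covariance used to build the weights.
    """

    nodes: np.ndarray
    weights: np.ndarray
    cov: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        nodes = np.atleast_2d(np.asarray(self.nodes, dtype=float))
        if nodes.shape[0] == 1 and nodes.shape[1] > 1 and np.ndim(self.nodes) == 1:
            nodes = nodes.T
        weights = np.asarray(self.weights, dtype=float)
        if weights.ndim != 1 or nodes.shape[0] != weights.shape[0]:
            raise ValueError("nodes and weights must have matching first dimension")
        if np.any(weights < 0):
            raise ValueError("quadrature weights must be nonnegative")
        if abs(weights.sum() - 1.0) > 1e-10:
            raise ValueError("quadrature weights must sum to 1 within 1e-10")
        cov = self.cov if self.cov is not None else np.eye(nodes.shape[1])
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights)
        object.__setattr__(self, "cov", np.asarray(cov, dtype=float))

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_dim(self) -> int:
        return self.nodes.shape[1]

    @classmethod
    def normal(
        cls,
        n_points: int = 49,
        bound: float = 6.0,
        dim: int = 1,
        cov: np.ndarray | None = None,
    ) -> "QuadratureGrid":
        """Rectangular grid with normal-density weights.

        ``n_points`` equally spaced nodes per dimension on ``[-bound, bound]``;
        multidimensional grids are tensor products.  With ``cov`` given, the
        weights use the corresponding multivariate normal density at the
        tensor nodes (e.g. a bivariate normal with correlation rho for D=2).
        """
        if n_points < 2:
            raise ValueError("need at least 2 quadrature points")
        axis = np.linspace(-bound, bound, n_points)
        if dim == 1:
            nodes = axis[:, None]
        else:
            mesh = np.meshgrid(*([axis] * dim), indexing="ij")
            nodes = np.column_stack([m.ravel() for m in mesh])
        if cov is None:
            cov = np.eye(dim)
        cov = np.asarray(cov, dtype=float)
        if cov.shape != (dim, dim):
            raise ValueError(f"cov must be {dim}x{dim}")
        dens = stats.multivariate_normal(mean=np.zeros(dim), cov=cov).pdf(nodes)
        dens = np.atleast_1d(dens)
        weights = dens / dens.sum()
        return cls(nodes=nodes, weights=weights, cov=cov)
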