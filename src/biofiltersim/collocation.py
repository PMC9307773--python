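"""Orthogonal collocation on [0, 1]: nodes, differentiation matrices, weights.

Interior nodes are the roots of the shifted Legendre polynomial of degree
``n_interior``; both endpoints are appended, so a grid has ``n_interior + 2``
nodes in total.  Differentiation matrices come from barycentric Lagrange
differentiation (stable for the small node counts used here, n <= ~30) and
quadrature weights from exact integration of the Lagrange basis, so that
derivatives and integrals of polynomials up to the grid's exactness degree
are reproduced to round-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CollocationGrid", "build_grid", "integrate_profile"]


@dataclass(frozen=True)
class CollocationGrid:
    """Nodes on [0,1] (endpoints included), derivative matrices and weights.

    d1 and d2 map samples-at-nodes to first/second derivative samples; the
    quadrature weights integrate samples over [0, 1] (they sum to 1).
    """

    nodes: np.ndarray
    d1: np.ndarray
    d2: np.ndarray
    quad_weights: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.nodes.size


def _barycentric_weights(x: np.ndarray) -> np.ndarray:
    # w_j = 1 / prod_{k != j} (x_j - x_k); scaled to avoid under/overflow
    n = x.size
    w = np.ones(n)
    for j in range(n):
        diff = x[j] - np.delete(x, j)
        w[j] = 1.0 / np.prod(diff * 4.0)  # factor 4 ~ 1/spacing keeps magnitudes sane
    return w / np.max(np.abs(w))


def _diff_matrix(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    n = x.size
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                d[i, j] = (w[j] / w[i]) / (x[i] - x[j])
        d[i, i] = -np.sum(d[i, np.arange(n) != i])
    return d


def _lagrange_eval(x: np.ndarray, w: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Matrix B with B[q, j] = l_j(pts[q]) via the barycentric formula."""
    diff = pts[:, None] - x[None, :]
    exact = np.isclose(diff, 0.0, atol=1e-15)
    diff_safe = np.where(exact, 1.0, diff)
    terms = w[None, :] / diff_safe
    b = terms / terms.sum(axis=1, keepdims=True)
    b[exact.any(axis=1)] = 0.0
    b[exact] = 1.0
    return b


def build_grid(n_interior: int) -> CollocationGrid:
    """Collocation grid with ``n_interior`` shifted-Legendre interior nodes.

    Parameters
    ----------
    n_interior : number of interior nodes (>= 1); the grid carries
        ``n_interior + 2`` nodes including x=0 and x=1.
    """
    if n_interior < 1:
        raise ValueError(f"n_interior must be >= 1, got {n_interior}")
    roots, _ = np.polynomial.legendre.leggauss(n_interior)
    nodes = np.concatenate(([0.0], (roots + 1.0) / 2.0, [1.0]))
    w = _barycentric_weights(nodes)
    d1 = _diff_matrix(nodes, w)
    # exact on the interpolation space, where the derivative drops a degree
    d2 = d1 @ d1
    # integrate each Lagrange basis polynomial with a Gauss rule that is
    # exact for its degree
    n_total = nodes.size
    gx, gw = np.polynomial.legendre.leggauss(n_total)
    gx01 = (gx + 1.0) / 2.0
    gw01 = gw / 2.0
    basis = _lagrange_eval(nodes, w, gx01)
    quad_weights = gw01 @ basis
    return CollocationGrid(nodes=nodes, d1=d1, d2=d2, quad_weights=quad_weights)


def integrate_profile(grid: CollocationGrid, values: np.ndarray) -> float:
    """Quadrature of node samples over [0, 1]: sum_j w_j * values_j."""
    values = np.asarray(values, dtype=float)
    if values.shape != (grid.n_nodes,):
        raise ValueError(
            f"expected {grid.n_nodes} samples (one per node), got shape {values.shape}"
        )
    return float(grid.quad_weights @ values)
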