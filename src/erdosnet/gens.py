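"""Generalized Erdős numbers (GENs): asymmetric topological closeness.

The closeness E_ij of node i *from the perspective of* node j on a weighted
undirected network is defined self-consistently through a weighted harmonic
mean over j's neighbours,

    W_j / E_ij = sum_{l in C_j} w_jl / (E_il + 1/w_jl),      E_ii = 0,

where W_j is the strength of j and C_j its neighbour set.  Because E_ii = 0,
a direct connection contributes w_ij^2 to the sum, strictly more than any
indirect term, so directly connected nodes are always closer than indirectly
connected ones.  The measure is real-valued, non-local (finite for any pair
in the same component) and asymmetric: a hub is closer to a leaf than the
leaf is to the hub, reflecting that the hub's finite resources are shared
among many neighbours.

The fixed point is found by synchronous (Jacobi) sweeps of the update above,
started from E = 1 and halted when the largest entrywise change drops below
a tolerance (0.005 by default).  Pairs in different components are assigned
``inf``; the importance map sends that sentinel to 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .graph import WeightedGraph

DEFAULT_TOL = 0.005


class ConvergenceError(RuntimeError):
    """Fixed-point iteration did not reach the tolerance within max_sweeps."""


@dataclass
class ClosenessMatrix:
    """GEN matrix with convergence metadata.

    ``E[i, j]`` is the closeness of node i from node j (small = close).
    The diagonal is 0 and cross-component entries are ``inf``.
    """

    E: np.ndarray
    sweeps: int
    residual: float

    @property
    def n(self) -> int:
        return self.E.shape[0]


def gen_sweep(E: np.ndarray, g: WeightedGraph) -> np.ndarray:
    """One synchronous Jacobi sweep of the GEN fixed-point map.

    Entries of E that are ``inf`` (cross-component pairs) stay ``inf``:
    their harmonic contributions vanish, the denominator is 0 and the
    quotient W_j/0 is again ``inf``.  Columns of isolated nodes (W_j = 0)
    are set to ``inf`` with a warning.
    """
    a = g.adjacency
    w_all = a.data
    n = g.n
    strengths = g.strengths
    uniform = w_all.size > 0 and np.all(w_all == w_all[0])
    old = np.errstate(divide="ignore", invalid="ignore")
    with old:
        if uniform:
            w0 = w_all[0]
            # D[i, j] = sum_{l in C_j} w0 / (E[i, l] + 1/w0)  via one spmm
            recip = w0 / (E + 1.0 / w0)
            pattern = a.copy()
            pattern.data = np.ones_like(pattern.data)
            denom = recip @ pattern
        else:
            denom = np.zeros_like(E)
            indptr, indices, data = a.indptr, a.indices, a.data
            for j in range(n):
                nbrs = indices[indptr[j] : indptr[j + 1]]
                if nbrs.size == 0:
                    continue
                wv = data[indptr[j] : indptr[j + 1]]
                denom[:, j] = (wv / (E[:, nbrs] + 1.0 / wv)).sum(axis=1)
        new = strengths[np.newaxis, :] / denom
    new[:, strengths == 0] = np.inf
    if np.any(strengths == 0):
        warnings.warn("isolated node(s): closeness set to inf", stacklevel=2)
    np.fill_diagonal(new, 0.0)
    return new


def compute_gens(
    g: WeightedGraph,
    tol: float = DEFAULT_TOL,
    init: float = 1.0,
    max_sweeps: int = 10_000,
) -> ClosenessMatrix:
    """Iterate :func:`gen_sweep` from a constant start until convergence.

    Parameters
    ----------
    g : WeightedGraph
    tol : float
        Halt when ``max_ij |E(t+1) - E(t)| <= tol`` over same-component pairs.
    init : float
        Constant initial guess for every same-component off-diagonal entry.
    max_sweeps : int
        Guard against (unproven) non-convergence.
    """
    if g.n == 0:
        raise ValueError("empty graph")
    if tol <= 0:
        raise ValueError("tol must be positive")
    _, member = sp.csgraph.connected_components(g.adjacency, directed=False)
    same = member[:, None] == member[None, :]
    E = np.where(same, float(init), np.inf)
    np.fill_diagonal(E, 0.0)
    finite_mask = same & ~np.eye(g.n, dtype=bool)
    for sweep in range(1, max_sweeps + 1):
        new = gen_sweep(E, g)
        np.fill_diagonal(new, 0.0)
        delta = float(np.max(np.abs(new[finite_mask] - E[finite_mask]))) if finite_mask.any() else 0.0
        E = new
        if delta <= tol:
            return ClosenessMatrix(E, sweep, delta)
    raise ConvergenceError(
        f"GEN iteration did not converge in {max_sweeps} sweeps "
        f"(last residual {delta:.3g} > tol {tol})"
    )


def importance(E: ClosenessMatrix | np.ndarray) -> np.ndarray:
    """Importance matrix ψ_ij = 1/E_ij; ψ_ii = 0; inf (cross-component) -> 0."""
    mat = E.E if isinstance(E, ClosenessMatrix) else np.asarray(E)
    with np.errstate(divide="ignore"):
        psi = 1.0 / mat
    psi[~np.isfinite(mat)] = 0.0
    np.fill_diagonal(psi, 0.0)
    return psi
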