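"""Pairwise proximity baselines: mean first passage times and resistance distance.

Both are computed from the weighted graph Laplacian L = diag(W) - w and its
Moore-Penrose pseudoinverse L+.  The random walk is the standard discrete-time
weighted walk with transition probability P_{i->j} = w_ij / W_i.

Conventions
-----------
tau[i, j] : expected number of steps for a walker started at i to first
    reach j (source -> target); asymmetric.
R[i, j]   : effective resistance between i and j with conductances w_ij;
    symmetric, a metric.

The commute-time identity tau_ij + tau_ji = (sum_k W_k) * R_ij ties the two.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .graph import WeightedGraph


def _require_connected(g: WeightedGraph) -> None:
    n_comp, _ = sp.csgraph.connected_components(g.adjacency, directed=False)
    if n_comp != 1:
        raise ValueError(f"graph must be connected (found {n_comp} components)")


def _laplacian_pinv(g: WeightedGraph) -> np.ndarray:
    a = g.adjacency.toarray()
    L = np.diag(g.strengths) - a
    return np.linalg.pinv(L, hermitian=True)


def mfpt_matrix(g: WeightedGraph) -> np.ndarray:
    """Mean first passage times tau[i, j] of the weighted random walk.

    Uses the closed form via the Laplacian pseudoinverse,
    ``tau_ij = sum_k W_k (Lp_ik - Lp_ij - Lp_jk + Lp_jj)``,
    equivalent to solving the absorbing linear system for each target.
    """
    _require_connected(g)
    if g.n == 1:
        return np.zeros((1, 1))
    W = g.strengths
    vol = W.sum()
    Lp = _laplacian_pinv(g)
    d = Lp @ W  # d_i = sum_k Lp_ik W_k
    tau = d[:, None] - d[None, :] + vol * (np.diag(Lp)[None, :] - Lp)
    np.fill_diagonal(tau, 0.0)
    return tau


def mfpt_by_target_solve(g: WeightedGraph) -> np.ndarray:
    """MFPTs by one absorbing linear solve per target (O(N^4); test oracle)."""
    _require_connected(g)
    n = g.n
    a = g.adjacency.toarray()
    P = a / g.strengths[:, None]
    tau = np.zeros((n, n))
    for j in range(n):
        keep = np.arange(n) != j
        A = np.eye(n - 1) - P[np.ix_(keep, keep)]
        h = np.linalg.solve(A, np.ones(n - 1))
        tau[keep, j] = h
    return tau


def resistance_matrix(g: WeightedGraph) -> np.ndarray:
    """Resistance distance R_ij = Lp_ii + Lp_jj - 2 Lp_ij (symmetric metric)."""
    _require_connected(g)
    Lp = _laplacian_pinv(g)
    dg = np.diag(Lp)
    R = dg[:, None] + dg[None, :] - 2.0 * Lp
    np.fill_diagonal(R, 0.0)
    return R
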