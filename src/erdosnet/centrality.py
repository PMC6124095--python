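"""Centrality measures and rank-comparison metrics.

Two centralities derive from the GEN importance matrix psi (psi_ij = 1/E_ij,
the importance node j assigns to node i):

* Erdős centrality  Psi_i = sum_{l in C_i} psi_il — importance assigned to i
  by its direct neighbours.
* Importance eigenvector centrality g_i — stationary probability of the
  random walk whose step j -> i has probability proportional to psi_ij.
  Unlike PageRank's uniform teleportation, this walk jumps to non-neighbours
  with a probability set by the network topology itself (heterogeneous
  teleportation); low-degree nodes teleport almost surely on large networks.

Classical reference measures (degree, PageRank, betweenness, random-walk and
non-backtracking centrality) and the top-n rank-intersection metric lambda
used to compare orderings are also provided.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .graph import ParameterError, WeightedGraph


# -- GEN-derived measures ---------------------------------------------------


def erdos_centrality(psi: np.ndarray, g: WeightedGraph) -> np.ndarray:
    """Psi_i = sum over neighbours l of i of psi[i, l]."""
    a = g.adjacency
    pattern = a.copy()
    pattern.data = np.ones_like(pattern.data)
    return np.asarray((pattern.multiply(psi)).sum(axis=1)).ravel()


def importance_transition(psi: np.ndarray) -> np.ndarray:
    """Row-stochastic importance walk P[j, i] = psi_ij / sum_{l != j} psi_lj.

    The walker at j steps to i with probability proportional to the
    importance j assigns to i; it never stays put (zero diagonal).
    """
    col = psi.sum(axis=0)  # psi_jj = 0 already
    if np.any(col <= 0):
        raise ValueError("node with no importance toward any other node")
    P = (psi / col[np.newaxis, :]).T
    np.fill_diagonal(P, 0.0)
    return P


def teleport_probability(psi: np.ndarray, g: WeightedGraph, i: int) -> float:
    """Probability the importance walk leaves i toward a non-neighbour."""
    P = importance_transition(psi)
    mask = np.ones(g.n, dtype=bool)
    mask[i] = False
    mask[g.neighbors(i)] = False
    return float(P[i, mask].sum())


def leading_eigenvector(P: np.ndarray, tol: float = 1e-12, max_iter: int = 100_000) -> np.ndarray:
    """Stationary distribution of a row-stochastic transition matrix.

    Dense eigen-decomposition for N <= 2000, power iteration beyond;
    normalized to sum 1, deterministic to ~1e-10.
    """
    P = np.asarray(P)
    n = P.shape[0]
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition matrix is not row-stochastic")
    if n <= 2000:
        vals, vecs = np.linalg.eig(P.T)
        lead = int(np.argmin(np.abs(vals - 1.0)))
        v = np.abs(np.real(vecs[:, lead]))
    else:
        v = np.full(n, 1.0 / n)
        for _ in range(max_iter):
            nxt = v @ P
            if np.max(np.abs(nxt - v)) < tol:
                v = nxt
                break
            v = nxt
        else:
            raise RuntimeError("power iteration did not converge")
    return v / v.sum()


# -- classical measures -----------------------------------------------------


def pagerank(g: WeightedGraph, gamma: float) -> np.ndarray:
    """PageRank Pr_i = (1-gamma)/N + gamma * sum_{j in C_i} Pr_j / k_j.

    Solved as a dense linear system for gamma < 1; at gamma = 1 the walk has
    no teleportation and the stationary distribution W_i / sum_k W_k (k_i/2M
    on unweighted graphs) is returned.  Normalized to sum 1.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ParameterError(f"gamma must be in [0, 1]; got {gamma}")
    n = g.n
    k = g.degrees.astype(float)
    if gamma == 1.0:
        W = g.strengths
        return W / W.sum()
    a = (g.adjacency != 0).toarray().astype(float)
    M = np.divide(a, k[np.newaxis, :], out=np.zeros_like(a), where=k > 0)
    pr = np.linalg.solve(np.eye(n) - gamma * M, np.full(n, (1.0 - gamma) / n))
    return pr / pr.sum()


def degree_centrality(g: WeightedGraph) -> np.ndarray:
    return g.degrees.astype(float)


def betweenness_centrality(g: WeightedGraph) -> np.ndarray:
    """Shortest-path betweenness (unweighted paths), via networkx."""
    bc = nx.betweenness_centrality(g.to_networkx(), normalized=True)
    return np.array([bc[i] for i in range(g.n)])


def random_walk_centrality(tau: np.ndarray) -> np.ndarray:
    """Node potential c from MFPT asymmetries, c_i = mean_k (tau_ik - tau_ki).

    For the reversible walk on a connected graph the pairwise identity
    ``tau_ij - tau_ji = c_i - c_j`` holds exactly; central (easily reached)
    nodes get the largest c.  Raises if the identity residual exceeds 1e-8.
    """
    tau = np.asarray(tau)
    c = tau.mean(axis=1) - tau.mean(axis=0)
    resid = np.max(np.abs((tau - tau.T) - (c[:, None] - c[None, :])))
    if resid > 1e-8:
        raise ValueError(f"MFPT potential identity violated (residual {resid:.3g})")
    return c


def _hashimoto(g: WeightedGraph) -> tuple[sp.csr_array, np.ndarray]:
    """Sparse non-backtracking (Hashimoto) matrix and directed-edge heads."""
    ends = []
    for u, v, _ in g.edges:
        ends.append((u, v))
        ends.append((v, u))
    ends = np.array(ends)  # directed edge e: ends[e] = (tail, head)
    n_dir = len(ends)
    by_tail: dict[int, list[int]] = {}
    for e, (u, _) in enumerate(ends):
        by_tail.setdefault(int(u), []).append(e)
    rows, cols = [], []
    for e, (u, v) in enumerate(ends):
        for f in by_tail.get(int(v), []):
            if ends[f][1] != u:  # forbid immediate reversal
                rows.append(e)
                cols.append(f)
    B = sp.csr_array(
        (np.ones(len(rows)), (rows, cols)), shape=(n_dir, n_dir)
    )
    return B, ends[:, 1]


def nonbacktracking_centrality(g: WeightedGraph) -> np.ndarray:
    """Leading-eigenvector centrality of the 2M x 2M non-backtracking matrix.

    Node score = sum of the Perron eigenvector over incoming directed edges,
    normalized to sum 1.  Raises on forests (spectral radius 0).
    """
    if nx.is_forest(g.to_networkx()):
        raise ValueError("non-backtracking centrality undefined on a forest")
    B, heads = _hashimoto(g)
    n_dir = B.shape[0]
    if n_dir <= 2000:
        vals, vecs = np.linalg.eig(B.toarray())
        lead = int(np.argmax(np.real(vals)))
        y = np.abs(np.real(vecs[:, lead]))
    else:
        vals, vecs = spla.eigs(B.astype(float), k=1, which="LR")
        y = np.abs(np.real(vecs[:, 0]))
    score = np.bincount(heads, weights=y, minlength=g.n)
    return score / score.sum()


# -- rankings and the intersection metric -----------------------------------


def rank_nodes(scores: np.ndarray) -> np.ndarray:
    """Node ids sorted by descending score; ties broken by ascending id."""
    scores = np.asarray(scores)
    return np.lexsort((np.arange(scores.size), -scores))


def lambda_curve(oX: np.ndarray, oY: np.ndarray) -> np.ndarray:
    """lambda_XY(n) for every n = 1..N in O(N log N).

    lambda_XY(n) = (1/n) sum_{k<=n} |top_k(X) ∩ top_k(Y)| / k.
    """
    oX = np.asarray(oX)
    oY = np.asarray(oY)
    N = oX.size
    if sorted(oX.tolist()) != list(range(N)) or sorted(oY.tolist()) != list(range(N)):
        raise ParameterError("rankings must be permutations of 0..N-1")
    posY = np.empty(N, dtype=int)
    posY[oY] = np.arange(N)
    p = posY[oX]
    # element at X-rank j (0-based) is in both top-k sets for k-1 >= max(j, p_j)
    entry = np.maximum(np.arange(N), p) + 1  # smallest k counting this element
    counts = np.cumsum(np.bincount(entry, minlength=N + 2)[1 : N + 1])
    k = np.arange(1, N + 1)
    return np.cumsum(counts / k) / k


def top_n_intersection(oX: np.ndarray, oY: np.ndarray, n: int) -> float:
    """Fractional top-n rank agreement lambda_XY(n) in [0, 1]."""
    N = len(oX)
    if not 1 <= n <= N:
        raise ParameterError(f"n must be in [1, {N}]; got {n}")
    return float(lambda_curve(oX, oY)[n - 1])
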