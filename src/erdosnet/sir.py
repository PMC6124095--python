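"""Exact stochastic (Gillespie) SIR epidemics on networks.

Each susceptible-infected contact edge (i infectious, j susceptible) fires
at rate r_I * w_ij; each infected node recovers at rate r_R.  Inter-event
times are drawn from the competing-exponentials distribution, so the
simulation is statistically exact for the continuous-time Markov SIR model.

The pairwise epidemic proximity used downstream is the harmonic-mean
infection time over K repeated outbreaks seeded at i,

    h_ij = K / sum_k 1 / t_{i->j}^(k),

with runs in which j is never infected contributing 0 to the reciprocal sum
(t = inf), so stochastic die-off lowers closeness instead of being
discarded.

The inner event loop is compiled with numba; node selection is a linear
scan over per-node infection pressures, recomputed each event so that no
floating-point drift accumulates over long runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .graph import WeightedGraph


@dataclass(frozen=True)
class SIRParams:
    """Infection rate per S-I contact (per unit time) and per-node recovery rate."""

    r_I: float
    r_R: float

    def __post_init__(self) -> None:
        if self.r_I <= 0:
            raise ValueError("r_I must be positive")
        if self.r_R < 0:
            raise ValueError("r_R must be non-negative")


@dataclass
class EpidemicRun:
    """Outcome of one outbreak: per-node infection/recovery times (inf = never)."""

    source: int
    infection_time: np.ndarray
    recovery_time: np.ndarray
    seed: int


@njit(cache=False)
def _gillespie_kernel(indptr, indices, weights, n, source, r_I, r_R, seed):
    np.random.seed(seed)
    state = np.zeros(n, dtype=np.uint8)  # 0=S 1=I 2=R
    t_inf = np.full(n, np.inf)
    t_rec = np.full(n, np.inf)
    pressure = np.zeros(n)  # sum of w over infected neighbours, susceptibles only
    infected = np.empty(n, dtype=np.int64)
    n_inf = 1
    infected[0] = source
    state[source] = 1
    t_inf[source] = 0.0
    for idx in range(indptr[source], indptr[source + 1]):
        pressure[indices[idx]] += weights[idx]
    t = 0.0
    while n_inf > 0:
        total_p = 0.0
        for v in range(n):
            if state[v] == 0:
                total_p += pressure[v]
        rate_inf = r_I * total_p
        rate_rec = r_R * n_inf
        total = rate_inf + rate_rec
        if total <= 0.0:
            break
        t += np.random.exponential(1.0 / total)
        if np.random.random() * total < rate_inf:
            # infection: susceptible chosen proportionally to its pressure
            r = np.random.random() * total_p
            c = 0.0
            v = -1
            for u in range(n):
                if state[u] == 0 and pressure[u] > 0.0:
                    c += pressure[u]
                    v = u
                    if r < c:
                        break
            state[v] = 1
            t_inf[v] = t
            infected[n_inf] = v
            n_inf += 1
            pressure[v] = 0.0
            for idx in range(indptr[v], indptr[v + 1]):
                u = indices[idx]
                if state[u] == 0:
                    pressure[u] += weights[idx]
        else:
            j = np.int64(np.random.random() * n_inf)
            if j >= n_inf:
                j = n_inf - 1
            v = infected[j]
            infected[j] = infected[n_inf - 1]
            n_inf -= 1
            state[v] = 2
            t_rec[v] = t
            for idx in range(indptr[v], indptr[v + 1]):
                u = indices[idx]
                if state[u] == 0:
                    pressure[u] -= weights[idx]
    return t_inf, t_rec


def gillespie_sir(
    g: WeightedGraph, source: int, params: SIRParams, seed: int
) -> EpidemicRun:
    """One exact SIR outbreak seeded at ``source``; runs until no infecteds remain."""
    if not 0 <= source < g.n:
        raise ValueError(f"source {source} out of range")
    a = g.adjacency
    t_inf, t_rec = _gillespie_kernel(
        a.indptr,
        a.indices,
        a.data,
        g.n,
        int(source),
        float(params.r_I),
        float(params.r_R),
        np.uint32(seed),
    )
    return EpidemicRun(source, t_inf, t_rec, int(seed))


def harmonic_infection_times(
    g: WeightedGraph,
    params: SIRParams,
    K: int,
    seed: int,
    sources: np.ndarray | None = None,
) -> np.ndarray:
    """N x N matrix of harmonic-mean infection times h[i, j].

    K outbreaks are simulated from each source i (all nodes by default);
    rows for unsimulated sources are NaN.  h_ii = 0; h_ij = inf when j is
    infected in no run.  Run seeds derive deterministically from ``seed``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if sources is None:
        sources = np.arange(g.n)
    sources = np.asarray(sources)
    a = g.adjacency
    h = np.full((g.n, g.n), np.nan)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(sources))
    for row, (src, child) in enumerate(zip(sources, children)):
        run_seeds = child.generate_state(K, dtype=np.uint32)
        recip = np.zeros(g.n)
        for k in range(K):
            t_inf, _ = _gillespie_kernel(
                a.indptr, a.indices, a.data, g.n,
                int(src), float(params.r_I), float(params.r_R), run_seeds[k],
            )
            finite = np.isfinite(t_inf)
            finite[src] = False
            recip[finite] += 1.0 / t_inf[finite]
        with np.errstate(divide="ignore"):
            h[src] = K / recip
        h[src, src] = 0.0
    return h


def epidemic_threshold(g: WeightedGraph, params: SIRParams) -> tuple[bool, float]:
    """Whether r_I > r_R / <k> (strict), and the margin r_I * <k> / r_R."""
    k_mean = g.mean_degree
    if params.r_R == 0:
        return True, np.inf
    margin = params.r_I * k_mean / params.r_R
    return margin > 1.0, margin
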