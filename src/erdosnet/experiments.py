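"""Validation experiments: power-law fits of infection time against closeness,
asymmetry regression between GENs and MFPTs, disconnected-closeness scaling,
and centrality rank-overlap sweeps over random-graph ensembles.

Index conventions: h[i, j] is the infection time of j for an outbreak seeded
at i; it is compared against x[i, j] = E[j, i] (closeness of j from i's
perspective), tau[i, j] and R[i, j].  Each predictor is normalized by its
grand mean <x> = N^-2 sum_ij x_ij before fitting, so the fitted prefactor c
absorbs the arbitrary scale of the closeness measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import pearsonr

from . import centrality as ct
from .gens import compute_gens, importance
from .graph import ParameterError, WeightedGraph, generate_ba, generate_er, largest_component
from .proximity import mfpt_matrix


@dataclass(frozen=True)
class EnsembleSpec:
    """Parameters of a random-graph ensemble sweep."""

    model: str  # "ER" or "BA"
    n_nodes: int
    mean_degree: float
    n_realizations: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model.upper() not in ("ER", "BA"):
            raise ParameterError(f"unknown model {self.model!r}")
        if self.n_realizations < 1:
            raise ParameterError("n_realizations must be >= 1")
        if self.mean_degree >= self.n_nodes:
            raise ParameterError("mean_degree must be below n_nodes")

    def realizations(self):
        """Yield the graphs of the ensemble with derived per-realization seeds."""
        child_seeds = np.random.SeedSequence(self.seed).generate_state(
            self.n_realizations, dtype=np.uint32
        )
        for s in child_seeds:
            s = int(s) % (2**31)
            if self.model.upper() == "ER":
                yield generate_er(self.n_nodes, self.mean_degree, s)
            else:
                m = max(1, round(self.mean_degree / 2))
                yield generate_ba(self.n_nodes, m, s)


@dataclass
class FitResult:
    """Power-law fit y = c * xhat^alpha with residual statistics."""

    c: float
    alpha: float
    sigma: float  # residual standard deviation
    m: float  # mean residual
    n_pairs: int
    filters: dict = field(default_factory=dict)


def power_law_fit(
    y: np.ndarray,
    x: np.ndarray,
    g: WeightedGraph,
    min_target_degree: int = 0,
    exclude_neighbours: bool = True,
) -> FitResult:
    """Nonlinear least-squares fit of y = c * (x/<x>)^alpha over node pairs.

    Pairs used: i != j, both entries finite and positive, non-adjacent when
    ``exclude_neighbours``, and target degree k_j > min_target_degree.  The
    fit is performed in linear space (so the mean residual m is meaningful),
    seeded from a log-log regression.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = g.n
    finite_x = np.isfinite(x)
    xmean = x[finite_x].sum() / n**2  # grand mean over all ordered pairs
    xhat = x / xmean
    mask = np.isfinite(y) & finite_x & (y > 0) & (x > 0)
    np.fill_diagonal(mask, False)
    if exclude_neighbours:
        mask &= ~(g.adjacency.toarray() > 0)
    mask &= (g.degrees > min_target_degree)[np.newaxis, :]
    xv, yv = xhat[mask], y[mask]
    if xv.size < 10:
        raise ValueError(f"only {xv.size} usable pairs (need >= 10)")
    slope, intercept = np.polyfit(np.log(xv), np.log(yv), 1)
    p0 = (float(np.exp(intercept)), float(slope))
    popt, _ = curve_fit(lambda t, c, a: c * t**a, xv, yv, p0=p0, maxfev=20_000)
    resid = yv - popt[0] * xv ** popt[1]
    return FitResult(
        c=float(popt[0]),
        alpha=float(popt[1]),
        sigma=float(np.sqrt(np.mean(resid**2))),
        m=float(np.mean(resid)),
        n_pairs=int(xv.size),
        filters={
            "min_target_degree": min_target_degree,
            "exclude_neighbours": exclude_neighbours,
        },
    )


@dataclass
class AsymmetryResult:
    """Regression of MFPT asymmetry on GEN asymmetry for one network."""

    slope: float  # raw least-squares slope through the origin, dtau vs dE
    slope_normalized: float  # slope of dtau vs dE/<E> (= slope * <E>)
    alpha: float  # |slope_normalized| / N, the scaling coefficient
    correlation: float
    convention: str  # sign convention used for the MFPT difference


def asymmetry_slope(E: np.ndarray, tau: np.ndarray, n_nodes: int) -> AsymmetryResult:
    """Slope of Delta-tau against Delta-E over all ordered pairs.

    Delta-E_ij = E_ij - E_ji and Delta-tau_ij = tau_ji - tau_ij; the point
    cloud is antisymmetric so the least-squares line passes through the
    origin.  Because the GEN scale is arbitrary (no dynamic units), the
    scaling coefficient alpha is extracted with the GEN asymmetry divided by
    the grand mean <E> = N^-2 sum_ij E_ij, the same normalization used for
    the infection-time fits: Delta-tau ~ -(Delta-E/<E>) * alpha * N.  The
    raw slope is also reported so alternative readings can be checked.
    """
    E = np.asarray(E)
    tau = np.asarray(tau)
    n = E.shape[0]
    off = ~np.eye(n, dtype=bool)
    dE = (E - E.T)[off]
    dTau = (tau.T - tau)[off]
    ok = np.isfinite(dE) & np.isfinite(dTau)
    dE, dTau = dE[ok], dTau[ok]
    if dE.size == 0 or np.allclose(dE, 0.0):
        raise ValueError("GEN asymmetries all zero: slope undefined")
    slope = float(np.dot(dE, dTau) / np.dot(dE, dE))
    e_mean = float(E[np.isfinite(E)].sum()) / n**2
    corr = float(pearsonr(dE, dTau).statistic)
    return AsymmetryResult(
        slope=slope,
        slope_normalized=slope * e_mean,
        alpha=abs(slope) * e_mean / n_nodes,
        correlation=corr,
        convention="dtau_ij = tau_ji - tau_ij vs dE_ij = E_ij - E_ji",
    )


def loglog_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Least-squares slope of log y against log x (power-law exponent)."""
    slope, _ = np.polyfit(np.log(np.asarray(x, float)), np.log(np.asarray(y, float)), 1)
    return float(slope)


def disconnected_closeness_scaling(specs: list[EnsembleSpec], tol: float = 0.005) -> float:
    """Log-log slope of mean non-neighbour closeness E_d against network size.

    For each ensemble, E is averaged over ordered same-component non-adjacent
    pairs and over realizations; a log-log regression across ensemble sizes
    gives the scaling exponent (expected ~1/2 for sparse ER networks).
    """
    if len(specs) < 3:
        raise ParameterError("need at least 3 network sizes")
    sizes, means = [], []
    for spec in specs:
        vals = []
        for g in spec.realizations():
            E = compute_gens(g, tol=tol).E
            adj = g.adjacency.toarray() > 0
            mask = np.isfinite(E) & ~adj
            np.fill_diagonal(mask, False)
            vals.append(E[mask].mean())
        sizes.append(spec.n_nodes)
        means.append(np.mean(vals))
    return loglog_slope(sizes, means)


OVERLAP_METHODS = ("degree", "pagerank", "betweenness", "random_walk", "nonbacktracking")


def centrality_overlap_experiment(
    spec: EnsembleSpec,
    methods: tuple[str, ...] = OVERLAP_METHODS,
    gamma: float = 0.85,
    tol: float = 0.005,
) -> pd.DataFrame:
    """Ensemble-averaged lambda(n) between the Erdős-centrality ranking and others.

    Returns a DataFrame indexed by n = 1..N with one column per method.
    Disconnected realizations are reduced to their largest component (the
    index then runs to the smallest component size across realizations).
    """
    curves: dict[str, list[np.ndarray]] = {m: [] for m in methods}
    for g in spec.realizations():
        g, _ = largest_component(g)
        psi = importance(compute_gens(g, tol=tol))
        o_erdos = ct.rank_nodes(ct.erdos_centrality(psi, g))
        tau = None
        for method in methods:
            if method == "degree":
                scores = ct.degree_centrality(g)
            elif method == "pagerank":
                scores = ct.pagerank(g, gamma)
            elif method == "betweenness":
                scores = ct.betweenness_centrality(g)
            elif method == "random_walk":
                tau = mfpt_matrix(g) if tau is None else tau
                scores = ct.random_walk_centrality(tau)
            elif method == "nonbacktracking":
                scores = ct.nonbacktracking_centrality(g)
            else:
                raise ParameterError(f"unknown method {method!r}")
            curves[method].append(ct.lambda_curve(o_erdos, ct.rank_nodes(scores)))
    n_min = min(len(c) for m in methods for c in curves[m])
    data = {m: np.mean([c[:n_min] for c in curves[m]], axis=0) for m in methods}
    return pd.DataFrame(data, index=pd.RangeIndex(1, n_min + 1, name="n"))


def importance_eigenvector_degree_exponent(
    specs: list[EnsembleSpec], tol: float = 0.005
) -> float:
    """Log-log regression exponent of g_i against degree k_i, per ensemble.

    For each realization the GEN importance transition matrix is built and
    its stationary vector g computed.  Within an ensemble (fixed N and mean
    degree, hence a common prefactor) the (log k, log g) points of all
    realizations are pooled into one regression; the exponents of the
    ensembles are then averaged.  Pooling *across* ensembles would mix
    different prefactors and bias the exponent low.
    """
    exponents = []
    for spec in specs:
        logk, logg = [], []
        for g in spec.realizations():
            g, _ = largest_component(g)
            psi = importance(compute_gens(g, tol=tol))
            P = ct.importance_transition(psi)
            gi = ct.leading_eigenvector(P)
            k = g.degrees.astype(float)
            logk.append(np.log(k))
            logg.append(np.log(gi))
        slope, _ = np.polyfit(np.concatenate(logk), np.concatenate(logg), 1)
        exponents.append(float(slope))
    return float(np.mean(exponents))
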