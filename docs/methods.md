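# Methods

## The closeness model

`erdosnet` implements a pairwise measure of topological closeness on a
weighted undirected network in which nodes share a finite resource.  The
closeness E_ij of node i as felt by node j is defined self-consistently
through a weighted harmonic mean over j's neighbourhood C_j:

    W_j / E_ij = Σ_{l ∈ C_j} w_jl / (E_il + 1/w_jl),     E_ii ≡ 0,

with w_jl the edge weight and W_j = Σ_l w_jl the strength of j.  Three
properties follow directly from this form and drive everything else in the
package:

* **Non-locality.** E_ij is finite for every pair in the same component,
  even with no shared neighbours; cross-component pairs carry an `inf`
  sentinel.
* **Asymmetry.** E_ij ≠ E_ji in general.  A hub divides its attention among
  many neighbours, so a leaf is far from the hub's perspective while the hub
  is near from the leaf's (star graph: E_{hub,leaf} = 1 < E_{leaf,hub} = 2).
* **Finite resources.** Attaching extra neighbours to a node strictly
  *increases* its closeness values toward everyone else (the chain with q
  extra leaves on one end: E grows monotonically in q), in contrast to
  resistance distance, which can only decrease when edges are added.

A degenerate consequence worth knowing: q disjoint 2-paths between a pair
give exactly the same E for every q, because each mid-node relation reduces
to the degree-one identity E_ij = E_ik + 1/w_jk.  Multiple routes do help in
less symmetric arrangements (adding a 2-path beside a 3-path lowers the
end-to-end E from 4.588 to 3.236); the naive "more paths, closer" intuition
is not a theorem of this model and is not asserted as one in the tests.

## Solver

The fixed point is computed by synchronous (Jacobi) sweeps of the defining
update, all entries updated from the previous iterate, with E_ii = 0
re-imposed after every sweep.  Defaults: constant start E = 1, halting rule
max_ij |E(t+1) − E(t)| ≤ 0.005, a guard of 10 000 sweeps (convergence is
unproven in general; every graph family exercised here converges — typical
sweep counts at the default tolerance are ~30 for toy graphs, ~130 for
ER(512, ⟨k⟩=20), ~550 for ER(1024, ⟨k⟩=4)).  A sweep costs O(NM); for
uniform-weight graphs it is a single dense×sparse product.  Isolated nodes
get `inf` columns with a warning.  Note the halting rule bounds the last
*change*, not the distance to the fixed point; tests that check closed forms
to better than the default tolerance use a tighter one.

Importance is the elementwise inverse, ψ_ij = 1/E_ij (diagonal and
cross-component entries 0).

## Centralities

* **Erdős centrality** Ψ_i = Σ_{l∈C_i} ψ_il, the importance i's direct
  neighbours assign to it.
* **Importance eigenvector centrality** g: stationary distribution of the
  walk P[j→i] = ψ_ij / Σ_{l≠j} ψ_lj.  The denominator is the one choice
  that makes each row a probability distribution over destinations, and it
  reproduces the closed-form degree-one teleport probability
  1 − (Σ_{l≠i} ψ_li)^{-1} exactly.  The stationary
  vector is obtained from a dense eigen-decomposition for N ≤ 2000 and
  power iteration (tol 1e−12, ≤1e5 iterations) beyond.
* **PageRank** at damping γ is solved as a dense linear system; γ = 1
  returns the exact random-walk stationary law W_i/ΣW.
* **Random-walk centrality** is the potential c_i = mean_k(τ_ik − τ_ki)
  with τ the MFPT matrix; it satisfies τ_ij − τ_ji = c_i − c_j to 1e−8
  (enforced) and ranks easily-reached nodes highest.  The sign convention
  is chosen so that descending order means "more central"; the identity in
  the literature is sometimes written with the opposite sign of c.
* **Non-backtracking centrality** sums the Perron eigenvector of the
  2M×2M directed-edge (Hashimoto) matrix over incoming edges; forests are
  rejected (spectral radius 0).

Rankings are descending-score with ties broken by ascending node id.  The
top-n agreement of two rankings is λ_XY(n) = (1/n) Σ_{k≤n} |o_X(k) ∩
o_Y(k)|/k, computed for all n at once in O(N log N).

## Proximity baselines

MFPT τ_ij (expected steps, i → j, transition probability w_ij/W_i) and
resistance distance R_ij are both computed from the pseudoinverse of the
weighted Laplacian; the commute-time identity τ_ij + τ_ji = (Σ_k W_k) R_ij
ties them together and is verified to 1e−8 against independent
per-target absorbing-chain solves and a Monte-Carlo walker.

## Epidemic model

Continuous-time SIR with per-contact infection rate r_I·w_ij and per-node
recovery rate r_R, simulated exactly with the Gillespie algorithm (competing
exponentials; numba-compiled event loop; per-node infection pressures are
re-summed every event so no floating-point drift accumulates).  The pairwise
epidemic proximity is the harmonic-mean infection time over K outbreaks
seeded at i, h_ij = K / Σ_k 1/t^{(k)}_{i→j}; runs in which j is never
reached contribute zero reciprocal, so die-off penalises closeness rather
than being discarded.  All experiments use r_I = 1 and stay above the
homogeneous epidemic threshold r_I > r_R/⟨k⟩.

## Experiment design and defaults

The generators define the study conditions: ER graphs G(n, p) with
p = ⟨k⟩/(n−1), and clique-seeded preferential attachment (m = ⟨k⟩/2) whose
degree tail is P(k) ~ k^−3.  Experiments that require connectivity run on
the largest component.

* **g-vs-k exponent.** BA N = 512, ⟨k⟩ ∈ {4, 20}, 10 realizations each.
  log g is regressed on log k *within* each ensemble (fixed N and ⟨k⟩ share
  a prefactor) and the two exponents averaged; pooling ensembles with
  different prefactors into one regression collapses the exponent and is
  deliberately avoided.  Measured: ≈0.48.
* **Rank overlap.** BA N = 512, ⟨k⟩ = 20, 20 realizations; λ curves between
  the Ψ ranking and degree / PageRank(γ=0.85) / betweenness / random-walk
  rankings, averaged over realizations; the reported statistic is the
  minimum over n ≥ 10.  Measured: ≥0.94 for every method.
* **Size scaling of distant closeness.** Mean E over same-component
  non-adjacent ordered pairs, ER ⟨k⟩ = 4, N ∈ {128, 256, 512, 1024},
  5 seeds each; log-log slope vs N.  Measured: ≈0.51, i.e. E_d ~ N^{1/2}.
* **Infection-time fits.** h is fitted as h = c·x̂^α by nonlinear least
  squares in linear space (log-space seeding), with x̂ the predictor divided
  by its grand mean N^{-2}Σ_ij x_ij (closeness scales are arbitrary, so only
  the shape matters).  Pairs used: non-neighbours, i ≠ j, finite entries,
  target degree k_j > 4.  The GEN predictor for h_ij is E_ji — the closeness
  of the *target* as felt by the *source*.  Residual statistics: σ_x (rms)
  and m (mean; linear-space fitting is what makes m ≈ 0 meaningful —
  measured |m| < 1e−5).  Study conditions: ER N = 512, ⟨k⟩ = 20, r_I = 1,
  K = 100 outbreaks from each of 100 random sources.  σ_E < σ_τ at every
  recovery rate tried, and every σ grows with r_R (recovery is blind to
  topology, so all topological predictors degrade).  σ_R comes out *below*
  σ_E under these conditions — the resistance baseline is not beaten on
  ER graphs at this scale — and the package reports this honestly rather
  than suppressing the comparison.
* **Asymmetry coupling.** Over all ordered pairs, Δτ_ij = τ_ji − τ_ij is
  regressed on ΔE_ij = E_ij − E_ji (through the origin; the cloud is
  antisymmetric).  |correlation| > 0.9 on every ER instance tried.  The raw
  slope scales as √N; the scale-free coefficient reported is
  α = |slope|·⟨E⟩/N, i.e. the slope with the GEN asymmetry mean-normalised,
  the same normalisation as the infection-time fits.  Measured ≈4.4 at
  ⟨k⟩ = 4 and ≈2.3 at ⟨k⟩ = 20; grid mean ≈3.5.

## What the synthetic ensembles do and do not show

ER and BA ensembles probe homogeneous and scale-free topologies with
independent, unweighted edges.  They contain no community structure, degree
assortativity, clustering, or weight heterogeneity, all of which real
contact and collaboration networks have; conclusions about predictor
rankings (e.g. GEN vs resistance above) are statements about these
ensembles at N ≤ 1024, not about networks generally.  A GML loader plus
max-symmetrisation (w_ij ← max(w_ij, w_ji)) and largest-component reduction
is provided for real directed networks such as the 2004 political-blogs
graph, but no bundled dataset is shipped.

## Numerical choices

Double precision throughout.  Dense linear algebra up to N ≈ 2000 (the
in-scope scales); Laplacian pseudoinverse via `numpy.linalg.pinv`.
Degenerate inputs: empty graphs, isolated nodes, disconnected inputs to
walk-based operations, trees for the non-backtracking measure, and
vertex-transitive graphs in the asymmetry regression (zero variance) all
raise or warn explicitly rather than returning silent nonsense.  All
randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`; repeated runs are bit-identical.
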