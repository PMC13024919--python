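# Methods

This note records the statistical model, the estimator defaults and the
numerical and design choices behind `copulagm`, at the level of detail a
user needs to judge what a passing test suite does and does not establish.

## Model and score

The hypothesis class is the set of decomposable (chordal) undirected graphs
on `d` continuous variables. Chordality buys two things: a junction-tree
factorisation of any Markov density into clique marginals over separator
marginals, and locality of score changes under single-edge edits. The score
is the copula-information criterion

    S(G) = n·I(G) − (log n / 2)·Λ(G),
    I(G) = Σ_cliques ψ(K) − Σ_separators ψ(S),

where `ψ(A) = E[log c_A(U_A)]` is the negative copula entropy of the subset
`A` and `Λ` aggregates `λ(A) = |A|(|A|+1)/2` (the parameter count of a
Gaussian model on `|A|` variables; `λ(A) = |A|` is available as an
alternative) in the same clique-minus-separator pattern. Separators enter
with the multiplicity induced by the *maintained* junction tree: at the
population level the decomposition is a property of the graph, but finite
`ψ̂` values can differ slightly across equivalent trees, so one tree is kept
current throughout the search and used consistently for scoring and for the
local deltas. `n` is the training-sample size `|J_tr|` — the number of rows
actually entering the `ψ̂` estimates — not the pre-split sample size.

For a valid insertion of `{i, j}` with admissibility separator `S`, the new
maximal clique `S∪{i,j}` replaces separator `S` with `S∪{i}` and `S∪{j}`,
so the score difference collapses to four terms (deletion is the exact
negation). Move deltas are therefore computed from a memo of `κ(A)` values
keyed by the sorted variable tuple; the cache is exact (it stores finished
floats) and cannot change any decision, which the tests verify.

## Copula-entropy estimator

`ψ̂(A)` is an out-of-fold predictive log-score. The training rows are split
into `k = 5` folds. For fold `r`, marginal ECDFs are fitted on the
complement `J_−r` (size `m`), and every row gets pseudo-observations
`clamp(ε, 1−ε, m/(m+1)·F̂(x))`. These are probit-transformed and a Gaussian
product-kernel density with per-variable variances `θ` is evaluated at the
fold-`r` rows using only `J_−r` rows as centers; dividing by the probit
Jacobian `Π φ(z_i)` gives the copula density. `ψ̂(A)` averages the log of
this density over all training rows, each scored by the fold that held it
out, with denominator `|J_tr|`. `ψ̂(∅) = 0`.

Defaults, with rationale:

- `k = 5` folds — standard cross-validation choice; for fixed `k` the
  difference from leave-one-out assessment vanishes asymptotically.
- `ε = 1e−5` — far below `1/(m+1)` for any realistic fold size, so the
  clamp only guards exact-0/1 pathologies and perturbs the functional
  negligibly while keeping `Φ⁻¹` finite.
- `δ_floor = 1e−100` — the density floor (`log δ_floor ≈ −230`) is far
  below machine-precision densities and never binds for sane inputs; it
  exists so that `ψ̂` stays finite under extreme tail queries. Candidates
  whose score still comes out non-finite are treated as inadmissible for
  that iteration and retried after the state changes.
- Ties in the data share a pseudo-observation value (right-continuous
  ECDF).

### Bandwidth

One global diagonal bandwidth vector `θ` (kernel *variances*) is selected
once, before the search, by maximising the leave-one-out predictive
log-score of the full `d`-dimensional probit sample over `ξ = log θ` with
L-BFGS-B (analytic gradient, default 200 iterations, relative tolerance
1e−8), and is then fixed; every subset uses the coordinate projection
`θ_A`. The box constraints are

    log(Var(Z_j)/β_max) ≤ ξ_j ≤ log(Var(Z_j)/β_min),

with `β_min = 1` and `β_max = n_tr^{2/5}`: the lower end is the
optimal-rate scale for a second-order kernel, the upper end the data
variance itself, so the box brackets every sensible KDE bandwidth. The
optimiser starts from the Silverman-scale value `(1.06 n^{−1/5})²·Var(Z_j)`
clipped into the box; hitting the iteration cap is accepted, an abnormal
termination falls back to the box midpoint with a warning. Variances use
denominator `n_tr − 1`.

### The likelihood baseline

The `ng_ll` score shares the folds, the kernel, the bandwidth-selection
procedure and the clique-minus-separator aggregation, but fits densities on
the *raw* coordinates (standardised by training mean/sd — an affine map
whose log-Jacobian cancels in every four-term delta) with no penalty term.
This maximal sharing means benchmark differences between the two scores
isolate the scoring functional, not the machinery. The baseline is *not*
rank-invariant: a monotone column transform changes its score, which is the
behavioural contrast the benchmark probes.

## Search

Greedy forward/backward search from the empty graph: each iteration
enumerates all admissible insertions (clique-tree path criterion) and
deletions (unique containing clique), evaluates every delta, and applies
the single best strictly improving move (`Δ > 0`, no slack). Ties prefer
insertion over deletion, then lexicographic edge order, making runs
reproducible. The iteration cap `d(d−1)` is a safety net only; strict
improvement of a bounded score terminates on its own. The clique tree is
updated incrementally (new clique spliced at a path edge whose separator
equals `S`, subsumed cliques absorbed); the update is contract-tested to be
equivalent to rebuilding from scratch. Disconnected graphs are kept as
clique forests; cross-component insertions are always admissible with
`S = ∅`, which is score-neutral (`ψ̂(∅) = λ(∅) = 0`). When several cliques
contain an endpoint, the closest pair in the tree is used, ties broken by
smallest clique index — any valid representative yields the same delta
because `S` is fixed by the admissibility criterion. No amortised
dynamic-tree data structures are used: plain tree traversal is ample at the
few-hundred-variable scale this package targets.

## Synthetic benchmark generator

The generator emulates a Gaussian-copula Markov random field with known
chordal structure: Erdős–Rényi `G(d, ρ)` → minimum-degree fill-in
triangulation (deterministic, lexicographic tie-breaks) → independent
Gamma(shape 2, rate 1) edge weights → ridge-regularised Laplacian precision
`Q = νI + D − W` (strictly diagonally dominant, so positive definite with
min eigenvalue ≥ ν, and with zeros exactly off the edge set) → standardise
`Q⁻¹` to a correlation matrix → latent `Z ~ N(0, R)`, `U = Φ(Z)`, and
component-wise quantile transforms to Normal(0,1) (`X = Z` exactly),
Exponential(1) and Beta(1/2,1/2) marginals. All three marginal regimes
share the same `U`, hence identical ranks — the exact perturbation a
rank-invariant score must ignore. `ν = 1.0` by default; it is the main free
parameter controlling signal strength (larger `ν` weakens all latent
correlations). The RNG stream order is fixed (graph, then weights for all
vertex pairs in lexicographic order, then normals) so one seed reproduces a
dataset bit-for-bit; weights are drawn for every pair and masked by the
edge indicator so the stream does not depend on the edge set.

What the generator does *not* emulate: non-Gaussian copulas, discrete or
ordinal variables, heteroscedastic noise, non-chordal ground truths beyond
their triangulated completions, and dependence between rows. Passing
recovery tests therefore show that the estimator and search do their job
when the model class is correct — they do not certify behaviour under
copula misspecification or non-IID sampling.

## Benchmark protocol and problem sizes

Per seed: simulate truth and data, split rows 70/30 into train/test
(deterministic per seed), select the bandwidth and estimate all `ψ̂` on the
training rows only, learn one graph per score and marginal family, and
compare against the truth by SHD, precision, recall and F1 (degenerate
ratios reported as 0 with a flag so aggregation stays total). The test
split never influences learning; it only feeds an optional held-out
predictive log-score column. The headline reproduction in
`scripts/acceptance.py` runs `(d, n, ρ, ν) = (30, 2000, 0.1, 1.0)` over
five seeds — the full benchmark scale, with the seed count chosen to keep a
single-CPU run around ten minutes; the in-suite ordering check
(copula score beats the likelihood baseline) runs a reduced
`(d, n) = (15, 800)` configuration over five seeds for the same reason.

## Known limitations

- Greedy search finds a local optimum; no restarts or sampling.
- Repeated KDE evaluation scales as `O(n² · |A|)` per subset; large cliques
  (say `|A| > 10`) are slow and increasingly bandwidth-sensitive.
- The score is defined relative to the maintained junction tree; equivalent
  trees can differ in the last float digits of the global score (never in
  the population limit).
- With heavily tied data (many duplicated values) pseudo-observations
  degenerate toward a discrete copula, where the continuous theory is not
  identified.
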