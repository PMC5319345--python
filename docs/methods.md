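# Methods

## The degree-heterogeneity measure

For an unweighted, undirected simple graph on `N` nodes with empirical
degree distribution `P(k) = count(k)/N`, the index

```
h² = (1/N) Σ_{k : P(k)≠0} (1 − P(k))²
```

depends only on the *k-spectrum* (the set of observed degrees) and the
probability mass on each. Each realized degree contributes `(1 − P(k))²`,
so `h` grows both with the number of distinct degrees and with how thinly
the mass is spread. Isolated nodes contribute `k = 0` to the support; the
only condition on the sum is `P(k) ≠ 0`. Comparison indices that involve
`1/√k` (Estrada's `ρ`, Randić) instead reject graphs with isolated nodes.

The normalization constant is the index of the completely heterogeneous
graph on the same `N`: the graph realizing every degree `1..N−1` with
exactly one repeated degree `k* = ⌊N/2⌋` (even `N`: `N/2`; odd: `(N−1)/2`).
Substituting `P = 1/N` off `k*` and `2/N` at `k*` gives the closed form
`h_het(N)² = 1 − 3/N + (N+2)/N³`, used exactly for all `N ≥ 4`; the
first-order form `√(1 − 3/N)` is provided only as a documented helper
(`h_het_large_n`). `Hm = h/h_het(N) ∈ [0,1]`. `Hm` requires `N ≥ 4`
because the extremal construction starts at `N = 4` (and the closed form
vanishes at `N = 2`); the batch `report()` emits NaN for `Hm` on smaller
graphs instead of failing, so tiny graphs can still be scored on the other
indices.

### The extremal construction

Label `N−1` nodes by intended degree `a = 1..N−1` and join `a, b` iff
`a + b ≥ N`; attach the final node ν to every label `a ≥ N − k*`. The
threshold rule reproduces the inductive argument that the degree-`r` node
is adjacent exactly to the nodes of degree `N−1, …, N−r`; ν then has
degree `k*`, and no self-loop can arise because `a ≠ b` is required. The
test suite verifies the degree-multiset theorem exhaustively for
`N = 4..500` and checks `h(extremal) = h_het(N)` to `1e−12`. Whether this
graph is unique up to isomorphism is not addressed; the package provides
the canonical construction.

### Pair-sum convention for the comparison indices

Albertson `A = Σ |k_i − k_j|`, Estrada `ρ = Σ (k_i^{−1/2} − k_j^{−1/2})²`
and Randić `R = Σ (k_i k_j)^{−1/2}` all sum over **adjacent pairs**, each
undirected edge once. This is each index's original definition and the
unique convention under which a star attains `ρ = N − 2√(N−1)`, hence
`ρ_n = ρ/(N − 2√(N−1)) = 1`, and the Randić bounds `√(N−1) ≤ R ≤ N/2` are
met by the star and regular extremes.

## Graph generators

* **Erdős–Rényi** `G(n, p)` via networkx's `fast_gnp_random_graph`
  (distributionally identical to independent pair sampling, seeded).
* **Preferential attachment** parameterized by `(m0, kmin)`: a seed clique
  on `m0` nodes (default `max(kmin, 2)`); each arriving node draws `kmin`
  distinct targets from a repeated-nodes urn, giving exactly
  degree-proportional attachment and minimum output degree `kmin`.
* **Power-law configuration model** for arbitrary exponent: degrees drawn
  i.i.d. from `P(k) ∝ k^−γ` on `[kmin, n−1]`, sum made even by redrawing
  one entry, stub-matched, then simplified by dropping self-loops and
  parallel edges. Simplification can leave a small fraction of nodes
  (≈0.1–0.5% at `n = 2000`, `γ = 2.5`) below `kmin`; this is measured in
  the tests rather than repaired, since edge repair would distort the
  degree law.
* **Exponent estimation** for reporting uses least squares on
  logarithmically binned `log P(k)` vs `log k` (`k ≥ kmin`), bin ratio 1.5,
  densities normalized by bin width. Against known ground truth this is
  accurate to within ≈0.07 for γ in 2.1–3.0 at `n = 2000`; a discrete MLE
  was rejected because truncation of the sampled law at `n−1` biases it
  far more severely.

## Chaotic systems

Flows are integrated with fixed-step RK4 (step 0.01) and sampled every
0.05 time units; maps are iterated directly (`dt = 1`). The first 10 000
post-sampling points are discarded as transient, which is ample for every
registered system. Parameter defaults are the canonical chaotic regimes
listed in `dynamics.py`. The Duffing oscillator is the driven two-well
form `x'' = x − x³ − 0.25 x' + 0.3 cos t`; the linear `+x` term is
essential — without it the system at these drive parameters is not
chaotic. Independent realizations perturb the default initial condition
deterministically by the seed (uniform, amplitude 0.01; 0.1 for the torus
map). Divergence (`|x| > 1e6` or non-finite) raises an error naming the
system. Observational noise is additive white Gaussian with standard
deviation `percent/100 · std(series)`.

## Recurrence-network pipeline

* **Delay**: first local minimum of the autocorrelation (FFT-based,
  biased estimator), searched up to one tenth of the series length. If the
  ACF sits inside the sampling-noise band `3/√n` for two consecutive lags
  before any interior minimum, the current lag is returned — this yields
  τ = 1 for i.i.d. series without misfiring on oscillatory ACFs whose zero
  crossings pass through the band. For maps (`dt = 1`) the pipeline fixes
  τ = 1, since ACF minima are ill-defined for strongly mixing maps.
* **Embedding**: point `t` is `(x_t, x_{t+τ}, …, x_{t+(M−1)τ})`,
  min–max rescaled to `[0,1]` per coordinate. Distances default to the
  maximum (Chebyshev) norm, which keeps ε comparable across `M`;
  Euclidean is available.
* **Threshold**: the default is the smallest ε whose giant component
  covers at least half the nodes — the percolation transition of the RN,
  computed exactly by adding candidate edges in distance order through a
  union–find structure. Choosing ε at (not far above) this transition is
  the standard prescription for the sparsest network that still represents
  the attractor as a whole. Larger coverage demands (e.g. 99%) force ε to
  bridge the sparsest outlying regions — tails of a noise attractor, the
  lobe extremes of Lorenz — and inflate the degrees of the dense core
  several-fold; empirically this pushes the Gaussian-noise RN from
  `Hm ≈ 0.08` to `≈ 0.36`, losing the documented agreement with an
  Erdős–Rényi graph of matched mean degree. The exact transition distance
  is returned rather than a value rounded up to a 0.01 grid: in sparse
  networks the threshold is itself ~0.02–0.03, and grid rounding makes
  per-seed results bimodal. Rounding and coverage remain parameters. An
  alternative criterion selects ε as the order statistic achieving a
  requested edge density (recurrence rate) exactly.
* **No Theiler window**: temporal neighbors are not excluded (a config
  option exists through graph post-processing if needed). For flows this
  means the time-ordered chain of samples contributes short-range edges,
  which is part of why percolation occurs at small ε.

## Experiment protocol and problem sizes

Every sweep spawns per-run seeds from a master seed via
`numpy.random.SeedSequence` (all seeds kept below 2³¹) and reports the
mean of `Hm` over realizations with the standard deviation across
realizations as the error bar — 10 realizations per condition by default.
Problem sizes used by the packaged experiments: networks of `N = 2000`
for the three-way comparison, attractor table and noise sweep; `N` from
1000 to 10000 (five log-spaced points) for the scale-free decay fit;
embedding dimensions 3–5 with the M = 5 value reported as the converged
attractor score. The decay exponent is an unweighted least-squares slope
of `log(mean Hm)` vs `log N`; no claim is made that the decay is exactly
a power law outside the fitted range.

## What the synthetic generators do and do not emulate

The generators and simulators reproduce the study conditions this package
is designed around: ideal ER/preferential-attachment/configuration-model
ensembles and noise-free (or Gaussian-noise-contaminated) trajectories of
low-dimensional chaotic systems at fixed sampling. They do not emulate
real measured time series (observational gaps, nonstationarity, colored
noise) or real-world network artifacts (sampling bias, weighted/directed
edges). Passing tests therefore validate the measure and pipeline on clean
ensembles; applying `Hm` to real data additionally requires the user to
judge embedding quality and stationarity.

## Known limitations

* The ε-selection rule is a stand-in: published per-system attractor
  scores depend on the original authors' threshold procedure, whose
  parameters are not recoverable here. With the uniform percolation rule,
  flow attractors (Lorenz, Rössler, Ueda) and the Gaussian reference land
  in the expected ranges, but the two-dimensional maps (Hénon, Lozi) score
  lower than their published values, and the Hénon/Lozi ranking is within
  run-to-run noise rather than resolved.
* `Hm` of a recurrence network drifts mildly downward from M = 3 to M = 5
  under the percolation rule; the drift is comparable to the run-to-run
  spread at `N = 2000` and 10 realizations, so M-invariance holds only
  approximately at this problem size.
* The completely heterogeneous construction realizes one extremal graph;
  uniqueness up to isomorphism is not investigated.
* Weighted (strength-distribution) and directed variants, entropy-based
  and Gini-based heterogeneity measures are out of scope.
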