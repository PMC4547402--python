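# Methods

## Model

driverank ranks genes by the stationary distribution of Markov chains built
from three data views of one tumor cohort. Write *B* for the m×n binary
patient–mutation matrix, *W* for the symmetric nonnegative gene-interaction
weight matrix, and *H* for the matrix of pairwise Pearson correlations of
gene expression across samples (diagonal zeroed). Four stochastic operators
are derived:

* `Br = row-normalized B`, `Bc = column-normalized B` — a patient moves to
  one of their mutated genes uniformly, and a gene moves to one of its
  carriers uniformly (the mutual-reinforcement or "voting" reading: a
  gene's score aggregates the scores of the patients carrying it, and vice
  versa);
* `Cr = α·Br + (1−α)/n` and `Cc = α·Bc + (1−α)/m` — uniform teleportation
  with probability 1−α makes both operators strictly positive;
* `Cg = D⁻¹W` — the degree-normalized interaction walk;
* `Ch = D⁻¹|H|` — the co-expression walk.

The six integrated models compose these operators in different orders (see
README for the table); the composition of column-stochastic maps is
column-stochastic, and because `Crᵀ` and `Cc` are strictly positive for
α < 1, every product chain is strictly positive. Perron–Frobenius then
gives a unique strictly positive stationary vector with eigenvalue 1, so
the gene ranking is well defined and independent of the starting vector.
The test suite asserts exactly these conclusions (positivity, simplex
normalization, start-independence, agreement with a dense
eigendecomposition) rather than re-proving them.

### Assumptions

* Mutations are informative in aggregate: genes mutated in many patients,
  and genes interacting or co-expressed with such genes, are more likely
  drivers.
* The three sources describe one gene universe; symbols are matched
  verbatim (no alias resolution).
* Edge weights and correlations are meaningful up to row normalization —
  multiplying *W* by a constant changes nothing.

## Design choices

**Signed correlations.** `D⁻¹H` over raw signed correlations would produce
negative "probabilities", so the co-expression walk uses |H| before
normalization, the standard co-expression-network practice. Strongly
anti-correlated genes are therefore treated as strongly coupled, which is a
deliberate, documented deviation from a literal normalization of signed
values.

**Self-correlation.** The diagonal of *H* is zeroed; a self-loop of weight
1 would dominate every row of `D⁻¹H` and trap the walk.

**Dangling rows.** Genes with zero interaction degree (or an all-zero
correlation row, e.g. zero-variance expression) get a uniform transition
row — the PageRank dangling-node convention — keeping every operator
row-stochastic.

**Alignment.** The three gene sets are reconciled by intersection and then
pruned to a fixed point so that every gene is mutated in ≥ 1 patient and
every patient carries ≥ 1 in-universe mutation: every normalizer in
`Br`/`Bc` must be positive. The surviving universe is sorted
lexicographically, which makes all matrices and rankings reproducible.
Alignment is idempotent.

**α domain.** α ∈ [0, 1); α = 1 removes the strict positivity on which
uniqueness rests and is rejected up front. Default α = 0.75.

**Penalized walk (RW-MMP).** σ is the mean over all n² entries of *H*
(including the zero diagonal). |σ| < 1e-6 is rejected as degenerate. The
stochastic operator is computed in log space (softmax-style row
normalization), which is algebraically identical to row-normalizing
`W·exp(H/σ)` but immune to overflow when |H|/σ is large — σ is a global
mean and can legitimately be ~1e-4 on weakly correlated cohorts.

**RW-MMA.** The literal finite schedule (caps l, m, r with
indicator-weighted averaging) is available explicitly, but the default
mode runs all three component updates every iteration until convergence,
since no canonical caps exist. RW-MMA defines no patient chain; its
result carries `pi = None`, as does FREQ and RW-GC.

**Benchmark damping.** RW-GC (co-expression walk alone) gets the same
teleportation damping as the main models; an undamped `Ch` may be
reducible or periodic, in which case no unique stationary vector exists.

**Solver.** Power iteration from the uniform vector, L1 tolerance 1e-10,
max 10 000 iterations, defensive renormalization each step. Chains are
applied as nested matrix–vector products; the dense product matrix is
never formed outside of test oracles. Non-convergence (possible only for
undamped, periodic chains, e.g. a pure PPI walk on a bipartite component —
reachable through the additive model with weight (0, 1, 0)) raises an
error carrying the last residual rather than returning a bogus vector. An
optional start vector exists for start-independence checks; note that for
the periodic two-state swap chain the uniform default start is already
stationary, so demonstrating the failure mode requires an asymmetric
start.

**Ties.** `scores_to_ranks` breaks equal scores lexicographically; ranks
are 1-based. FREQ, with small-integer scores, is the only model where ties
are common.

## Evaluation protocol

Two deliberately distinct summaries are exposed:

* `top_percent_report`: cutoff = ⌈p/100 · n⌉ genes; reports how many truth
  genes appear at or above the cutoff and the mean rank *of those found*
  (absent when none are found). This mirrors the top-1% table protocol.
* `mean_truth_rank` (used by the α sweep and the weight grid): mean rank of
  all truth genes over the full list, no cutoff.

Precision at threshold k is hits(k)/k; recall is hits(k)/|truth ∩ universe|.
Truth genes absent from the aligned universe are dropped with a logged
warning and excluded from the recall denominator.

The additive-weight grid enumerates all (w_pm, w_ppi, w_corr) triples at a
given step on the simplex and reports, for each weight fixed at each grid
value, the best mean truth rank over the free pair (a one-at-a-time
sensitivity scan).

## Synthetic cohorts

The generator emulates the statistical premises of the models, not any
particular tumor type:

* genes are assigned to modules round-robin; the PPI network is a planted
  partition (edge probability `p_within` inside modules, `p_between`
  across, weight 1);
* expression is one latent factor per module:
  `X_g = √ρ·factor + √(1−ρ)·noise + noise_sd·ε`, giving within-module
  correlation ≈ ρ/(1 + noise_sd²);
* mutations are independent Bernoulli coin flips at `p_driver_mut` for the
  planted drivers and `p_passenger_mut` otherwise;
* drivers are spread round-robin across modules at rng-chosen positions
  within each module, so driver status is independent of lexicographic
  order (this matters under the null: the frequency benchmark's integer
  scores are tie-broken lexicographically).

All randomness derives from a single seed; if alignment would drop a
driver (a driver that happens never to mutate), the dataset is regenerated
with the seed incremented, up to 10 attempts.

Reference conditions (the defaults, used by `scripts/acceptance.py` and
the planted-recovery test): 500 genes, 10 modules, 25 drivers, 100
patients, 60 expression samples, `p_driver_mut` 0.15, `p_passenger_mut`
0.02, `p_within` 0.1, `p_between` 0.005, `rho_within` 0.6, `noise_sd` 0.1.
The null-calibration test uses a lighter cohort (200 genes, 60 patients,
10 "drivers", both mutation rates 0.08, ρ = 0) across 20 seeds so the
whole suite stays fast; the mutation rate is raised under the null so that
no gene is silent in every patient and alignment keeps the label sets
comparable.

### What the generator does and does not show

Passing tests establish that the operators and solvers are correct and
that the models recover planted frequency/module signal well above chance.
They do not establish performance on real cohorts: the generator has no
mutual exclusivity between drivers, no subclonal structure, no
hypermutators, no expression platform effects, and its mutation signal is
unrealistically clean. In particular, under the reference conditions the
frequency signal alone separates drivers perfectly, so the frequency
benchmark is already optimal there and network integration can at best tie
it on mean driver rank; the value of integration on real data rests on
frequency being noisy and incomplete, a regime the generator reproduces
only when the two mutation rates are brought close together. Models whose
chain ends in network smoothing (RW-MMPFS especially) trade per-gene
mutation evidence for neighborhood structure and can lose a purely
per-gene planted signal entirely.

## Known limitations

* Dense in-memory matrices: fine to ~20k genes on a workstation, not
  beyond.
* Gene symbols are matched verbatim; upstream identifier hygiene (alias
  resolution, MAF/VCF parsing, probe mapping) is out of scope. The
  ingestion contract is the binary patient×gene matrix; any upstream
  filtering of mutation classes (e.g. keeping only indels and base
  substitutions) happens before driverank sees the data.
* The co-expression walk discards correlation sign (see above).
* No statistical significance is attached to rank differences between
  models.
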