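# driverank

Random-walk prioritization of cancer driver genes by integrating three
heterogeneous views of a tumor cohort:

* a **patient–mutation bipartite graph** — the binary matrix *B* (m patients ×
  n genes) with *B*ᵢⱼ = 1 iff patient *i* carries a somatic mutation in gene *j*;
* a **gene–gene interaction network** — a symmetric nonnegative weight
  matrix *W* (PPI / functional interactions);
* a **gene co-expression network** — the matrix *H* of pairwise Pearson
  correlations of expression profiles across samples.

It is a library (plus a thin `driverank` CLI) for researchers who want to
rank mutated genes by how central they are to a cohort, rather than by raw
mutation frequency alone.

## The model

Each data view becomes a stochastic transition operator:

* `Cr = α·Br + (1−α)/n`, where `Br` row-normalizes *B* — a patient follows
  one of their mutated genes, or teleports to a uniformly random gene with
  probability 1−α (PageRank-style damping, default α = 0.75);
* `Cc = α·Bc + (1−α)/m`, where `Bc` column-normalizes *B* — the analogous
  gene→patient move;
* `Cg = D⁻¹W` — one step of the degree-normalized PPI walk;
* `Ch = D⁻¹|H|` — one step of the co-expression walk.

Six integrated models compose these operators into a Markov chain on genes
and rank genes by the chain's stationary distribution **μ** (teleportation
makes the chain strictly positive, so Perron–Frobenius guarantees a unique
positive stationary vector; a companion chain yields patient scores **π**):

| model | gene-score equation |
|---|---|
| RW-MMGCS | μ = Crᵀ Cc Cgᵀ Chᵀ μ |
| RW-MMGIS | μ = Crᵀ Cc Chᵀ Cgᵀ μ |
| RW-AM    | μ = (w_pm·Crᵀ Cc + w_ppi·Cgᵀ + w_corr·Chᵀ) μ, weights (0.3, 0.3, 0.4) |
| RW-MMP   | μ = Crᵀ Cc C̃gᵀ μ with C̃g from W̃ᵢⱼ = Wᵢⱼ·exp(Hᵢⱼ/σ), σ = mean(H) |
| RW-MMA   | per-iteration average of the three component updates |
| RW-MMPFS | μ = Chᵀ Cgᵀ Crᵀ Cc μ |

plus three benchmarks: mutation frequency (FREQ), the damped co-expression
walk alone (RW-GC), and the bipartite walk alone (RW-PM). Rankings are
evaluated against a ground-truth gene set (a curated 25-gene ovarian-cancer
set ships with the package) via top-percent reports, precision/recall
curves, a teleportation-α sweep and an additive-weight grid. A synthetic
cohort generator with planted drivers, modular PPI and module-correlated
expression makes the whole pipeline testable without any external download.

## Worked example

```bash
python examples/01_simulate_and_rank.py
```

simulates 80 genes / 50 patients with 10 planted drivers (20% per-patient
mutation rate vs a 3% background), ranks genes with RW-MMGCS and prints:

```
aligned universe: 59 genes, 50 patients
converged in 8 iterations (L1 residual 5.3e-11)

top 10 genes (score = stationary probability; * = planted driver):
   1. G73  0.06387 *
   2. G32  0.05083 *
   3. G51  0.04585 *
   ...
9/10 of the top genes are planted drivers (chance would put ~1.7 there).
```

The score column is the gene's stationary probability mass — the long-run
fraction of time the integrated random walk spends at that gene; planted
drivers concentrate at the top because patients "vote" for the genes they
carry and the network walks reinforce genes in well-connected, co-expressed
neighborhoods. `examples/02_compare_models.py` prints the same comparison
across all nine models, `03_alpha_sweep.py` shows how driver recovery
degrades as teleportation takes over (α → 0), and `04_file_workflow.py`
runs the TSV-file workflow that the CLI uses.

The same pipeline from the shell:

```bash
driverank simulate --n-genes 100 --n-patients 50 --n-samples 25 \
    --n-modules 5 --n-drivers 10 --seed 3 -o cohort/
driverank rank --ppi cohort/ppi.tsv --expression cohort/expression.tsv \
    --mutations cohort/mutations.tsv -m rw-mmgcs -o out/
driverank evaluate --ppi cohort/ppi.tsv --expression cohort/expression.tsv \
    --mutations cohort/mutations.tsv --truth cohort/truth_genes.txt -o out/
```

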