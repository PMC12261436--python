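# Methods

## Model

GRACKLE factorizes a nonnegative expression matrix `Y ∈ R^{m×n}`
(m samples, n genes) as `Y ≈ WH`, `W ∈ R^{m×k}_{≥0}`, `H ∈ R^{k×n}_{≥0}`,
minimizing

    f(W, H) = ||Y − WH||²_F + λ₁ tr(Wᵀ L_S W) + λ₂ tr(H L_G Hᵀ),

with `L_S = D_S − S_S` and `L_G = D_G − S_G` the combinatorial Laplacians
of a sample-similarity matrix and a gene-similarity matrix, and `D` the
diagonal of row sums. Since
`tr(Wᵀ L W) = ½ Σ_{ij} S_ij ||w_i − w_j||²`, the penalties pull entities
that the priors call similar toward similar latent embeddings (the local
invariance assumption of graph-regularized NMF). Special cases: plain NMF
(λ₁ = λ₂ = 0), GNMF (λ₁ = 0, `S_G` a learned kNN gene affinity), pr-GNMF
(λ₁ = 0, `S_G` a prior interaction network).

### Priors

* `S_S = M Mᵀ` for a nonnegative metadata matrix `M` (samples ×
  annotations). One-hot single-label metadata gives the block indicator
  of shared labels (diagonal 1); multi-label metadata gives integer
  counts of shared annotations. Negative metadata is rejected — it would
  break the nonnegativity of the multiplicative updates. The nonzero
  diagonal is kept in `S_S` (and therefore in `D_S`); graph diagnostics
  ignore it.
* `S_G` is the OR-symmetrization of a binarized directed TF→gene
  network: `S_G[i,j] = 1` iff an edge runs in either direction.
  Binarization uses the strict indicator `w > 1` for
  regulatory-probability networks (configurable cutoff). Genes missing
  from the network become isolated (zero) rows.
* GNMF's learned graph: Euclidean k-nearest-neighbor affinity (default
  k = 5), OR-symmetrized, distance ties broken deterministically by
  lower index.

### Updates, initialization, stopping

The solver alternates the multiplicative updates

    W ← W ⊙ (Y Hᵀ + λ₁ S_S W) ⊘ (W H Hᵀ + λ₁ D_S W + ε)
    H ← H ⊙ (Wᵀ Y + λ₂ H S_G) ⊘ (Wᵀ W H + λ₂ H D_G + ε)

(W first, then H against the updated W). These are the standard
dimensionally consistent dual-graph-regularized updates; each follows
from the same auxiliary-function majorization as single-graph GNMF, so
the objective is non-increasing at every step — the test suite asserts
this on random instances at relative tolerance 1e−9 rather than taking
it on faith. `ε = 1e−12` guards every denominator against 0/0 and is
orders of magnitude below the data scale. Factors are initialized
uniformly on (1e−6, 1] from a seeded generator: strictly positive, so no
entry is spuriously locked at zero (multiplicative updates can never
revive an exact zero). Iteration stops when the relative Frobenius
change of `H` falls below `tol = 1e−4` or after `max_iter = 100`
iterations; "relative change in H" is read as the Frobenius norm ratio
`||H_t − H_{t−1}||_F / ||H_{t−1}||_F`, the standard convergence measure
for matrix iterates. The λ = 0 configuration runs the identical code
path as the plain-NMF entry point, bit for bit.

Held-out samples are embedded by solving `min_{w≥0} ||y − wH||₂` per
sample with an active-set NNLS solver; recovery is exact (to solver
tolerance) when `H` has full row rank.

## Synthetic cohorts

The simulator emulates the structure of a regulatory-network-driven
cohort study; every stage is a pure function of the master seed
(sub-stage seeds derived by fixed offsets).

1. **Network** — a planted-block directed TF→gene network: genes split
   into equal blocks (default 10 blocks of 40 genes for 400 genes), TFs
   (default n/5) spread round-robin over blocks; a TF regulates a
   within-block gene with probability `within_p = 0.5` and a cross-block
   gene with `between_p = 0.002`. The within/between contrast controls
   modularity (lowering it emulates a less modular network); a
   `triangle_boost` option closes open TF→TF→gene triads to raise
   transitivity. Defaults are chosen so Louvain community detection
   recovers the planted blocks as the network's modules. Edge weights
   are drawn on (1, 2], i.e. above the binarization cutoff.
2. **Modules** — Louvain communities of the undirected projection
   (seeded, deterministic numbering by smallest member).
3. **Expression** — a discrete stochastic engine with regulator-gated
   transcription. Per iteration each gene's RNA count gains
   Poisson(rate) molecules — rate `transcription_bound = 0.02` if at
   least one regulator is active (its TF protein present and the
   influence surviving a Bernoulli unbinding draw at
   `tf_unbinding = 0.005`), else `transcription_basal = 0.01` — and
   loses Binomial(count, `rna_degradation = 0.005`); TF protein follows
   its own RNA via `translation = 0.002` and
   `protein_degradation = 0.005`. The six default rates are the standard
   delayed-event defaults in printed order. An unregulated gene is a
   birth-death chain with stationary mean basal/degradation = 2, which
   anchors the engine's calibration (tested against the closed form).
   Per sample the iteration count is drawn uniformly from 400–600 —
   emulating profiles captured at arbitrary cell-cycle points — and
   three replicate chains are averaged.
4. **Perturbation** — five of the detected modules (≥ 3 genes) are
   drawn at random; each is assigned an equal share of samples whose
   module-gene values are multiplied by `upregulation_factor = 2`,
   modeling subgroup-specific pathway activation. Labels record the
   perturbed module per sample.
5. **Background noise** — per sample, a fraction `noise_fraction` of
   the genes *outside that sample's own module* is drawn independently
   and upregulated by |N(0, sd)| (upregulation only, never negative).
   The per-sample scheme means rising noise makes samples of one
   subgroup increasingly display spurious activation of other
   subgroups' modules — this is what erodes label-free factorizations
   and what sample-similarity regularization defends against. A
   per-cohort mode (one global draw among genes outside every perturbed
   module, perturbed modules untouched) is available as an option. The
   default sd is 0.5 × the per-gene value range, making a typical
   spurious bump commensurate with the genuine 2× module upregulation;
   with a much smaller sd the noise sweep is inert (every method stays
   at ceiling) and the benchmark discriminates nothing.
6. **Scaling** — per-gene min–max to [0, 1]; constant genes map to 0.

What the generator does *not* emulate: down-regulation, time-series
dynamics, transcript-length/library-size effects, batch structure,
correlated measurement noise, or realistic edge-weight distributions.
Passing benchmarks on these cohorts therefore demonstrate that the
dual-graph regularization recovers planted sample–gene programs under
stochastic expression and structured background noise — not performance
on any particular real dataset.

## Evaluation protocol

* **Subgroup alignment accuracy** — after a 70/30 split, fit on the
  training samples (with `S_S` built only from training metadata),
  NNLS-project the test samples, and for each subgroup compare the
  argmax-by-mean LV of its test samples (in `W_test`) with the
  argmax-by-mean LV of its module genes (in `H`); the score is the
  fraction of subgroups where the two agree. Mean aggregation is used;
  a per-sample-majority variant was considered and rejected as noisier
  at small subgroup sizes. Non-injective subgroup→LV maps are allowed
  but logged. Ties resolve to the lowest LV index.
* **ARI** — samples clustered by top-loading LV, compared to external
  labels with the adjusted Rand index (Hubert–Arabie); the permuted-
  metadata control permutes whole metadata rows, so the permuted `S_S`
  is `P S_S Pᵀ` with an unchanged spectrum.
* **Fisher enrichment** — per (LV, condition) 2×2 table tested
  one-sided (greater) via the hypergeometric upper tail; a pair is
  "enriched" at unadjusted p < 0.05 (Benjamini–Hochberg optional). The
  count of enriched pairs is the grid-search metric for the
  condition-stratification workflow, which subsamples 70 % per
  iteration without a test split and scores the training embedding.
* **Grid search** — λ₁ × λ₂ cells × iterations, per-iteration seed =
  master seed + iteration index; the paired baselines (NMF at (0, 0),
  pr-GNMF at (0, max λ₂), GNMF at the maximum of its own grid
  {1, 10, 10², 10³, 10⁴}) run under identical splits and seeds. Best
  cell ties resolve to the smallest λ₁ then λ₂ (prefer less
  regularization).

## Problem sizes

The simulation benchmark in the test suite runs 20 seeds at the default
cohort size (400 genes × 100 samples, 5 perturbed modules among 10,
k = 5) over the coarse grid {0, 0.5, 1}², at noise fractions 0 and 0.6 —
one 70/30 split per seed rather than 100 repeated splits, which keeps
the paired comparison well-powered (a sign test across seeds) at a few
minutes of runtime. Oracle tests (Fisher, ARI, update step, Laplacian
quadratic form) run exhaustively at small margins/sizes where exact
enumeration is feasible.

## Known limitations

* The update rules handle dense similarity matrices in O(m²k + n²k) per
  iteration; very large gene sets would want sparse `S_G` support.
* The engine's unbinding is memoryless (an edge's influence is redrawn
  each iteration); there is no explicit bound-state persistence or
  transcriptional delay distribution.
* `graph_metrics` reports degree-distribution Shannon entropy (natural
  log of the normalized degree sequence) as its "graph entropy"; other
  graph-entropy definitions exist and would give different numbers.
* Rank k is user-supplied; no automatic rank selection.
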