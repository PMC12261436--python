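# grackle-nmf

Dual graph-regularized nonnegative matrix factorization (GRACKLE) for
expression matrices, with the NMF / GNMF / pr-GNMF baselines, a stochastic
gene-regulatory-network expression simulator, and a benchmarking harness.

## The problem

Unsupervised factorizations of bulk or single-cell expression data (NMF,
PCA, autoencoders) find dominant axes of variation, but nothing ties those
axes to the sample annotations or the molecular interactions a biologist
cares about — interpretation happens *post hoc* and often fails. GRACKLE
constrains the factorization with two pieces of prior knowledge at once:

* a **sample-similarity matrix** `S_S` built from sample metadata
  (phenotype labels, subtype assignments, matched omic cluster labels) as
  the dot product of the annotation matrix with itself, and
* a **gene-similarity matrix** `S_G` built from a gene regulatory network
  (e.g. a PANDA-style TF→gene network binarized at edge weight > 1) or any
  other gene–gene interaction graph.

The factorization `Y ≈ WH` (`Y` nonnegative, samples × genes; `W` m × k;
`H` k × n) minimizes

```
|| Y − WH ||²_F  +  λ₁ · tr(Wᵀ L_S W)  +  λ₂ · tr(H L_G Hᵀ)
```

where `L = D − S` is the combinatorial graph Laplacian of each similarity
matrix and λ₁, λ₂ tune how strongly similar samples (genes) are pulled
toward similar latent representations. Solved by multiplicative updates

```
W ← W ⊙ (Y Hᵀ + λ₁ S_S W) ⊘ (W H Hᵀ + λ₁ D_S W)
H ← H ⊙ (Wᵀ Y + λ₂ H S_G) ⊘ (Wᵀ W H + λ₂ H D_G)
```

which preserve nonnegativity and never increase the objective. λ₁ = λ₂ = 0
is classical NMF; λ₁ = 0 with a learned kNN gene graph is GNMF; λ₁ = 0
with a prior network graph is pr-GNMF. Each latent variable (LV) couples a
column of `W` (a sample program) with a row of `H` (a gene program), so
subgroups and their gene modules land on the same LV. Held-out samples are
embedded by nonnegative least squares against the trained `H`.

Who this is for: computational biologists stratifying heterogeneous
cohorts (tumor subtypes, co-occurring conditions) who have partial sample
annotation and a prior interaction network, and want latent factors that
align with both.

## Worked example

Simulate a small cohort (120 genes, 40 samples, 4 perturbed network
modules, 30 % background noise), fit GRACKLE with the subgroup labels as
metadata and the simulated GRN as the gene prior, and score the result:

```
grackle simulate --n-genes 120 --n-samples 40 --n-subgroups 4 \
    --noise-fraction 0.3 --seed 7 --out demo/cohort
# one-hot the labels into demo/meta.tsv, then:
grackle fit --expression demo/cohort/expression.tsv --metadata demo/meta.tsv \
    --network demo/cohort/grn.tsv --k 4 --lambda1 0.5 --lambda2 0.1 \
    --seed 7 --out demo/fit
grackle evaluate --w demo/fit/W.tsv --labels demo/cohort/labels.tsv \
    --h demo/fit/H.tsv --modules demo/cohort/modules.tsv --out demo/eval
```

prints

```
fit: k=4 lambda1=0.5 lambda2=0.1 n_iter=100 converged=False final_loss=221.536
{
  "ari_top_lv_vs_labels": 0.7613044669772541,
  "subgroup_alignment_accuracy": 1.0
}
```

`subgroup_alignment_accuracy = 1.0` means every planted subgroup's samples
and its perturbed module's genes share the same top-loading latent
variable — the factorization recovered all four sample–gene programs. The
ARI of 0.76 measures how well clustering samples by their top LV agrees
with the true subgroup labels. `fit` also writes `W.tsv`, `H.tsv` and
`fit_report.json` (loss history, convergence state, seed).

Other subcommands: `project` (NNLS embedding of held-out samples),
`gridsearch` (λ₁ × λ₂ sweep over repeated 70/30 splits or 70 %
subsamples, with NMF / GNMF / pr-GNMF baselines under identical splits),
and `benchmark` (simulation study in one shot). Everything is also
available as a library: `grackle.fit`, `grackle.simulate_cohort`,
`grackle.grid_search`, `grackle.simulation_noise_benchmark`, ….

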