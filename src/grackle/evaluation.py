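"""Benchmarking protocol: splits, alignment metrics, enrichment, grid search.

The evaluation harness mirrors the three study designs the factorization
is meant for:

1. *Simulation benchmark* — repeated 70/30 train/test splits; the model
   is fit on the training samples, held-out samples are embedded by NNLS
   against the trained gene factor H, and performance is the subgroup
   alignment accuracy: a planted subgroup counts as correctly recovered
   when the latent variable with the highest mean loading over the
   subgroup's test samples (in W_test) is the same latent variable with
   the highest mean loading over the subgroup's module genes (in H).
2. *Subtype stratification* — samples are clustered by their top-loading
   latent variable and compared against external labels with the
   adjusted Rand index; a permuted-metadata similarity serves as the
   negative control.
3. *Condition enrichment* — samples are grouped by top-loading latent
   variable on subsampled cohorts (no test split) and each (LV,
   condition) pair is tested with a one-sided Fisher exact test; the
   metric is the number of enriched pairs.

``grid_search`` sweeps (lambda1, lambda2) over any of these metrics with
per-iteration derived seeds and computes the NMF / GNMF / pr-GNMF
baselines under the identical splits for paired comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.metrics import adjusted_rand_score

from . import factorization as fac
from .graphs import SimilarityGraph, knn_affinity, sample_similarity_from_metadata

logger = logging.getLogger("grackle")

DEFAULT_TRAIN_FRACTION = 0.7
DEFAULT_ALPHA = 0.05


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

def split_cohort(
    expr: np.ndarray,
    labels: list | np.ndarray,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    seed: int = 0,
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Random train/test split keeping labels aligned.

    Returns ``((expr_train, labels_train), (expr_test, labels_test))``.
    The test partition always keeps at least one sample.  A subgroup
    absent from the training partition triggers a warning, not an error.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    labels = np.asarray(labels)
    n = expr.shape[0]
    n_train = min(int(round(train_fraction * n)), n - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    tr, te = perm[:n_train], perm[n_train:]
    missing = set(np.unique(labels)) - set(np.unique(labels[tr]))
    if missing:
        logger.warning("split_cohort: subgroups absent from train: %s", missing)
    return (expr[tr], labels[tr]), (expr[te], labels[te])


def subsample_cohort(
    expr: np.ndarray,
    labels: list | np.ndarray,
    fraction: float = DEFAULT_TRAIN_FRACTION,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Subsample a fraction of the cohort without a held-out test set."""
    (tr, lab_tr), _ = split_cohort(expr, labels, train_fraction=fraction, seed=seed)
    return tr, lab_tr


# ---------------------------------------------------------------------------
# Alignment metrics
# ---------------------------------------------------------------------------

def subgroup_alignment_accuracy(
    W_test: np.ndarray,
    H: np.ndarray,
    sample_labels: list | np.ndarray,
    gene_modules: list | np.ndarray,
    label_to_module: dict | None = None,
    background_label: str = "background",
) -> float:
    """Fraction of subgroups whose sample- and gene-side top LVs agree.

    For each subgroup g the sample-side LV is the argmax over latent
    variables of the mean ``W_test`` loading of g's samples, and the
    gene-side LV is the argmax of the mean ``H`` loading over the genes
    of g's module.  The subgroup is counted correct iff they coincide.
    Ties resolve to the lowest LV index; empty subgroups are excluded
    from the denominator.
    """
    W_test = np.asarray(W_test, dtype=float)
    H = np.asarray(H, dtype=float)
    sample_labels = np.asarray(sample_labels)
    gene_modules = np.asarray(gene_modules)
    subgroups = [g for g in np.unique(sample_labels) if str(g) != background_label]
    if not subgroups:
        raise ValueError("no non-background subgroups in labels")
    if W_test.shape[1] < len(subgroups):
        logger.warning(
            "fewer latent variables (%d) than subgroups (%d)",
            W_test.shape[1], len(subgroups),
        )
    n_correct = 0
    n_scored = 0
    assigned: dict = {}
    for g in subgroups:
        mod = label_to_module[g] if label_to_module else g
        s_mask = sample_labels == g
        g_mask = gene_modules.astype(str) == str(mod)
        if not s_mask.any() or not g_mask.any():
            logger.info("subgroup %s empty on one side; excluded", g)
            continue
        lv_sample = int(np.argmax(W_test[s_mask].mean(axis=0)))
        lv_gene = int(np.argmax(H[:, g_mask].mean(axis=1)))
        assigned[g] = (lv_sample, lv_gene)
        n_scored += 1
        if lv_sample == lv_gene:
            n_correct += 1
    if n_scored == 0:
        raise ValueError("no subgroup could be scored")
    lv_counts = pd.Series([a[0] for a in assigned.values()]).value_counts()
    if (lv_counts > 1).any():
        logger.info("non-injective subgroup -> LV map: %s", dict(lv_counts))
    return n_correct / n_scored


def cluster_by_top_lv(W: np.ndarray) -> np.ndarray:
    """Assign each sample to its top-loading latent variable (argmax row).

    Ties resolve to the lowest LV index; all-zero rows go to LV 0 (logged).
    """
    W = np.asarray(W, dtype=float)
    if W.size and W.min() < 0:
        raise ValueError("W must be nonnegative")
    zero_rows = ~W.any(axis=1)
    if zero_rows.any():
        logger.info("cluster_by_top_lv: %d all-zero rows -> LV 0", zero_rows.sum())
    return W.argmax(axis=1)


def adjusted_rand_index(a, b) -> float:
    """Hubert-Arabie adjusted Rand index between two labelings."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"label length mismatch: {a.shape} vs {b.shape}")
    return float(adjusted_rand_score(a, b))


def permuted_label_control(
    metadata: np.ndarray, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Row-permuted metadata for the negative-control similarity.

    Permutes whole metadata rows (annotation columns intact), so the
    derived SS is ``P SS P^T`` and keeps its eigenvalue multiset.  For
    n > 3 the identity permutation is resampled away.  Returns the
    permuted metadata and the permutation.
    """
    M = np.asarray(metadata)
    n = M.shape[0]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    while n > 3 and np.array_equal(perm, np.arange(n)):
        perm = rng.permutation(n)
    return M[perm], perm


# ---------------------------------------------------------------------------
# Fisher enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentTable:
    """Per (LV, condition) one-sided Fisher enrichment results."""

    table: pd.DataFrame
    alpha: float
    n_enriched: int


def fisher_one_sided_p(a: int, b: int, c: int, d: int) -> float:
    """One-sided (greater) Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Computed as the upper hypergeometric tail: with ``N = a+b+c+d`` draws
    of size ``a+b`` from a population with ``a+c`` successes,
    ``p = P(X >= a) = sf(a - 1)``.
    """
    N = a + b + c + d
    return float(hypergeom.sf(a - 1, N, a + c, a + b))


def fisher_enrichment(
    groups: np.ndarray,
    conditions: np.ndarray | pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    bh_adjust: bool = False,
) -> EnrichmentTable:
    """One-sided Fisher enrichment of each condition within each LV group.

    ``groups`` is the per-sample top-LV assignment; ``conditions`` a
    binary samples x conditions matrix.  For every (LV, condition) the
    2x2 table (in-LV vs out-LV x condition-positive vs not) is tested
    with alternative 'greater'.  Pairs with ``p < alpha`` count as
    enriched (after optional Benjamini-Hochberg adjustment).  A
    condition with zero positives is recorded with p = 1 and flagged.
    """
    if isinstance(conditions, pd.DataFrame):
        cond_names = list(conditions.columns)
        C = conditions.to_numpy()
    else:
        C = np.asarray(conditions)
        cond_names = [f"cond{j}" for j in range(C.shape[1])]
    if not np.isin(C, (0, 1)).all():
        raise ValueError("conditions must be binary 0/1 flags")
    groups = np.asarray(groups)
    rows = []
    for lv in np.unique(groups):
        in_mask = groups == lv
        n_in = int(in_mask.sum())
        n_out = int((~in_mask).sum())
        for j, name in enumerate(cond_names):
            pos_in = int(C[in_mask, j].sum())
            pos_out = int(C[~in_mask, j].sum())
            zero_flag = (pos_in + pos_out) == 0
            p = 1.0 if zero_flag else fisher_one_sided_p(
                pos_in, n_in - pos_in, pos_out, n_out - pos_out
            )
            num = pos_in * (n_out - pos_out)
            den = (n_in - pos_in) * pos_out
            odds = np.inf if den == 0 and num > 0 else (num / den if den else np.nan)
            rows.append({
                "lv": int(lv), "condition": name,
                "in_pos": pos_in, "in_total": n_in,
                "out_pos": pos_out, "out_total": n_out,
                "odds_ratio": odds, "p": p, "zero_positives": zero_flag,
            })
    table = pd.DataFrame(rows)
    pcol = "p"
    if bh_adjust and len(table):
        from statsmodels.stats.multitest import multipletests

        table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
        pcol = "p_adj"
    n_enriched = int((table[pcol] < alpha).sum()) if len(table) else 0
    return EnrichmentTable(table=table, alpha=alpha, n_enriched=n_enriched)


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------

@dataclass
class GridSearchResult:
    """Mean metric over a (lambda1, lambda2) grid plus paired baselines."""

    lambda1_grid: list[float]
    lambda2_grid: list[float]
    metric_name: str
    mean_metric: np.ndarray  # len(l1) x len(l2)
    per_iteration_metric: np.ndarray  # len(l1) x len(l2) x n_iterations
    best: tuple[float, float, float]  # (lambda1, lambda2, mean metric)
    baselines: dict[str, float] = field(default_factory=dict)
    per_iteration_baselines: dict[str, np.ndarray] = field(default_factory=dict)

    def mean_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.mean_metric, index=self.lambda1_grid, columns=self.lambda2_grid
        )


def _metric_for_model(
    metric: str,
    W_eval: np.ndarray,
    H: np.ndarray,
    labels_eval: np.ndarray,
    gene_modules: np.ndarray | None,
    conditions_eval: np.ndarray | None,
    alpha: float,
) -> float:
    if metric == "accuracy":
        if gene_modules is None:
            raise ValueError("metric 'accuracy' requires gene_modules")
        return subgroup_alignment_accuracy(W_eval, H, labels_eval, gene_modules)
    if metric == "ari":
        return adjusted_rand_index(cluster_by_top_lv(W_eval), labels_eval)
    if metric == "n_enriched":
        if conditions_eval is None:
            raise ValueError("metric 'n_enriched' requires conditions")
        return float(
            fisher_enrichment(
                cluster_by_top_lv(W_eval), conditions_eval, alpha=alpha
            ).n_enriched
        )
    raise ValueError(f"unknown metric {metric!r}")


def grid_search(
    Y: np.ndarray,
    metadata: np.ndarray,
    SG: SimilarityGraph | np.ndarray | None,
    k: int,
    lambda1_grid,
    lambda2_grid,
    n_iterations: int = 10,
    metric: str = "accuracy",
    mode: str = "split",
    labels: np.ndarray | None = None,
    gene_modules: np.ndarray | None = None,
    conditions: np.ndarray | None = None,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    alpha: float = DEFAULT_ALPHA,
    max_iter: int = fac.DEFAULT_MAX_ITER,
    tol: float = fac.DEFAULT_TOL,
    seed: int = 0,
    with_baselines: bool = True,
    gnmf_lambda_grid: tuple[float, ...] = fac.GNMF_LAMBDA_GRID,
) -> GridSearchResult:
    """Sweep (lambda1, lambda2) over repeated splits or subsamples.

    Per iteration ``i`` (seed ``seed + i``): split the cohort 70/30
    (``mode='split'``) or subsample 70% (``mode='subsample'``); build SS
    from the *training* metadata; fit every grid cell; evaluate on the
    NNLS-projected test samples (split mode) or the training embedding
    (subsample mode).  Baselines under the identical splits: NMF =
    (0, 0); pr-GNMF = (0, max lambda2 of the grid) with the prior SG;
    GNMF on its own learned gene graph at the maximum of its lambda grid.
    Best cell ties resolve to the smallest lambda1, then lambda2.
    """
    if mode not in ("split", "subsample"):
        raise ValueError("mode must be 'split' or 'subsample'")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    lambda1_grid = sorted(float(x) for x in lambda1_grid)
    lambda2_grid = sorted(float(x) for x in lambda2_grid)
    if not lambda1_grid or not lambda2_grid:
        raise ValueError("lambda grids must be non-empty")
    if labels is None:
        labels = np.zeros(Y.shape[0], dtype=int)
    labels = np.asarray(labels)
    metadata = np.asarray(metadata, dtype=float)
    SG_m = SG.matrix if isinstance(SG, SimilarityGraph) else (
        None if SG is None else np.asarray(SG, dtype=float)
    )
    if any(l2 > 0 for l2 in lambda2_grid) and SG_m is None:
        raise ValueError("nonzero lambda2 grid requires a gene-similarity graph")

    n1, n2 = len(lambda1_grid), len(lambda2_grid)
    per_iter = np.zeros((n1, n2, n_iterations))
    base_names = ["nmf", "pr_gnmf", "gnmf"] if with_baselines else []
    per_iter_base = {b: np.zeros(n_iterations) for b in base_names}

    for it in range(n_iterations):
        it_seed = seed + it
        idx = np.arange(Y.shape[0])
        (tr_idx_expr, lab_tr), (te_idx_expr, lab_te) = split_cohort(
            np.column_stack([idx]), labels, train_fraction=train_fraction,
            seed=it_seed,
        )
        tr = tr_idx_expr.ravel().astype(int)
        te = te_idx_expr.ravel().astype(int)
        Y_tr = Y[tr]
        SS_tr = sample_similarity_from_metadata(metadata[tr]).matrix

        def eval_model(model: fac.FactorModel) -> float:
            if mode == "split":
                W_eval = fac.project_samples(Y[te], model.H).W_test
                lab_eval = lab_te
                cond_eval = conditions[te] if conditions is not None else None
            else:
                W_eval = model.W
                lab_eval = lab_tr
                cond_eval = conditions[tr] if conditions is not None else None
            return _metric_for_model(
                metric, W_eval, model.H, lab_eval, gene_modules, cond_eval, alpha
            )

        for i, l1 in enumerate(lambda1_grid):
            for j, l2 in enumerate(lambda2_grid):
                model = fac.fit(
                    Y_tr, k, SS=SS_tr if l1 > 0 else None,
                    SG=SG_m if l2 > 0 else None, lambda1=l1, lambda2=l2,
                    max_iter=max_iter, tol=tol, seed=it_seed,
                )
                per_iter[i, j, it] = eval_model(model)

        if with_baselines:
            nmf_model = fac.fit(
                Y_tr, k, max_iter=max_iter, tol=tol, seed=it_seed
            )
            per_iter_base["nmf"][it] = eval_model(nmf_model)
            l2_max = max(lambda2_grid)
            if SG_m is not None and l2_max > 0:
                pr = fac.fit(
                    Y_tr, k, SG=SG_m, lambda1=0.0, lambda2=l2_max,
                    max_iter=max_iter, tol=tol, seed=it_seed,
                )
                per_iter_base["pr_gnmf"][it] = eval_model(pr)
            else:
                per_iter_base["pr_gnmf"][it] = per_iter_base["nmf"][it]
            gnmf_model = fac.fit(
                Y_tr, k,
                SG=knn_affinity(
                    Y_tr, n_neighbors=fac.GNMF_N_NEIGHBORS, axis="gene"
                ),
                lambda1=0.0, lambda2=max(gnmf_lambda_grid),
                max_iter=max_iter, tol=tol, seed=it_seed,
            )
            per_iter_base["gnmf"][it] = eval_model(gnmf_model)

    mean_metric = per_iter.mean(axis=2)
    # best cell: max mean, ties -> smallest lambda1 then lambda2 (grids are
    # scanned in order, argmax returns the first maximum)
    flat = mean_metric.ravel()
    best_flat = int(np.argmax(flat))
    bi, bj = divmod(best_flat, n2)
    best = (lambda1_grid[bi], lambda2_grid[bj], float(mean_metric[bi, bj]))
    baselines = {b: float(v.mean()) for b, v in per_iter_base.items()}
    return GridSearchResult(
        lambda1_grid=lambda1_grid, lambda2_grid=lambda2_grid,
        metric_name=metric, mean_metric=mean_metric,
        per_iteration_metric=per_iter, best=best, baselines=baselines,
        per_iteration_baselines=per_iter_base,
    )


# ---------------------------------------------------------------------------
# Simulation benchmark (cohort sweep over seeds and noise levels)
# ---------------------------------------------------------------------------

def simulation_noise_benchmark(
    seeds,
    noise_fractions=(0.0, 0.6),
    lambda_grid=(0.0, 0.5, 1.0),
    k: int = 5,
    n_genes: int = 400,
    n_samples: int = 100,
    n_subgroups: int = 5,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
) -> dict[float, dict]:
    """Paired GRACKLE-vs-NMF accuracy sweep over simulated cohorts.

    For each seed one cohort is generated (the noise stage re-applied per
    noise fraction on the shared pre-noise expression) and split 70/30
    once; every (lambda1, lambda2) cell of ``lambda_grid`` x
    ``lambda_grid`` is fit on the training samples with SS built from the
    *training* subgroup labels and SG from the cohort's GRN, the test
    samples are NNLS-projected, and subgroup alignment accuracy is
    scored.  Returns, per noise fraction: per-seed NMF accuracy (the
    (0, 0) cell), the grid cell with the best mean accuracy, and its
    per-seed accuracies for a paired comparison.
    """
    from .simulation import add_background_noise, min_max_scale, simulate_cohort

    lambda_grid = sorted(float(x) for x in lambda_grid)
    cells = [(l1, l2) for l1 in lambda_grid for l2 in lambda_grid]
    acc: dict[float, dict[tuple[float, float], list[float]]] = {
        nf: {c: [] for c in cells} for nf in noise_fractions
    }
    for seed in seeds:
        cohort = simulate_cohort(
            n_genes=n_genes, n_samples=n_samples, n_subgroups=n_subgroups,
            noise_fraction=0.0, seed=seed,
        )
        labels = np.asarray(cohort.subgroup_labels)
        gene_modules = np.asarray([cohort.modules[g] for g in cohort.gene_ids])
        uniq = sorted(set(labels))
        meta = np.zeros((n_samples, len(uniq)))
        for col, lab in enumerate(uniq):
            meta[labels == lab, col] = 1.0
        from .graphs import gene_similarity_from_grn

        SG = gene_similarity_from_grn(cohort.grn, cohort.gene_ids).matrix
        idx = np.arange(n_samples)
        (tr_idx, _), (te_idx, _) = split_cohort(
            idx[:, None], labels, train_fraction=train_fraction, seed=seed
        )
        tr = tr_idx.ravel().astype(int)
        te = te_idx.ravel().astype(int)
        SS = sample_similarity_from_metadata(meta[tr]).matrix
        for nf in noise_fractions:
            noisy = add_background_noise(
                cohort.expression_perturbed, cohort.modules, cohort.gene_ids,
                cohort.perturbed_modules, nf, sample_labels=labels,
                seed=seed + 3,
            )
            Y = min_max_scale(noisy)
            for l1, l2 in cells:
                model = fac.fit(
                    Y[tr], k, SS=SS if l1 > 0 else None,
                    SG=SG if l2 > 0 else None, lambda1=l1, lambda2=l2,
                    seed=seed,
                )
                W_test = fac.project_samples(Y[te], model.H).W_test
                acc[nf][(l1, l2)].append(
                    subgroup_alignment_accuracy(
                        W_test, model.H, labels[te], gene_modules
                    )
                )
    out: dict[float, dict] = {}
    for nf in noise_fractions:
        means = {c: float(np.mean(v)) for c, v in acc[nf].items()}
        best_cell = max(means, key=lambda c: (means[c], -c[0], -c[1]))
        out[nf] = {
            "nmf": acc[nf][(0.0, 0.0)],
            "best_cell": best_cell,
            "best": acc[nf][best_cell],
            "mean_grid": means,
        }
    return out
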