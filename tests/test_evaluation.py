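"""Splits, alignment accuracy, ARI, Fisher enrichment, grid search."""

import itertools
import math

import numpy as np
import pytest

from grackle import evaluation as ev
from grackle import factorization as fac
from grackle.graphs import gene_similarity_from_grn, sample_similarity_from_metadata


class TestSplitCohort:
    def test_seventy_thirty(self):
        expr = np.arange(200).reshape(100, 2).astype(float)
        labels = np.repeat(np.arange(5), 20)
        (tr, ltr), (te, lte) = ev.split_cohort(expr, labels, seed=0)
        assert tr.shape[0] == 70 and te.shape[0] == 30
        assert len(ltr) == 70 and len(lte) == 30
        # no overlap, full coverage
        assert len(np.intersect1d(tr[:, 0], te[:, 0])) == 0
        assert len(np.union1d(tr[:, 0], te[:, 0])) == 100

    def test_test_partition_never_empty(self):
        expr = np.arange(10).reshape(10, 1).astype(float)
        (tr, _), (te, _) = ev.split_cohort(expr, np.zeros(10), 0.99, seed=0)
        assert tr.shape[0] == 9 and te.shape[0] == 1

    def test_reproducible(self):
        expr = np.random.default_rng(0).random((20, 3))
        labels = np.zeros(20)
        a = ev.split_cohort(expr, labels, seed=7)
        b = ev.split_cohort(expr, labels, seed=7)
        np.testing.assert_array_equal(a[0][0], b[0][0])

    def test_labels_stay_aligned(self):
        expr = np.arange(30).reshape(30, 1).astype(float)
        labels = np.arange(30)  # label equals row value
        (tr, ltr), (te, lte) = ev.split_cohort(expr, labels, seed=5)
        np.testing.assert_array_equal(tr[:, 0], ltr)
        np.testing.assert_array_equal(te[:, 0], lte)


class TestAlignmentAccuracy:
    def _block_factors(self, k=5, spg=4, gpm=6):
        """Block-diagonal W_test and H aligned per subgroup."""
        W = np.zeros((k * spg, k))
        H = np.zeros((k, k * gpm))
        labels = []
        modules = []
        for g in range(k):
            W[g * spg:(g + 1) * spg, g] = 1.0
            H[g, g * gpm:(g + 1) * gpm] = 1.0
            labels += [str(g)] * spg
            modules += [str(g)] * gpm
        return W, H, np.array(labels), np.array(modules)

    def test_aligned_blocks_score_one(self):
        W, H, labels, modules = self._block_factors()
        assert ev.subgroup_alignment_accuracy(W, H, labels, modules) == 1.0

    def test_cyclically_permuted_gene_side_scores_zero(self):
        W, H, labels, modules = self._block_factors()
        H_perm = np.roll(H, 1, axis=0)  # cyclic 5-permutation of LV axis
        assert ev.subgroup_alignment_accuracy(W, H_perm, labels, modules) == 0.0

    def test_single_swapped_pair_scores_point_eight(self):
        W, H, labels, modules = self._block_factors()
        H_swap = H.copy()
        H_swap[[3, 4]] = H_swap[[4, 3]]
        assert ev.subgroup_alignment_accuracy(W, H_swap, labels, modules) == 0.6
        # swapping the same LVs on both sides restores full accuracy
        W_swap = W.copy()
        W_swap[:, [3, 4]] = W_swap[:, [4, 3]]
        assert ev.subgroup_alignment_accuracy(W_swap, H_swap, labels, modules) == 1.0

    def test_invariant_to_simultaneous_lv_permutation(self):
        W, H, labels, modules = self._block_factors()
        rng = np.random.default_rng(0)
        perm = rng.permutation(W.shape[1])
        acc0 = ev.subgroup_alignment_accuracy(W, H, labels, modules)
        acc1 = ev.subgroup_alignment_accuracy(W[:, perm], H[perm], labels, modules)
        assert acc0 == acc1

    def test_background_samples_excluded(self):
        W, H, labels, modules = self._block_factors(k=3)
        labels = labels.copy()
        labels[:2] = "background"
        acc = ev.subgroup_alignment_accuracy(W, H, labels, modules)
        assert acc == 1.0


class TestClusterByTopLv:
    def test_argmax_and_tie_rule(self):
        W = np.array([[0.9, 0.1], [0.2, 0.8], [0.5, 0.5], [0.0, 0.0]])
        np.testing.assert_array_equal(ev.cluster_by_top_lv(W), [0, 1, 0, 0])

    def test_identity_like(self):
        np.testing.assert_array_equal(ev.cluster_by_top_lv(np.eye(4)), np.arange(4))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ev.cluster_by_top_lv(np.array([[-1.0, 0.0]]))


def ari_pair_counting_oracle(a, b):
    """Brute-force ARI over all sample pairs."""
    n = len(a)
    pairs = list(itertools.combinations(range(n), 2))
    n11 = sum(1 for i, j in pairs if a[i] == a[j] and b[i] == b[j])
    n00 = sum(1 for i, j in pairs if a[i] != a[j] and b[i] != b[j])
    n10 = sum(1 for i, j in pairs if a[i] == a[j] and b[i] != b[j])
    n01 = sum(1 for i, j in pairs if a[i] != a[j] and b[i] == b[j])
    total = len(pairs)
    index = n11
    expected = (n11 + n10) * (n11 + n01) / total
    max_index = ((n11 + n10) + (n11 + n01)) / 2
    if max_index == expected:
        return 1.0
    return (index - expected) / (max_index - expected)


class TestAdjustedRandIndex:
    def test_identical_labelings(self):
        assert ev.adjusted_rand_index([1, 2, 3, 1], [1, 2, 3, 1]) == 1.0

    def test_constant_labeling_scores_zero(self):
        assert ev.adjusted_rand_index([1, 1, 1, 1], [1, 2, 1, 2]) == 0.0

    def test_hand_case_matches_pair_counting(self):
        a, b = [1, 1, 2, 2], [1, 2, 1, 2]
        np.testing.assert_allclose(
            ev.adjusted_rand_index(a, b), ari_pair_counting_oracle(a, b)
        )

    def test_random_pairs_match_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(3, 13))
            a = rng.integers(0, 4, n)
            b = rng.integers(0, 4, n)
            np.testing.assert_allclose(
                ev.adjusted_rand_index(a, b), ari_pair_counting_oracle(a, b),
                atol=1e-12,
            )

    def test_symmetric_and_rename_invariant(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 3, 20)
        b = rng.integers(0, 3, 20)
        assert ev.adjusted_rand_index(a, b) == ev.adjusted_rand_index(b, a)
        assert ev.adjusted_rand_index(a, b) == ev.adjusted_rand_index(2 - a, b)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ev.adjusted_rand_index([1, 2], [1, 2, 3])


class TestPermutedLabelControl:
    def test_relation_to_original_similarity(self):
        rng = np.random.default_rng(0)
        meta = np.eye(3)[rng.integers(0, 3, 12)].astype(float)
        permuted, perm = ev.permuted_label_control(meta, seed=4)
        SS = sample_similarity_from_metadata(meta).matrix
        SSp = sample_similarity_from_metadata(permuted).matrix
        P = np.eye(12)[perm]
        np.testing.assert_array_equal(SSp, P @ SS @ P.T)
        np.testing.assert_allclose(
            np.sort(np.linalg.eigvalsh(SSp)), np.sort(np.linalg.eigvalsh(SS)),
            atol=1e-9,
        )

    def test_label_histogram_unchanged_and_not_identity(self):
        meta = np.eye(2)[[0, 0, 1, 1, 0, 1]].astype(float)
        for seed in range(10):
            permuted, perm = ev.permuted_label_control(meta, seed=seed)
            assert not np.array_equal(perm, np.arange(6))
            np.testing.assert_array_equal(
                permuted.sum(axis=0), meta.sum(axis=0)
            )


def fisher_enumeration_oracle(a, b, c, d):
    """Sum of probabilities of all tables with fixed margins at least as extreme."""
    r1, r2 = a + b, c + d
    c1 = a + c
    N = r1 + r2
    denom = math.comb(N, r1)
    p = 0.0
    for x in range(max(0, r1 - (N - c1)), min(r1, c1) + 1):
        if x >= a:
            p += math.comb(c1, x) * math.comb(N - c1, r1 - x) / denom
    return p


class TestFisherEnrichment:
    def test_single_most_extreme_table(self):
        p = ev.fisher_one_sided_p(10, 0, 0, 10)
        np.testing.assert_allclose(p, 1.0 / math.comb(20, 10), rtol=1e-12)

    def test_no_enrichment_direction(self):
        assert ev.fisher_one_sided_p(5, 5, 5, 5) > 0.5

    def test_small_table_matches_enumeration(self):
        np.testing.assert_allclose(
            ev.fisher_one_sided_p(3, 1, 1, 3), fisher_enumeration_oracle(3, 1, 1, 3),
            rtol=1e-12,
        )

    def test_matches_scipy_fisher_exact(self):
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b, c, d = rng.integers(0, 15, 4)
            table = [[a, b], [c, d]]
            np.testing.assert_allclose(
                ev.fisher_one_sided_p(a, b, c, d),
                fisher_exact(table, alternative="greater")[1],
                rtol=1e-9,
            )

    def test_enrichment_table_counts(self):
        groups = np.array([0] * 10 + [1] * 10)
        conditions = np.zeros((20, 2))
        conditions[:8, 0] = 1  # condition 0 concentrated in LV0
        conditions[::2, 1] = 1  # condition 1 spread evenly
        res = ev.fisher_enrichment(groups, conditions)
        t = res.table
        row = t[(t.lv == 0) & (t.condition == "cond0")].iloc[0]
        assert row.in_pos == 8 and row.in_total == 10 and row.out_pos == 0
        assert row.p < 0.05
        assert res.n_enriched >= 1
        spread = t[(t.condition == "cond1")]
        assert (spread.p > 0.05).all()

    def test_zero_positive_condition_flagged(self):
        groups = np.array([0, 0, 1, 1])
        conditions = np.zeros((4, 1))
        res = ev.fisher_enrichment(groups, conditions)
        assert (res.table.p == 1.0).all()
        assert res.table.zero_positives.all()
        assert res.n_enriched == 0

    def test_non_binary_conditions_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            ev.fisher_enrichment(np.array([0, 1]), np.array([[0.5], [1.0]]))


class TestGridSearch:
    def _toy(self):
        rng = np.random.default_rng(6)
        # 3 planted sample groups over 30 samples x 24 genes
        labels = np.repeat([0, 1, 2], 10)
        Y = rng.random((30, 24)) * 0.1
        modules = np.repeat([0, 1, 2], 8)
        for g in range(3):
            Y[np.ix_(labels == g, modules == g)] += 1.0
        meta = np.eye(3)[labels].astype(float)
        SG = np.zeros((24, 24))
        for m in range(3):
            idx = np.where(modules == m)[0]
            for i in idx:
                for j in idx:
                    if i != j:
                        SG[i, j] = 1.0
        return Y, meta, SG, labels, modules.astype(str)

    def test_zero_grid_reduces_to_nmf_baseline(self):
        Y, meta, SG, labels, modules = self._toy()
        res = ev.grid_search(
            Y, meta, SG, k=3, lambda1_grid=[0], lambda2_grid=[0],
            n_iterations=3, metric="accuracy", labels=np.array(
                [str(l) for l in labels]
            ),
            gene_modules=modules, seed=5,
        )
        np.testing.assert_allclose(res.mean_metric[0, 0], res.baselines["nmf"])
        np.testing.assert_array_equal(
            res.per_iteration_metric[0, 0], res.per_iteration_baselines["nmf"]
        )

    def test_shapes_and_best_cell(self):
        Y, meta, SG, labels, modules = self._toy()
        res = ev.grid_search(
            Y, meta, SG, k=3, lambda1_grid=[0, 0.5, 1], lambda2_grid=[0, 0.5, 1],
            n_iterations=2, metric="accuracy",
            labels=np.array([str(l) for l in labels]),
            gene_modules=modules, seed=1, with_baselines=False,
        )
        assert res.mean_metric.shape == (3, 3)
        assert res.per_iteration_metric.shape == (3, 3, 2)
        np.testing.assert_allclose(
            res.mean_metric, res.per_iteration_metric.mean(axis=2)
        )
        l1, l2, best_val = res.best
        assert best_val == res.mean_metric.max()
        # best is at least the unregularized cell by construction of max
        assert best_val >= res.mean_metric[0, 0]

    def test_reproducible_from_master_seed(self):
        Y, meta, SG, labels, modules = self._toy()
        kw = dict(
            k=3, lambda1_grid=[0, 1], lambda2_grid=[0], n_iterations=2,
            metric="ari", labels=labels, seed=9, with_baselines=False,
        )
        a = ev.grid_search(Y, meta, SG, **kw)
        b = ev.grid_search(Y, meta, SG, **kw)
        np.testing.assert_array_equal(a.per_iteration_metric, b.per_iteration_metric)
        assert a.best == b.best

    def test_metric_requirements_enforced(self):
        Y, meta, SG, labels, modules = self._toy()
        with pytest.raises(ValueError, match="gene_modules"):
            ev.grid_search(
                Y, meta, SG, k=3, lambda1_grid=[0], lambda2_grid=[0],
                n_iterations=1, metric="accuracy", labels=labels, seed=0,
                with_baselines=False,
            )
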