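import itertools

import numpy as np
import pytest
from scipy.stats import spearmanr

from longicluster import (
    RESPONDER,
    NONRESPONDER,
    aggregate_scores,
    build_views,
    majority_vote,
    map_clusters_to_labels,
    run_ensemble,
    run_weak_learner,
    sample_gene_subset,
    select_top_k,
)
from longicluster.ensemble import replicate_rng, WeakLearnerResult
from longicluster.model import fit_icluster

from conftest import ANALYSIS_TIMEPOINTS


class TestSampleGeneSubset:
    def test_full_subset_is_all_indices(self):
        rng = replicate_rng(0, 0)
        assert list(sample_gene_subset(20, 20, rng)) == list(range(20))

    def test_same_substream_same_subset(self):
        a = sample_gene_subset(662, 20, replicate_rng(5, 3))
        b = sample_gene_subset(662, 20, replicate_rng(5, 3))
        assert np.array_equal(a, b)

    def test_oversized_subset_rejected(self):
        with pytest.raises(ValueError):
            sample_gene_subset(10, 11, replicate_rng(0, 0))

    def test_inclusion_frequencies_binomial(self):
        # each gene should appear ~ draws * m / p times, within 4 sigma
        p, m, draws = 662, 20, 10_000
        counts = np.zeros(p, dtype=int)
        for r in range(draws):
            counts[sample_gene_subset(p, m, replicate_rng(123, r))] += 1
        rate = m / p
        expected = draws * rate
        sigma = np.sqrt(draws * rate * (1 - rate))
        assert np.all(np.abs(counts - expected) < 4 * sigma)


class TestClusterLabelMapping:
    def test_perfect_agreement(self):
        mapping, acc = map_clusters_to_labels(
            [1, 1, 2, 2], [RESPONDER, RESPONDER, NONRESPONDER, NONRESPONDER])
        assert acc == 1.0
        assert mapping == {1: RESPONDER, 2: NONRESPONDER}

    def test_exact_tie_uses_declared_rule(self):
        mapping, acc = map_clusters_to_labels(
            [1, 2, 1, 2], [RESPONDER, RESPONDER, NONRESPONDER, NONRESPONDER])
        assert acc == 0.5
        # both mappings score 0.5 and both clusters hold one responder:
        # the lower cluster id maps to responder
        assert mapping[1] == RESPONDER

    def test_matches_brute_force_over_both_mappings(self):
        # exhaustive over every clustering x labeling with n <= 8
        for n in (4, 6, 8):
            for cl in itertools.product([1, 2], repeat=n):
                for truth_bits in itertools.product([0, 1], repeat=n):
                    truth = [RESPONDER if b else NONRESPONDER
                             for b in truth_bits]
                    _, acc = map_clusters_to_labels(list(cl), truth)
                    best = max(
                        np.mean([(c == resp_cluster) == bool(b)
                                 for c, b in zip(cl, truth_bits)])
                        for resp_cluster in (1, 2))
                    assert acc == pytest.approx(best)

    def test_three_clusters_rejected(self):
        with pytest.raises(ValueError):
            map_clusters_to_labels([1, 2, 3], [RESPONDER] * 3)


class TestWeakLearner:
    def test_informative_subset_is_accurate(self, reference_data,
                                            reference_views,
                                            reference_labels):
        data, truth = reference_data
        informative = [data.gene_ids.index(g)
                       for g in truth.informative_gene_ids[:8]]
        rng = replicate_rng(0, 0)
        noise = [i for i in range(300)
                 if data.gene_ids[i] not in truth.informative_gene_ids]
        subset = np.sort(informative + list(rng.choice(noise, 12,
                                                       replace=False)))
        wl = run_weak_learner(reference_views, subset, reference_labels)
        assert wl.accuracy >= 0.9

    def test_noise_subsets_center_near_majority_rate(self, noise_data):
        data, _ = noise_data
        views = build_views(data, ANALYSIS_TIMEPOINTS)
        rng = np.random.default_rng(0)
        labels = rng.permutation(data.response_labels(views.subject_ids))
        accs = []
        for r in range(60):
            subset = sample_gene_subset(80, 20, replicate_rng(99, r))
            accs.append(run_weak_learner(views, subset, labels).accuracy)
        majority = max(np.mean(labels == RESPONDER),
                       np.mean(labels == NONRESPONDER))
        # best-of-two mapping biases accuracy a bit above the majority rate,
        # but the null distribution must sit nowhere near the 0.75 cutoff
        assert majority - 0.05 < np.mean(accs) < 0.72

    def test_all_genes_equals_full_fit(self, reference_views,
                                       reference_labels):
        wl = run_weak_learner(reference_views, np.arange(300),
                              reference_labels)
        full = fit_icluster(reference_views, K=2, lam=0.0, seed=0)
        assert np.array_equal(wl.fit.cluster_labels, full.cluster_labels)
        assert np.allclose(wl.fit.W_stacked, full.W_stacked)


def _fake_learner(gene_indices, W_per_view, predicted):
    fit = fit_icluster([np.random.default_rng(0).normal(
        size=(len(gene_indices), 4))], K=2)
    fit.W = [np.asarray(w, float).reshape(-1, 1) for w in W_per_view]
    return WeakLearnerResult(
        gene_indices=np.asarray(gene_indices), fit=fit,
        label_mapping={1: RESPONDER, 2: NONRESPONDER},
        accuracy=1.0, predicted=np.asarray(predicted))


class TestAggregateScores:
    def test_sums_over_learners_and_views(self):
        a = _fake_learner([0, 1], [[0.6, 0.3], [0.4, 0.2]], [RESPONDER] * 4)
        b = _fake_learner([0, 2], [[0.1, 0.2], [0.1, 0.1]], [RESPONDER] * 4)
        scores = aggregate_scores([a, b], p=4)
        assert scores == pytest.approx([1.2, 0.5, 0.3, 0.0])

    def test_empty_kept_gives_zeros(self):
        assert np.all(aggregate_scores([], p=5) == 0)

    def test_sum_of_absolutes_across_views(self):
        wl = _fake_learner([3], [[0.1], [-0.2], [0.3], [-0.4]],
                           [RESPONDER] * 4)
        scores = aggregate_scores([wl], p=5)
        assert scores[3] == pytest.approx(1.0)
        wl_max = aggregate_scores([wl], p=5, use_max=True)
        assert wl_max[3] == pytest.approx(0.4)


class TestMajorityVote:
    def test_strict_majority_wins(self):
        learners = [_fake_learner([0], [[1.0]], [RESPONDER]) for _ in range(3)]
        learners += [_fake_learner([0], [[1.0]], [NONRESPONDER])]
        voted, counts = majority_vote(learners, 1)
        assert voted[0] == RESPONDER
        assert counts[0].tolist() == [1, 3]

    def test_exact_tie_defaults_to_nonresponder(self):
        learners = [_fake_learner([0], [[1.0]], [RESPONDER])] * 2
        learners += [_fake_learner([0], [[1.0]], [NONRESPONDER])] * 2
        voted, _ = majority_vote(learners, 1)
        assert voted[0] == NONRESPONDER
        voted_r, _ = majority_vote(learners, 1, tie_label=RESPONDER)
        assert voted_r[0] == RESPONDER

    def test_single_learner_vote_is_its_prediction(self):
        wl = _fake_learner([0], [[1.0]], [RESPONDER, NONRESPONDER])
        voted, _ = majority_vote([wl], 2)
        assert list(voted) == [RESPONDER, NONRESPONDER]

    def test_empty_kept_rejected(self):
        with pytest.raises(ValueError):
            majority_vote([], 3)


class TestSelectTopK:
    def test_descending_order(self):
        assert select_top_k({"g1": 1.2, "g2": 0.5, "g3": 0.3}, 2) == \
            ["g1", "g2"]

    def test_tie_breaks_lexicographically(self):
        assert select_top_k({"b": 1.0, "a": 1.0}, 1) == ["a"]

    def test_k_equal_to_gene_count_is_permutation(self):
        scores = {"g3": 0.1, "g1": 5.0, "g2": 2.0}
        assert sorted(select_top_k(scores, 3)) == ["g1", "g2", "g3"]

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            select_top_k({"a": 1.0}, 2)


class TestRunEnsemble:
    def test_reproducible_for_same_seed(self, reference_views,
                                        reference_labels):
        kwargs = dict(n_replicates=40, subset_size=20,
                      accuracy_cutoff=0.75, seed=21)
        a = run_ensemble(reference_views, reference_labels, **kwargs)
        b = run_ensemble(reference_views, reference_labels, **kwargs)
        assert np.array_equal(a.gene_scores, b.gene_scores)
        assert np.array_equal(a.vote_counts, b.vote_counts)
        assert a.to_dict() == b.to_dict()

    def test_single_replicate_votes_are_its_predictions(
            self, reference_views, reference_labels):
        res = run_ensemble(reference_views, reference_labels,
                           n_replicates=1, accuracy_cutoff=0.0, seed=4)
        rng = replicate_rng(4, 0)
        subset = sample_gene_subset(300, 20, rng)
        wl = run_weak_learner(reference_views, subset, reference_labels)
        assert list(res.voted_labels) == list(wl.predicted)
        assert res.kept_count == 1

    def test_impossible_cutoff_fails_loudly(self, noise_data):
        data, _ = noise_data
        views = build_views(data, ANALYSIS_TIMEPOINTS)
        labels = data.response_labels(views.subject_ids)
        with pytest.raises(RuntimeError, match="0.999"):
            run_ensemble(views, labels, n_replicates=30,
                         accuracy_cutoff=0.999, seed=0)

    def test_score_support_only_in_kept_subsets(self, reference_views,
                                                reference_labels):
        res = run_ensemble(reference_views, reference_labels,
                           n_replicates=60, accuracy_cutoff=0.75, seed=13)
        assert res.kept_count > 0
        positive = res.gene_scores > 0
        assert np.all(res.times_kept[positive] >= 1)
        assert np.all(res.times_sampled >= res.times_kept)
        assert np.all(res.vote_counts.sum(axis=1) == res.kept_count)

    def test_permuted_labels_weaken_filter_and_scores(
            self, reference_data, reference_views, reference_labels):
        _, truth = reference_data
        res_true = run_ensemble(reference_views, reference_labels,
                                n_replicates=150, accuracy_cutoff=0.0, seed=2)
        informative = np.isin(reference_views.gene_ids,
                              truth.informative_gene_ids).astype(float)
        rng = np.random.default_rng(0)
        for perm_seed in range(5):
            permuted = rng.permutation(np.asarray(reference_labels))
            res_perm = run_ensemble(reference_views, permuted,
                                    n_replicates=150, accuracy_cutoff=0.0,
                                    seed=2)
            assert _pass_rate(res_perm) <= _pass_rate(res_true)
            # scores of the learners that would pass the 0.75 filter carry
            # no systematic advantage for the planted genes
            passing = res_perm.replicate_accuracies > 0.75
            if passing.any():
                res75 = run_ensemble(reference_views, permuted,
                                     n_replicates=150, accuracy_cutoff=0.75,
                                     seed=2)
                rho = spearmanr(res75.gene_scores, informative).statistic
                assert abs(rho) <= 0.2


def _pass_rate(result, cutoff=0.75):
    """Fraction of replicates whose label agreement exceeds the cutoff."""
    return float(np.mean(result.replicate_accuracies > cutoff))
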