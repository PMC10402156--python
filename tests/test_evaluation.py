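import numpy as np
import pytest
from scipy import stats

from stripehic.evaluation import (distance_stratified_pearson,
                                  insulation_score, map_peaks_to_bins,
                                  paired_ttest, peak_level_auc,
                                  peak_level_labels, peak_pair_score,
                                  significant_interaction_auc)
from stripehic.hic import ContactMap, label_significant_bins
from stripehic.io_formats import PeakInterval


def random_map(n, rng, chrom="chr1"):
    cm = ContactMap(chrom, n, 10_000)
    for i in range(n):
        for j in range(i, n):
            cm.set(i, j, float(rng.normal()))
    return cm


class TestDistanceStratifiedPearson:
    def test_identical_maps_give_one_everywhere(self, rng):
        m = random_map(40, rng)
        r = distance_stratified_pearson(m, m, max_distance_bins=20)
        defined = ~np.isnan(r.values)
        assert defined.any()
        np.testing.assert_allclose(r.values[defined], 1.0, atol=1e-12)
        assert r.mean == pytest.approx(1.0)

    def test_per_distance_affine_invariance(self, rng):
        truth = random_map(40, rng)
        pred = random_map(40, rng)
        r1 = distance_stratified_pearson(pred, truth, max_distance_bins=15)
        scaled = pred.copy_empty()
        for (i, j), v in pred.items():
            scaled.set(i, j, 3.0 * v + (j - i))  # distance-dependent affine
        r2 = distance_stratified_pearson(scaled, truth, max_distance_bins=15)
        np.testing.assert_allclose(r1.values, r2.values, atol=1e-10,
                                   equal_nan=True)

    def test_matches_direct_formula_oracle(self, rng):
        pred, truth = random_map(30, rng), random_map(30, rng)
        r = distance_stratified_pearson(pred, truth, max_distance_bins=10)
        pd_, td_ = pred.to_dense(), truth.to_dense()
        for d in range(11):
            x = np.array([pd_[i, i + d] for i in range(30 - d)])
            y = np.array([td_[i, i + d] for i in range(30 - d)])
            expect = stats.pearsonr(x, y).statistic
            assert r.values[d] == pytest.approx(expect, abs=1e-10)

    def test_undefined_distances_excluded_from_mean(self, rng):
        truth = random_map(20, rng)
        pred = truth.copy_empty()
        for (i, j), v in truth.items():
            pred.set(i, j, v if j - i != 3 else 0.0)  # constant at d=3
        r = distance_stratified_pearson(pred, truth, max_distance_bins=5)
        assert np.isnan(r.values[3])
        assert r.mean == pytest.approx(1.0)

    def test_storage_order_invariance(self, rng):
        truth = random_map(25, rng)
        pred = random_map(25, rng)
        shuffled = pred.copy_empty()
        items = list(pred.items())
        for k in rng.permutation(len(items)):
            (i, j), v = items[k]
            shuffled.set(i, j, v)
        r1 = distance_stratified_pearson(pred, truth, max_distance_bins=10)
        r2 = distance_stratified_pearson(shuffled, truth, max_distance_bins=10)
        np.testing.assert_array_equal(r1.values, r2.values)


def mannwhitney_auroc(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((pos[:, None] > neg[None, :]).sum()
               + 0.5 * (pos[:, None] == neg[None, :]).sum()
               for _ in [0])
    return wins / (len(pos) * len(neg))


class TestSignificantInteractionAuc:
    def test_perfect_scores_give_auroc_one(self, rng):
        truth = random_map(40, rng)
        labels = label_significant_bins(truth, 0.2, max_distance_bins=15)
        auroc, auprc = significant_interaction_auc(truth, labels,
                                                   max_distance_bins=15)
        defined = ~np.isnan(auroc.values)
        np.testing.assert_allclose(auroc.values[defined], 1.0)

    def test_random_scores_near_half(self, rng):
        n = 400
        truth = ContactMap("chr1", n, 10_000)
        pred = ContactMap("chr1", n, 10_000)
        for i in range(n - 1):
            truth.set(i, i + 1, float(rng.normal()))
            pred.set(i, i + 1, float(rng.normal()))
        labels = label_significant_bins(truth, 0.5, max_distance_bins=1)
        auroc, _ = significant_interaction_auc(pred, labels,
                                               max_distance_bins=1)
        assert 0.35 < auroc.values[1] < 0.65

    def test_matches_rank_statistic_oracle(self, rng):
        pred = random_map(30, rng)
        truth = random_map(30, rng)
        labels = label_significant_bins(truth, 0.3, max_distance_bins=8)
        auroc, _ = significant_interaction_auc(pred, labels,
                                               max_distance_bins=8)
        dense = pred.to_dense()
        for d in range(9):
            i = np.arange(30 - d)
            y = np.array([(a, a + d) in labels for a in i], dtype=int)
            if y.min() == y.max():
                assert np.isnan(auroc.values[d])
                continue
            oracle = mannwhitney_auroc(dense[i, i + d], y)
            assert auroc.values[d] == pytest.approx(oracle, abs=1e-10)


class TestPeakMapping:
    def test_boundary_spanning_peak_in_both_bins(self):
        peaks = [PeakInterval("chr1", 19_995, 20_010, "p")]
        assert map_peaks_to_bins(peaks)["p"] == {1, 2}

    def test_interior_peak_single_bin(self):
        peaks = [PeakInterval("chr1", 12_000, 13_000, "p")]
        assert map_peaks_to_bins(peaks)["p"] == {1}

    def test_peak_starting_on_boundary_right_bin_only(self):
        peaks = [PeakInterval("chr1", 20_000, 20_500, "p")]
        assert map_peaks_to_bins(peaks)["p"] == {2}


class TestPeakLabels:
    BINS = {"a": {0}, "b": {5}, "c": {5, 6}}

    def test_threshold_is_strict(self):
        pv = {(0, 5): 0.24}
        labels = peak_level_labels([("a", "b")], pv, self.BINS)
        assert labels[("a", "b")] == 1
        pv = {(0, 5): 0.25}
        labels = peak_level_labels([("a", "b")], pv, self.BINS)
        assert labels[("a", "b")] == 0

    def test_any_rule_over_bin_pairs(self):
        pv = {(0, 5): 0.9, (0, 6): 0.01}
        labels = peak_level_labels([("a", "c")], pv, self.BINS)
        assert labels[("a", "c")] == 1

    def test_missing_pvalues_dropped(self):
        labels = peak_level_labels([("a", "b")], {}, self.BINS)
        assert ("a", "b") not in labels


class TestPeakPairScore:
    def test_single_bin_pair(self, rng):
        m = random_map(10, rng)
        assert peak_pair_score(m, {2}, {7}) == m.value(2, 7)

    def test_max_of_four(self, rng):
        m = random_map(10, rng)
        expect = max(m.value(i, j) for i in (2, 3) for j in (7, 8))
        assert peak_pair_score(m, {2, 3}, {7, 8}) == expect

    def test_matches_brute_force_all_reductions(self, rng):
        m = random_map(12, rng)
        a, b = {1, 2, 3}, {6, 9}
        vals = [m.value(i, j) for i in a for j in b]
        assert peak_pair_score(m, a, b, "max") == max(vals)
        assert peak_pair_score(m, a, b, "min") == min(vals)
        assert peak_pair_score(m, a, b, "mean") == pytest.approx(np.mean(vals))


class TestPeakLevelAuc:
    def test_distance_constraint_excludes_far_pairs(self):
        scores = [0.9, 0.1, 0.99]
        labels = [1, 0, 0]  # third pair would be a confusing FP...
        dists = [100_000, 200_000, 600_000]  # ...but sits beyond 500kb
        auprc, auroc = peak_level_auc(scores, labels, dists)
        assert auprc == 1.0 and auroc == 1.0

    def test_perfect_scores(self):
        auprc, auroc = peak_level_auc([0.9, 0.8, 0.1], [1, 1, 0])
        assert auprc == 1.0 and auroc == 1.0

    def test_single_class_reported_missing(self):
        auprc, auroc = peak_level_auc([0.5, 0.6], [1, 1])
        assert np.isnan(auprc) and np.isnan(auroc)

    def test_matches_oracle_on_toy_set(self, rng):
        from sklearn.metrics import average_precision_score, roc_auc_score

        scores = rng.normal(size=20)
        labels = rng.integers(0, 2, size=20)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        auprc, auroc = peak_level_auc(scores, labels)
        assert auroc == pytest.approx(roc_auc_score(labels, scores))
        assert auprc == pytest.approx(average_precision_score(labels, scores))


class TestInsulation:
    def test_constant_map_constant_interior(self):
        n = 20
        cm = ContactMap("chr1", n, 10_000)
        for i in range(n):
            for j in range(i, n):
                cm.set(i, j, 2.0)
        score = insulation_score(cm, window_bins=4)
        interior = score[4:n - 4]
        np.testing.assert_allclose(interior, 2.0)
        assert np.isnan(score[0]) and np.isnan(score[-1])

    def test_block_boundary_is_local_minimum(self):
        n = 30
        cm = ContactMap("chr1", n, 10_000)
        for i in range(n):
            for j in range(i, n):
                same_block = (i < 15) == (j < 15)
                cm.set(i, j, 5.0 if same_block else 0.1)
        score = insulation_score(cm, window_bins=5)
        interior = np.arange(5, n - 5)
        assert interior[np.nanargmin(score[5:n - 5])] in (14, 15)

    def test_matches_nested_loop_oracle(self, rng):
        cm = random_map(25, rng)
        w = 4
        score = insulation_score(cm, window_bins=w)
        dense = cm.to_dense()
        for b in range(w, 25 - w):
            expect = dense[b - w:b + 1, b:b + w + 1].mean()
            assert score[b] == pytest.approx(expect)

    def test_window_too_large_raises(self, rng):
        with pytest.raises(ValueError):
            insulation_score(random_map(5, rng), window_bins=5)


class TestPairedTtest:
    def test_equal_inputs_no_difference(self):
        t, p = paired_ttest([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert (t, p) == (0.0, 1.0)

    def test_hand_formula_oracle(self):
        a = np.array([0.5, 0.6, 0.7, 0.8])
        b = np.array([0.4, 0.5, 0.65, 0.7])
        d = a - b
        t_expect = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        t, p = paired_ttest(a, b)
        assert t == pytest.approx(t_expect)
        assert 0 < p < 1

    def test_sign_flip_negates_t(self, rng):
        a = rng.normal(size=6)
        b = rng.normal(size=6)
        t1, p1 = paired_ttest(a, b)
        t2, p2 = paired_ttest(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_constant_nonzero_difference_flagged(self):
        t, p = paired_ttest([1.0, 2.0], [0.5, 1.5])
        assert np.isinf(t) and t > 0 and p == 0.0
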