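import itertools

import numpy as np
import pytest
import scipy.sparse as sp

from stripehic.coaccess import (CellByBinMatrix, MetacellAssignment,
                                binarize_cells, build_metacells,
                                jaccard_coaccessibility, lsi_embedding,
                                metacell_profiles, subsample_for_augmentation)
from stripehic.io_formats import FragmentRecord, GenomeLayout
from stripehic.tracks import CellSet


def jaccard_oracle(profiles: np.ndarray, center, window) -> np.ndarray:
    """Brute-force set-based Jaccard (the independent reference)."""
    out = np.zeros((len(center), len(window)))
    cols = {b: set(np.nonzero(profiles[:, b])[0].tolist())
            for b in set(center) | set(w for w in window if w >= 0)}
    for a, i in enumerate(center):
        for b, j in enumerate(window):
            if j < 0:
                continue
            si, sj = cols[i], cols[j]
            union = si | sj
            out[a, b] = len(si & sj) / len(union) if union else 0.0
    return out


@pytest.fixture
def layout():
    return GenomeLayout(["chr1"], [10_000])


class TestBinarize:
    def test_multiple_insertions_binarized(self, layout):
        cells = CellSet(["a"], {"a": 5})
        frags = [FragmentRecord("chr1", 100, 140, "a", 1)] * 5
        m = binarize_cells(frags, cells, layout, "chr1")
        assert m.matrix[0, 0] == 1
        assert m.matrix.max() == 1

    def test_empty_cell_row_retained(self, layout):
        cells = CellSet(["a", "b"], {"a": 1, "b": 0})
        frags = [FragmentRecord("chr1", 100, 140, "a", 1)]
        m = binarize_cells(frags, cells, layout, "chr1")
        assert m.n_cells == 2
        assert m.matrix[1].nnz == 0

    def test_density_counts_distinct_pairs(self, layout, rng):
        cells = CellSet(["a", "b", "c"], {"a": 1, "b": 1, "c": 1})
        pairs = set()
        frags = []
        for _ in range(40):
            c = rng.choice(["a", "b", "c"])
            s = int(rng.integers(0, 9500) // 500 * 500) + 10
            frags.append(FragmentRecord("chr1", s, s + 100, str(c), 1))
            pairs.add((str(c), s // 500))
        m = binarize_cells(frags, cells, layout, "chr1")
        assert m.matrix.nnz == len(pairs)


class TestLsiEmbedding:
    def test_identical_cells_identical_rows(self):
        X = sp.csr_matrix(np.array([[1, 0, 1]] * 2 + [[0, 1, 0]] * 3))
        emb = lsi_embedding(X, n_components=2, seed=0)
        np.testing.assert_allclose(emb[0], emb[1], atol=1e-9)

    def test_orthogonal_cells_separated(self):
        X = sp.csr_matrix(np.array([[1, 0]] * 3 + [[0, 1]] * 3))
        emb = lsi_embedding(X, n_components=1, seed=0)
        within = abs(emb[0, 0] - emb[1, 0])
        between = abs(emb[0, 0] - emb[3, 0])
        assert between > 10 * max(within, 1e-12)

    def test_rank_k_reconstruction_matches_dense_svd(self, rng):
        X = rng.random((8, 6))
        Xs = sp.csr_matrix(X)
        emb = lsi_embedding(Xs, n_components=3, seed=0)
        # oracle: dense SVD of the same TF-IDF matrix
        tf = X / X.sum(axis=1, keepdims=True)
        idf = np.log1p(X.shape[0] / np.maximum((X > 0).sum(axis=0), 1))
        tfidf = tf * idf
        u, s, _ = np.linalg.svd(tfidf, full_matrices=False)
        oracle = np.abs(u[:, :3] * s[:3])
        np.testing.assert_allclose(np.abs(emb), oracle, atol=1e-8)

    def test_too_few_cells_raises(self):
        with pytest.raises(ValueError):
            lsi_embedding(sp.eye(3, format="csr"), n_components=3)


def _two_blob_embedding(k, rng):
    a = rng.normal(0, 0.01, size=(k, 2))
    b = rng.normal(100, 0.01, size=(k, 2))
    return np.vstack([a, b])


class TestBuildMetacells:
    def test_disjoint_limit(self, rng):
        k = 10
        emb = _two_blob_embedding(k, rng)
        mc = build_metacells(emb, k=k, overlap_cap=0.0, seed=0)
        assert mc.n_metacells == 2
        assert set(mc.members[0].tolist()).isdisjoint(mc.members[1].tolist())

    def test_no_constraint_gives_one_per_cell(self, rng):
        emb = rng.normal(size=(30, 3))
        mc = build_metacells(emb, k=5, overlap_cap=1.0, seed=0)
        assert mc.n_metacells == 30

    def test_all_pairs_satisfy_cap_exhaustively(self, rng):
        emb = rng.normal(size=(60, 4))
        k, cap = 8, 0.5
        mc = build_metacells(emb, k=k, overlap_cap=cap, seed=1)
        for a, b in itertools.combinations(mc.members, 2):
            shared = len(set(a.tolist()) & set(b.tolist())) / k
            assert shared <= cap

    def test_k_exceeding_cells_raises(self, rng):
        with pytest.raises(ValueError):
            build_metacells(rng.normal(size=(5, 2)), k=6)

    def test_every_set_has_exactly_k_members(self, rng):
        mc = build_metacells(rng.normal(size=(40, 3)), k=7, seed=2)
        assert all(len(m) == 7 for m in mc.members)


class TestMetacellProfiles:
    def test_or_aggregation(self):
        X = sp.csr_matrix(np.array([[1, 0], [0, 0], [0, 0]], dtype=np.int8))
        mc = MetacellAssignment([np.array([0, 1, 2])], k=3, overlap_cap=1.0)
        prof = metacell_profiles(X, mc)
        assert prof[0, 0] == 1 and prof[0, 1] == 0

    def test_rows_equal_bitwise_or_oracle(self, rng):
        X = sp.csr_matrix((rng.random((20, 15)) < 0.3).astype(np.int8))
        members = [rng.choice(20, size=6, replace=False) for _ in range(5)]
        mc = MetacellAssignment(members, k=6, overlap_cap=1.0)
        prof = metacell_profiles(X, mc).toarray()
        dense = X.toarray()
        for m, cells in enumerate(members):
            oracle = np.bitwise_or.reduce(dense[cells], axis=0)
            np.testing.assert_array_equal(prof[m], oracle)


class TestJaccard:
    def test_worked_example(self):
        profiles = sp.csr_matrix(np.array([[1, 1], [0, 1], [1, 0], [1, 1]]))
        J = jaccard_coaccessibility(profiles, [0], [1])
        assert J[0, 0] == pytest.approx(2 / 4)

    def test_identical_nonzero_profiles(self):
        profiles = sp.csr_matrix(np.array([[1, 1], [0, 0], [1, 1]]))
        J = jaccard_coaccessibility(profiles, [0], [0, 1])
        np.testing.assert_allclose(J, [[1.0, 1.0]])

    def test_silent_bins_give_zero(self):
        profiles = sp.csr_matrix(np.zeros((4, 3)))
        J = jaccard_coaccessibility(profiles, [0], [1, 2])
        np.testing.assert_array_equal(J, 0.0)

    def test_matches_brute_force_on_random_matrix(self, rng):
        profiles = (rng.random((30, 200)) < 0.2).astype(np.int8)
        center = rng.choice(200, size=10, replace=False)
        window = rng.choice(200, size=50, replace=False)
        J = jaccard_coaccessibility(sp.csr_matrix(profiles), center, window)
        np.testing.assert_allclose(J, jaccard_oracle(profiles, center, window))

    def test_symmetry_and_bounds(self, rng):
        profiles = (rng.random((25, 40)) < 0.3).astype(np.int8)
        P = sp.csr_matrix(profiles)
        bins = np.arange(40)
        J = jaccard_coaccessibility(P, bins, bins)
        assert J.min() >= 0 and J.max() <= 1
        np.testing.assert_allclose(J, J.T)

    def test_metacell_permutation_invariance(self, rng):
        profiles = (rng.random((20, 30)) < 0.3).astype(np.int8)
        perm = rng.permutation(20)
        J1 = jaccard_coaccessibility(sp.csr_matrix(profiles),
                                     np.arange(5), np.arange(30))
        J2 = jaccard_coaccessibility(sp.csr_matrix(profiles[perm]),
                                     np.arange(5), np.arange(30))
        np.testing.assert_allclose(J1, J2)


class TestSubsample:
    def test_size_within_range(self, rng):
        idx = subsample_for_augmentation(10_000, (500, 5000), rng)
        assert 500 <= idx.size <= 5000
        assert np.unique(idx).size == idx.size

    def test_fixed_seed_reproducible(self):
        a = subsample_for_augmentation(100, (10, 50), np.random.default_rng(9))
        b = subsample_for_augmentation(100, (10, 50), np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)

    def test_degenerate_range(self, rng):
        assert subsample_for_augmentation(100, (7, 7), rng).size == 7

    def test_small_population_sampled_with_replacement(self, rng):
        idx = subsample_for_augmentation(5, (10, 20), rng)
        assert idx.size == 10

    def test_empty_population_raises(self, rng):
        with pytest.raises(ValueError):
            subsample_for_augmentation(0, (1, 2), rng)


def test_anchor_pairs_enriched_over_background(micro_sim, micro_dataset):
    """Mean Jaccard at planted anchors exceeds distance-matched background."""
    cfg, bundle = micro_sim
    ds = micro_dataset
    per = cfg.hic_resolution // cfg.coacc_resolution
    prof = ds.profiles["chr1"]
    n500 = prof.shape[1]
    anchor_j, bg_j = [], []
    anchors = {b for l in bundle.genome.loops if l.chrom == "chr1"
               for b in (l.bin_i, l.bin_j)}
    for loop in bundle.genome.loops:
        if loop.chrom != "chr1":
            continue
        bi = loop.bin_i * per + per // 2
        bj = loop.bin_j * per + per // 2
        anchor_j.append(jaccard_coaccessibility(prof, [bi], [bj])[0, 0])
        # distance-matched non-anchor pair
        off = 7 * per
        if bj + off < n500 and (loop.bin_j + 7) not in anchors \
                and (loop.bin_i + 7) not in anchors:
            bg_j.append(jaccard_coaccessibility(
                prof, [bi + off], [bj + off])[0, 0])
    assert np.mean(anchor_j) > np.mean(bg_j)
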