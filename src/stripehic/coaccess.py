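"""Metacell construction and Jaccard co-accessibility slices."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import TruncatedSVD
from sklearn.neighbors import NearestNeighbors


@dataclass
class CellByBinMatrix:
    """Sparse binary cells x 500bp-bins accessibility, one chromosome or
    genome-wide."""

    matrix: sp.csr_matrix
    barcodes: list[str]
    resolution: int = 500
    chrom: str | None = None

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[1]


def binarize_cells(fragments, cells, layout, chrom: str,
                   resolution: int = 500) -> CellByBinMatrix:
    """Entry (c, b) = 1 iff cell ``c`` has >= 1 insertion in bin ``b``.

    Both fragment endpoints count as insertions, matching the pseudobulk
    convention.
    """
    barcodes = list(cells.barcodes) if cells is not None else None
    if barcodes is None:
        seen = []
        seen_set = set()
        frs = []
        for fr in fragments:
            frs.append(fr)
            if fr.barcode not in seen_set:
                seen_set.add(fr.barcode)
                seen.append(fr.barcode)
        barcodes = seen
        fragments = frs
    bc_index = {b: i for i, b in enumerate(barcodes)}
    n_bins = layout.bin_count(chrom, resolution)
    rows, cols = [], []
    for fr in fragments:
        if fr.chrom != chrom or fr.barcode not in bc_index:
            continue
        c = bc_index[fr.barcode]
        rows.extend((c, c))
        cols.extend((fr.start // resolution, (fr.end - 1) // resolution))
    data = np.ones(len(rows), dtype=np.int8)
    m = sp.csr_matrix((data, (rows, cols)), shape=(len(barcodes), n_bins))
    m.data[:] = 1  # collapse duplicate insertions
    m.sum_duplicates()
    m.data[:] = 1
    return CellByBinMatrix(matrix=m, barcodes=barcodes, resolution=resolution,
                           chrom=chrom)


def lsi_embedding(cell_by_tile: sp.spmatrix, n_components: int = 30,
                  seed: int = 0) -> np.ndarray:
    """TF-IDF then truncated SVD — a lightweight LSI stand-in.

    Deterministic for a given seed; degenerate rank yields fewer components
    with a warning.
    """
    X = sp.csr_matrix(cell_by_tile, dtype=float)
    if X.shape[0] < n_components + 1:
        raise ValueError("need at least n_components + 1 cells")
    tf = X.multiply(1.0 / np.maximum(X.sum(axis=1), 1))
    df = np.asarray((X > 0).sum(axis=0)).ravel()
    idf = np.log1p(X.shape[0] / np.maximum(df, 1))
    tfidf = sp.csr_matrix(tf.multiply(idf))
    max_rank = min(tfidf.shape) - 1
    k = min(n_components, max_rank)
    if k < n_components:
        import warnings

        warnings.warn(f"rank-deficient input: using {k} components")
    svd = TruncatedSVD(n_components=k, random_state=seed)
    return svd.fit_transform(tfidf)


@dataclass
class MetacellAssignment:
    """Overlapping kNN cell groups (Cicero-style aggregation)."""

    members: list[np.ndarray]
    k: int
    overlap_cap: float

    @property
    def n_metacells(self) -> int:
        return len(self.members)


def build_metacells(embedding: np.ndarray, k: int = 50,
                    overlap_cap: float = 0.76,
                    seed: int = 0) -> MetacellAssignment:
    """Greedy kNN grouping: visit seed cells in random order, take each
    seed's k-nearest-neighbor set (including itself), and accept it iff its
    shared-member fraction with every accepted set is <= ``overlap_cap``.
    """
    n = embedding.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds n_cells={n}")
    nn = NearestNeighbors(n_neighbors=k).fit(embedding)
    _, knn = nn.kneighbors(embedding)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    accepted: list[np.ndarray] = []
    accepted_sets: list[set[int]] = []
    for seed_cell in order:
        cand = np.sort(knn[seed_cell])
        cand_set = set(cand.tolist())
        ok = all(len(cand_set & s) / k <= overlap_cap for s in accepted_sets)
        if ok:
            accepted.append(cand)
            accepted_sets.append(cand_set)
    return MetacellAssignment(members=accepted, k=k, overlap_cap=overlap_cap)


def metacell_profiles(cell_by_bin: CellByBinMatrix | sp.spmatrix,
                      assignment: MetacellAssignment) -> sp.csr_matrix:
    """Binary metacell x bin matrix: OR over member cells."""
    X = cell_by_bin.matrix if isinstance(cell_by_bin, CellByBinMatrix) \
        else sp.csr_matrix(cell_by_bin)
    rows = []
    for members in assignment.members:
        agg = X[members].sum(axis=0)
        rows.append(sp.csr_matrix((np.asarray(agg) > 0).astype(np.int8)))
    return sp.vstack(rows).tocsr()


def jaccard_coaccessibility(profiles: sp.spmatrix, center_bins,
                            window_bins) -> np.ndarray:
    """Jaccard similarity between center bins and window bins across metacells.

    ``J(i, j) = |m: p(m,i)=1 and p(m,j)=1| / |m: p(m,i)=1 or p(m,j)=1|``,
    with 0/0 defined as 0. Window-bin indices of -1 denote positions outside
    the chromosome and produce zero columns.
    """
    P = sp.csr_matrix(profiles, dtype=float)
    center_bins = np.asarray(center_bins, dtype=int)
    window_bins = np.asarray(window_bins, dtype=int)
    valid = window_bins >= 0
    wb = window_bins[valid]
    C = P[:, center_bins]            # m x nc
    W = P[:, wb]                     # m x nw_valid
    inter = np.asarray((C.T @ W).todense())
    nc = np.asarray(C.sum(axis=0)).ravel()
    nw = np.asarray(W.sum(axis=0)).ravel()
    union = nc[:, None] + nw[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        J = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    out = np.zeros((center_bins.size, window_bins.size))
    out[:, valid] = J
    return out


def subsample_for_augmentation(n_items: int, n_range: tuple[int, int],
                               rng: np.random.Generator) -> np.ndarray:
    """Uniform random subset of size n ~ Uniform[n_range].

    Populations smaller than the lower bound are sampled with replacement up
    to the lower bound so augmentation never starves.
    """
    if n_items == 0:
        raise ValueError("empty population")
    lo, hi = n_range
    if lo > hi:
        raise ValueError("invalid range")
    n = int(rng.integers(lo, hi + 1))
    if n_items < lo:
        return rng.choice(n_items, size=lo, replace=True)
    n = min(n, n_items)
    return rng.choice(n_items, size=n, replace=False)
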