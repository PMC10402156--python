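"""Synthetic paired scATAC + contact-map generator with planted loop structure.

Cells carry cluster-specific loops whose two anchors open together (latent
Bernoulli coupling), producing Jaccard co-accessibility enrichment at anchor
pairs; contact counts follow a distance-decay baseline with a multiplicative
enhancement at the same anchors. Decoy anchor pairs are equally accessible
but open independently and carry no contact enrichment, so co-accessibility
(not marginal accessibility) is the informative signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .hic import ContactMap
from .io_formats import GenomeLayout


@dataclass(frozen=True)
class SimConfig:
    chrom_length: int = 5_000_000
    n_chroms: int = 3
    n_cells: int = 800
    n_clusters: int = 2
    n_loops: int = 30          # per chromosome, split across clusters
    n_decoys: int = 0          # accessible-but-uncoupled anchor pairs
    p_anchor: float = 0.25
    p_bg: float = 0.02
    theta: float = 0.4         # loop latent on-probability
    c: float = 0.8             # P(both anchors open | loop on)
    anchor_span_bins: int = 1  # 500bp sub-bins opening jointly per anchor
    decay_amplitude: float = 100.0   # A in mu(d) = A * (d + d0)^(-alpha)
    decay_offset_bins: int = 1       # d0, in 10kb bins
    decay_exponent: float = 1.0      # alpha
    beta: float = 5.0          # loop contact enhancement factor
    nb_dispersion: float | None = None  # None = Poisson counts
    hic_resolution: int = 10_000
    coacc_resolution: int = 500
    min_loop_dist_bp: int = 50_000
    max_loop_dist_bp: int = 2_000_000

    def __post_init__(self) -> None:
        for p in (self.p_anchor, self.p_bg, self.theta, self.c):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    @property
    def anchor_marginal_rate(self) -> float:
        """Marginal open-probability of a loop anchor (decoys match it)."""
        t, c, p = self.theta, self.c, self.p_anchor
        return t * (c + (1 - c) * p) + (1 - t) * p


@dataclass(frozen=True)
class Loop:
    chrom: str
    bin_i: int
    bin_j: int
    cluster: int  # -1 marks a decoy pair


@dataclass
class SimGenome:
    config: SimConfig
    layout: GenomeLayout
    loops: list[Loop]
    decoys: list[Loop]
    cell_clusters: np.ndarray = field(repr=False)

    def loops_of(self, chrom: str, cluster: int | None = None) -> list[Loop]:
        return [l for l in self.loops
                if l.chrom == chrom and (cluster is None or l.cluster == cluster)]


def _anchor_coacc_bin(bin_10kb: int, config: SimConfig) -> int:
    """The designated 500bp bin of a 10kb anchor (its center sub-bin)."""
    per = config.hic_resolution // config.coacc_resolution
    return bin_10kb * per + per // 2


def _anchor_coacc_bins(bin_10kb: int, config: SimConfig) -> np.ndarray:
    """All 500bp sub-bins of an anchor (anchor_span_bins wide, centered)."""
    per = config.hic_resolution // config.coacc_resolution
    start = bin_10kb * per + per // 2 - config.anchor_span_bins // 2
    return np.arange(start, start + config.anchor_span_bins)


def simulate_genome(config: SimConfig, seed: int) -> SimGenome:
    """Place loop/decoy anchors on 10kb bins with distances in
    [min_loop_dist, max_loop_dist]; assign cells to clusters uniformly."""
    rng = np.random.default_rng(seed)
    names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    layout = GenomeLayout(names, [config.chrom_length] * config.n_chroms)
    res = config.hic_resolution
    n_bins = config.chrom_length // res
    d_lo = config.min_loop_dist_bp // res
    d_hi = config.max_loop_dist_bp // res
    if d_hi < d_lo or n_bins <= d_lo + 1:
        raise ValueError("infeasible loop-distance range for chromosome length")

    def place(n: int, used: set[int], tag_clusters) -> list[Loop]:
        out = []
        for idx in range(n):
            for _ in range(1000):
                d = int(rng.integers(d_lo, min(d_hi, n_bins - 1) + 1))
                i = int(rng.integers(0, n_bins - d))
                j = i + d
                if i not in used and j not in used:
                    used.add(i)
                    used.add(j)
                    out.append(Loop(chrom, i, j, tag_clusters(idx)))
                    break
            else:
                raise RuntimeError("could not place anchors without collisions")
        return out

    loops: list[Loop] = []
    decoys: list[Loop] = []
    for chrom in names:
        used: set[int] = set()
        loops += place(config.n_loops, used,
                       lambda idx: idx % config.n_clusters)
        decoys += place(config.n_decoys, used, lambda idx: -1)
    cell_clusters = rng.integers(0, config.n_clusters, size=config.n_cells)
    return SimGenome(config=config, layout=layout, loops=loops, decoys=decoys,
                     cell_clusters=cell_clusters)


def simulate_scatac(sim: SimGenome, seed: int
                    ) -> tuple[pd.DataFrame, dict[str, sp.csr_matrix]]:
    """Per-cell binary 500bp accessibility plus a matching fragments table.

    Background bins open ~ Bernoulli(p_bg). For each loop of the cell's
    cluster a latent state ~ Bernoulli(theta) is drawn: when on, both anchors
    open jointly with probability ``c`` (else independently with p_anchor);
    when off, anchors open independently with p_anchor. Decoy anchors open
    independently at the loop anchors' marginal rate in every cell. One
    fragment is synthesized inside each open 500bp bin.
    """
    cfg = sim.config
    rng = np.random.default_rng(seed)
    n_cells = cfg.n_cells
    res = cfg.coacc_resolution
    matrices: dict[str, sp.csr_matrix] = {}
    frag_rows: list[pd.DataFrame] = []
    barcodes = [f"cell{i:05d}" for i in range(n_cells)]
    q = cfg.anchor_marginal_rate
    for chrom in sim.layout.chrom_names:
        n_bins = sim.layout.bin_count(chrom, res)
        open_mat = rng.random((n_cells, n_bins)) < cfg.p_bg
        for loop in sim.loops_of(chrom):
            cells = np.nonzero(sim.cell_clusters == loop.cluster)[0]
            bi = _anchor_coacc_bins(loop.bin_i, cfg)
            bj = _anchor_coacc_bins(loop.bin_j, cfg)
            on = rng.random(cells.size) < cfg.theta
            joint = on & (rng.random(cells.size) < cfg.c)
            indep_i = rng.random(cells.size) < cfg.p_anchor
            indep_j = rng.random(cells.size) < cfg.p_anchor
            open_i = joint | (~joint & indep_i)
            open_j = joint | (~joint & indep_j)
            open_mat[np.ix_(cells, bi)] |= open_i[:, None]
            open_mat[np.ix_(cells, bj)] |= open_j[:, None]
        for decoy in (d for d in sim.decoys if d.chrom == chrom):
            for b10 in (decoy.bin_i, decoy.bin_j):
                bb = _anchor_coacc_bins(b10, cfg)
                open_mat[:, bb] |= (rng.random(n_cells) < q)[:, None]
        cells_idx, bins_idx = np.nonzero(open_mat)
        starts = bins_idx * res + rng.integers(0, res - 100,
                                               size=bins_idx.size)
        lengths = rng.integers(30, 100, size=bins_idx.size)
        frag_rows.append(pd.DataFrame({
            "chrom": chrom,
            "start": starts,
            "end": starts + lengths,
            "barcode": np.asarray(barcodes, dtype=object)[cells_idx],
            "count": 1,
        }))
        matrices[chrom] = sp.csr_matrix(open_mat.astype(np.int8))
    frag_df = pd.concat(frag_rows, ignore_index=True)
    return frag_df, matrices


def expected_contacts(sim: SimGenome, chrom: str,
                      cluster_weights) -> np.ndarray:
    """Noise-free expected count matrix for one chromosome under a cluster
    mixture: e(i,j) = mu(|i-j|) * (1 + (beta-1) * sum_k w_k [loop_k at (i,j)]).
    """
    cfg = sim.config
    n = sim.layout.bin_count(chrom, cfg.hic_resolution)
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    mu = cfg.decay_amplitude * np.power(
        d + cfg.decay_offset_bins, -cfg.decay_exponent)
    enh = np.ones((n, n))
    w = np.asarray(cluster_weights, dtype=float)
    if not np.isclose(w.sum(), 1.0):
        raise ValueError("cluster weights must sum to 1")
    for loop in sim.loops_of(chrom):
        boost = (cfg.beta - 1.0) * w[loop.cluster]
        enh[loop.bin_i, loop.bin_j] += boost
        enh[loop.bin_j, loop.bin_i] += boost
    return mu * enh


def simulate_contacts(sim: SimGenome, cluster_weights, seed: int,
                      max_distance_bp: int | None = None
                      ) -> dict[str, ContactMap]:
    """Sample per-chromosome contact counts (Poisson, or negative binomial
    when ``nb_dispersion`` is set) around the expected mixture map."""
    cfg = sim.config
    rng = np.random.default_rng(seed)
    max_d_bp = max_distance_bp or cfg.max_loop_dist_bp
    max_d = max_d_bp // cfg.hic_resolution
    out: dict[str, ContactMap] = {}
    for chrom in sim.layout.chrom_names:
        e = expected_contacts(sim, chrom, cluster_weights)
        n = e.shape[0]
        cm = ContactMap(chrom, n, cfg.hic_resolution)
        for dd in range(min(max_d, n - 1) + 1):
            i = np.arange(0, n - dd)
            mean = e[i, i + dd]
            if cfg.nb_dispersion is None:
                counts = rng.poisson(mean)
            else:
                r = cfg.nb_dispersion
                counts = rng.negative_binomial(r, r / (r + mean))
            nz = counts > 0
            for ii, cval in zip(i[nz].tolist(), counts[nz].tolist()):
                cm.set(ii, ii + dd, float(cval))
        out[chrom] = cm
    return out


def ground_truth_labels(sim: SimGenome, cluster: int | None = None
                        ) -> dict[str, set[tuple[int, int]]]:
    """Planted loop bin pairs per chromosome (optionally one cluster)."""
    out: dict[str, set[tuple[int, int]]] = {c: set()
                                            for c in sim.layout.chrom_names}
    for loop in sim.loops:
        if cluster is None or loop.cluster == cluster:
            out[loop.chrom].add((loop.bin_i, loop.bin_j))
    return out


def synthetic_ctcf_tracks(sim: SimGenome, seed: int,
                          acc_resolution: int = 50) -> dict[str, np.ndarray]:
    """Sparse positive motif-score-like track with peaks at all anchors."""
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    per = sim.config.hic_resolution // acc_resolution
    for chrom in sim.layout.chrom_names:
        n = sim.layout.bin_count(chrom, acc_resolution)
        track = np.zeros(n)
        bg = rng.random(n) < 0.001
        track[bg] = rng.uniform(1.0, 6.0, size=int(bg.sum()))
        for loop in sim.loops + sim.decoys:
            if loop.chrom != chrom:
                continue
            for b10 in (loop.bin_i, loop.bin_j):
                pos = b10 * per + per // 2
                if pos < n:
                    track[pos] = rng.uniform(5.0, 12.0)
        out[chrom] = track
    return out


@dataclass
class SimBundle:
    """Everything one simulation run produces."""

    genome: SimGenome
    fragments: pd.DataFrame
    cell_by_bin: dict[str, sp.csr_matrix]
    contacts_bulk: dict[str, ContactMap]
    contacts_by_cluster: dict[int, dict[str, ContactMap]]
    ctcf: dict[str, np.ndarray]


def simulate(config: SimConfig, seed: int,
             cluster_weights=None) -> SimBundle:
    """Run the full generator with deterministic per-stage substreams."""
    genome = simulate_genome(config, seed)
    frag_df, mats = simulate_scatac(genome, seed + 1)
    if cluster_weights is None:
        counts = np.bincount(genome.cell_clusters,
                             minlength=config.n_clusters)
        cluster_weights = counts / counts.sum()
    bulk = simulate_contacts(genome, cluster_weights, seed + 2)
    by_cluster = {}
    for k in range(config.n_clusters):
        w = np.zeros(config.n_clusters)
        w[k] = 1.0
        by_cluster[k] = simulate_contacts(genome, w, seed + 3 + k)
    ctcf = synthetic_ctcf_tracks(genome, seed + 100)
    return SimBundle(genome=genome, fragments=frag_df, cell_by_bin=mats,
                     contacts_bulk=bulk, contacts_by_cluster=by_cluster,
                     ctcf=ctcf)
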