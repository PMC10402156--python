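"""Input tracks: pseudobulk accessibility and CTCF motif/ChIP score at 50bp."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import ModelGeometry
from .io_formats import GenomeLayout, bedgraph_to_track


@dataclass
class CellSet:
    """Barcodes passing QC with their genome-wide fragment totals."""

    barcodes: list[str]
    fragment_totals: dict[str, int]
    tss_scores: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self._index = set(self.barcodes)

    def __contains__(self, barcode: str) -> bool:
        return barcode in self._index

    def __len__(self) -> int:
        return len(self.barcodes)


def filter_cells(barcode_stats: pd.DataFrame, min_fragments: int = 1000,
                 min_tss: float | None = 4.0) -> CellSet:
    """QC filter: drop barcodes with fewer than ``min_fragments`` fragments
    or TSS enrichment below ``min_tss`` (both thresholds are strict: a
    barcode at exactly the threshold is kept).

    ``barcode_stats`` needs columns ``barcode`` and ``n_fragments``; a
    ``tss`` column is used only when present and ``min_tss`` is not None.
    """
    df = barcode_stats
    keep = df["n_fragments"] >= min_fragments
    n_frag_fail = int((~keep).sum())
    n_tss_fail = 0
    if min_tss is not None and "tss" in df.columns:
        tss_ok = df["tss"] >= min_tss
        n_tss_fail = int((~tss_ok).sum())
        keep &= tss_ok
    kept = df[keep]
    if len(kept) == 0:
        raise ValueError(
            f"no cells pass QC ({n_frag_fail} failed fragment filter, "
            f"{n_tss_fail} failed TSS filter)")
    tss = None
    if "tss" in df.columns:
        tss = dict(zip(kept["barcode"], kept["tss"]))
    return CellSet(
        barcodes=list(kept["barcode"]),
        fragment_totals=dict(zip(kept["barcode"], kept["n_fragments"])),
        tss_scores=tss,
    )


@dataclass
class PseudobulkTrack:
    chrom: str
    resolution: int
    values: np.ndarray = field(repr=False)
    n_cells_used: int = 0
    library_size: float = 0.0


def insertion_counts(fragments, cells: CellSet | None, layout: GenomeLayout,
                     chrom: str, resolution: int = 50) -> np.ndarray:
    """Raw per-bin Tn5 insertion counts on one chromosome.

    Each fragment contributes its two endpoints (start and end-1), weighted
    by the record's count; fragments from barcodes outside ``cells`` are
    ignored.
    """
    n = layout.bin_count(chrom, resolution)
    raw = np.zeros(n)
    for fr in fragments:
        if fr.chrom != chrom:
            continue
        if cells is not None and fr.barcode not in cells:
            continue
        raw[fr.start // resolution] += fr.count
        raw[(fr.end - 1) // resolution] += fr.count
    return raw


def pseudobulk_accessibility(fragments, cells: CellSet | None,
                             layout: GenomeLayout, chrom: str,
                             scale: float = 1e8,
                             resolution: int = 50) -> PseudobulkTrack:
    """Aggregate, library-size normalize, and log1p-transform accessibility.

    ``value = log1p(raw * scale / library_size)`` where ``library_size`` is
    the genome-wide insertion total of the retained cells, making the track
    invariant to uniform sequencing-depth changes.
    """
    fragments = list(fragments)
    per_chrom = {}
    library = 0.0
    for c in layout.chrom_names:
        raw = insertion_counts(fragments, cells, layout, c, resolution)
        library += raw.sum()
        if c == chrom:
            per_chrom[c] = raw
    if library == 0:
        raise ValueError("library size is zero: no insertions from retained cells")
    values = np.log1p(per_chrom[chrom] * scale / library)
    return PseudobulkTrack(chrom=chrom, resolution=resolution, values=values,
                           n_cells_used=len(cells) if cells is not None else 0,
                           library_size=library)


def normalize_track(raw: np.ndarray, library_size: float,
                    scale: float = 1e8) -> np.ndarray:
    """log1p(raw * scale / library_size); shared by dataset builders."""
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return np.log1p(np.asarray(raw, dtype=float) * scale / library_size)


@dataclass(frozen=True)
class MotifHit:
    chrom: str
    start: int
    end: int
    strand: str
    score: float


_COMP = str.maketrans("ACGTN", "TGCAN")
_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _pwm_log_odds(pwm: np.ndarray, background: float = 0.25) -> np.ndarray:
    pwm = np.asarray(pwm, dtype=float)
    if pwm.shape[1] != 4:
        pwm = pwm.T
    if pwm.shape[1] != 4:
        raise ValueError("PWM must have 4 columns (A,C,G,T)")
    if (pwm == 0).any():
        # zero probabilities would give -inf log-odds; add a flat pseudocount
        pwm = pwm + 0.25
        pwm = pwm / pwm.sum(axis=1, keepdims=True)
    return np.log2(pwm / background)


def scan_ctcf_motifs(sequence: str, pwms, chrom: str = "",
                     background: float = 0.25) -> list[MotifHit]:
    """Scan both strands with log2-odds PWMs; keep per-position best hit > 0.

    Windows containing N are skipped. At each start position the maximum
    score over all PWMs and both strands is retained, and only positive
    log-odds hits are reported.
    """
    seq = sequence.upper()
    rc = seq.translate(_COMP)[::-1]
    n = len(seq)
    best_score = np.full(n, -np.inf)
    best_meta: dict[int, tuple[int, str]] = {}  # pos -> (width, strand)
    for pwm in pwms:
        lo = _pwm_log_odds(pwm, background)
        w = lo.shape[0]
        if w > n:
            continue
        for strand, s in (("+", seq), ("-", rc)):
            codes = np.frombuffer(s.encode(), dtype=np.uint8)
            idx = np.full(n, -1, dtype=int)
            for b, k in _BASE_IDX.items():
                idx[codes == ord(b)] = k
            valid = idx >= 0
            n_win = n - w + 1
            scores = np.zeros(n_win)
            ok = np.ones(n_win, dtype=bool)
            for off in range(w):
                sl = idx[off: off + n_win]
                ok &= valid[off: off + n_win]
                scores += lo[off, np.where(sl >= 0, sl, 0)]
            for p in np.nonzero(ok)[0]:
                # map reverse-strand window back to forward coordinates
                fwd = p if strand == "+" else n - w - p
                if scores[p] > best_score[fwd]:
                    best_score[fwd] = scores[p]
                    best_meta[fwd] = (w, strand)
    hits = []
    for pos in sorted(best_meta):
        if best_score[pos] <= 0:
            continue
        w, strand = best_meta[pos]
        hits.append(MotifHit(chrom, pos, pos + w, strand, float(best_score[pos])))
    return hits


@dataclass
class MotifScoreTrack:
    chrom: str
    resolution: int
    values: np.ndarray = field(repr=False)
    source: str = "motif"


def motif_track_from_hits(hits, layout: GenomeLayout, chrom: str,
                          min_overlap: int = 10,
                          resolution: int = 50) -> MotifScoreTrack:
    """Per-bin max hit score among hits overlapping the bin by >= 10bp."""
    n = layout.bin_count(chrom, resolution)
    values = np.zeros(n)
    for h in hits:
        if h.chrom and h.chrom != chrom:
            continue
        b0 = h.start // resolution
        b1 = (h.end - 1) // resolution
        for b in range(max(b0, 0), min(b1, n - 1) + 1):
            lo = max(h.start, b * resolution)
            hi = min(h.end, (b + 1) * resolution)
            if hi - lo >= min_overlap and h.score > values[b]:
                values[b] = h.score
    return MotifScoreTrack(chrom=chrom, resolution=resolution, values=values,
                           source="motif")


def chip_track_from_bedgraph(path, layout: GenomeLayout, chrom: str,
                             resolution: int = 50) -> MotifScoreTrack:
    """CTCF ChIP signal as per-50bp-bin length-weighted means."""
    values = bedgraph_to_track(path, layout, chrom, resolution)
    return MotifScoreTrack(chrom=chrom, resolution=resolution, values=values,
                           source="chip")


def extract_window(values: np.ndarray, center_hic_bin: int,
                   geometry: ModelGeometry, resolution: int,
                   n_bins_chrom: int | None = None,
                   shift_bins: int = 0) -> np.ndarray:
    """Fixed-length window of a per-bin track centered on one contact-map bin.

    Positions beyond the chromosome edges are zero-padded. ``shift_bins``
    displaces the window origin (used for ±50bp training augmentation).
    """
    values = np.asarray(values, dtype=float)
    n = values.size if n_bins_chrom is None else n_bins_chrom
    if not 0 <= center_hic_bin:
        raise IndexError("center bin outside chromosome")
    win_len = geometry.window_bp // resolution
    start = geometry.window_start_bp(center_hic_bin) // resolution + shift_bins
    if start >= n or start + win_len <= 0:
        raise IndexError("center bin outside chromosome")
    out = np.zeros(win_len)
    lo = max(start, 0)
    hi = min(start + win_len, values.size)
    if hi > lo:
        out[lo - start: hi - start] = values[lo:hi]
    return out
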