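"""Readers/writers for the text formats the tool touches.

Coordinate conventions: BED/fragments intervals are 0-based half-open;
contact-map bins are addressed by their start coordinate (a multiple of the
map resolution).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from typing import Iterator, TextIO

import numpy as np

from .hic import ContactMap

logger = logging.getLogger(__name__)


class GenomeLayout:
    """Ordered chromosome names and lengths; derives bin counts."""

    def __init__(self, chrom_names, chrom_lengths):
        names = list(chrom_names)
        lengths = [int(x) for x in chrom_lengths]
        if len(names) != len(lengths):
            raise ValueError("names/lengths length mismatch")
        if any(l <= 0 for l in lengths):
            raise ValueError("chromosome lengths must be positive")
        self.chrom_names = names
        self.lengths = dict(zip(names, lengths))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def length(self, chrom: str) -> int:
        return self.lengths[chrom]

    def bin_count(self, chrom: str, resolution: int) -> int:
        return -(-self.lengths[chrom] // resolution)  # ceil division


def read_chrom_sizes(path) -> GenomeLayout:
    """Two-column TSV: chromosome name, length in bp."""
    names, lengths = [], []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            names.append(parts[0])
            lengths.append(int(parts[1]))
    return GenomeLayout(names, lengths)


def write_chrom_sizes(layout: GenomeLayout, path) -> None:
    with open(path, "w") as fh:
        for name in layout.chrom_names:
            fh.write(f"{name}\t{layout.lengths[name]}\n")


@dataclass(frozen=True)
class FragmentRecord:
    chrom: str
    start: int
    end: int
    barcode: str
    count: int = 1


def _open_text(path) -> TextIO:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fragments(path, layout: GenomeLayout) -> Iterator[FragmentRecord]:
    """Stream a 10x-style fragments TSV(.gz): chrom, start, end, barcode[, count].

    Rows on chromosomes absent from ``layout`` are skipped (a skip count is
    logged); malformed coordinates raise with the offending line number.
    """
    skipped = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"line {lineno}: expected >=4 columns")
            chrom = parts[0]
            if chrom not in layout:
                skipped += 1
                continue
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer coordinate") from exc
            count = 1
            if len(parts) >= 5 and parts[4] != "":
                count = int(parts[4])
            if start >= end:
                raise ValueError(f"line {lineno}: start >= end")
            if count <= 0:
                raise ValueError(f"line {lineno}: count must be positive")
            yield FragmentRecord(chrom, start, end, parts[3], count)
    if skipped:
        logger.warning("read_fragments: skipped %d rows on unknown chromosomes",
                       skipped)


def write_fragments(records, path) -> None:
    op = gzip.open if str(path).endswith(".gz") else open
    with op(path, "wt") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.barcode}\t{r.count}\n")


@dataclass(frozen=True)
class PeakInterval:
    chrom: str
    start: int
    end: int
    id: str = ""


def read_peaks(path, merge_gap: int = 500) -> list[PeakInterval]:
    """BED3+ peaks, sorted and transitively merged.

    Peaks on the same chromosome whose gap is <= ``merge_gap`` bp are merged
    (the published convention merges peaks within 500bp of each other).
    """
    raw: list[tuple[str, int, int]] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            raw.append((parts[0], int(parts[1]), int(parts[2])))
    return merge_peaks(raw, merge_gap)


def merge_peaks(intervals, merge_gap: int = 500) -> list[PeakInterval]:
    """Sort then sweep-merge (chrom, start, end) triples."""
    out: list[PeakInterval] = []
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in intervals:
        if s >= e:
            raise ValueError(f"empty interval {chrom}:{s}-{e}")
        by_chrom.setdefault(chrom, []).append((s, e))
    idx = 0
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s - cur_e <= merge_gap:
                cur_e = max(cur_e, e)
            else:
                out.append(PeakInterval(chrom, cur_s, cur_e, f"peak_{idx}"))
                idx += 1
                cur_s, cur_e = s, e
        out.append(PeakInterval(chrom, cur_s, cur_e, f"peak_{idx}"))
        idx += 1
    return out


def write_peaks(peaks, path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.id}\n")


def read_contact_table(path, resolution: int,
                       layout: GenomeLayout) -> dict[str, ContactMap]:
    """Triplet text (chrom, bin1_start, bin2_start, value) -> per-chrom maps.

    Duplicate pairs (including both-triangle dumps) are summed. Bin starts
    must be multiples of ``resolution``.
    """
    maps: dict[str, ContactMap] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, b1, b2, val = line.split("\t")
            if chrom not in layout:
                continue
            b1, b2 = int(b1), int(b2)
            if b1 % resolution or b2 % resolution:
                raise ValueError(
                    f"line {lineno}: bin start not a multiple of {resolution}")
            cm = maps.get(chrom)
            if cm is None:
                cm = ContactMap(chrom, layout.bin_count(chrom, resolution),
                                resolution)
                maps[chrom] = cm
            cm.add(b1 // resolution, b2 // resolution, float(val))
    return maps


def write_contact_table(maps, path) -> None:
    """Write per-chromosome maps as an upper-triangle triplet table."""
    if isinstance(maps, ContactMap):
        maps = {maps.chrom: maps}
    with open(path, "w") as fh:
        for chrom in sorted(maps):
            cm = maps[chrom]
            for (i, j) in sorted(cm._data):
                v = cm._data[(i, j)]
                fh.write(f"{chrom}\t{i * cm.resolution}\t{j * cm.resolution}"
                         f"\t{v!r}\n")


def write_track_bedgraph(values, resolution: int, chrom: str, path,
                         mode: str = "w") -> None:
    """Write a per-bin vector as bedGraph, run-length merging equal values."""
    values = np.asarray(values, dtype=float)
    with open(path, mode) as fh:
        if values.size == 0:
            return
        run_start = 0
        for b in range(1, values.size + 1):
            if b == values.size or values[b] != values[run_start]:
                fh.write(f"{chrom}\t{run_start * resolution}\t{b * resolution}"
                         f"\t{float(values[run_start])!r}\n")
                run_start = b


def read_bedgraph(path, chrom: str | None = None
                  ) -> list[tuple[str, int, int, float]]:
    """Read bedGraph intervals, optionally restricted to one chromosome."""
    out = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            c, s, e, v = line.split("\t")
            if chrom is not None and c != chrom:
                continue
            out.append((c, int(s), int(e), float(v)))
    return out


def bedgraph_to_track(path, layout: GenomeLayout, chrom: str,
                      resolution: int) -> np.ndarray:
    """Per-bin length-weighted mean of bedGraph signal (uncovered bp = 0)."""
    n = layout.bin_count(chrom, resolution)
    acc = np.zeros(n)
    for _, s, e, v in read_bedgraph(path, chrom):
        e = min(e, layout.length(chrom))
        b0, b1 = s // resolution, -(-e // resolution)
        for b in range(b0, min(b1, n)):
            lo, hi = max(s, b * resolution), min(e, (b + 1) * resolution)
            if hi > lo:
                acc[b] += v * (hi - lo)
    return acc / resolution
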