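"""Window-example construction: ties tracks, co-accessibility and targets
together for training and inference."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .coaccess import (MetacellAssignment, build_metacells, lsi_embedding,
                       metacell_profiles, jaccard_coaccessibility)
from .geometry import ModelGeometry
from .hic import ContactMap, VStripeTarget, clip_targets, \
    distance_stratified_zscore, low_signal_mask, target_vstripe
from .io_formats import GenomeLayout
from .tracks import extract_window, normalize_track


@dataclass
class WindowExample:
    """One training/inference example for a window centered at bin ``t``."""

    chrom: str
    t: int
    acc_ctcf: np.ndarray = field(repr=False)   # (2, L0)
    coacc: np.ndarray = field(repr=False)      # (center_coacc_bins, Wc)
    target_right: VStripeTarget | None = None
    target_left: VStripeTarget | None = None


def _per_cell_bin_matrix(frag_df: pd.DataFrame, barcodes: list[str],
                         n_bins: int, resolution: int,
                         binary: bool) -> sp.csr_matrix:
    """Cells x bins matrix of insertion counts (or presence) from fragments."""
    bc_codes = pd.Categorical(frag_df["barcode"], categories=barcodes).codes
    keep = bc_codes >= 0
    starts = frag_df["start"].to_numpy()[keep]
    ends = frag_df["end"].to_numpy()[keep]
    counts = (frag_df["count"].to_numpy()[keep] if "count" in frag_df
              else np.ones(keep.sum(), dtype=int))
    cells = bc_codes[keep]
    rows = np.concatenate([cells, cells])
    cols = np.concatenate([starts // resolution, (ends - 1) // resolution])
    data = np.concatenate([counts, counts]).astype(float)
    m = sp.csr_matrix((data, (rows, cols)), shape=(len(barcodes), n_bins))
    if binary:
        m.data[:] = 1
    return m


class StripeDataset:
    """Precomputed per-chromosome inputs and targets for one cell population.

    Holds per-cell insertion counts at the accessibility resolution, binary
    per-cell 500bp profiles, the CTCF track, the clipped Z-score target map
    and its low-signal mask, plus a fixed metacell assignment; examples are
    assembled on demand (optionally from cell/metacell subsamples).
    """

    def __init__(self, layout: GenomeLayout, geometry: ModelGeometry,
                 barcodes: list[str], acc_scale: float = 1e8):
        self.layout = layout
        self.geometry = geometry
        self.barcodes = list(barcodes)
        self.acc_scale = acc_scale
        self.acc_counts: dict[str, sp.csr_matrix] = {}
        self.bin500: dict[str, sp.csr_matrix] = {}
        self.ctcf: dict[str, np.ndarray] = {}
        self.z: dict[str, ContactMap] = {}
        self.mask: dict[str, np.ndarray] = {}
        self.metacells: MetacellAssignment | None = None
        self.profiles: dict[str, sp.csr_matrix] = {}
        self.cell_totals: np.ndarray | None = None
        self._full_track: dict[str, np.ndarray] = {}

    # -- construction ------------------------------------------------------
    @classmethod
    def from_fragments(cls, frag_df: pd.DataFrame, layout: GenomeLayout,
                       geometry: ModelGeometry, ctcf_tracks: dict[str, np.ndarray],
                       contact_counts: dict[str, ContactMap] | None = None,
                       z_maps: dict[str, ContactMap] | None = None,
                       barcodes: list[str] | None = None,
                       clip: tuple[float, float] = (-16.0, 16.0),
                       mask_quantile: float = 0.01,
                       n_lsi: int = 12, metacell_k: int = 20,
                       overlap_cap: float = 0.76, seed: int = 0,
                       acc_scale: float = 1e8) -> "StripeDataset":
        """Build a dataset from a fragments table plus either raw contact
        counts (normalized internally) or precomputed Z-score maps."""
        if barcodes is None:
            barcodes = sorted(frag_df["barcode"].unique())
        ds = cls(layout, geometry, barcodes, acc_scale)
        g = geometry
        for chrom in layout.chrom_names:
            sub = frag_df[frag_df["chrom"] == chrom]
            n_acc = layout.bin_count(chrom, g.acc_resolution)
            n_500 = layout.bin_count(chrom, g.coacc_resolution)
            ds.acc_counts[chrom] = _per_cell_bin_matrix(
                sub, barcodes, n_acc, g.acc_resolution, binary=False)
            ds.bin500[chrom] = _per_cell_bin_matrix(
                sub, barcodes, n_500, g.coacc_resolution, binary=True)
            ds.ctcf[chrom] = np.asarray(
                ctcf_tracks.get(chrom, np.zeros(n_acc)), dtype=float)
        ds.cell_totals = np.zeros(len(barcodes))
        for chrom in layout.chrom_names:
            ds.cell_totals += np.asarray(
                ds.acc_counts[chrom].sum(axis=1)).ravel()
        if z_maps is None:
            if contact_counts is None:
                raise ValueError("need contact_counts or z_maps")
            z_maps = {}
            for chrom, counts in contact_counts.items():
                mask = low_signal_mask(counts, mask_quantile)
                z = distance_stratified_zscore(counts, g.max_distance_bp, mask)
                z_maps[chrom] = clip_targets(z, *clip)
                ds.mask[chrom] = mask
        else:
            clipped = {}
            for chrom, z in z_maps.items():
                clipped[chrom] = clip_targets(z, *clip)
                if contact_counts is not None and chrom in contact_counts:
                    ds.mask[chrom] = low_signal_mask(contact_counts[chrom],
                                                     mask_quantile)
                else:
                    ds.mask[chrom] = np.zeros(z.n_bins, dtype=bool)
            z_maps = clipped
        ds.z = z_maps
        ds.build_metacells(n_lsi=n_lsi, k=metacell_k, overlap_cap=overlap_cap,
                           seed=seed)
        return ds

    def build_metacells(self, n_lsi: int = 12, k: int = 20,
                        overlap_cap: float = 0.76, seed: int = 0) -> None:
        genome_wide = sp.hstack([self.bin500[c] for c in self.layout.chrom_names],
                                format="csr")
        emb = lsi_embedding(genome_wide, n_components=n_lsi, seed=seed)
        self.metacells = build_metacells(emb, k=k, overlap_cap=overlap_cap,
                                         seed=seed)
        self.profiles = {c: metacell_profiles(self.bin500[c], self.metacells)
                         for c in self.layout.chrom_names}

    # -- track assembly ------------------------------------------------------
    def full_population_track(self, chrom: str) -> np.ndarray:
        if chrom not in self._full_track:
            raw = np.asarray(self.acc_counts[chrom].sum(axis=0)).ravel()
            self._full_track[chrom] = normalize_track(
                raw, self.cell_totals.sum(), self.acc_scale)
        return self._full_track[chrom]

    def accessibility_window(self, chrom: str, t: int,
                             cell_idx: np.ndarray | None = None,
                             shift_bp: int = 0) -> np.ndarray:
        g = self.geometry
        if cell_idx is None:
            track = self.full_population_track(chrom)
        else:
            raw = np.asarray(self.acc_counts[chrom][cell_idx].sum(axis=0)).ravel()
            lib = self.cell_totals[cell_idx].sum()
            track = normalize_track(raw, lib, self.acc_scale)
        return extract_window(track, t, g, g.acc_resolution,
                              shift_bins=shift_bp // g.acc_resolution)

    def ctcf_window(self, chrom: str, t: int, shift_bp: int = 0) -> np.ndarray:
        g = self.geometry
        return extract_window(self.ctcf[chrom], t, g, g.acc_resolution,
                              shift_bins=shift_bp // g.acc_resolution)

    def coacc_slice(self, chrom: str, t: int,
                    metacell_idx: np.ndarray | None = None,
                    shift_bp: int = 0) -> np.ndarray:
        g = self.geometry
        profiles = self.profiles[chrom]
        if metacell_idx is not None:
            profiles = profiles[metacell_idx]
        n500 = profiles.shape[1]
        nc = g.center_coacc_bins
        center = t * nc + np.arange(nc)
        start = (g.window_start_bp(t) + shift_bp) // g.coacc_resolution
        window = start + np.arange(g.coacc_window_len)
        window = np.where((window >= 0) & (window < n500), window, -1)
        valid_center = center < n500
        out = np.zeros((nc, g.coacc_window_len))
        if valid_center.any():
            out[valid_center] = jaccard_coaccessibility(
                profiles, center[valid_center], window)
        return out

    def example(self, chrom: str, t: int,
                cell_idx: np.ndarray | None = None,
                metacell_idx: np.ndarray | None = None,
                shift_bp: int = 0, with_target: bool = True,
                zero_coacc: bool = False) -> WindowExample:
        acc = self.accessibility_window(chrom, t, cell_idx, shift_bp)
        ctcf = self.ctcf_window(chrom, t, shift_bp)
        if zero_coacc:
            coacc = np.zeros((self.geometry.center_coacc_bins,
                              self.geometry.coacc_window_len))
        else:
            coacc = self.coacc_slice(chrom, t, metacell_idx, shift_bp)
        tr = tl = None
        if with_target and chrom in self.z:
            z, mask = self.z[chrom], self.mask[chrom]
            tr = target_vstripe(z, t, "right", mask, self.geometry.out_len)
            tl = target_vstripe(z, t, "left", mask, self.geometry.out_len)
        return WindowExample(chrom=chrom, t=t,
                             acc_ctcf=np.stack([acc, ctcf]), coacc=coacc,
                             target_right=tr, target_left=tl)

    def restrict_cells(self, cell_idx: np.ndarray) -> "StripeDataset":
        """Dataset view over a cell subset (for per-cluster deconvolution);
        metacells are rebuilt within the subset."""
        sub = StripeDataset(self.layout, self.geometry,
                            [self.barcodes[i] for i in cell_idx],
                            self.acc_scale)
        for chrom in self.layout.chrom_names:
            sub.acc_counts[chrom] = self.acc_counts[chrom][cell_idx]
            sub.bin500[chrom] = self.bin500[chrom][cell_idx]
            sub.ctcf[chrom] = self.ctcf[chrom]
        sub.z = self.z
        sub.mask = self.mask
        sub.cell_totals = self.cell_totals[cell_idx]
        return sub

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)
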