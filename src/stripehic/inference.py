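"""Chromosome-wide prediction by V-stripe assembly; per-cluster deconvolution."""

from __future__ import annotations

import numpy as np

from .dataset import StripeDataset
from .hic import ContactMap
from .model import VStripeModel


def assemble_stripes(stripes, n_bins: int, resolution: int,
                     chrom: str) -> ContactMap:
    """Average overlapping stripe predictions into a symmetric map.

    ``stripes`` yields ``(t, left, right, left_valid, right_valid)``. The
    right stripe of center ``i`` and the left stripe of center ``j = i + d``
    both predict pair (i, j); interior pairs are the mean of the two, edge
    pairs use whichever single prediction exists. Pairs with no valid
    prediction are absent from the result (not zero).
    """
    sums: dict[tuple[int, int], float] = {}
    counts: dict[tuple[int, int], int] = {}
    for t, left, right, lval, rval in stripes:
        for d in np.nonzero(rval)[0]:
            j = t + int(d)
            if j < n_bins:
                sums[(t, j)] = sums.get((t, j), 0.0) + float(right[d])
                counts[(t, j)] = counts.get((t, j), 0) + 1
        for d in np.nonzero(lval)[0]:
            i = t - int(d)
            if i >= 0:
                sums[(i, t)] = sums.get((i, t), 0.0) + float(left[d])
                counts[(i, t)] = counts.get((i, t), 0) + 1
    out = ContactMap(chrom, n_bins, resolution)
    for k, s in sums.items():
        out.set(k[0], k[1], s / counts[k])
    return out


def predict_chromosome(model, dataset: StripeDataset, chrom: str,
                       centers=None, batch_size: int = 16,
                       zero_coacc: bool = False) -> ContactMap:
    """Predict the contact map of one chromosome by stripe assembly.

    Inference is deterministic: the full cell/metacell population is used and
    no shift augmentation is applied; windows beyond chromosome edges are
    zero-padded. ``model`` is either a trained :class:`VStripeModel` or a
    callable oracle ``t -> (left, right, left_valid, right_valid)`` (used to
    isolate assembly correctness from model error).
    """
    g = dataset.geometry
    n_bins = dataset.layout.bin_count(chrom, g.hic_resolution)
    if centers is None:
        centers = range(n_bins)
    centers = [int(t) for t in centers]

    def gen():
        if callable(model) and not isinstance(model, VStripeModel):
            for t in centers:
                yield (t, *model(t))
            return
        for i in range(0, len(centers), batch_size):
            chunk = centers[i:i + batch_size]
            exs = [dataset.example(chrom, t, with_target=False,
                                   zero_coacc=zero_coacc) for t in chunk]
            acc = np.stack([e.acc_ctcf for e in exs])
            coacc = np.stack([e.coacc for e in exs])
            left, right = model.predict_vstripe(acc, coacc)
            all_valid = np.ones(g.out_len, dtype=bool)
            for k, t in enumerate(chunk):
                yield (t, left[k], right[k], all_valid, all_valid)

    return assemble_stripes(gen(), n_bins, g.hic_resolution, chrom)


def deconvolve_clusters(model, dataset: StripeDataset,
                        cluster_cells: dict[str, np.ndarray], chroms,
                        min_cells: int = 100, centers=None,
                        metacell_kwargs: dict | None = None
                        ) -> dict[str, dict[str, ContactMap]]:
    """Per-cluster contact-map prediction from cluster-restricted scATAC.

    Each cluster's map is computed exactly as :func:`predict_chromosome` on a
    dataset view containing only that cluster's cells (metacells are rebuilt
    within the cluster).
    """
    import warnings

    out: dict[str, dict[str, ContactMap]] = {}
    for name, cell_idx in cluster_cells.items():
        cell_idx = np.asarray(cell_idx, dtype=int)
        if cell_idx.size < min_cells:
            warnings.warn(f"cluster {name}: only {cell_idx.size} cells")
        sub = dataset.restrict_cells(cell_idx)
        sub.build_metacells(**(metacell_kwargs or {}))
        out[name] = {chrom: predict_chromosome(model, sub, chrom,
                                               centers=centers)
                     for chrom in chroms}
    return out
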