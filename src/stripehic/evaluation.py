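"""Evaluation metrics: distance-stratified correlation, significant-interaction
AUROC/AUPRC at bin and peak level, insulation score, paired model comparison."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .hic import ContactMap


@dataclass
class DistanceStratifiedMetric:
    chrom: str
    distances: np.ndarray = field(repr=False)
    values: np.ndarray = field(repr=False)  # NaN where undefined

    @property
    def mean(self) -> float:
        """Mean over defined distances (undefined excluded, not zero-filled)."""
        defined = ~np.isnan(self.values)
        return float(np.nanmean(self.values)) if defined.any() else np.nan


def _pairs_at_distance(n_bins: int, d: int, mask: np.ndarray | None):
    i = np.arange(0, n_bins - d)
    j = i + d
    if mask is not None:
        usable = ~np.asarray(mask, dtype=bool)
        ok = usable[i] & usable[j]
        i, j = i[ok], j[ok]
    return i, j


def distance_stratified_pearson(pred: ContactMap, truth: ContactMap,
                                mask: np.ndarray | None = None,
                                max_distance_bins: int = 200,
                                require_pred: bool = True
                                ) -> DistanceStratifiedMetric:
    """Pearson r between predicted and true values at each genomic distance.

    Distances with fewer than 2 pairs or zero variance on either side are
    undefined (NaN) and excluded from the mean. When ``require_pred`` is set,
    only pairs actually covered by a prediction are compared.
    """
    if pred.n_bins != truth.n_bins:
        raise ValueError("prediction/truth geometry mismatch")
    n = pred.n_bins
    pd_, td_ = pred.to_dense(), truth.to_dense()
    max_d = min(max_distance_bins, n - 1)
    vals = np.full(max_d + 1, np.nan)
    for d in range(max_d + 1):
        i, j = _pairs_at_distance(n, d, mask)
        if require_pred and len(i):
            has = np.array([pred.has_pair(a, b) for a, b in zip(i, j)])
            i, j = i[has], j[has]
        if len(i) < 2:
            continue
        x, y = pd_[i, j], td_[i, j]
        if x.std() == 0 or y.std() == 0:
            continue
        vals[d] = np.corrcoef(x, y)[0, 1]
    return DistanceStratifiedMetric(chrom=pred.chrom,
                                    distances=np.arange(max_d + 1),
                                    values=vals)


def significant_interaction_auc(pred: ContactMap,
                                labels: set[tuple[int, int]],
                                mask: np.ndarray | None = None,
                                max_distance_bins: int = 200
                                ) -> tuple[DistanceStratifiedMetric,
                                           DistanceStratifiedMetric]:
    """Per-distance (AUROC, AUPRC) of predicted values against binary labels.

    Distances where only one class is present are undefined and skipped.
    """
    n = pred.n_bins
    dense = pred.to_dense()
    max_d = min(max_distance_bins, n - 1)
    auroc = np.full(max_d + 1, np.nan)
    auprc = np.full(max_d + 1, np.nan)
    for d in range(max_d + 1):
        i, j = _pairs_at_distance(n, d, mask)
        if len(i) < 2:
            continue
        y = np.array([(a, b) in labels for a, b in zip(i, j)], dtype=int)
        if y.min() == y.max():
            continue
        scores = dense[i, j]
        auroc[d] = roc_auc_score(y, scores)
        auprc[d] = average_precision_score(y, scores)
    dist = np.arange(max_d + 1)
    return (DistanceStratifiedMetric(pred.chrom, dist, auroc),
            DistanceStratifiedMetric(pred.chrom, dist, auprc))


def map_peaks_to_bins(peaks, resolution: int = 10_000) -> dict[str, set[int]]:
    """Peak id -> set of contact-map bins overlapped by >= 1bp.

    A peak spanning a bin boundary is assigned to both bins (half-open
    intervals: a peak starting exactly on a boundary belongs only to the
    right bin).
    """
    out: dict[str, set[int]] = {}
    for p in peaks:
        b0 = p.start // resolution
        b1 = (p.end - 1) // resolution
        out[p.id] = set(range(b0, b1 + 1))
    return out


def peak_level_labels(peak_pairs, pair_pvalues: dict[tuple[int, int], float],
                      peak_bins: dict[str, set[int]],
                      fdr_threshold: float = 0.25) -> dict[tuple[str, str], int]:
    """Label a peak pair positive iff any associated bin pair has FDR p <
    threshold (strict). Pairs with no p-value on any bin pair are dropped."""
    labels: dict[tuple[str, str], int] = {}
    for a, b in peak_pairs:
        ps = [pair_pvalues[(min(i, j), max(i, j))]
              for i in peak_bins[a] for j in peak_bins[b]
              if (min(i, j), max(i, j)) in pair_pvalues]
        if not ps:
            continue
        labels[(a, b)] = int(any(p < fdr_threshold for p in ps))
    return labels


def peak_pair_score(pred: ContactMap, bins_a: set[int], bins_b: set[int],
                    reduction: str = "max") -> float:
    """Score of a peak pair from the predicted map over its associated bin
    pairs (max by default; min/mean configurable)."""
    vals = [pred.value(i, j) for i in bins_a for j in bins_b]
    if reduction == "max":
        return float(max(vals))
    if reduction == "min":
        return float(min(vals))
    if reduction == "mean":
        return float(np.mean(vals))
    raise ValueError(f"unknown reduction {reduction!r}")


def peak_level_auc(scores, labels, distances=None,
                   max_distance_bp: int = 500_000
                   ) -> tuple[float, float]:
    """(AUPRC, AUROC) over peak pairs, distance-constrained to 500kb.

    Returns (nan, nan) when only one class remains after filtering.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if distances is not None:
        keep = np.asarray(distances) <= max_distance_bp
        scores, labels = scores[keep], labels[keep]
    if len(labels) == 0 or labels.min() == labels.max():
        return (np.nan, np.nan)
    return (float(average_precision_score(labels, scores)),
            float(roc_auc_score(labels, scores)))


def insulation_score(cmap: ContactMap, window_bins: int = 30) -> np.ndarray:
    """Mean contact signal in the square [b-w, b] x [b, b+w] per bin ``b``.

    Local minima mark domain boundaries. Bins within ``w`` of either edge are
    undefined (NaN).
    """
    n = cmap.n_bins
    if window_bins >= n:
        raise ValueError("window_bins must be smaller than n_bins")
    dense = cmap.to_dense()
    w = window_bins
    out = np.full(n, np.nan)
    for b in range(w, n - w):
        out[b] = dense[b - w:b + 1, b:b + w + 1].mean()
    return out


def paired_ttest(metric_a, metric_b) -> tuple[float, float]:
    """Two-sided paired t-test across chromosomes.

    Zero-variance differences are handled explicitly: all-zero differences
    give (0.0, 1.0); constant nonzero differences give (±inf, 0.0).
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length vectors with >= 2 entries")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff, 0.0):
            return (0.0, 1.0)
        return (float(np.inf) * np.sign(diff.mean()), 0.0)
    t, p = stats.ttest_rel(a, b)
    return (float(t), float(p))
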