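"""Contact-map container, Z-score normalization stand-in, targets and labels."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ContactMap:
    """Per-chromosome intra-chromosomal contact matrix with symmetric access.

    Values (raw counts or Z-scores) are stored on the upper triangle only,
    keyed by ``(i, j)`` with ``i <= j``. Absent pairs read as 0 via
    :meth:`value`; :meth:`has_pair` distinguishes stored zeros from absence.
    """

    def __init__(self, chrom: str, n_bins: int, resolution: int):
        if n_bins <= 0:
            raise ValueError("n_bins must be positive")
        self.chrom = chrom
        self.n_bins = int(n_bins)
        self.resolution = int(resolution)
        self._data: dict[tuple[int, int], float] = {}
        self.clipped = False

    @staticmethod
    def _key(i: int, j: int) -> tuple[int, int]:
        return (i, j) if i <= j else (j, i)

    def _check(self, i: int, j: int) -> None:
        if not (0 <= i < self.n_bins and 0 <= j < self.n_bins):
            raise IndexError(f"bin pair ({i},{j}) outside [0,{self.n_bins})")

    def add(self, i: int, j: int, value: float) -> None:
        """Accumulate ``value`` onto pair (i,j); duplicates are summed."""
        self._check(i, j)
        k = self._key(i, j)
        self._data[k] = self._data.get(k, 0.0) + float(value)

    def set(self, i: int, j: int, value: float) -> None:
        self._check(i, j)
        self._data[self._key(i, j)] = float(value)

    def value(self, i: int, j: int) -> float:
        self._check(i, j)
        return self._data.get(self._key(i, j), 0.0)

    def has_pair(self, i: int, j: int) -> bool:
        self._check(i, j)
        return self._key(i, j) in self._data

    def items(self):
        """Iterate stored upper-triangle ((i, j), value) pairs."""
        return self._data.items()

    def __len__(self) -> int:
        return len(self._data)

    def to_dense(self) -> np.ndarray:
        """Full symmetric dense matrix (absent pairs are 0)."""
        m = np.zeros((self.n_bins, self.n_bins))
        for (i, j), v in self._data.items():
            m[i, j] = v
            m[j, i] = v
        return m

    def marginals(self) -> np.ndarray:
        """Row totals of the symmetric matrix (diagonal counted once)."""
        out = np.zeros(self.n_bins)
        for (i, j), v in self._data.items():
            out[i] += v
            if j != i:
                out[j] += v
        return out

    def copy_empty(self) -> "ContactMap":
        return ContactMap(self.chrom, self.n_bins, self.resolution)

    @classmethod
    def from_dense(cls, chrom: str, dense: np.ndarray, resolution: int,
                   keep_zeros: bool = False) -> "ContactMap":
        n = dense.shape[0]
        cm = cls(chrom, n, resolution)
        iu, ju = np.triu_indices(n)
        vals = dense[iu, ju]
        if not keep_zeros:
            nz = vals != 0
            iu, ju, vals = iu[nz], ju[nz], vals[nz]
        for i, j, v in zip(iu.tolist(), ju.tolist(), vals.tolist()):
            cm._data[(i, j)] = v
        return cm


def distance_stratified_zscore(counts: ContactMap,
                               max_distance: int = 2_000_000,
                               mask: np.ndarray | None = None) -> ContactMap:
    """Distance-stratified Z normalization of raw counts.

    A lightweight stand-in for model-based Hi-C normalization: for every
    genomic distance ``d`` (in bins) up to ``max_distance``,
    ``z = (log1p(x) - mean_d) / sd_d`` over unmasked pairs. Distances with
    zero variance yield z = 0. Every in-range unmasked pair receives a value
    (absent raw pairs enter as x = 0).
    """
    n = counts.n_bins
    res = counts.resolution
    max_d = max_distance // res
    if max_d > n - 1:
        import warnings

        warnings.warn("max_distance exceeds chromosome span; truncating")
        max_d = n - 1
    if mask is None:
        mask = np.zeros(n, dtype=bool)
    usable = ~np.asarray(mask, dtype=bool)
    dense = counts.to_dense()
    z = counts.copy_empty()
    for d in range(max_d + 1):
        i = np.arange(0, n - d)
        j = i + d
        ok = usable[i] & usable[j]
        if not ok.any():
            continue
        x = np.log1p(dense[i[ok], j[ok]])
        mu = x.mean()
        sd = x.std(ddof=0)
        vals = np.zeros_like(x) if sd == 0 else (x - mu) / sd
        for ii, jj, v in zip(i[ok].tolist(), j[ok].tolist(), vals.tolist()):
            z._data[(ii, jj)] = v
    return z


def clip_targets(z: ContactMap, lo: float = -16.0, hi: float = 16.0) -> ContactMap:
    """Clip Z values into [lo, hi]; idempotent."""
    if lo >= hi:
        raise ValueError("lo must be < hi")
    out = z.copy_empty()
    for k, v in z._data.items():
        out._data[k] = min(max(v, lo), hi)
    out.clipped = True
    return out


def low_signal_mask(counts: ContactMap, quantile: float = 0.01) -> np.ndarray:
    """Boolean mask of low-signal bins (True = masked / excluded).

    A bin is masked iff its marginal total is zero, or at/below the given
    quantile of the nonzero marginals.
    """
    marg = counts.marginals()
    masked = marg == 0
    nonzero = marg[marg > 0]
    if quantile > 0 and nonzero.size:
        thr = np.quantile(nonzero, quantile)
        masked |= marg <= thr
    return masked


@dataclass
class VStripeTarget:
    """One-sided stripe target: contacts between bin ``t`` and ``t±d``."""

    t: int
    side: str  # "left" | "right"
    values: np.ndarray = field(repr=False)
    valid: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if self.values.shape != self.valid.shape:
            raise ValueError("values/valid shape mismatch")


def target_vstripe(z: ContactMap, t: int, side: str,
                   mask: np.ndarray | None = None,
                   out_len: int = 201) -> VStripeTarget:
    """Extract the one-sided V-stripe at center ``t`` from a Z map.

    ``values[d] = z(t, t±d)``; entries are invalid when the partner bin is
    outside the chromosome or when either bin is masked.
    """
    n = z.n_bins
    if not 0 <= t < n:
        raise IndexError(f"center bin {t} outside [0,{n})")
    if mask is None:
        mask = np.zeros(n, dtype=bool)
    sign = 1 if side == "right" else -1
    values = np.zeros(out_len)
    valid = np.zeros(out_len, dtype=bool)
    for d in range(out_len):
        j = t + sign * d
        if not 0 <= j < n:
            continue
        if mask[t] or mask[j]:
            continue
        if not z.has_pair(t, j):
            continue
        values[d] = z.value(t, j)
        valid[d] = True
    return VStripeTarget(t=t, side=side, values=values, valid=valid)


def label_significant_bins(z: ContactMap, top_fraction: float = 0.10,
                           mask: np.ndarray | None = None,
                           max_distance_bins: int | None = None
                           ) -> set[tuple[int, int]]:
    """Top-``top_fraction`` pairs by Z per chromosome.

    Exactly ``floor(top_fraction * n_unmasked)`` pairs are labeled, chosen by
    descending z with lexicographic (i, j) tie-break. Candidates are all
    unmasked upper-triangle pairs within ``max_distance_bins``; pairs absent
    from the map score 0.
    """
    n = z.n_bins
    if mask is None:
        mask = np.zeros(n, dtype=bool)
    max_d = n - 1 if max_distance_bins is None else min(max_distance_bins, n - 1)
    pairs: list[tuple[float, int, int]] = []
    usable = ~np.asarray(mask, dtype=bool)
    for d in range(max_d + 1):
        for i in range(n - d):
            j = i + d
            if usable[i] and usable[j]:
                pairs.append((z.value(i, j), i, j))
    if not pairs:
        raise ValueError("no unmasked pairs")
    k = int(np.floor(top_fraction * len(pairs)))
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    return {(i, j) for _, i, j in pairs[:k]}
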