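"""Sequence kernels over CNV profiles and the subject similarity matrix.

Three levels of similarity are composed:

* ``single_pair_kernel`` ``Ks(x, y)`` — similarity of two individual CNVs,
  the product of a positional Jaccard overlap, a type-agreement term, and a
  dosage term that halves per unit difference in distance-from-reference
  copy number.  Always in [0, 1].
* ``pair_group_kernel`` ``KPG(Gi, Gj)`` — two same-size CNV groups compared
  by pairing CNVs at the same ordinal position and averaging ``Ks``.
* ``whole_genome_group_kernel`` ``KWG(Pi, Pj)`` — two sliding-window group
  series compared by, for each anchor group ``Gz`` of the first series,
  taking the best match among the neighbouring groups ``G(z-1), Gz,
  G(z+1)`` of the second series and summing those maxima.  This is the
  sequence-order-aware aggregate: a shared run of similar CNVs in the same
  order scores once per window.

``kernel_matrix`` assembles the d x d subject similarity matrix used as
the covariance of the random effect in the score test.  Because the
anchor/neighbour construction of ``KWG`` is not exchange-symmetric and the
per-window maxima can make the matrix indefinite, the matrix is
symmetrized by averaging with its transpose and (by default) projected to
the nearest PSD matrix by clipping negative eigenvalues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .cnv_core import (
    CNVDataError,
    CNVGroup,
    CNVProfile,
    CNVRecord,
    GroupSeries,
    chrom_sort_key,
)

__all__ = [
    "dr",
    "single_pair_kernel",
    "pair_group_kernel",
    "extract_group_series",
    "whole_genome_group_kernel",
    "kernel_matrix",
    "KernelMatrix",
    "read_kernel_tsv",
]

#: diploid reference copy number
_REFERENCE_DOSAGE = 2


def dr(dosage: int | float) -> float:
    """Distance of a dosage from the diploid reference: ``|dosage - 2|``."""
    if dosage < 0:
        raise CNVDataError(f"negative dosage: {dosage}")
    return abs(float(dosage) - _REFERENCE_DOSAGE)


def single_pair_kernel(x: CNVRecord, y: CNVRecord) -> float:
    """Similarity of two CNVs in [0, 1].

    Product of three terms: intersection/union of the base-pair intervals
    (0 for different chromosomes or disjoint segments), a type term
    ``(1[type match] + 1)/2``, and a dosage term ``(1/2)**|dr(x) - dr(y)|``.
    """
    if chrom_sort_key(x.chrom) != chrom_sort_key(y.chrom):
        return 0.0
    inter = min(x.end, y.end) - max(x.start, y.start) + 1
    if inter <= 0:
        return 0.0
    union = x.length + y.length - inter
    overlap = inter / union
    type_term = (float(x.cnv_type == y.cnv_type) + 1.0) / 2.0
    dosage_term = 0.5 ** abs(dr(x.dosage) - dr(y.dosage))
    return overlap * type_term * dosage_term


def pair_group_kernel(gi: CNVGroup, gj: CNVGroup) -> float:
    """Mean of ``single_pair_kernel`` over position-paired CNVs of two groups."""
    if gi.size != gj.size:
        raise CNVDataError(
            f"group size mismatch: {gi.size} vs {gj.size}"
        )
    return sum(
        single_pair_kernel(a, b) for a, b in zip(gi.records, gj.records)
    ) / gi.size


def extract_group_series(profile: CNVProfile, n: int) -> GroupSeries:
    """All stride-1 windows of size ``n``: ``max(0, l - n + 1)`` groups."""
    if n < 1:
        raise CNVDataError(f"group size must be >= 1, got {n}")
    records = profile.records
    groups = tuple(
        CNVGroup(records[z : z + n]) for z in range(len(records) - n + 1)
    )
    return GroupSeries(groups=groups, n=n)


def whole_genome_group_kernel(
    pi_series: GroupSeries,
    pj_series: GroupSeries,
    sum_bound: str = "max",
    normalized: bool = False,
) -> float:
    """Aggregate similarity of two group series (non-negative).

    0 if either series is empty.  Otherwise, for each anchor index ``z``
    up to ``max(pi, qj)`` (or ``min`` with ``sum_bound='min'``), the best
    of the neighbour candidates ``KPG(Gz_i, G(z-1)_j)``, ``KPG(Gz_i,
    Gz_j)``, ``KPG(Gz_i, G(z+1)_j)`` is added; candidates whose index
    falls outside either series are skipped and an anchor with no valid
    candidate contributes 0.  ``normalized`` divides by the number of
    anchor terms (off by default: the raw sum is the defined quantity).
    """
    if pi_series.n != pj_series.n:
        raise CNVDataError(
            f"series built with different n: {pi_series.n} vs {pj_series.n}"
        )
    p, q = len(pi_series), len(pj_series)
    if p == 0 or q == 0:
        return 0.0
    if sum_bound == "max":
        zmax = max(p, q)
    elif sum_bound == "min":
        zmax = min(p, q)
    else:
        raise CNVDataError(f"sum_bound must be 'max' or 'min', got {sum_bound!r}")
    total = 0.0
    for z in range(1, zmax + 1):
        if z > p:
            continue
        candidates = [
            pair_group_kernel(pi_series[z - 1], pj_series[w - 1])
            for w in (z - 1, z, z + 1)
            if 1 <= w <= q
        ]
        if candidates:
            total += max(candidates)
    return total / zmax if normalized else total


@dataclass
class KernelMatrix:
    """Symmetric d x d subject similarity matrix.

    ``values[i, i]`` equals the group count of subject ``i`` (before any
    PSD adjustment); ``psd_adjusted`` records whether negative eigenvalues
    were clipped.
    """

    values: np.ndarray
    sample_ids: list[str]
    group_size: int
    psd_adjusted: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        d = len(self.sample_ids)
        if self.values.shape != (d, d):
            raise CNVDataError(
                f"kernel shape {self.values.shape} does not match "
                f"{d} sample ids"
            )

    @property
    def d(self) -> int:
        return len(self.sample_ids)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.sample_ids
        ).to_csv(path, sep="\t", index_label=f"n={self.group_size}")

    def __iter__(self) -> Iterator:  # convenience for np.asarray
        return iter(self.values)


def read_kernel_tsv(path) -> KernelMatrix:
    """Load a kernel matrix written by :meth:`KernelMatrix.to_tsv`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    label = str(df.index.name or "")
    if not label.startswith("n="):
        raise CNVDataError(f"{path} is not a kernel TSV (missing n= header)")
    return KernelMatrix(
        values=df.to_numpy(dtype=float),
        sample_ids=[str(c) for c in df.columns],
        group_size=int(label[2:]),
    )


# ---------------------------------------------------------------------------
# Vectorized cohort-level computation
# ---------------------------------------------------------------------------


class _ProfileArrays:
    """Columnar view of one profile for vectorized kernel evaluation."""

    __slots__ = ("start", "end", "length", "chrom", "type_code", "drv", "l")

    def __init__(self, profile: CNVProfile, chrom_codes: dict) -> None:
        recs = profile.records
        self.l = len(recs)
        self.start = np.fromiter((r.start for r in recs), float, self.l)
        self.end = np.fromiter((r.end for r in recs), float, self.l)
        self.length = self.end - self.start + 1.0
        self.chrom = np.fromiter(
            (chrom_codes[r.chrom] for r in recs), np.int64, self.l
        )
        self.type_code = np.fromiter((r.cnv_type for r in recs), np.int64, self.l)
        self.drv = np.abs(
            np.fromiter((r.dosage for r in recs), float, self.l)
            - _REFERENCE_DOSAGE
        )


def _ks_block(a: _ProfileArrays, b: _ProfileArrays) -> np.ndarray:
    """All single-pair kernel values between two profiles (la x lb)."""
    inter = (
        np.minimum(a.end[:, None], b.end[None, :])
        - np.maximum(a.start[:, None], b.start[None, :])
        + 1.0
    )
    np.clip(inter, 0.0, None, out=inter)
    same_chrom = a.chrom[:, None] == b.chrom[None, :]
    inter *= same_chrom
    union = a.length[:, None] + b.length[None, :] - inter
    type_term = (
        (a.type_code[:, None] == b.type_code[None, :]).astype(float) + 1.0
    ) / 2.0
    dosage_term = 0.5 ** np.abs(a.drv[:, None] - b.drv[None, :])
    return (inter / union) * type_term * dosage_term


def _window_means(diag: np.ndarray, n: int) -> np.ndarray:
    if diag.size < n:
        return np.empty(0)
    c = np.concatenate(([0.0], np.cumsum(diag)))
    return (c[n:] - c[:-n]) / n


def _kwg_from_block(
    block: np.ndarray, n: int, sum_bound: str, normalized: bool
) -> float:
    """Group-series kernel from the pairwise single-CNV block.

    The position-paired group kernel for anchor z and candidate offset o
    is the mean of a length-n window along the block diagonal of offset o,
    so the whole computation reduces to sliding means over three
    diagonals.
    """
    li, lj = block.shape
    p, q = li - n + 1, lj - n + 1
    if p <= 0 or q <= 0:
        return 0.0
    zmax = max(p, q) if sum_bound == "max" else min(p, q)
    best = np.zeros(zmax)
    for offset in (-1, 0, 1):
        means = _window_means(np.diagonal(block, offset=offset), n)
        if means.size == 0:
            continue
        z0 = 1 if offset >= 0 else 2  # first valid anchor index
        lo = z0 - 1
        hi = min(lo + means.size, zmax)
        if hi > lo:
            np.maximum(best[lo:hi], means[: hi - lo], out=best[lo:hi])
    total = float(best.sum())
    return total / zmax if normalized else total


try:  # optional JIT acceleration of the cohort loop
    import numba as _numba
except ImportError:  # pragma: no cover - numba is a hard install dep
    _numba = None


if _numba is not None:

    @_numba.njit(cache=True)
    def _kwg_pair_jit(
        start, end, chrom, tcode, drv, ai, li, aj, lj, n, use_max, normalized
    ):  # pragma: no cover - exercised via kernel_matrix
        p = li - n + 1
        q = lj - n + 1
        if p <= 0 or q <= 0:
            return 0.0
        zmax = max(p, q) if use_max else min(p, q)
        total = 0.0
        for z in range(zmax):
            if z >= p:
                continue
            best = 0.0
            for o in range(-1, 2):
                w = z + o
                if w < 0 or w >= q:
                    continue
                acc = 0.0
                for m in range(n):
                    xi = ai + z + m
                    yj = aj + w + m
                    if chrom[xi] != chrom[yj]:
                        continue
                    lo_ = start[xi] if start[xi] > start[yj] else start[yj]
                    hi_ = end[xi] if end[xi] < end[yj] else end[yj]
                    inter = hi_ - lo_ + 1.0
                    if inter <= 0.0:
                        continue
                    union = (
                        (end[xi] - start[xi] + 1.0)
                        + (end[yj] - start[yj] + 1.0)
                        - inter
                    )
                    tt = 1.0 if tcode[xi] == tcode[yj] else 0.5
                    dd = 2.0 ** (-abs(drv[xi] - drv[yj]))
                    acc += (inter / union) * tt * dd
                kpg = acc / n
                if kpg > best:
                    best = kpg
            total += best
        if normalized:
            total /= zmax
        return total

    @_numba.njit(cache=True)
    def _kernel_values_jit(
        start, end, chrom, tcode, drv, offsets, n, use_max, normalized
    ):  # pragma: no cover - exercised via kernel_matrix
        d = offsets.shape[0] - 1
        values = np.zeros((d, d))
        for i in range(d):
            ai = offsets[i]
            li = offsets[i + 1] - ai
            if li < n:
                continue
            values[i, i] = _kwg_pair_jit(
                start, end, chrom, tcode, drv, ai, li, ai, li, n,
                use_max, normalized,
            )
            for j in range(i + 1, d):
                aj = offsets[j]
                lj = offsets[j + 1] - aj
                if lj < n:
                    continue
                forward = _kwg_pair_jit(
                    start, end, chrom, tcode, drv, ai, li, aj, lj, n,
                    use_max, normalized,
                )
                backward = _kwg_pair_jit(
                    start, end, chrom, tcode, drv, aj, lj, ai, li, n,
                    use_max, normalized,
                )
                values[i, j] = 0.5 * (forward + backward)
                values[j, i] = values[i, j]
        return values


def _kernel_values_numpy(
    cols: list[_ProfileArrays], n: int, sum_bound: str, normalized: bool
) -> np.ndarray:
    d = len(cols)
    values = np.zeros((d, d))
    for i in range(d):
        if cols[i].l < n:
            continue
        block_ii = _ks_block(cols[i], cols[i])
        values[i, i] = _kwg_from_block(block_ii, n, sum_bound, normalized)
        for j in range(i + 1, d):
            if cols[j].l < n:
                continue
            block = _ks_block(cols[i], cols[j])
            forward = _kwg_from_block(block, n, sum_bound, normalized)
            backward = _kwg_from_block(block.T, n, sum_bound, normalized)
            values[i, j] = values[j, i] = 0.5 * (forward + backward)
    return values


def kernel_matrix(
    profiles: Sequence[CNVProfile],
    n: int,
    psd_fix: bool = True,
    sum_bound: str = "max",
    normalized: bool = False,
) -> KernelMatrix:
    """Subject-by-subject similarity matrix ``K[i, j] = KWG(Pi, Pj)``.

    The raw kernel is computed in both anchor directions and averaged
    (symmetrization); with ``psd_fix`` (default) negative eigenvalues are
    then clipped to zero so the matrix is a valid covariance.  Subjects
    whose profile is shorter than ``n`` have an all-zero row/column and
    are reported in a warning.
    """
    if len(profiles) < 2:
        raise CNVDataError("kernel matrix needs at least 2 profiles")
    if n < 1:
        raise CNVDataError(f"group size must be >= 1, got {n}")
    if sum_bound not in ("max", "min"):
        raise CNVDataError(f"sum_bound must be 'max' or 'min', got {sum_bound!r}")
    chroms = sorted(
        {r.chrom for p in profiles for r in p.records}, key=chrom_sort_key
    )
    chrom_codes = {c: i for i, c in enumerate(chroms)}
    cols = [_ProfileArrays(p, chrom_codes) for p in profiles]
    empty = [p.sample_id for p, c in zip(profiles, cols) if c.l < n]
    if _numba is not None:
        offsets = np.zeros(len(cols) + 1, dtype=np.int64)
        offsets[1:] = np.cumsum([c.l for c in cols])
        values = _kernel_values_jit(
            np.concatenate([c.start for c in cols]) if offsets[-1] else np.empty(0),
            np.concatenate([c.end for c in cols]) if offsets[-1] else np.empty(0),
            np.concatenate([c.chrom for c in cols]) if offsets[-1] else np.empty(0, np.int64),
            np.concatenate([c.type_code for c in cols]) if offsets[-1] else np.empty(0, np.int64),
            np.concatenate([c.drv for c in cols]) if offsets[-1] else np.empty(0),
            offsets,
            n,
            sum_bound == "max",
            normalized,
        )
    else:
        values = _kernel_values_numpy(cols, n, sum_bound, normalized)
    if empty:
        warnings.warn(
            f"subject(s) with fewer than n={n} CNVs have an all-zero "
            f"kernel row: {empty}",
            stacklevel=2,
        )
    psd_adjusted = False
    if psd_fix and values.any():
        eigval, eigvec = np.linalg.eigh(values)
        floor = -1e-12 * max(1.0, float(eigval[-1]))
        if eigval[0] < floor:
            clipped = np.clip(eigval, 0.0, None)
            values = (eigvec * clipped) @ eigvec.T
            values = 0.5 * (values + values.T)
            psd_adjusted = True
    return KernelMatrix(
        values=values,
        sample_ids=[p.sample_id for p in profiles],
        group_size=n,
        psd_adjusted=psd_adjusted,
    )
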