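"""Methylome change-point segmentation and UMR/LMR/FMR classification.

Per-CpG methylation fractions are segmented per chromosome by exact
penalised change-point partitioning (PELT): the segmentation minimising the
total within-segment sum of squared deviations plus a BIC-type penalty per
segment, subject to a minimum of ``min_cpgs_per_segment`` CpGs per segment.
Adjacent segments whose means differ by less than ``min_seg_diff`` are then
merged (smallest difference first), so every surviving boundary reflects a
methylation change of at least that size. CpG runs separated by more than
``max_join_dist`` bp are never joined. Segments are then classified:

* UMR  — unmethylated region: mean <= ``umr_max_meth`` and >= ``umr_min_cpgs``
  CpGs (long CpG-rich promoter/CpG-island segments);
* LMR  — low-methylated region: mean <= ``lmr_max_meth``, not a UMR
  (shorter distal segments, a proxy for regulatory elements);
* FMR  — fully methylated background, everything else.

Segment means are coverage-weighted (sum of methylated reads over sum of
total reads), so low-coverage CpGs do not dominate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .intervals import GenomicInterval

UMR = "UMR"
LMR = "LMR"
FMR = "FMR"


@dataclass(frozen=True)
class CpGRecord:
    """One CpG with methylated/total read counts (position 0-based)."""

    chrom: str
    pos: int
    meth_count: int
    total_count: int

    def __post_init__(self) -> None:
        if self.total_count < 1:
            raise ValueError(f"CpG {self.chrom}:{self.pos}: total_count must be >= 1")
        if not (0 <= self.meth_count <= self.total_count):
            raise ValueError(
                f"CpG {self.chrom}:{self.pos}: meth_count outside [0, total_count]"
            )

    @property
    def fraction(self) -> float:
        return self.meth_count / self.total_count


@dataclass(frozen=True)
class MethylomeSegment:
    interval: GenomicInterval
    mean_meth: float
    n_cpgs: int
    seg_class: str | None = None


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable segmentation/classification thresholds (all config keys)."""

    min_cpgs_per_segment: int = 4
    min_seg_diff: float = 0.10
    max_join_dist: int = 5000
    umr_max_meth: float = 0.10
    lmr_max_meth: float = 0.50
    umr_min_cpgs: int = 30
    smoothing_span: int = 3

    def __post_init__(self) -> None:
        if not (self.umr_max_meth < self.lmr_max_meth < 1):
            raise ValueError("require umr_max_meth < lmr_max_meth < 1")
        if self.min_cpgs_per_segment < 2:
            raise ValueError("min_cpgs_per_segment must be >= 2")


class NoData:
    """Sentinel distinguishing 'no CpGs in region' from a methylation of 0."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "NoData"


NO_DATA = NoData()


# ---------------------------------------------------------------------------
# Region means and deltas
# ---------------------------------------------------------------------------

class CpGTable:
    """Sorted per-chromosome CpG arrays for fast region queries."""

    def __init__(self, cpgs: Sequence[CpGRecord]):
        by_chrom: dict[str, list[CpGRecord]] = {}
        for c in cpgs:
            by_chrom.setdefault(c.chrom, []).append(c)
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, recs in by_chrom.items():
            pos = np.array([r.pos for r in recs], dtype=np.int64)
            order = np.argsort(pos, kind="stable")
            self._data[chrom] = (
                pos[order],
                np.array([r.meth_count for r in recs], dtype=np.int64)[order],
                np.array([r.total_count for r in recs], dtype=np.int64)[order],
            )

    def chroms(self):
        return self._data.keys()

    def arrays(self, chrom: str):
        return self._data.get(chrom)

    def region_counts(self, region: GenomicInterval) -> tuple[int, int, int]:
        """(n_cpgs, sum_meth, sum_total) for CpGs with start <= pos < end."""
        data = self._data.get(region.chrom)
        if data is None:
            return 0, 0, 0
        pos, m, t = data
        lo = int(np.searchsorted(pos, region.start, "left"))
        hi = int(np.searchsorted(pos, region.end, "left"))
        return hi - lo, int(m[lo:hi].sum()), int(t[lo:hi].sum())


def mean_methylation(
    cpgs: Sequence[CpGRecord] | CpGTable, region: GenomicInterval
):
    """Coverage-weighted mean methylation over a region.

    Returns ``NO_DATA`` when the region holds no CpGs — distinct from a true
    mean of zero.
    """
    table = cpgs if isinstance(cpgs, CpGTable) else CpGTable(cpgs)
    n, m, t = table.region_counts(region)
    if n == 0:
        return NO_DATA
    return m / t


def methylation_delta(
    region: GenomicInterval,
    cpgs_t1: Sequence[CpGRecord] | CpGTable,
    cpgs_t2: Sequence[CpGRecord] | CpGTable,
):
    """Methylation change t2 - t1 in percentage points (negative = loss).

    A loss of at least 30 points marks a newly hypomethylated (new-LMR)
    region; gains/losses of at least 5 points mark dynamic TSS-UMR genes.
    Returns ``NO_DATA`` if either time point lacks CpGs in the region.
    """
    m1 = mean_methylation(cpgs_t1, region)
    m2 = mean_methylation(cpgs_t2, region)
    if m1 is NO_DATA or m2 is NO_DATA:
        return NO_DATA
    return 100.0 * (m2 - m1)


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def _smooth(x: np.ndarray, span: int) -> np.ndarray:
    """Centred moving average with shrinking windows at the edges."""
    if span <= 1 or len(x) < 3:
        return x
    kernel = np.ones(span)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def _noise_sd(x: np.ndarray, lag: int) -> float:
    """Robust noise scale from lag differences (median absolute / expectation).

    The lag equals the smoothing span so that the differenced values are
    (nearly) independent even after moving-average smoothing.
    """
    lag = max(lag, 1)
    if len(x) <= lag + 1:
        return 0.0
    d = np.abs(x[lag:] - x[:-lag])
    med = float(np.median(d))
    # median(|N(0, sqrt(2) sigma)|) = sqrt(2) sigma * 0.6745
    return med / (np.sqrt(2.0) * 0.6745)


def pelt_segment(x: np.ndarray, min_n: int, beta: float) -> list[tuple[int, int]]:
    """Exact penalised SSE partitioning of a 1-D signal (PELT).

    Minimises sum of within-segment squared deviations + ``beta`` per
    segment, with every segment at least ``min_n`` points long (a block
    shorter than ``2*min_n`` stays whole). Returns half-open index pairs.
    """
    n = len(x)
    if n < 2 * min_n:
        return [(0, n)]
    s1 = np.concatenate(([0.0], np.cumsum(x)))
    s2 = np.concatenate(([0.0], np.cumsum(x * x)))
    F = np.full(n + 1, np.inf)
    F[0] = -beta
    prev = np.zeros(n + 1, dtype=np.int64)
    # active candidate buffer; a change-point s becomes usable at t = s + min_n
    active = np.empty(n + 1, dtype=np.int64)
    active[0] = 0
    m = 1
    for t in range(min_n, n + 1):
        newly = t - min_n
        if newly > 0 and np.isfinite(F[newly]):
            active[m] = newly
            m += 1
        arr = active[:m]
        seglen = (t - arr).astype(float)
        seg_sum = s1[t] - s1[arr]
        cost = (s2[t] - s2[arr]) - seg_sum * seg_sum / seglen
        base = F[arr] + cost
        j = int(np.argmin(base))
        F[t] = base[j] + beta
        prev[t] = arr[j]
        # PELT pruning: a candidate worse than F[t] even before the penalty
        # can never be optimal again
        keep = base <= F[t]
        m_new = int(np.count_nonzero(keep))
        if m_new < m:
            active[:m_new] = arr[keep]
            m = m_new
    bounds = []
    t = n
    while t > 0:
        s = int(prev[t])
        bounds.append((s, t))
        t = s
    bounds.reverse()
    return bounds


def _merge_similar(
    bounds: list[tuple[int, int]],
    m: np.ndarray,
    t: np.ndarray,
    min_diff: float,
) -> list[tuple[int, int]]:
    """Merge adjacent segments (smallest mean difference first) while the
    coverage-weighted means differ by less than ``min_diff``."""
    bounds = list(bounds)
    if len(bounds) < 2:
        return bounds

    def wmean(lo, hi):
        return m[lo:hi].sum() / t[lo:hi].sum()

    means = [wmean(lo, hi) for lo, hi in bounds]
    while len(bounds) > 1:
        diffs = [abs(means[i + 1] - means[i]) for i in range(len(bounds) - 1)]
        j = int(np.argmin(diffs))
        if diffs[j] >= min_diff:
            break
        lo = bounds[j][0]
        hi = bounds[j + 1][1]
        bounds[j : j + 2] = [(lo, hi)]
        means[j : j + 2] = [wmean(lo, hi)]
    return bounds


def segment_methylome(
    cpgs: Sequence[CpGRecord] | CpGTable, params: SegmentationParams | None = None
) -> list[MethylomeSegment]:
    """Partition sorted CpGs into contiguous segments (classes unset).

    Input must be sorted by (chrom, pos) (a :class:`CpGTable` is always
    sorted). Every CpG lands in exactly one segment; segment intervals span
    the first to last member CpG (+1 bp).
    """
    params = params or SegmentationParams()
    if isinstance(cpgs, CpGTable):
        arrays = {c: cpgs.arrays(c) for c in cpgs.chroms()}
    else:
        prev = None
        for c in cpgs:
            key = (c.chrom, c.pos)
            if prev is not None and key < prev:
                raise ValueError("CpG records must be sorted by (chrom, pos)")
            prev = key
        by_chrom: dict[str, list[CpGRecord]] = {}
        for c in cpgs:
            by_chrom.setdefault(c.chrom, []).append(c)
        arrays = {
            chrom: (
                np.array([r.pos for r in recs], dtype=np.int64),
                np.array([r.meth_count for r in recs], dtype=np.int64),
                np.array([r.total_count for r in recs], dtype=np.int64),
            )
            for chrom, recs in by_chrom.items()
        }

    segments: list[MethylomeSegment] = []
    for chrom, (pos, m_arr, t_arr) in arrays.items():
        m = m_arr.astype(float)
        t = t_arr.astype(float)
        frac = m / t
        # hard breaks at large CpG gaps
        gap_breaks = np.flatnonzero(np.diff(pos) > params.max_join_dist) + 1
        blocks = np.split(np.arange(len(pos)), gap_breaks)
        for block in blocks:
            lo0, hi0 = int(block[0]), int(block[-1]) + 1
            x = _smooth(frac[lo0:hi0], params.smoothing_span)
            sigma = _noise_sd(x, params.smoothing_span)
            n_block = hi0 - lo0
            # BIC-type per-segment penalty; the smoothing span scales it to
            # compensate for the autocorrelation the moving average induces
            beta = max(
                2.0 * sigma * sigma * max(params.smoothing_span, 1) * np.log(max(n_block, 2)),
                1e-8,
            )
            bounds = pelt_segment(x, params.min_cpgs_per_segment, beta)
            bounds = _merge_similar(
                bounds, m[lo0:hi0], t[lo0:hi0], params.min_seg_diff
            )
            for lo, hi in bounds:
                a, b = lo0 + lo, lo0 + hi
                segments.append(
                    MethylomeSegment(
                        interval=GenomicInterval(chrom, int(pos[a]), int(pos[b - 1]) + 1),
                        mean_meth=float(m[a:b].sum() / t[a:b].sum()),
                        n_cpgs=b - a,
                    )
                )
    segments.sort(key=lambda s: (s.interval.chrom, s.interval.start))
    return segments


def classify_segments(
    segs: Sequence[MethylomeSegment], params: SegmentationParams | None = None
) -> list[MethylomeSegment]:
    """Label segments UMR / LMR / FMR from mean methylation and CpG count."""
    params = params or SegmentationParams()
    out = []
    for s in segs:
        if s.mean_meth <= params.umr_max_meth and s.n_cpgs >= params.umr_min_cpgs:
            cls = UMR
        elif (
            s.mean_meth <= params.lmr_max_meth
            and s.n_cpgs >= params.min_cpgs_per_segment
        ):
            cls = LMR
        else:
            cls = FMR
        out.append(replace(s, seg_class=cls))
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_cpg_table(path, dialect: str = "native") -> list[CpGRecord]:
    """Read a CpG table.

    ``native``: 0-based 5-column TSV (chrom, pos, meth_count, total_count,
    fraction — fraction ignored on read). ``bismark``: Bismark-coverage
    style (chrom, start1, end1, meth%, count_meth, count_unmeth; 1-based,
    converted on read).
    """
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if dialect == "native":
                out.append(CpGRecord(f[0], int(f[1]), int(f[2]), int(f[3])))
            elif dialect == "bismark":
                cm, cu = int(f[4]), int(f[5])
                out.append(CpGRecord(f[0], int(f[1]) - 1, cm, cm + cu))
            else:
                raise ValueError(f"unknown CpG table dialect {dialect!r}")
    out.sort(key=lambda c: (c.chrom, c.pos))
    return out


def write_cpg_table(path, cpgs: Sequence[CpGRecord]) -> None:
    with open(path, "w") as fh:
        for c in cpgs:
            fh.write(
                f"{c.chrom}\t{c.pos}\t{c.meth_count}\t{c.total_count}\t{c.fraction:.4f}\n"
            )


def write_segments_bed(path, segs: Sequence[MethylomeSegment]) -> None:
    """BED6: class in the name field, mean methylation x1000 in the score."""
    with open(path, "w") as fh:
        for s in segs:
            iv = s.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{s.seg_class or 'NA'}\t"
                f"{round(s.mean_meth * 1000)}\t.\n"
            )


def read_segments_bed(path) -> list[MethylomeSegment]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(
                MethylomeSegment(
                    interval=GenomicInterval(f[0], int(f[1]), int(f[2])),
                    mean_meth=float(f[4]) / 1000.0,
                    n_cpgs=0,
                    seg_class=None if f[3] == "NA" else f[3],
                )
            )
    return out
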