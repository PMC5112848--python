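"""Fragment-to-signal engine.

Converts aligned-fragment intervals into depth-normalised binned tracks
(RPKM), log2(ChIP/Input) ratio tracks, meta-profile matrices around
reference points or scaled gene bodies, binned replicate correlations,
per-feature coverage summaries, and enriched-region calls from a simplified
sliding-window Poisson peak caller.

Fragments are stored as per-chromosome sorted start/end arrays so that a
million-fragment sample stays cheap to bin and to window-count.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .intervals import GeneModel, GenomeIndex, GenomicInterval, STRAND_MINUS


class CoverageError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FragmentSet
# ---------------------------------------------------------------------------

class FragmentSet:
    """A set of aligned fragments (post-alignment, pre-analysis).

    ``total_mapped`` defaults to the number of fragments held; it may exceed
    it when the set is a subsample of a larger library.
    """

    def __init__(
        self,
        by_chrom: Mapping[str, tuple[np.ndarray, np.ndarray]],
        total_mapped: int | None = None,
        label: str = "",
    ):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        n = 0
        for chrom, (starts, ends) in by_chrom.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            if starts.shape != ends.shape:
                raise CoverageError(f"{chrom}: start/end arrays differ in length")
            if np.any(ends <= starts):
                raise CoverageError(f"{chrom}: fragments with end <= start")
            order = np.argsort(starts, kind="stable")
            self._by_chrom[chrom] = (starts[order], ends[order])
            n += len(starts)
        self.n_fragments = n
        self.total_mapped = total_mapped if total_mapped is not None else n
        if self.n_fragments > 0 and self.total_mapped < self.n_fragments:
            raise CoverageError("total_mapped < number of fragments")
        self.label = label

    @classmethod
    def from_intervals(
        cls,
        fragments: Sequence[GenomicInterval],
        total_mapped: int | None = None,
        label: str = "",
    ) -> "FragmentSet":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for f in fragments:
            by_chrom.setdefault(f.chrom, []).append((f.start, f.end))
        arrays = {
            c: (
                np.array([s for s, _ in v], dtype=np.int64),
                np.array([e for _, e in v], dtype=np.int64),
            )
            for c, v in by_chrom.items()
        }
        return cls(arrays, total_mapped=total_mapped, label=label)

    @classmethod
    def read_bed(cls, path, label: str = "") -> "FragmentSet":
        starts: dict[str, list[int]] = {}
        ends: dict[str, list[int]] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = line.split("\t")
                starts.setdefault(f[0], []).append(int(f[1]))
                ends.setdefault(f[0], []).append(int(f[2]))
        arrays = {
            c: (np.array(starts[c], dtype=np.int64), np.array(ends[c], dtype=np.int64))
            for c in starts
        }
        return cls(arrays, label=label)

    def write_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self._by_chrom):
                s, e = self._by_chrom[chrom]
                for a, b in zip(s.tolist(), e.tolist()):
                    fh.write(f"{chrom}\t{a}\t{b}\n")

    def chroms(self):
        return self._by_chrom.keys()

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        if chrom in self._by_chrom:
            return self._by_chrom[chrom]
        empty = np.empty(0, dtype=np.int64)
        return empty, empty

    def count_in(self, chrom: str, start: int, end: int) -> int:
        """Number of fragments overlapping [start, end)."""
        s, e = self.arrays(chrom)
        if len(s) == 0:
            return 0
        e_sorted = np.sort(e)
        return int(np.searchsorted(s, end, "left") - np.searchsorted(e_sorted, start, "right"))


# ---------------------------------------------------------------------------
# BinnedTrack
# ---------------------------------------------------------------------------

@dataclass
class BinnedTrack:
    """Fixed-bin per-chromosome signal vectors.

    The last bin of each chromosome may cover fewer than ``bin_size`` bases.
    ``units`` is one of ``RPKM``, ``log2_ratio``, ``fraction``, ``count``.
    """

    genome: GenomeIndex
    bin_size: int
    values: dict[str, np.ndarray]
    units: str = "RPKM"

    def __post_init__(self) -> None:
        for chrom in self.genome:
            want = -(-self.genome[chrom] // self.bin_size)
            got = len(self.values.get(chrom, ()))
            if got != want:
                raise CoverageError(
                    f"{chrom}: expected {want} bins of {self.bin_size} bp, got {got}"
                )

    def n_bins(self, chrom: str) -> int:
        return len(self.values[chrom])

    def value_at(self, chrom: str, pos: int) -> float:
        return float(self.values[chrom][pos // self.bin_size])

    def concatenated(self) -> np.ndarray:
        return np.concatenate([self.values[c] for c in self.genome])

    def same_shape(self, other: "BinnedTrack") -> bool:
        return (
            self.bin_size == other.bin_size
            and list(self.genome) == list(other.genome)
            and all(self.genome[c] == other.genome[c] for c in self.genome)
        )

    def write_bedgraph(self, path) -> None:
        """4-column bedGraph with a metadata comment line (units, bin size)."""
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "wt") as fh:
            fh.write(f"# epidyn bedGraph units={self.units} bin_size={self.bin_size}\n")
            for chrom in self.genome:
                vals = self.values[chrom]
                L = self.genome[chrom]
                for i, v in enumerate(vals.tolist()):
                    fh.write(
                        f"{chrom}\t{i * self.bin_size}\t{min((i + 1) * self.bin_size, L)}\t{v:g}\n"
                    )

    @classmethod
    def read_bedgraph(cls, path, genome: GenomeIndex) -> "BinnedTrack":
        opener = gzip.open if str(path).endswith(".gz") else open
        units, bin_size = "RPKM", None
        rows: dict[str, list[tuple[int, float]]] = {}
        with opener(path, "rt") as fh:
            for line in fh:
                if line.startswith("#"):
                    for tok in line.split():
                        if tok.startswith("units="):
                            units = tok.split("=", 1)[1]
                        elif tok.startswith("bin_size="):
                            bin_size = int(tok.split("=", 1)[1])
                    continue
                chrom, start, _end, val = line.split("\t")
                rows.setdefault(chrom, []).append((int(start), float(val)))
        if bin_size is None:
            raise CoverageError("bedGraph lacks the epidyn bin_size metadata line")
        values = {}
        for chrom in genome:
            n = -(-genome[chrom] // bin_size)
            arr = np.zeros(n)
            for start, val in rows.get(chrom, []):
                arr[start // bin_size] = val
            values[chrom] = arr
        return cls(genome, bin_size, values, units=units)


def rpkm_track(frags: FragmentSet, genome: GenomeIndex, bin_size: int) -> BinnedTrack:
    """Binned coverage normalised to reads per kilobase per million mapped.

    A fragment increments every bin it overlaps, then each bin count is
    scaled by ``1e9 / (bin_size * total_mapped)``.
    """
    if bin_size < 1:
        raise CoverageError("bin_size must be >= 1")
    if frags.total_mapped == 0:
        raise CoverageError("total_mapped is zero; cannot normalise to RPKM")
    scale = 1e9 / (bin_size * frags.total_mapped)
    values = {}
    for chrom in genome:
        n = -(-genome[chrom] // bin_size)
        counts = np.zeros(n + 1)
        s, e = frags.arrays(chrom)
        if len(s):
            first = np.clip(s // bin_size, 0, n - 1)
            last = np.clip((e - 1) // bin_size, 0, n - 1)
            np.add.at(counts, first, 1.0)
            np.add.at(counts, last + 1, -1.0)
            counts = np.cumsum(counts)
        values[chrom] = counts[:n] * scale
    return BinnedTrack(genome, bin_size, values, units="RPKM")


def binned_count_track(frags: FragmentSet, genome: GenomeIndex, bin_size: int) -> BinnedTrack:
    """Raw fragment-overlap counts per bin (units ``count``)."""
    t = rpkm_track(frags, genome, bin_size)
    scale = 1e9 / (bin_size * frags.total_mapped)
    return BinnedTrack(
        genome, bin_size, {c: v / scale for c, v in t.values.items()}, units="count"
    )


def log2_ratio_track(
    chip: BinnedTrack, input_: BinnedTrack, pseudocount: float = 0.5
) -> BinnedTrack:
    """log2((chip + pc) / (input + pc)) per bin; equal tracks give all zeros."""
    if not chip.same_shape(input_):
        raise CoverageError("chip and input tracks differ in genome or bin size")
    values = {
        c: np.log2((chip.values[c] + pseudocount) / (input_.values[c] + pseudocount))
        for c in chip.genome
    }
    return BinnedTrack(chip.genome, chip.bin_size, values, units="log2_ratio")


# ---------------------------------------------------------------------------
# Meta-profile matrices
# ---------------------------------------------------------------------------

@dataclass
class MetaProfileMatrix:
    """Rows = regions/genes, columns = positional bins (5'-most first).

    Minus-strand rows are flipped on construction so column 0 is always the
    5'-most position. Cells outside chromosome bounds are NaN and excluded
    from column means.
    """

    row_ids: list[str]
    values: np.ndarray  # (n_rows, n_cols), NaN = missing
    coords: np.ndarray  # per-column coordinate axis (bp rel. to anchor / body fraction)
    bin_size: int
    mode: str  # "reference_point" | "scaled_region"

    def column_means(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(self.values, axis=0)

    def write_tsv(self, path) -> None:
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "wt") as fh:
            fh.write("row_id\t" + "\t".join(f"{c:g}" for c in self.coords) + "\n")
            for rid, row in zip(self.row_ids, self.values):
                fh.write(rid + "\t" + "\t".join(f"{v:g}" for v in row) + "\n")


def _range_mean(csum: np.ndarray, nbins: int, lo_bin: int, hi_bin: int) -> float:
    """Mean of track bins [lo_bin, hi_bin); NaN if fully out of range."""
    lo = max(lo_bin, 0)
    hi = min(hi_bin, nbins)
    if hi <= lo:
        return np.nan
    return (csum[hi] - csum[lo]) / (hi - lo)


def reference_point_matrix(
    track: BinnedTrack,
    regions: Sequence[GenomicInterval],
    flank: int,
    out_bins: int,
) -> MetaProfileMatrix:
    """Signal matrix centred on region midpoints, spanning +/-``flank`` bp.

    Each of the ``out_bins`` columns is the mean of the track bins it covers;
    minus-strand rows are reversed. Positions beyond chromosome ends are NaN.
    """
    if not regions:
        raise CoverageError("empty region list")
    if out_bins < 1 or flank < 1:
        raise CoverageError("flank and out_bins must be positive")
    col_w = 2 * flank / out_bins
    bs = track.bin_size
    rows = np.full((len(regions), out_bins), np.nan)
    ids = []
    csums = {c: np.concatenate(([0.0], np.cumsum(v))) for c, v in track.values.items()}
    j_arr = np.arange(out_bins)
    for i, r in enumerate(regions):
        ids.append(r.name or f"{r.chrom}:{r.start}-{r.end}")
        if r.chrom not in track.values:
            continue
        csum = csums[r.chrom]
        nb = track.n_bins(r.chrom)
        center = r.midpoint
        a = center - flank + j_arr * col_w
        b = a + col_w
        lo = np.floor(a / bs).astype(np.int64)
        hi = np.floor((b - 1) / bs).astype(np.int64) + 1
        lo_c = np.clip(lo, 0, nb)
        hi_c = np.clip(hi, 0, nb)
        width = hi_c - lo_c
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(width > 0, (csum[hi_c] - csum[lo_c]) / np.maximum(width, 1), np.nan)
        rows[i] = vals
        if r.strand == STRAND_MINUS:
            rows[i] = rows[i, ::-1]
    coords = (np.arange(out_bins) + 0.5) * col_w - flank
    return MetaProfileMatrix(ids, rows, coords, int(col_w), "reference_point")


def scaled_region_matrix(
    track: BinnedTrack,
    genes: Sequence[GeneModel],
    flank: int,
    body_bins: int,
    flank_bins: int,
) -> MetaProfileMatrix:
    """Gene-body meta-profile: upstream flank, body rescaled to a common
    width, downstream flank; rows strand-flipped so the TSS is always left.
    """
    if not genes:
        raise CoverageError("empty gene list")
    bs = track.bin_size
    flank_w = flank / flank_bins
    n_cols = body_bins + 2 * flank_bins
    rows = np.full((len(genes), n_cols), np.nan)
    ids = []
    csums = {c: np.concatenate(([0.0], np.cumsum(v))) for c, v in track.values.items()}
    for i, g in enumerate(genes):
        ids.append(g.gene_id)
        if g.chrom not in track.values:
            continue
        csum = csums[g.chrom]
        nb = track.n_bins(g.chrom)
        gs, ge = g.interval.start, g.interval.end
        # upstream flank (genomic left), body, downstream flank
        edges = (
            [gs - flank + k * flank_w for k in range(flank_bins)]
            + [gs + (ge - gs) * k / body_bins for k in range(body_bins)]
            + [ge + k * flank_w for k in range(flank_bins + 1)]
        )
        for j in range(n_cols):
            a, b = edges[j], edges[j + 1]
            lo = int(np.floor(a / bs))
            hi = int(np.floor((b - 1) / bs)) + 1
            if hi <= lo:  # gene shorter than body_bins bp: nearest-bin sample
                lo = int(np.floor((a + b) / 2 / bs))
                hi = lo + 1
            rows[i, j] = _range_mean(csum, nb, lo, hi)
        if g.strand == STRAND_MINUS:
            rows[i] = rows[i, ::-1]
    coords = np.concatenate(
        [
            -flank + (np.arange(flank_bins) + 0.5) * flank_w,
            (np.arange(body_bins) + 0.5) / body_bins,  # body fraction axis
            (np.arange(flank_bins) + 0.5) * flank_w,
        ]
    )
    return MetaProfileMatrix(ids, rows, coords, int(flank_w), "scaled_region")


def column_mean_profile(m: MetaProfileMatrix) -> np.ndarray:
    """Per-column mean over rows, ignoring missing (NaN) cells."""
    if m.values.size == 0:
        raise CoverageError("empty matrix")
    return m.column_means()


# ---------------------------------------------------------------------------
# Binned correlation
# ---------------------------------------------------------------------------

def _rebin(track: BinnedTrack, bin_size: int) -> np.ndarray:
    """Concatenated genome-wide vector, rebinned to ``bin_size`` by summing."""
    if bin_size % track.bin_size != 0:
        raise CoverageError("target bin_size must be a multiple of the track's")
    k = bin_size // track.bin_size
    parts = []
    for chrom in track.genome:
        v = track.values[chrom]
        pad = (-len(v)) % k
        vv = np.concatenate([v, np.zeros(pad)])
        parts.append(vv.reshape(-1, k).sum(axis=1))
    return np.concatenate(parts)


def binned_correlation(
    tracks: Sequence[BinnedTrack],
    bin_size: int,
    method: str = "spearman",
    restrict_to: Sequence[GenomicInterval] | None = None,
) -> np.ndarray:
    """Pairwise track correlation after rebinning to ``bin_size`` by summation.

    Used for replicate concordance (e.g. 10 kb bins over protein-coding
    genes, 100 kb genome-wide). ``restrict_to`` masks bins that do not
    overlap the given intervals.
    """
    if len(tracks) < 2:
        raise CoverageError("need at least two tracks")
    if method not in ("pearson", "spearman"):
        raise CoverageError(f"unknown method {method!r}")
    base = tracks[0]
    for t in tracks[1:]:
        if not t.same_shape(base):
            raise CoverageError("tracks differ in genome or bin size")
    data = np.vstack([_rebin(t, bin_size) for t in tracks])
    if restrict_to is not None:
        mask = np.zeros(data.shape[1], dtype=bool)
        offset = 0
        for chrom in base.genome:
            n = -(-base.genome[chrom] // bin_size)
            for iv in restrict_to:
                if iv.chrom == chrom:
                    lo = iv.start // bin_size
                    hi = min((iv.end - 1) // bin_size + 1, n)
                    mask[offset + lo : offset + hi] = True
            offset += n
        data = data[:, mask]
    if data.shape[1] < 3:
        raise CoverageError("fewer than 3 usable bins")
    if method == "spearman":
        data = np.vstack([stats.rankdata(row) for row in data])
    mat = np.corrcoef(data)
    np.fill_diagonal(mat, 1.0)
    return mat


# ---------------------------------------------------------------------------
# Simplified enrichment peak caller
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakCall:
    interval: GenomicInterval
    fold_enrichment: float
    p_value: float
    q_value: float


def _window_counts(frags: FragmentSet, chrom: str, starts: np.ndarray, width: int) -> np.ndarray:
    """Fragment midpoints falling in each window [start, start+width).

    Midpoint counting keeps the expected count exactly proportional to the
    window width, so background rates estimated at one scale transfer
    linearly to another (overlap counting would inflate narrow windows by
    the fragment length).
    """
    s, e = frags.arrays(chrom)
    if len(s) == 0:
        return np.zeros(len(starts))
    mids = np.sort((s + e) // 2)
    return (
        np.searchsorted(mids, starts + width, "left")
        - np.searchsorted(mids, starts, "left")
    ).astype(float)


def call_enriched_peaks(
    treat: FragmentSet,
    ctrl: FragmentSet | None,
    genome: GenomeIndex,
    window: int = 300,
    step: int = 100,
    q_max: float = 0.05,
) -> list[PeakCall]:
    """Sliding-window Poisson peak caller with a local background rate.

    For each window, the treatment fragment count is tested against a
    Poisson null whose rate is the maximum of the genome-wide, 1 kb and
    10 kb control rates (scaled to treatment depth) — a simplified analogue
    of local-lambda peak calling. Window p-values are Benjamini-Hochberg
    corrected; significant windows that overlap or abut are merged, and each
    merged peak reports the strongest member window's fold enrichment and
    smallest p/q.
    """
    if window < step:
        raise CoverageError("window must be >= step")
    use_ctrl = ctrl is not None and ctrl.n_fragments > 0
    if not use_ctrl:
        warnings.warn("empty control: background estimated from treatment")
        ctrl = treat
    scale = treat.n_fragments / ctrl.n_fragments
    glam = ctrl.n_fragments * scale * window / genome.total_length

    per_chrom: list[tuple[str, np.ndarray, np.ndarray, np.ndarray]] = []
    all_p: list[np.ndarray] = []
    for chrom in genome:
        L = genome[chrom]
        starts = np.arange(0, max(L - window, 0) + 1, step, dtype=np.int64)
        if len(starts) == 0:
            starts = np.array([0], dtype=np.int64)
        t_cnt = _window_counts(treat, chrom, starts, window)
        lam1 = _window_counts(ctrl, chrom, np.maximum(starts + window // 2 - 500, 0), 1000)
        lam10 = _window_counts(ctrl, chrom, np.maximum(starts + window // 2 - 5000, 0), 10000)
        lam = np.maximum.reduce(
            [
                np.full(len(starts), glam),
                lam1 * scale * window / 1000,
                lam10 * scale * window / 10000,
            ]
        )
        lam = np.maximum(lam, 1e-9)
        p = stats.poisson.sf(t_cnt - 1, lam)  # P(X >= count)
        per_chrom.append((chrom, starts, t_cnt, lam))
        all_p.append(p)
    pvals = np.concatenate(all_p)
    qvals = stats.false_discovery_control(pvals, method="bh")

    peaks: list[PeakCall] = []
    offset = 0
    for chrom, starts, t_cnt, lam in per_chrom:
        n = len(starts)
        q = qvals[offset : offset + n]
        p = pvals[offset : offset + n]
        offset += n
        sig = np.flatnonzero(q <= q_max)
        if len(sig) == 0:
            continue
        fold = t_cnt / lam
        # merge overlapping/adjacent significant windows
        run_start = sig[0]
        prev = sig[0]
        runs = []
        for idx in sig[1:]:
            if starts[idx] <= starts[prev] + window:  # overlap or abut
                prev = idx
            else:
                runs.append((run_start, prev))
                run_start = prev = idx
        runs.append((run_start, prev))
        L = genome[chrom]
        for a, b in runs:
            members = sig[(sig >= a) & (sig <= b)]
            best = members[np.argmax(fold[members])]
            peaks.append(
                PeakCall(
                    interval=GenomicInterval(
                        chrom, int(starts[a]), min(int(starts[b]) + window, L)
                    ),
                    fold_enrichment=float(fold[best]),
                    p_value=float(max(p[members].min(), np.nextafter(0, 1))),
                    q_value=float(max(q[members].min(), np.nextafter(0, 1))),
                )
            )
    return peaks


def write_peaks(path, peaks: Sequence[PeakCall]) -> None:
    """narrowPeak-style BED6+: name, fold, strand, then fold/p/q columns."""
    with open(path, "w") as fh:
        for i, pk in enumerate(peaks):
            iv = pk.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak_{i + 1}\t"
                f"{min(pk.fold_enrichment * 10, 1000):.0f}\t.\t"
                f"{pk.fold_enrichment:.4f}\t{pk.p_value:.3e}\t{pk.q_value:.3e}\n"
            )


def read_peaks(path) -> list[PeakCall]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            fold = float(f[6]) if len(f) > 6 else 0.0
            p = float(f[7]) if len(f) > 7 else 1.0
            q = float(f[8]) if len(f) > 8 else 1.0
            out.append(
                PeakCall(GenomicInterval(f[0], int(f[1]), int(f[2]), name=f[3] if len(f) > 3 else ""), fold, p, q)
            )
    return out


def region_mean_signal(track: BinnedTrack, region: GenomicInterval) -> float:
    """Length-weighted mean track value over one region."""
    return feature_coverage_summary(track, {"_": [region]})["_"]


# ---------------------------------------------------------------------------
# Per-feature coverage summary
# ---------------------------------------------------------------------------

def feature_coverage_summary(
    track: BinnedTrack,
    features: Mapping[str, Sequence[GenomicInterval]],
) -> dict[str, float]:
    """Length-weighted mean track signal per feature label.

    Mirrors per-feature coverage comparisons (e.g. 5hmC RPKM over 5'UTRs,
    exons, introns, 3'UTRs and intergenic space). Labels with zero total
    length are dropped with a warning.
    """
    if not features:
        raise CoverageError("no feature sets given")
    bs = track.bin_size
    out: dict[str, float] = {}
    for label, ivs in features.items():
        total_len = 0
        total_sig = 0.0
        for iv in ivs:
            if iv.chrom not in track.values:
                continue
            v = track.values[iv.chrom]
            lo = iv.start // bs
            hi = (iv.end - 1) // bs + 1
            idx = np.arange(lo, min(hi, len(v)))
            bin_lo = idx * bs
            bin_hi = np.minimum(bin_lo + bs, track.genome[iv.chrom])
            w = np.minimum(bin_hi, iv.end) - np.maximum(bin_lo, iv.start)
            total_sig += float(np.dot(v[idx], w))
            total_len += int(w.sum())
        if total_len == 0:
            warnings.warn(f"feature {label!r} has zero total length; excluded")
            continue
        out[label] = total_sig / total_len
    return out
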