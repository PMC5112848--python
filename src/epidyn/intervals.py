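"""Genomic coordinate model and interval primitives.

All coordinates are 0-based, half-open (BED convention). GTF-style 1-based
input is converted on read. These types and operations underpin every other
module: 5hmC peaks, methylome segments, enhancers and gene models are all
:class:`GenomicInterval`-based, and the overlap rules used to compare peak
sets (reciprocal-overlap "common" peaks) or to place regions near genes
reduce to the primitives defined here.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

STRAND_PLUS = "+"
STRAND_MINUS = "-"
STRAND_UNKNOWN = "."

_VALID_STRANDS = {STRAND_PLUS, STRAND_MINUS, STRAND_UNKNOWN}


class BedParseError(ValueError):
    """Raised when a BED/GTF record cannot be interpreted."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic region.

    Parameters
    ----------
    chrom : chromosome name.
    start, end : 0-based half-open coordinates; ``0 <= start < end``.
    strand : '+', '-' or '.' (unknown).
    score : optional numeric score (BED column 5).
    name : optional identifier (BED column 4).
    """

    chrom: str
    start: int
    end: int
    strand: str = STRAND_UNKNOWN
    score: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals (0 if different chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> tuple[float, float]:
    """Overlap expressed as a fraction of each interval's own length.

    Two peaks are called "common" when both fractions reach the configured
    threshold (0.5 by default), i.e. they share at least half of their
    respective lengths.
    """
    ov = overlap_length(a, b)
    return ov / a.length(), ov / b.length()


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene model with exon structure.

    ``tss``/``tes`` are strand-aware: for a minus-strand gene the TSS is the
    last base of the interval. ``thick_start``/``thick_end`` delimit the CDS
    (BED12 thick coordinates); exonic sequence outside them forms the UTRs.
    """

    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    thick_start: int | None = None
    thick_end: int | None = None
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.interval.strand not in (STRAND_PLUS, STRAND_MINUS):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        prev_end = self.interval.start - 1
        for ex in self.exons:
            if ex.chrom != self.interval.chrom:
                raise ValueError(f"gene {self.gene_id}: exon on wrong chromosome")
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"gene {self.gene_id}: exon outside gene interval")
            if ex.start <= prev_end:
                raise ValueError(f"gene {self.gene_id}: exons overlap or unsorted")
            prev_end = ex.end - 1

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        if self.strand == STRAND_PLUS:
            return self.interval.start
        return self.interval.end - 1

    @property
    def tes(self) -> int:
        if self.strand == STRAND_PLUS:
            return self.interval.end - 1
        return self.interval.start

    def introns(self) -> tuple[GenomicInterval, ...]:
        """Gaps between consecutive exons; tiles the non-exonic gene body."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return tuple(out)

    def utr_intervals(self) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
        """(five_prime, three_prime) UTR sub-intervals derived from thick coords.

        Exonic sequence before ``thick_start`` / after ``thick_end`` is UTR;
        which end is 5' depends on strand. Genes without thick coordinates
        have no UTRs.
        """
        if self.thick_start is None or self.thick_end is None:
            return [], []
        left, right = [], []
        for ex in self.exons:
            if ex.start < self.thick_start:
                left.append(
                    GenomicInterval(
                        self.chrom, ex.start, min(ex.end, self.thick_start), self.strand
                    )
                )
            if ex.end > self.thick_end:
                right.append(
                    GenomicInterval(
                        self.chrom, max(ex.start, self.thick_end), ex.end, self.strand
                    )
                )
        if self.strand == STRAND_PLUS:
            return left, right
        return right, left


class GenomeIndex:
    """Ordered chromosome-name -> length map; validates interval bounds."""

    def __init__(self, sizes: dict[str, int] | Iterable[tuple[str, int]]):
        self._sizes: dict[str, int] = dict(sizes)
        for chrom, length in self._sizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom}: non-positive length {length}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._sizes

    def __getitem__(self, chrom: str) -> int:
        return self._sizes[chrom]

    def __iter__(self):
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def items(self):
        return self._sizes.items()

    @property
    def total_length(self) -> int:
        return sum(self._sizes.values())

    def validate(self, iv: GenomicInterval) -> None:
        if iv.chrom not in self._sizes:
            raise ValueError(f"unknown chromosome {iv.chrom}")
        if iv.end > self._sizes[iv.chrom]:
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {self._sizes[iv.chrom]}"
            )

    @classmethod
    def read_tsv(cls, path) -> "GenomeIndex":
        sizes = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                chrom, length = line.split("\t")[:2]
                sizes.append((chrom, int(length)))
        return cls(sizes)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, length in self._sizes.items():
                fh.write(f"{chrom}\t{length}\n")


# ---------------------------------------------------------------------------
# BED / GTF-lite parsing
# ---------------------------------------------------------------------------

def _int_field(value: str, line: str) -> int:
    try:
        return int(value)
    except ValueError as exc:
        raise BedParseError(f"non-integer coordinate {value!r} in line: {line!r}") from exc


def parse_bed_record(line: str, dialect: str = "bed6"):
    """Parse one BED line into a :class:`GenomicInterval` or :class:`GeneModel`.

    ``dialect`` is one of ``bed3``, ``bed6``, ``bed12``. BED12 records become
    gene models with exons reconstructed from block sizes/starts and UTRs
    from the thick coordinates.
    """
    if dialect not in ("bed3", "bed6", "bed12"):
        raise ValueError(f"unknown BED dialect {dialect!r}")
    fields = line.rstrip("\n").split("\t")
    need = {"bed3": 3, "bed6": 3, "bed12": 12}[dialect]
    if len(fields) < need:
        raise BedParseError(f"expected >= {need} fields, got {len(fields)}: {line!r}")
    chrom = fields[0]
    start = _int_field(fields[1], line)
    end = _int_field(fields[2], line)
    if start >= end:
        raise BedParseError(f"start >= end in line: {line!r}")
    name = fields[3] if len(fields) > 3 and dialect != "bed3" else ""
    score: float | None = None
    if len(fields) > 4 and dialect != "bed3" and fields[4] not in (".", ""):
        try:
            score = float(fields[4])
        except ValueError as exc:
            raise BedParseError(f"non-numeric score in line: {line!r}") from exc
    strand = STRAND_UNKNOWN
    if len(fields) > 5 and dialect != "bed3" and fields[5] in _VALID_STRANDS:
        strand = fields[5]

    if dialect != "bed12":
        return GenomicInterval(chrom, start, end, strand=strand, score=score, name=name)

    thick_start = _int_field(fields[6], line)
    thick_end = _int_field(fields[7], line)
    n_blocks = _int_field(fields[9], line)
    sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
    starts = [int(x) for x in fields[11].rstrip(",").split(",")]
    if len(sizes) != n_blocks or len(starts) != n_blocks:
        raise BedParseError(f"block count mismatch in line: {line!r}")
    exons = tuple(
        GenomicInterval(chrom, start + off, start + off + size, strand)
        for off, size in zip(starts, sizes)
    )
    return GeneModel(
        gene_id=name or f"{chrom}:{start}-{end}",
        interval=GenomicInterval(chrom, start, end, strand),
        exons=exons,
        thick_start=thick_start if thick_start < thick_end else None,
        thick_end=thick_end if thick_start < thick_end else None,
    )


def read_bed(path, dialect: str = "bed6") -> list:
    """Read a whole BED file; blank lines and ``#``/track lines are skipped."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            out.append(parse_bed_record(line, dialect))
    return out


def write_bed(path, intervals: Sequence[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            score = "." if iv.score is None else f"{iv.score:g}"
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t{iv.strand}\n"
            )


def write_bed12(path, genes: Sequence[GeneModel]) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e.length()) for e in g.exons)
            starts = ",".join(str(e.start - g.interval.start) for e in g.exons)
            ts = g.thick_start if g.thick_start is not None else g.interval.start
            te = g.thick_end if g.thick_end is not None else g.interval.start
            fh.write(
                f"{g.chrom}\t{g.interval.start}\t{g.interval.end}\t{g.gene_id}\t0\t"
                f"{g.strand}\t{ts}\t{te}\t0\t{len(g.exons)}\t{sizes},\t{starts},\n"
            )


def read_gtf_lite(path) -> list[GeneModel]:
    """Read a minimal 9-column GTF (1-based, converted to 0-based half-open).

    Only ``gene`` and ``exon`` features are used; genes are keyed by the
    ``gene_id "..."`` attribute. CDS features, when present, set the thick
    coordinates.
    """
    import re

    gene_rows: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise BedParseError(f"GTF line with <9 fields: {line!r}")
            chrom, _src, feat, start1, end1, _score, strand, _frame, attrs = f[:9]
            m = re.search(r'gene_id "([^"]+)"', attrs)
            if m is None:
                raise BedParseError(f"GTF line without gene_id: {line!r}")
            gid = m.group(1)
            start, end = int(start1) - 1, int(end1)
            row = gene_rows.setdefault(
                gid, {"chrom": chrom, "strand": strand, "exons": [], "cds": []}
            )
            if feat == "exon":
                row["exons"].append((start, end))
            elif feat == "CDS":
                row["cds"].append((start, end))
            elif feat == "gene":
                row["span"] = (start, end)
    genes = []
    for gid, row in gene_rows.items():
        exons = sorted(row["exons"])
        if not exons:
            continue
        span = row.get("span", (exons[0][0], exons[-1][1]))
        thick = None
        if row["cds"]:
            thick = (min(s for s, _ in row["cds"]), max(e for _, e in row["cds"]))
        genes.append(
            GeneModel(
                gene_id=gid,
                interval=GenomicInterval(row["chrom"], span[0], span[1], row["strand"]),
                exons=tuple(
                    GenomicInterval(row["chrom"], s, e, row["strand"]) for s, e in exons
                ),
                thick_start=thick[0] if thick else None,
                thick_end=thick[1] if thick else None,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.interval.start, g.gene_id))
    return genes


# ---------------------------------------------------------------------------
# Feature annotation
# ---------------------------------------------------------------------------

FEATURE_LABELS = ("promoter", "TES", "5'UTR", "3'UTR", "exon", "intron", "intergenic")


class FeatureAnnotator:
    """Assigns each region exactly one genomic-feature label by midpoint.

    Precedence: promoter > TES > 5'UTR > 3'UTR > exon > intron > intergenic,
    so that feature compositions over a peak set sum to 100%. The promoter
    window is TSS -``promoter_up``/+``promoter_down`` bp (strand-aware); the
    TES window is TES +/- ``tes_flank`` bp.
    """

    def __init__(
        self,
        genes: Sequence[GeneModel],
        promoter_up: int = 1000,
        promoter_down: int = 100,
        tes_flank: int = 1000,
    ):
        self.promoter_up = promoter_up
        self.promoter_down = promoter_down
        self.tes_flank = tes_flank
        self._by_chrom: dict[str, list[GeneModel]] = {}
        for g in sorted(genes, key=lambda g: (g.chrom, g.interval.start)):
            self._by_chrom.setdefault(g.chrom, []).append(g)
        self._starts = {
            c: [g.interval.start for g in gs] for c, gs in self._by_chrom.items()
        }
        # widest reach of any window beyond a gene span
        self._reach = max(promoter_up, promoter_down, tes_flank)

    def _candidates(self, chrom: str, pos: int) -> list[GeneModel]:
        genes = self._by_chrom.get(chrom, [])
        if not genes:
            return []
        starts = self._starts[chrom]
        hi = bisect.bisect_right(starts, pos + self._reach)
        out = []
        for g in genes[max(0, hi - 8) : hi]:  # genes are near-nonoverlapping
            if g.interval.end + self._reach > pos:
                out.append(g)
        return out

    def _promoter_window(self, g: GeneModel) -> tuple[int, int]:
        if g.strand == STRAND_PLUS:
            return g.tss - self.promoter_up, g.tss + self.promoter_down + 1
        return g.tss - self.promoter_down, g.tss + self.promoter_up + 1

    def annotate(self, region: GenomicInterval) -> str:
        pos = region.midpoint
        cands = self._candidates(region.chrom, pos)
        if not cands:
            return "intergenic"
        hits: set[str] = set()
        for g in cands:
            lo, hi = self._promoter_window(g)
            if lo <= pos < hi:
                hits.add("promoter")
            if g.tes - self.tes_flank <= pos <= g.tes + self.tes_flank:
                hits.add("TES")
            utr5, utr3 = g.utr_intervals()
            if any(u.contains(pos) for u in utr5):
                hits.add("5'UTR")
            if any(u.contains(pos) for u in utr3):
                hits.add("3'UTR")
            if any(e.contains(pos) for e in g.exons):
                hits.add("exon")
            if g.interval.contains(pos):
                hits.add("intron")  # downgraded below if an exon hit exists
        for label in ("promoter", "TES", "5'UTR", "3'UTR", "exon", "intron"):
            if label in hits:
                return label
        return "intergenic"

    def annotate_all(self, regions: Sequence[GenomicInterval]) -> list[str]:
        return [self.annotate(r) for r in regions]


def annotate_interval(
    x: GenomicInterval,
    genes: Sequence[GeneModel],
    promoter_up: int = 1000,
    promoter_down: int = 100,
    tes_flank: int = 1000,
) -> str:
    """One-shot feature annotation; see :class:`FeatureAnnotator`."""
    if not genes:
        warnings.warn("empty gene list: everything is intergenic")
        return "intergenic"
    return FeatureAnnotator(genes, promoter_up, promoter_down, tes_flank).annotate(x)


def feature_composition(labels: Iterable[str]) -> dict[str, float]:
    """Fraction of regions per feature label (sums to 1)."""
    labels = list(labels)
    n = len(labels)
    return {lab: labels.count(lab) / n for lab in FEATURE_LABELS if n}


# ---------------------------------------------------------------------------
# Random matched background regions
# ---------------------------------------------------------------------------

def random_matched_regions(
    template: Sequence[GenomicInterval],
    genome: GenomeIndex,
    seed: int,
) -> list[GenomicInterval]:
    """Length-matched random background regions.

    Returns exactly ``len(template)`` intervals whose length multiset equals
    the template's. Each region is placed uniformly over all valid start
    positions genome-wide (chromosomes weighted by their number of valid
    starts), mirroring shuffled-background controls for peak annotation.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    chroms = list(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=np.int64)
    out = []
    for tmpl in template:
        L = tmpl.length()
        valid = lengths - L + 1
        valid = np.maximum(valid, 0)
        if valid.sum() == 0:
            raise ValueError(
                f"template length {L} exceeds every chromosome in the genome"
            )
        ci = rng.choice(len(chroms), p=valid / valid.sum())
        start = int(rng.integers(0, valid[ci]))
        out.append(GenomicInterval(chroms[ci], start, start + L, name=tmpl.name))
    return out


# ---------------------------------------------------------------------------
# Gene proximity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneDistance:
    gene_id: str
    distance: int  # unsigned distance used for ranking (0 inside gene body)
    signed: int  # midpoint - TSS in genomic coordinates


class GeneProximityIndex:
    """Per-chromosome TSS index for nearest-gene queries."""

    def __init__(self, genes: Sequence[GeneModel]):
        self._by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)
        self._tss_sorted: dict[str, tuple[np.ndarray, list[GeneModel]]] = {}
        for chrom, gs in self._by_chrom.items():
            gs_sorted = sorted(gs, key=lambda g: (g.tss, g.gene_id))
            self._tss_sorted[chrom] = (
                np.array([g.tss for g in gs_sorted], dtype=np.int64),
                gs_sorted,
            )

    def nearest_two_genes(
        self, region: GenomicInterval, max_dist: int
    ) -> list[GeneDistance]:
        """The next and second-next genes within ``max_dist`` of the region.

        Distance is |region midpoint - gene TSS|, or 0 when the midpoint
        falls inside the gene body. Ties break lexicographically by gene id.
        """
        if region.chrom not in self._tss_sorted:
            return []
        tss, genes = self._tss_sorted[region.chrom]
        mid = region.midpoint
        lo = int(np.searchsorted(tss, mid - max_dist, side="left"))
        hi = int(np.searchsorted(tss, mid + max_dist, side="right"))
        cands: list[GeneDistance] = []
        seen = set()
        for g in genes[lo:hi]:
            d = 0 if g.interval.contains(mid) else abs(mid - g.tss)
            if d <= max_dist:
                cands.append(GeneDistance(g.gene_id, d, mid - g.tss))
                seen.add(g.gene_id)
        # genes whose body contains the midpoint but whose TSS is far away
        for g in genes[:lo] + genes[hi:]:
            if g.gene_id not in seen and g.interval.contains(mid):
                cands.append(GeneDistance(g.gene_id, 0, mid - g.tss))
        cands.sort(key=lambda gd: (gd.distance, gd.gene_id))
        return cands[:2]


def nearest_two_genes(
    region: GenomicInterval, genes: Sequence[GeneModel], max_dist: int
) -> list[GeneDistance]:
    """Convenience wrapper over :class:`GeneProximityIndex` for one region."""
    return GeneProximityIndex(genes).nearest_two_genes(region, max_dist)


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: overlapping/abutting members merged, sorted output."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda i: i.start)
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out
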