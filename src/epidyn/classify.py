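"""Dynamic-region classification between two developmental time points.

Implements the region definitions linking the neonatal (t1) and adult (t2)
epigenomes:

* common / t1-only / t2-only 5hmC peaks — reciprocal overlap of at least
  50% of each peak's own length;
* stable / new LMRs — a t2 LMR is *new* when it lost at least 30 percentage
  points of mean CpG methylation since t1, *stable* when it overlaps a t1
  LMR;
* cell-type-specific / constitutive LMRs — a target LMR overlapping the LMR
  set of no other cell type (specific) or of every other cell type
  (constitutive);
* demethylated / hypermethylated TSS-UMR genes — the gene's TSS (but not
  its TES) lies in a UMR whose methylation moved by at least 5 points;
* stable / new enhancers — from H3K4me1/H3K27ac peak presence and
  enrichment over input at both time points (1.3x / 4x rules).

Every label carries an evidence map holding exactly the quantities its rule
tested, so labels can be re-derived from evidence alone.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .intervals import GenomicInterval, GeneModel, overlap_length, reciprocal_overlap
from .segmentation import (
    CpGRecord,
    CpGTable,
    MethylomeSegment,
    NO_DATA,
    methylation_delta,
    LMR,
    UMR,
)

COMMON_PEAK = "common_peak"
T1_ONLY_PEAK = "t1_only_peak"
T2_ONLY_PEAK = "t2_only_peak"
STABLE_LMR = "stable_LMR"
NEW_LMR = "new_LMR"
UNCLASSIFIED_LMR = "unclassified_LMR"
SPECIFIC_LMR = "specific_LMR"
CONSTITUTIVE_LMR = "constitutive_LMR"
DEMETH_GENE = "demethylated_gene_UMR"
HYPERMETH_GENE = "hypermethylated_gene_UMR"
STABLE_ENHANCER = "stable_enhancer"
NEW_ENHANCER = "new_enhancer"


@dataclass(frozen=True)
class RegionClassLabel:
    interval: GenomicInterval
    label: str
    evidence: Mapping[str, object] = field(default_factory=dict)


@dataclass(frozen=True)
class ThresholdConfig:
    """All classification thresholds, with the published defaults."""

    reciprocal_min: float = 0.5
    new_lmr_loss_min: float = 30.0  # percentage points
    tss_umr_delta_min: float = 5.0  # percentage points
    enh_low_max: float = 1.3  # fold over input, neonatal, new enhancers
    enh_high_min: float = 4.0  # fold over input, adult, new enhancers
    gene_proximity: int = 100_000  # bp

    def __post_init__(self) -> None:
        if not self.enh_low_max < self.enh_high_min:
            raise ValueError("require enh_low_max < enh_high_min")
        for name in ("reciprocal_min", "new_lmr_loss_min", "tss_umr_delta_min",
                     "enh_low_max", "enh_high_min", "gene_proximity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def stable_enh_max_change(self) -> float:
        """Largest bidirectional fold change allowed in a stable enhancer.

        The minimal possible change in a new enhancer is enh_high_min /
        enh_low_max (= 4 / 1.3 by default); stable enhancers must change
        less than that.
        """
        return self.enh_high_min / self.enh_low_max


# ---------------------------------------------------------------------------
# Overlap helpers
# ---------------------------------------------------------------------------

class _IntervalIndex:
    """Sorted per-chromosome interval lists for overlap queries."""

    def __init__(self, intervals: Sequence[GenomicInterval]):
        self._by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            self._by_chrom.setdefault(iv.chrom, []).append(iv)
        self._starts: dict[str, list[int]] = {}
        self._max_len: dict[str, int] = {}
        for chrom, ivs in self._by_chrom.items():
            ivs.sort(key=lambda i: (i.start, i.end))
            self._starts[chrom] = [i.start for i in ivs]
            self._max_len[chrom] = max(i.length() for i in ivs)

    def overlapping(self, region: GenomicInterval) -> list[GenomicInterval]:
        ivs = self._by_chrom.get(region.chrom)
        if not ivs:
            return []
        starts = self._starts[region.chrom]
        lo = bisect.bisect_left(starts, region.start - self._max_len[region.chrom])
        hi = bisect.bisect_left(starts, region.end)
        return [iv for iv in ivs[lo:hi] if overlap_length(iv, region) > 0]

    def overlaps_any(self, region: GenomicInterval) -> bool:
        return bool(self.overlapping(region))


def _check_non_overlapping(intervals: Sequence[GenomicInterval], name: str) -> None:
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for ivs in by_chrom.values():
        ivs = sorted(ivs, key=lambda i: i.start)
        for a, b in zip(ivs, ivs[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"{name} contains overlapping intervals "
                    f"({a.chrom}:{a.start}-{a.end} vs {b.chrom}:{b.start}-{b.end}); "
                    "merge the set before classification"
                )


# ---------------------------------------------------------------------------
# Common peaks
# ---------------------------------------------------------------------------

def classify_common_peaks(
    set_t1: Sequence[GenomicInterval],
    set_t2: Sequence[GenomicInterval],
    cfg: ThresholdConfig | None = None,
) -> tuple[list[RegionClassLabel], list[RegionClassLabel], list[RegionClassLabel]]:
    """Partition two peak sets into (t1_only, common, t2_only).

    A t1 peak is *common* when some t2 peak shares at least
    ``cfg.reciprocal_min`` of both peaks' lengths; common peaks are reported
    once per qualifying t1 member. Each peak records its best partner
    (largest reciprocal overlap, ties to the leftmost partner).
    """
    cfg = cfg or ThresholdConfig()
    _check_non_overlapping(set_t1, "set_t1")
    _check_non_overlapping(set_t2, "set_t2")
    idx2 = _IntervalIndex(set_t2) if set_t2 else None
    idx1 = _IntervalIndex(set_t1) if set_t1 else None

    def best_partner(peak, idx):
        best = None
        best_key = None
        if idx is None:
            return None, (0.0, 0.0)
        for cand in idx.overlapping(peak):
            fa, fb = reciprocal_overlap(peak, cand)
            key = (min(fa, fb), -cand.start)  # max reciprocal, ties -> leftmost
            if best_key is None or key > best_key:
                best, best_key = (cand, (fa, fb)), key
        if best is None:
            return None, (0.0, 0.0)
        return best

    t1_only, common, t2_only = [], [], []
    for pk in set_t1:
        partner, fracs = best_partner(pk, idx2)
        ev = {
            "frac_self": fracs[0],
            "frac_partner": fracs[1],
            "partner": None if partner is None else f"{partner.chrom}:{partner.start}-{partner.end}",
            "reciprocal_min": cfg.reciprocal_min,
        }
        if partner is not None and min(fracs) >= cfg.reciprocal_min:
            common.append(RegionClassLabel(pk, COMMON_PEAK, ev))
        else:
            t1_only.append(RegionClassLabel(pk, T1_ONLY_PEAK, ev))
    for pk in set_t2:
        partner, fracs = best_partner(pk, idx1)
        if partner is None or min(fracs) < cfg.reciprocal_min:
            t2_only.append(
                RegionClassLabel(
                    pk,
                    T2_ONLY_PEAK,
                    {
                        "frac_self": fracs[0],
                        "frac_partner": fracs[1],
                        "partner": None,
                        "reciprocal_min": cfg.reciprocal_min,
                    },
                )
            )
    return t1_only, common, t2_only


# ---------------------------------------------------------------------------
# LMR dynamics and cell specificity
# ---------------------------------------------------------------------------

def lmr_dynamics(
    lmrs_t2: Sequence[MethylomeSegment],
    lmrs_t1: Sequence[MethylomeSegment],
    cpgs_t1: Sequence[CpGRecord] | CpGTable,
    cpgs_t2: Sequence[CpGRecord] | CpGTable,
    cfg: ThresholdConfig | None = None,
) -> list[RegionClassLabel]:
    """Label each adult (t2) LMR as new, stable or unclassified.

    new_LMR: methylation loss of at least ``new_lmr_loss_min`` points since
    t1 (takes precedence). stable_LMR: overlaps (>= 1 bp) any t1 LMR.
    """
    cfg = cfg or ThresholdConfig()
    t1_table = cpgs_t1 if isinstance(cpgs_t1, CpGTable) else CpGTable(cpgs_t1)
    t2_table = cpgs_t2 if isinstance(cpgs_t2, CpGTable) else CpGTable(cpgs_t2)
    idx1 = _IntervalIndex([s.interval for s in lmrs_t1]) if lmrs_t1 else None
    out = []
    for seg in lmrs_t2:
        region = seg.interval
        delta = methylation_delta(region, t1_table, t2_table)
        partners = idx1.overlapping(region) if idx1 is not None else []
        partner = (
            f"{partners[0].chrom}:{partners[0].start}-{partners[0].end}"
            if partners
            else None
        )
        if delta is NO_DATA:
            warnings.warn(
                f"LMR {region.chrom}:{region.start}-{region.end}: missing CpG data"
            )
            label = UNCLASSIFIED_LMR
            ev = {"delta_meth": None, "overlaps_t1_lmr": bool(partners), "partner": partner}
        else:
            ev = {
                "delta_meth": delta,
                "overlaps_t1_lmr": bool(partners),
                "partner": partner,
                "new_lmr_loss_min": cfg.new_lmr_loss_min,
            }
            if delta <= -cfg.new_lmr_loss_min:
                label = NEW_LMR
            elif partners:
                label = STABLE_LMR
            else:
                label = UNCLASSIFIED_LMR
        out.append(RegionClassLabel(region, label, ev))
    return out


def lmr_cell_specificity(
    target_lmrs: Sequence[MethylomeSegment],
    other_sets: Sequence[Sequence[MethylomeSegment]],
) -> list[RegionClassLabel]:
    """Specific vs constitutive LMRs against other cell types' LMR sets.

    specific_LMR: overlaps no other set; constitutive_LMR: overlaps at least
    one LMR in *every* other set; anything in between gets no label (label
    ``None`` entries are omitted from the result).
    """
    if not other_sets:
        raise ValueError("need at least one other LMR set")
    indexes = [
        _IntervalIndex([s.interval for s in st]) if st else None for st in other_sets
    ]
    out = []
    for seg in target_lmrs:
        hits = [idx is not None and idx.overlaps_any(seg.interval) for idx in indexes]
        ev = {"overlap_pattern": tuple(hits), "n_other_sets": len(other_sets)}
        if not any(hits):
            out.append(RegionClassLabel(seg.interval, SPECIFIC_LMR, ev))
        elif all(hits):
            out.append(RegionClassLabel(seg.interval, CONSTITUTIVE_LMR, ev))
    return out


# ---------------------------------------------------------------------------
# TSS-UMR gene classes
# ---------------------------------------------------------------------------

@dataclass
class TssUmrDiagnostics:
    excluded_tss_and_tes: int = 0
    conflicting_genes: list[str] = field(default_factory=list)


def tss_umr_gene_classes(
    umrs_t1: Sequence[MethylomeSegment],
    umrs_t2: Sequence[MethylomeSegment],
    genes: Sequence[GeneModel],
    cpgs_t1: Sequence[CpGRecord] | CpGTable,
    cpgs_t2: Sequence[CpGRecord] | CpGTable,
    cfg: ThresholdConfig | None = None,
) -> tuple[list[RegionClassLabel], TssUmrDiagnostics]:
    """Gene-level UMR dynamics at transcription start sites.

    demethylated_gene_UMR: the gene's TSS (not its TES) lies in an adult
    (t2) UMR that lost >= ``tss_umr_delta_min`` points of methylation.
    hypermethylated_gene_UMR: TSS (not TES) in a neonatal (t1) UMR that
    gained >= ``tss_umr_delta_min`` points. Genes qualifying for both are
    flagged in the diagnostics, not silently assigned; genes whose TSS and
    TES both fall in the UMR are excluded and tallied.
    """
    cfg = cfg or ThresholdConfig()
    t1_table = cpgs_t1 if isinstance(cpgs_t1, CpGTable) else CpGTable(cpgs_t1)
    t2_table = cpgs_t2 if isinstance(cpgs_t2, CpGTable) else CpGTable(cpgs_t2)
    idx_t1 = _IntervalIndex([s.interval for s in umrs_t1]) if umrs_t1 else None
    idx_t2 = _IntervalIndex([s.interval for s in umrs_t2]) if umrs_t2 else None
    diags = TssUmrDiagnostics()
    out = []

    def containing_umr(idx, chrom, pos):
        if idx is None:
            return None
        point = GenomicInterval(chrom, pos, pos + 1)
        hits = idx.overlapping(point)
        return hits[0] if hits else None

    for g in genes:
        calls = []
        for idx, table_pair, want_sign, label in (
            (idx_t2, (t1_table, t2_table), -1, DEMETH_GENE),
            (idx_t1, (t1_table, t2_table), +1, HYPERMETH_GENE),
        ):
            umr = containing_umr(idx, g.chrom, g.tss)
            if umr is None:
                continue
            if umr.contains(g.tes):
                diags.excluded_tss_and_tes += 1
                continue
            delta = methylation_delta(umr, *table_pair)
            if delta is NO_DATA:
                continue
            if want_sign * delta >= cfg.tss_umr_delta_min:
                calls.append(
                    RegionClassLabel(
                        umr,
                        label,
                        {
                            "gene_id": g.gene_id,
                            "delta_meth": delta,
                            "tss": g.tss,
                            "tss_umr_delta_min": cfg.tss_umr_delta_min,
                        },
                    )
                )
        if len(calls) == 2:
            diags.conflicting_genes.append(g.gene_id)
        elif len(calls) == 1:
            out.append(calls[0])
    return out, diags


# ---------------------------------------------------------------------------
# Enhancers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkEvidence:
    peak_t1: bool
    peak_t2: bool
    enrich_t1: float  # fold over input
    enrich_t2: float

    def __post_init__(self) -> None:
        if self.enrich_t1 <= 0 or self.enrich_t2 <= 0:
            raise ValueError("enrichment over input must be positive")

    @property
    def fold_change(self) -> float:
        return max(self.enrich_t2 / self.enrich_t1, self.enrich_t1 / self.enrich_t2)


@dataclass(frozen=True)
class EnhancerEvidence:
    region: GenomicInterval
    marks: Mapping[str, MarkEvidence]  # e.g. {"H3K4me1": ..., "H3K27ac": ...}


def enhancer_classes(
    evidence: Sequence[EnhancerEvidence],
    cfg: ThresholdConfig | None = None,
) -> list[RegionClassLabel]:
    """Classify candidate regions as new or stable enhancers.

    new_enhancer: adult peaks in both marks, with every mark below
    ``enh_low_max`` fold at t1 and above ``enh_high_min`` fold at t2.
    stable_enhancer: peaks in both marks at both time points, with every
    mark's bidirectional fold change below ``enh_high_min / enh_low_max``
    (the minimal possible change of a new enhancer). New takes precedence.
    Regions meeting neither rule are omitted.
    """
    cfg = cfg or ThresholdConfig()
    out = []
    for ev in evidence:
        marks = ev.marks
        ev_map = {
            f"{mark}_{k}": v
            for mark, me in marks.items()
            for k, v in (
                ("e_t1", me.enrich_t1),
                ("e_t2", me.enrich_t2),
                ("peak_t1", me.peak_t1),
                ("peak_t2", me.peak_t2),
            )
        }
        ev_map["enh_low_max"] = cfg.enh_low_max
        ev_map["enh_high_min"] = cfg.enh_high_min
        is_new = all(
            me.peak_t2 and me.enrich_t1 < cfg.enh_low_max and me.enrich_t2 > cfg.enh_high_min
            for me in marks.values()
        )
        is_stable = all(
            me.peak_t1 and me.peak_t2 and me.fold_change < cfg.stable_enh_max_change
            for me in marks.values()
        )
        if is_new:
            out.append(RegionClassLabel(ev.region, NEW_ENHANCER, ev_map))
        elif is_stable:
            out.append(RegionClassLabel(ev.region, STABLE_ENHANCER, ev_map))
    return out


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_labels_bed(path, labels: Sequence[RegionClassLabel]) -> None:
    """BED6+ with the class in the name field and evidence as key=value columns."""
    with open(path, "w") as fh:
        for lab in labels:
            iv = lab.interval
            extra = "\t".join(
                f"{k}={v}" for k, v in lab.evidence.items() if not isinstance(v, tuple)
            )
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{lab.label}\t0\t{iv.strand}"
                + (f"\t{extra}" if extra else "")
                + "\n"
            )
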