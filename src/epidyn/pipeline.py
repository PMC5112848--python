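"""End-to-end orchestration of the two-time-point epigenome analysis.

Runs the stages in order — coverage tracks, peak calling, common-peak
classification, feature annotation against a length-matched random
background, methylome segmentation, LMR/UMR/enhancer classification,
meta-profiles per class, and the regulation statistics — and bundles the
tabular outputs. A companion evaluation path scores every recovered class
against the planted truth of a synthetic epigenome.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import classify as cl
from .classify import EnhancerEvidence, MarkEvidence, ThresholdConfig
from .coverage import (
    BinnedTrack,
    FragmentSet,
    PeakCall,
    call_enriched_peaks,
    column_mean_profile,
    reference_point_matrix,
    region_mean_signal,
    rpkm_track,
)
from .intervals import (
    FeatureAnnotator,
    GenomeIndex,
    GenomicInterval,
    GeneModel,
    GeneProximityIndex,
    feature_composition,
    random_matched_regions,
    reciprocal_overlap,
)
from .regstats import (
    ContingencyTable2x2,
    RegulatedFraction,
    TestResult,
    chi_square_2x2,
    mann_whitney_u,
    regulated_fraction_near,
)
from .segmentation import (
    CpGTable,
    LMR,
    MethylomeSegment,
    SegmentationParams,
    UMR,
    classify_segments,
    segment_methylome,
)
from .simulate import (
    AUX_SAMPLES,
    COMMON_PEAK_K,
    CONSTITUTIVE_LMR_K,
    DEMETH_K,
    HYPERMETH_K,
    MARKS,
    NEW_ENH_K,
    NEW_LMR_K,
    SPECIFIC_LMR_K,
    STABLE_ENH_K,
    STABLE_LMR_K,
    T1_PEAK_K,
    T2_PEAK_K,
    SimulationConfig,
    SyntheticEpigenome,
    simulate_all,
)


@dataclass
class PipelineConfig:
    """Analysis settings; defaults mirror the published constants."""

    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    seg_params: SegmentationParams = field(default_factory=SegmentationParams)
    track_bin: int = 100
    profile_flank: int = 100_000
    profile_bins: int = 200
    peak_window: int = 300
    peak_step: int = 100
    peak_q_max: float = 0.05
    hmc_peak_min_fold: float = 6.0  # keep only strong compact 5hmC peaks
    log2_pseudocount: float = 0.5
    seed: int = 0


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------

def filtered_hmc_peaks(
    treat: FragmentSet,
    ctrl: FragmentSet,
    genome: GenomeIndex,
    pcfg: PipelineConfig,
) -> list[GenomicInterval]:
    """Call 5hmC peaks against input and keep strong-fold calls."""
    peaks = call_enriched_peaks(
        treat, ctrl, genome, pcfg.peak_window, pcfg.peak_step, pcfg.peak_q_max
    )
    return [
        pk.interval for pk in peaks if pk.fold_enrichment >= pcfg.hmc_peak_min_fold
    ]


def segment_and_classify(table: CpGTable, params: SegmentationParams):
    """(all segments, LMR-class segments, UMR-class segments)."""
    segs = classify_segments(segment_methylome(table, params), params)
    lmrs = [s for s in segs if s.seg_class == LMR]
    umrs = [s for s in segs if s.seg_class == UMR]
    return segs, lmrs, umrs


def build_enhancer_evidence(
    chip: Mapping[tuple[str, str], tuple[FragmentSet, FragmentSet]],
    genome: GenomeIndex,
    pcfg: PipelineConfig,
) -> list[EnhancerEvidence]:
    """Candidate enhancers from adult H3K4me1 peaks (intersected with adult
    H3K27ac where both exist), with per-mark/time-point peak presence and
    RPKM enrichment over input."""
    peaks: dict[tuple[str, str], list[PeakCall]] = {}
    tracks: dict[tuple[str, str], tuple[BinnedTrack, BinnedTrack]] = {}
    bg_factor: dict[tuple[str, str], float] = {}
    for (mark, tp), (treat, ctrl) in chip.items():
        pk = call_enriched_peaks(
            treat, ctrl, genome, pcfg.peak_window, pcfg.peak_step, pcfg.peak_q_max
        )
        peaks[(mark, tp)] = pk
        tr_c = rpkm_track(treat, genome, pcfg.track_bin)
        tr_i = rpkm_track(ctrl, genome, pcfg.track_bin)
        tracks[(mark, tp)] = (tr_c, tr_i)
        # background normalisation: depth normalisation alone understates
        # enrichment when a noticeable share of the library sits in peaks,
        # so rescale by the chip/input ratio over non-peak bins
        mask = {c: np.zeros(tr_c.n_bins(c), dtype=bool) for c in genome}
        for p in pk:
            iv = p.interval
            mask[iv.chrom][iv.start // pcfg.track_bin : -(-iv.end // pcfg.track_bin)] = True
        num = den = 0.0
        for c in genome:
            keep = ~mask[c]
            num += float(tr_c.values[c][keep].sum())
            den += float(tr_i.values[c][keep].sum())
        bg_factor[(mark, tp)] = num / den if den > 0 else 1.0

    k27_adult = [pk.interval for pk in peaks[(MARKS[1], "t2")]]
    evidence = []
    for pk in peaks[(MARKS[0], "t2")]:
        region = pk.interval
        for other in k27_adult:
            if other.chrom == region.chrom and min(
                other.end, region.end
            ) > max(other.start, region.start):
                region = GenomicInterval(
                    region.chrom,
                    max(region.start, other.start),
                    min(region.end, other.end),
                )
                break
        marks = {}
        for mark in MARKS:
            pres = {}
            enr = {}
            for tp in ("t1", "t2"):
                pres[tp] = any(
                    p.interval.chrom == region.chrom
                    and min(p.interval.end, region.end) > max(p.interval.start, region.start)
                    for p in peaks[(mark, tp)]
                )
                chip_tr, inp_tr = tracks[(mark, tp)]
                pc = pcfg.log2_pseudocount
                enr[tp] = (
                    (region_mean_signal(chip_tr, region) + pc)
                    / (region_mean_signal(inp_tr, region) + pc)
                    / bg_factor[(mark, tp)]
                )
            marks[mark] = MarkEvidence(pres["t1"], pres["t2"], enr["t1"], enr["t2"])
        evidence.append(EnhancerEvidence(region, marks))
    return evidence


@dataclass
class ProfileStats:
    center_mean: float
    flank_mean: float
    boundary_max: float

    @property
    def center_flank_ratio(self) -> float:
        return self.center_mean / self.flank_mean

    @property
    def bimodal(self) -> bool:
        return self.center_mean < self.boundary_max


def profile_center_flank(
    profile: np.ndarray, coords: np.ndarray, boundary_reach: int = 5000
) -> ProfileStats:
    """Summarise a mean meta-profile: the two central columns, the outermost
    20 columns per side (flank baseline), and the maximum over columns
    within ``boundary_reach`` of the centre excluding the central pair."""
    n = len(profile)
    centre = profile[n // 2 - 1 : n // 2 + 1].mean()
    flank = np.concatenate([profile[:20], profile[-20:]]).mean()
    near = (np.abs(coords) <= boundary_reach)
    near[n // 2 - 1 : n // 2 + 1] = False
    boundary = profile[near].max() if near.any() else np.nan
    return ProfileStats(float(centre), float(flank), float(boundary))


# ---------------------------------------------------------------------------
# Truth matching / evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassEval:
    n_pred: int
    n_truth: int
    n_matched: int

    @property
    def precision(self) -> float:
        return self.n_matched / self.n_pred if self.n_pred else 0.0

    @property
    def recall(self) -> float:
        return self.n_matched / self.n_truth if self.n_truth else 0.0


def match_regions(
    pred: Sequence[GenomicInterval],
    truth: Sequence[GenomicInterval],
    min_reciprocal: float = 0.5,
) -> ClassEval:
    """1-1 greedy matching of predicted to truth regions at a reciprocal
    overlap threshold; precision over predictions, recall over truth."""
    used: set[int] = set()
    truth_by_chrom: dict[str, list[tuple[int, GenomicInterval]]] = {}
    for i, iv in enumerate(truth):
        truth_by_chrom.setdefault(iv.chrom, []).append((i, iv))
    matched = 0
    for p in pred:
        best = None
        for i, tiv in truth_by_chrom.get(p.chrom, []):
            if i in used:
                continue
            fa, fb = reciprocal_overlap(p, tiv)
            if min(fa, fb) >= min_reciprocal and (best is None or min(fa, fb) > best[1]):
                best = (i, min(fa, fb))
        if best is not None:
            used.add(best[0])
            matched += 1
    return ClassEval(len(pred), len(truth), matched)


def match_gene_sets(pred_ids: Sequence[str], truth_ids: Sequence[str]) -> ClassEval:
    pred_set, truth_set = set(pred_ids), set(truth_ids)
    return ClassEval(len(pred_set), len(truth_set), len(pred_set & truth_set))


# ---------------------------------------------------------------------------
# Full synthetic-epigenome analysis
# ---------------------------------------------------------------------------

@dataclass
class SyntheticAnalysisResult:
    seed: int
    class_evals: dict[str, ClassEval]
    frac_new: RegulatedFraction | None
    frac_stable: RegulatedFraction | None
    chi: TestResult | None
    mw_fold: TestResult | None
    hmc_new_lmr_t1: ProfileStats
    hmc_new_lmr_t2: ProfileStats
    hmc_stable_lmr_t1: ProfileStats
    hmc_stable_lmr_t2: ProfileStats
    peak_counts: dict[str, int]
    feature_tables: dict[str, pd.DataFrame]
    predicted: dict[str, list[GenomicInterval]]


def run_synthetic_analysis(
    cfg: SimulationConfig,
    pcfg: PipelineConfig | None = None,
    epi: SyntheticEpigenome | None = None,
) -> SyntheticAnalysisResult:
    """Simulate (or accept) a synthetic epigenome, run the full analysis,
    and score every recovered class against the planted truth."""
    pcfg = pcfg or PipelineConfig(seed=cfg.seed)
    if epi is None:
        epi = simulate_all(cfg)
    truth = epi.truth
    genome = truth.genome
    genes = truth.genes
    thr = pcfg.thresholds

    # --- 5hmC peaks and common-peak classification ------------------------
    peaks_t1 = filtered_hmc_peaks(epi.hmc["t1"], epi.hmc_input["t1"], genome, pcfg)
    peaks_t2 = filtered_hmc_peaks(epi.hmc["t2"], epi.hmc_input["t2"], genome, pcfg)
    t1_only, common, t2_only = cl.classify_common_peaks(peaks_t1, peaks_t2, thr)

    # --- feature annotation vs random background --------------------------
    annot = FeatureAnnotator(genes)
    all_peaks = peaks_t1 + [p for p in peaks_t2]
    comp_peaks = feature_composition(annot.annotate_all(all_peaks)) if all_peaks else {}
    random_bg = (
        random_matched_regions(all_peaks, genome, seed=pcfg.seed + 101)
        if all_peaks
        else []
    )
    comp_random = feature_composition(annot.annotate_all(random_bg)) if random_bg else {}

    # --- methylome segmentation -------------------------------------------
    table_t1 = CpGTable(epi.cpgs_t1)
    table_t2 = CpGTable(epi.cpgs_t2)
    _, lmrs_t1, umrs_t1 = segment_and_classify(table_t1, pcfg.seg_params)
    _, lmrs_t2, umrs_t2 = segment_and_classify(table_t2, pcfg.seg_params)
    aux_lmrs = []
    for s in AUX_SAMPLES:
        aux_table = CpGTable(truth.aux_methylomes[s])
        _, lm, _ = segment_and_classify(aux_table, pcfg.seg_params)
        aux_lmrs.append(lm)

    dyn = cl.lmr_dynamics(lmrs_t2, lmrs_t1, table_t1, table_t2, thr)
    new_lmrs = [d.interval for d in dyn if d.label == cl.NEW_LMR]
    stable_lmrs = [d.interval for d in dyn if d.label == cl.STABLE_LMR]

    spec_labels = cl.lmr_cell_specificity(lmrs_t2, aux_lmrs)
    specific = [s.interval for s in spec_labels if s.label == cl.SPECIFIC_LMR]
    constitutive = [s.interval for s in spec_labels if s.label == cl.CONSTITUTIVE_LMR]

    gene_labels, _diags = cl.tss_umr_gene_classes(
        umrs_t1, umrs_t2, genes, table_t1, table_t2, thr
    )
    demeth_ids = [l.evidence["gene_id"] for l in gene_labels if l.label == cl.DEMETH_GENE]
    hyper_ids = [l.evidence["gene_id"] for l in gene_labels if l.label == cl.HYPERMETH_GENE]

    # --- enhancers ---------------------------------------------------------
    evidence = build_enhancer_evidence(epi.chip, genome, pcfg)
    enh_labels = cl.enhancer_classes(evidence, thr)
    new_enh = [e.interval for e in enh_labels if e.label == cl.NEW_ENHANCER]
    stable_enh = [e.interval for e in enh_labels if e.label == cl.STABLE_ENHANCER]

    # --- meta-profiles at planted LMR classes ------------------------------
    hmc_rpkm = {
        tp: rpkm_track(epi.hmc[tp], genome, pcfg.track_bin) for tp in ("t1", "t2")
    }
    prof = {}
    for key, regions in ((NEW_LMR_K, truth.regions[NEW_LMR_K]),
                         (STABLE_LMR_K, truth.regions[STABLE_LMR_K])):
        for tp in ("t1", "t2"):
            m = reference_point_matrix(
                hmc_rpkm[tp], regions, pcfg.profile_flank, pcfg.profile_bins
            )
            prof[(key, tp)] = profile_center_flank(column_mean_profile(m), m.coords)

    # --- regulation statistics --------------------------------------------
    gene_index = GeneProximityIndex(genes)
    expr_map = {r.gene_id: r for r in epi.expression}
    frac_new = regulated_fraction_near(new_lmrs, gene_index, expr_map, thr.gene_proximity)
    frac_stable = regulated_fraction_near(
        stable_lmrs, gene_index, expr_map, thr.gene_proximity
    )
    chi = None
    if frac_new is not None and frac_stable is not None:
        chi = chi_square_2x2(
            ContingencyTable2x2(
                frac_new.n_up, frac_new.n_down, frac_stable.n_up, frac_stable.n_down
            )
        )

    def log2_folds(regions):
        ids = set()
        for r in regions:
            for gd in gene_index.nearest_two_genes(r, thr.gene_proximity):
                ids.add(gd.gene_id)
        return [
            np.log2((expr_map[g].fpkm_t2 + 1e-3) / (expr_map[g].fpkm_t1 + 1e-3))
            for g in ids
            if g in expr_map and expr_map[g].significant
        ]

    mw_fold = None
    folds_new, folds_stable = log2_folds(new_lmrs), log2_folds(stable_lmrs)
    if folds_new and folds_stable:
        mw_fold = mann_whitney_u(folds_new, folds_stable, "greater")

    # --- evaluation vs planted truth ---------------------------------------
    class_evals = {
        COMMON_PEAK_K: match_regions([c.interval for c in common], truth.regions[COMMON_PEAK_K]),
        T1_PEAK_K: match_regions([c.interval for c in t1_only], truth.regions[T1_PEAK_K]),
        T2_PEAK_K: match_regions([c.interval for c in t2_only], truth.regions[T2_PEAK_K]),
        NEW_LMR_K: match_regions(new_lmrs, truth.regions[NEW_LMR_K]),
        STABLE_LMR_K: match_regions(
            stable_lmrs,
            truth.regions[STABLE_LMR_K]
            + truth.regions[SPECIFIC_LMR_K]
            + truth.regions[CONSTITUTIVE_LMR_K],
        ),
        SPECIFIC_LMR_K: match_regions(
            specific, truth.regions[SPECIFIC_LMR_K] + truth.regions[NEW_LMR_K]
        ),
        CONSTITUTIVE_LMR_K: match_regions(constitutive, truth.regions[CONSTITUTIVE_LMR_K]),
        NEW_ENH_K: match_regions(new_enh, truth.regions[NEW_ENH_K]),
        STABLE_ENH_K: match_regions(stable_enh, truth.regions[STABLE_ENH_K]),
        DEMETH_K: match_gene_sets(demeth_ids, truth.gene_classes[DEMETH_K]),
        HYPERMETH_K: match_gene_sets(hyper_ids, truth.gene_classes[HYPERMETH_K]),
    }

    feature_tables = {
        "peak_feature_composition": pd.DataFrame(
            {"peaks": pd.Series(comp_peaks), "random": pd.Series(comp_random)}
        ),
    }

    return SyntheticAnalysisResult(
        seed=cfg.seed,
        class_evals=class_evals,
        frac_new=frac_new,
        frac_stable=frac_stable,
        chi=chi,
        mw_fold=mw_fold,
        hmc_new_lmr_t1=prof[(NEW_LMR_K, "t1")],
        hmc_new_lmr_t2=prof[(NEW_LMR_K, "t2")],
        hmc_stable_lmr_t1=prof[(STABLE_LMR_K, "t1")],
        hmc_stable_lmr_t2=prof[(STABLE_LMR_K, "t2")],
        peak_counts={
            "t1_peaks": len(peaks_t1),
            "t2_peaks": len(peaks_t2),
            "common": len(common),
            "t1_only": len(t1_only),
            "t2_only": len(t2_only),
        },
        feature_tables=feature_tables,
        predicted={
            NEW_LMR_K: new_lmrs,
            STABLE_LMR_K: stable_lmrs,
            SPECIFIC_LMR_K: specific,
            CONSTITUTIVE_LMR_K: constitutive,
            NEW_ENH_K: new_enh,
            STABLE_ENH_K: stable_enh,
        },
    )


def regulation_contrast_fast(cfg: SimulationConfig):
    """Planted-region regulation contrast without sequencing simulation.

    Builds only the genome, gene models, region placement and expression
    table, then measures the up-fractions near the planted new vs stable
    LMR sets and the chi-square comparison. Used to estimate the rejection
    rate over many seeds cheaply.
    """
    from .simulate import simulate_genome_and_genes, simulate_expression

    _genome, genes, truth = simulate_genome_and_genes(cfg)
    expr = simulate_expression(truth, cfg)
    index = GeneProximityIndex(genes)
    expr_map = {r.gene_id: r for r in expr}
    stable_like = (
        truth.regions[STABLE_LMR_K]
        + truth.regions[SPECIFIC_LMR_K]
        + truth.regions[CONSTITUTIVE_LMR_K]
    )
    frac_new = regulated_fraction_near(truth.regions[NEW_LMR_K], index, expr_map)
    frac_stable = regulated_fraction_near(stable_like, index, expr_map)
    chi = None
    if frac_new is not None and frac_stable is not None:
        chi = chi_square_2x2(
            ContingencyTable2x2(
                frac_new.n_up, frac_new.n_down, frac_stable.n_up, frac_stable.n_down
            )
        )
    return frac_new, frac_stable, chi


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------

def result_tables(res: SyntheticAnalysisResult) -> dict[str, pd.DataFrame]:
    """Flatten an analysis result into plot-ready tables."""
    rows = []
    for key, ev in res.class_evals.items():
        rows.append(
            {
                "class": key,
                "n_pred": ev.n_pred,
                "n_truth": ev.n_truth,
                "n_matched": ev.n_matched,
                "precision": ev.precision,
                "recall": ev.recall,
            }
        )
    tables = {"class_recovery": pd.DataFrame(rows)}

    stat_rows = []
    if res.frac_new is not None:
        stat_rows.append(
            {"quantity": "frac_up_near_new_lmr", "value": res.frac_new.frac_up,
             "n": res.frac_new.n}
        )
    if res.frac_stable is not None:
        stat_rows.append(
            {"quantity": "frac_up_near_stable_lmr", "value": res.frac_stable.frac_up,
             "n": res.frac_stable.n}
        )
    if res.chi is not None:
        stat_rows.append(
            {"quantity": "chi_square_statistic", "value": res.chi.statistic, "n": 1}
        )
        stat_rows.append({"quantity": "chi_square_p", "value": res.chi.p_value, "n": 1})
    if res.mw_fold is not None:
        stat_rows.append(
            {"quantity": "mann_whitney_fold_p", "value": res.mw_fold.p_value, "n": 1}
        )
    tables["regulation_stats"] = pd.DataFrame(stat_rows)

    prof_rows = []
    for name, ps in (
        ("new_lmr_t1", res.hmc_new_lmr_t1),
        ("new_lmr_t2", res.hmc_new_lmr_t2),
        ("stable_lmr_t1", res.hmc_stable_lmr_t1),
        ("stable_lmr_t2", res.hmc_stable_lmr_t2),
    ):
        prof_rows.append(
            {
                "profile": name,
                "center_mean": ps.center_mean,
                "flank_mean": ps.flank_mean,
                "boundary_max": ps.boundary_max,
                "center_flank_ratio": ps.center_flank_ratio,
                "bimodal": ps.bimodal,
            }
        )
    tables["hmc_profiles"] = pd.DataFrame(prof_rows)
    tables["peak_counts"] = pd.DataFrame(
        [{"set": k, "count": v} for k, v in res.peak_counts.items()]
    )
    tables.update(res.feature_tables)
    return tables


def write_report(tables: Mapping[str, pd.DataFrame], outdir, provenance: dict | None = None):
    """One TSV per table plus a manifest listing every emitted file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for name, df in tables.items():
        path = outdir / f"{name}.tsv"
        df.to_csv(path, sep="\t")
        digest = hashlib.sha256(path.read_bytes()).hexdigest()[:16]
        manifest.append({"file": path.name, "table": name, "sha256_16": digest})
    prov = provenance or {}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump({"files": manifest, "provenance": prov}, fh, indent=1, sort_keys=True)
    return manifest
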