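"""Synthetic two-time-point epigenome with known ground truth.

Generates a small genome with non-overlapping gene models and plants every
region class the analysis is meant to recover:

* methylomes (per-CpG binomial counts over a planted mean-methylation
  landscape) for the two cardiomyocyte time points plus three auxiliary
  cell types, containing stable / new / cell-type-specific / constitutive
  LMRs and dynamic TSS-spanning UMRs;
* 5hmC fragment sets with TSS depletion, expression-coupled gene-body
  enrichment, neonatal centre enrichment at new LMRs and bimodal flank
  enrichment at stable LMRs, plus strong compact peaks (t1-only / common /
  t2-only) and matched uniform inputs;
* H3K4me1 / H3K27ac ChIP fragment sets in which planted new enhancers are
  ~1.1-fold over input neonatally and ~5-fold in the adult, and stable
  enhancers ~4-fold at both time points;
* an expression table in which the next and second-next genes of new LMRs
  are upregulated with probability 0.624 and all other significant genes
  with probability 0.491.

All draws are deterministic functions of the configured seed; each stage
uses its own child seed stream so stages can be re-run independently.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Sequence

import numpy as np

from .coverage import FragmentSet
from .intervals import (
    GeneModel,
    GenomeIndex,
    GenomicInterval,
    GeneProximityIndex,
)
from .regstats import DOWN, ExpressionRecord, NONE, UP
from .segmentation import CpGRecord

INTENSITY_BIN = 100  # bp; all planted coordinates snap to this grid

MARKS = ("H3K4me1", "H3K27ac")
TIMEPOINTS = ("t1", "t2")
AUX_SAMPLES = ("aux0", "aux1", "aux2")  # stand-ins for ESC / fibroblast / neuron

# truth class keys
STABLE_LMR_K = "stable_lmr"
NEW_LMR_K = "new_lmr"
SPECIFIC_LMR_K = "specific_lmr"
CONSTITUTIVE_LMR_K = "constitutive_lmr"
DEMETH_K = "demeth_gene_umr"
HYPERMETH_K = "hypermeth_gene_umr"
NEW_ENH_K = "new_enhancer"
STABLE_ENH_K = "stable_enhancer"
T1_PEAK_K = "t1_peak"
COMMON_PEAK_K = "common_peak"
T2_PEAK_K = "t2_peak"

REGION_CLASS_KEYS = (
    STABLE_LMR_K,
    NEW_LMR_K,
    SPECIFIC_LMR_K,
    CONSTITUTIVE_LMR_K,
    DEMETH_K,
    HYPERMETH_K,
    NEW_ENH_K,
    STABLE_ENH_K,
    T1_PEAK_K,
    COMMON_PEAK_K,
    T2_PEAK_K,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic epigenome (all values config keys).

    Defaults are sized for a desk-scale run: ~23 Mb genome, ~2,500 genes,
    ~2.5e5 CpGs and 1e6 fragments per sequencing sample, with planted class
    counts large enough to measure precision/recall and the regulation
    contrast (~250 significant genes near new LMRs vs ~1,600 elsewhere).
    """

    seed: int = 0
    # genome shape
    n_chroms: int = 2
    chrom_size: int = 11_500_000
    n_genes: int = 2500
    gene_length_min: int = 2000
    gene_length_max: int = 5000
    gap_length_min: int = 4600
    gap_length_max: int = 6000
    big_gap_length: int = 10_000
    # methylome
    cpg_spacing_mean: int = 100
    lmr_cpg_spacing: int = 60
    umr_cpg_spacing: int = 25
    coverage_mean: float = 20.0
    background_meth: float = 0.8
    umr_meth: float = 0.05
    lmr_meth: float = 0.30
    demeth_meth_t1: float = 0.12
    demeth_meth_t2: float = 0.04
    hypermeth_meth_t1: float = 0.04
    hypermeth_meth_t2: float = 0.65
    # planted class counts
    n_stable_lmr: int = 1000
    n_new_lmr: int = 150
    n_specific_lmr: int = 60
    n_constitutive_lmr: int = 60
    n_new_enhancer: int = 40
    n_stable_enhancer: int = 40
    n_demeth_gene: int = 60
    n_hypermeth_gene: int = 60
    n_t1_peak: int = 60
    n_common_peak: int = 80
    n_t2_peak: int = 60
    # planted region geometry
    lmr_length: int = 1500
    tss_umr_length: int = 2000
    tss_umr_upstream: int = 500
    peak_length: int = 1000
    enhancer_length: int = 7000
    new_lmr_buffer_gaps: int = 2  # gaps kept free of stable-type LMRs around each new LMR
    # expression / regulation
    p_up_near_new: float = 0.624
    p_up_background: float = 0.491
    significant_fraction: float = 0.95
    gene_proximity: int = 100_000
    fpkm_log_mean: float = 2.0  # ln FPKM ~ Normal(fpkm_log_mean, fpkm_log_sd)
    fpkm_log_sd: float = 2.0
    # 5hmC signal model
    hmc_gene_body_slope: float = 0.6  # enrichment per log10(1 + FPKM)
    hmc_center_fold: float = 3.0  # neonatal centre fold at new LMRs
    hmc_flank_fold: float = 2.0  # boundary fold at stable LMRs
    tss_depletion: float = 0.3
    peak_fold: float = 10.0
    # ChIP signal model
    enh_new_fold_t1: float = 1.1
    enh_new_fold_t2: float = 5.0
    enh_stable_fold: float = 4.0
    # sequencing
    fragment_length: int = 200
    depth: int = 1_000_000

    def __post_init__(self) -> None:
        for name in ("p_up_near_new", "p_up_background"):
            if not (0 < getattr(self, name) < 1):
                raise ValueError(f"{name} must be in (0,1)")
        if not (0 <= self.significant_fraction <= 1):
            raise ValueError("significant_fraction must be in [0,1]")
        for name in ("hmc_center_fold", "hmc_flank_fold", "peak_fold",
                     "enh_new_fold_t2", "enh_stable_fold"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.chrom_size % INTENSITY_BIN != 0:
            raise ValueError(f"chrom_size must be a multiple of {INTENSITY_BIN}")


@dataclass
class PlantedMethRegion:
    interval: GenomicInterval
    mu: dict[str, float]  # sample name -> mean methylation
    cpg_spacing: int
    class_key: str
    gene_id: str | None = None


@dataclass
class SyntheticTruth:
    """Planted ground truth, serialised alongside the generated data."""

    genome: GenomeIndex
    genes: list[GeneModel]
    regions: dict[str, list[GenomicInterval]]
    meth_regions: list[PlantedMethRegion]
    gene_classes: dict[str, list[str]]  # demeth/hypermeth gene ids
    painted_up_genes: list[str] = field(default_factory=list)
    expression: list[ExpressionRecord] | None = None
    aux_methylomes: dict[str, list[CpGRecord]] | None = None

    def to_json(self) -> str:
        payload = {
            "genome": dict(self.genome.items()),
            "regions": {
                k: [[iv.chrom, iv.start, iv.end, iv.name] for iv in v]
                for k, v in self.regions.items()
            },
            "gene_classes": self.gene_classes,
            "painted_up_genes": sorted(self.painted_up_genes),
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @staticmethod
    def regions_from_json(path) -> dict[str, list[GenomicInterval]]:
        with open(path) as fh:
            payload = json.load(fh)
        return {
            k: [GenomicInterval(c, s, e, name=n) for c, s, e, n in v]
            for k, v in payload["regions"].items()
        }


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed % (2**31), stream])


def _snap(x: int) -> int:
    return int(round(x / INTENSITY_BIN)) * INTENSITY_BIN


# ---------------------------------------------------------------------------
# Genome, genes and region placement
# ---------------------------------------------------------------------------

def _make_gene(rng, chrom, start, length, strand, gid) -> GeneModel:
    n_ex = int(rng.integers(2, 9))
    for _ in range(20):
        raw = rng.random(2 * n_ex - 1) + 0.3
        bounds = np.round(np.cumsum(raw) / raw.sum() * length).astype(int)
        bounds[-1] = length
        bounds = np.concatenate([[0], bounds])
        if np.all(np.diff(bounds) > 0):
            break
        n_ex = max(2, n_ex - 1)
    else:
        bounds = np.array([0, length // 2, length])  # 2 exons, no intron: degenerate
    exons = tuple(
        GenomicInterval(chrom, start + int(bounds[2 * k]), start + int(bounds[2 * k + 1]), strand)
        for k in range(n_ex)
    )
    thick_start = (exons[0].start + exons[0].end) // 2
    thick_end = (exons[-1].start + exons[-1].end) // 2
    return GeneModel(
        gene_id=gid,
        interval=GenomicInterval(chrom, start, start + length, strand),
        exons=exons,
        thick_start=thick_start,
        thick_end=thick_end,
    )


@dataclass
class _Gap:
    chrom: str
    start: int
    end: int
    big: bool
    chrom_idx: int  # position of the gap along its chromosome

    @property
    def length(self) -> int:
        return self.end - self.start

    def centred(self, length: int) -> GenomicInterval:
        mid = (self.start + self.end) // 2
        s = _snap(mid - length // 2)
        return GenomicInterval(self.chrom, s, s + length)


def simulate_genome_and_genes(
    cfg: SimulationConfig,
) -> tuple[GenomeIndex, list[GeneModel], SyntheticTruth]:
    """Lay out chromosomes, genes and every planted region class.

    Genes alternate strands and never overlap; each intergenic gap hosts at
    most one planted region, enhancers go to enlarged gaps, and gaps
    adjacent to new-LMR gaps are kept free of stable-type LMRs so that the
    regulated-gene samples near new and stable LMRs stay disjoint.
    """
    rng = _rng(cfg, 1)
    genome = GenomeIndex(
        {f"chr{i + 1}": cfg.chrom_size for i in range(cfg.n_chroms)}
    )
    per_chrom = [cfg.n_genes // cfg.n_chroms] * cfg.n_chroms
    per_chrom[0] += cfg.n_genes - sum(per_chrom)

    n_big = cfg.n_new_enhancer + cfg.n_stable_enhancer
    big_ids = set(
        rng.choice(cfg.n_genes, size=n_big, replace=False).tolist()
    )

    genes: list[GeneModel] = []
    gaps: list[_Gap] = []
    gid = 0
    for ci, chrom in enumerate(genome):
        cursor = 1000
        gap_idx = 0
        for _ in range(per_chrom[ci]):
            if gid in big_ids:
                gap_len = cfg.big_gap_length
            else:
                gap_len = int(rng.integers(cfg.gap_length_min, cfg.gap_length_max + 1))
            gap_len = _snap(gap_len)
            gaps.append(_Gap(chrom, cursor, cursor + gap_len, gid in big_ids, gap_idx))
            cursor += gap_len
            length = _snap(int(rng.integers(cfg.gene_length_min, cfg.gene_length_max + 1)))
            strand = "+" if gid % 2 == 0 else "-"
            if cursor + length > cfg.chrom_size - 1000:
                raise ValueError("genes do not fit in the configured genome")
            genes.append(_make_gene(rng, chrom, cursor, length, strand, f"gene{gid:05d}"))
            cursor += length
            gid += 1
            gap_idx += 1

    # --- assign planted regions to gaps -----------------------------------
    normal_ids = [i for i, g in enumerate(gaps) if not g.big]
    big_gap_ids = [i for i, g in enumerate(gaps) if g.big]

    new_ids = rng.choice(normal_ids, size=cfg.n_new_lmr, replace=False)
    new_set = set(int(i) for i in new_ids)
    by_chrom_order: dict[str, list[int]] = {}
    for i, g in enumerate(gaps):
        by_chrom_order.setdefault(g.chrom, []).append(i)
    buffered = set(new_set)
    for chrom, order in by_chrom_order.items():
        pos_of = {g: k for k, g in enumerate(order)}
        for i in list(new_set):
            if gaps[i].chrom != chrom:
                continue
            k = pos_of[i]
            for dk in range(-cfg.new_lmr_buffer_gaps, cfg.new_lmr_buffer_gaps + 1):
                if 0 <= k + dk < len(order):
                    buffered.add(order[k + dk])

    stable_pool = [i for i in normal_ids if i not in buffered]
    need_stable = cfg.n_stable_lmr + cfg.n_specific_lmr + cfg.n_constitutive_lmr
    if len(stable_pool) < need_stable:
        raise ValueError("not enough intergenic gaps for the requested LMR counts")
    picked = rng.choice(stable_pool, size=need_stable, replace=False)
    stable_ids = picked[: cfg.n_stable_lmr]
    specific_ids = picked[cfg.n_stable_lmr : cfg.n_stable_lmr + cfg.n_specific_lmr]
    const_ids = picked[cfg.n_stable_lmr + cfg.n_specific_lmr :]

    used = set(int(i) for i in picked) | new_set
    peak_pool = [i for i in normal_ids if i not in used]
    need_peaks = cfg.n_t1_peak + cfg.n_common_peak + cfg.n_t2_peak
    if len(peak_pool) < need_peaks:
        raise ValueError("not enough intergenic gaps for the requested peak counts")
    pk = rng.choice(peak_pool, size=need_peaks, replace=False)
    t1_peak_ids = pk[: cfg.n_t1_peak]
    common_peak_ids = pk[cfg.n_t1_peak : cfg.n_t1_peak + cfg.n_common_peak]
    t2_peak_ids = pk[cfg.n_t1_peak + cfg.n_common_peak :]

    enh = rng.permutation(big_gap_ids)
    new_enh_ids = enh[: cfg.n_new_enhancer]
    stable_enh_ids = enh[cfg.n_new_enhancer : cfg.n_new_enhancer + cfg.n_stable_enhancer]

    def place(ids, length, prefix) -> list[GenomicInterval]:
        out = []
        for j, i in enumerate(sorted(int(x) for x in ids)):
            iv = gaps[i].centred(length)
            out.append(replace(iv, name=f"{prefix}{j:04d}"))
        return out

    regions = {
        STABLE_LMR_K: place(stable_ids, cfg.lmr_length, "sLMR"),
        NEW_LMR_K: place(new_ids, cfg.lmr_length, "nLMR"),
        SPECIFIC_LMR_K: place(specific_ids, cfg.lmr_length, "spLMR"),
        CONSTITUTIVE_LMR_K: place(const_ids, cfg.lmr_length, "coLMR"),
        NEW_ENH_K: place(new_enh_ids, cfg.enhancer_length, "nENH"),
        STABLE_ENH_K: place(stable_enh_ids, cfg.enhancer_length, "sENH"),
        T1_PEAK_K: place(t1_peak_ids, cfg.peak_length, "pk1_"),
        COMMON_PEAK_K: place(common_peak_ids, cfg.peak_length, "pkC_"),
        T2_PEAK_K: place(t2_peak_ids, cfg.peak_length, "pk2_"),
    }

    # --- TSS-UMR gene classes ---------------------------------------------
    eligible = [
        g
        for g in genes
        if g.interval.length() >= cfg.tss_umr_length - cfg.tss_umr_upstream + 1000
    ]
    sel = rng.choice(len(eligible), size=cfg.n_demeth_gene + cfg.n_hypermeth_gene, replace=False)
    demeth_genes = [eligible[int(i)] for i in sel[: cfg.n_demeth_gene]]
    hyper_genes = [eligible[int(i)] for i in sel[cfg.n_demeth_gene :]]

    def tss_umr(g: GeneModel, j: int, prefix: str) -> GenomicInterval:
        if g.strand == "+":
            s = _snap(g.tss - cfg.tss_umr_upstream)
            return GenomicInterval(g.chrom, s, s + cfg.tss_umr_length, name=f"{prefix}{j:04d}")
        e = _snap(g.tss + cfg.tss_umr_upstream)
        return GenomicInterval(g.chrom, e - cfg.tss_umr_length, e, name=f"{prefix}{j:04d}")

    regions[DEMETH_K] = [tss_umr(g, j, "dUMR") for j, g in enumerate(demeth_genes)]
    regions[HYPERMETH_K] = [tss_umr(g, j, "hUMR") for j, g in enumerate(hyper_genes)]
    gene_classes = {
        DEMETH_K: [g.gene_id for g in demeth_genes],
        HYPERMETH_K: [g.gene_id for g in hyper_genes],
    }

    # --- methylation landscape --------------------------------------------
    bg = cfg.background_meth
    lmr, umr = cfg.lmr_meth, cfg.umr_meth

    def mus(t1, t2, aux):
        d = {"t1": t1, "t2": t2}
        d.update({s: a for s, a in zip(AUX_SAMPLES, aux)})
        return d

    meth_regions: list[PlantedMethRegion] = []
    spec_map = {
        STABLE_LMR_K: (mus(lmr, lmr, (lmr, bg, bg)), cfg.lmr_cpg_spacing),
        NEW_LMR_K: (mus(bg, lmr, (bg, bg, bg)), cfg.lmr_cpg_spacing),
        SPECIFIC_LMR_K: (mus(lmr, lmr, (bg, bg, bg)), cfg.lmr_cpg_spacing),
        CONSTITUTIVE_LMR_K: (mus(lmr, lmr, (lmr, lmr, lmr)), cfg.lmr_cpg_spacing),
        DEMETH_K: (
            mus(cfg.demeth_meth_t1, cfg.demeth_meth_t2, (umr, umr, umr)),
            cfg.umr_cpg_spacing,
        ),
        HYPERMETH_K: (
            mus(cfg.hypermeth_meth_t1, cfg.hypermeth_meth_t2, (umr, umr, umr)),
            cfg.umr_cpg_spacing,
        ),
    }
    for key, (mu, spacing) in spec_map.items():
        gene_ids = gene_classes.get(key)
        for j, iv in enumerate(regions[key]):
            meth_regions.append(
                PlantedMethRegion(
                    iv,
                    mu,
                    spacing,
                    key,
                    gene_id=gene_ids[j] if gene_ids else None,
                )
            )
    meth_regions.sort(key=lambda r: (r.interval.chrom, r.interval.start))

    truth = SyntheticTruth(
        genome=genome,
        genes=genes,
        regions=regions,
        meth_regions=meth_regions,
        gene_classes=gene_classes,
    )
    return genome, genes, truth


# ---------------------------------------------------------------------------
# Methylomes
# ---------------------------------------------------------------------------

def _piece_positions(rng, start: int, end: int, spacing: int) -> np.ndarray:
    """Geometric inter-CpG spacings (mean ``spacing``) filling [start, end)."""
    length = end - start
    n_est = int(length / spacing * 1.8) + 12
    gaps = rng.geometric(1.0 / spacing, size=n_est)
    pos = start - 1 + np.cumsum(gaps)
    pos = pos[pos < end]
    while len(gaps) and (start - 1 + gaps.sum()) < end:  # rare under-draw
        extra = rng.geometric(1.0 / spacing, size=n_est)
        gaps = np.concatenate([gaps, extra])
        pos = start - 1 + np.cumsum(gaps)
        pos = pos[pos < end]
    return pos.astype(np.int64)


def simulate_methylomes(
    truth: SyntheticTruth, cfg: SimulationConfig
) -> tuple[list[CpGRecord], list[CpGRecord]]:
    """Two-time-point CpG tables (plus auxiliary cell types in the truth).

    CpG positions are a genome property shared by all samples; planted
    regions carry denser CpG spacing (CpG-island-like for UMRs). Per sample,
    coverage is Poisson (min 1) and the methylated count binomial around the
    planted mean. Auxiliary methylomes are stored as
    ``truth.aux_methylomes`` (sample name -> list of CpGRecord).
    """
    rng = _rng(cfg, 2)
    samples = list(TIMEPOINTS) + list(AUX_SAMPLES)
    all_records: dict[str, list[CpGRecord]] = {s: [] for s in samples}

    by_chrom: dict[str, list[PlantedMethRegion]] = {}
    for r in truth.meth_regions:
        by_chrom.setdefault(r.interval.chrom, []).append(r)

    for chrom in truth.genome:
        L = truth.genome[chrom]
        planted = sorted(by_chrom.get(chrom, []), key=lambda r: r.interval.start)
        pieces: list[tuple[int, int, dict[str, float] | None, int]] = []
        cursor = 0
        for r in planted:
            if r.interval.start > cursor:
                pieces.append((cursor, r.interval.start, None, cfg.cpg_spacing_mean))
            pieces.append((r.interval.start, r.interval.end, r.mu, r.cpg_spacing))
            cursor = r.interval.end
        if cursor < L:
            pieces.append((cursor, L, None, cfg.cpg_spacing_mean))

        pos_parts: list[np.ndarray] = []
        mu_parts: dict[str, list[np.ndarray]] = {s: [] for s in samples}
        for start, end, mu, spacing in pieces:
            for attempt in range(10):
                pos = _piece_positions(rng, start, end, spacing)
                if mu is None or len(pos) >= 4:
                    break
            else:
                raise RuntimeError(
                    f"planted region {chrom}:{start}-{end} holds <4 CpGs after retries"
                )
            pos_parts.append(pos)
            for s in samples:
                val = cfg.background_meth if mu is None else mu[s]
                mu_parts[s].append(np.full(len(pos), val))
        pos_all = np.concatenate(pos_parts)
        for s in samples:
            mu_all = np.concatenate(mu_parts[s])
            cov = np.maximum(rng.poisson(cfg.coverage_mean, size=len(pos_all)), 1)
            meth = rng.binomial(cov, mu_all)
            recs = all_records[s]
            for p, m, t in zip(pos_all.tolist(), meth.tolist(), cov.tolist()):
                recs.append(CpGRecord(chrom, p, m, t))

    truth.aux_methylomes = {s: all_records[s] for s in AUX_SAMPLES}
    return all_records["t1"], all_records["t2"]


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(
    truth: SyntheticTruth, cfg: SimulationConfig
) -> list[ExpressionRecord]:
    """Log-normal FPKMs with an external-style differential call.

    The planted regulation effect sits exactly where the downstream
    statistic samples: the next and second-next genes of each new LMR are
    upregulated with probability ``p_up_near_new`` when significant, all
    other significant genes with ``p_up_background``.
    """
    rng = _rng(cfg, 3)
    index = GeneProximityIndex(truth.genes)
    painted: set[str] = set()
    for region in truth.regions[NEW_LMR_K]:
        for gd in index.nearest_two_genes(region, cfg.gene_proximity):
            painted.add(gd.gene_id)
    truth.painted_up_genes = sorted(painted)

    records = []
    for g in truth.genes:
        fpkm1 = float(np.exp(rng.normal(cfg.fpkm_log_mean, cfg.fpkm_log_sd)))
        significant = bool(rng.random() < cfg.significant_fraction)
        if not significant:
            fpkm2 = fpkm1 * float(np.exp(rng.normal(0.0, 0.05)))
            records.append(ExpressionRecord(g.gene_id, fpkm1, fpkm2, False, NONE))
            continue
        p_up = cfg.p_up_near_new if g.gene_id in painted else cfg.p_up_background
        up = bool(rng.random() < p_up)
        fold = max(float(np.exp(rng.normal(np.log(2.0), 0.5))), 1.2)
        fpkm2 = fpkm1 * fold if up else fpkm1 / fold
        records.append(
            ExpressionRecord(g.gene_id, fpkm1, fpkm2, True, UP if up else DOWN)
        )
    truth.expression = records
    return records


# ---------------------------------------------------------------------------
# Fragment sets
# ---------------------------------------------------------------------------

def _base_intensity(genome: GenomeIndex) -> dict[str, np.ndarray]:
    return {c: np.ones(genome[c] // INTENSITY_BIN) for c in genome}


def _apply(intensity: dict[str, np.ndarray], iv: GenomicInterval, factor: float) -> None:
    arr = intensity[iv.chrom]
    lo = max(iv.start // INTENSITY_BIN, 0)
    hi = min(-(-iv.end // INTENSITY_BIN), len(arr))
    arr[lo:hi] *= factor


def _sample_fragments(
    intensity: dict[str, np.ndarray],
    genome: GenomeIndex,
    depth: int,
    frag_len: int,
    rng: np.random.Generator,
    label: str,
) -> FragmentSet:
    chroms = list(genome)
    weights = np.concatenate([intensity[c] for c in chroms])
    p = weights / weights.sum()
    counts = rng.multinomial(depth, p)
    offsets = rng.random(depth) * INTENSITY_BIN
    bin_starts = np.concatenate(
        [np.arange(len(intensity[c]), dtype=np.int64) * INTENSITY_BIN for c in chroms]
    )
    mids = np.repeat(bin_starts, counts) + offsets
    sizes = [len(intensity[c]) for c in chroms]
    cum = np.cumsum([0] + sizes)
    by_chrom = {}
    counts_per_chrom = [counts[cum[i] : cum[i + 1]].sum() for i in range(len(chroms))]
    ccum = np.cumsum([0] + counts_per_chrom)
    for i, chrom in enumerate(chroms):
        m = mids[ccum[i] : ccum[i + 1]]
        starts = np.clip((m - frag_len / 2).astype(np.int64), 0, genome[chrom] - 1)
        ends = np.clip(starts + frag_len, 1, genome[chrom])
        by_chrom[chrom] = (starts, ends)
    return FragmentSet(by_chrom, total_mapped=depth, label=label)


def _hmc_intensity(truth: SyntheticTruth, cfg: SimulationConfig, tp: str) -> dict[str, np.ndarray]:
    fpkm = {
        r.gene_id: (r.fpkm_t1 if tp == "t1" else r.fpkm_t2) for r in truth.expression
    }
    intensity = _base_intensity(truth.genome)
    for g in truth.genes:
        _apply(intensity, g.interval, 1.0 + cfg.hmc_gene_body_slope * np.log10(1.0 + fpkm[g.gene_id]))
    for g in truth.genes:
        tss = _snap(g.tss)
        lo = max(tss - 1000, 0)
        _apply(intensity, GenomicInterval(g.chrom, lo, tss + 1000), cfg.tss_depletion)
    bimodal = (
        truth.regions[STABLE_LMR_K]
        + truth.regions[SPECIFIC_LMR_K]
        + truth.regions[CONSTITUTIVE_LMR_K]
        + (truth.regions[NEW_LMR_K] if tp == "t2" else [])
    )
    for iv in bimodal:
        _apply(intensity, GenomicInterval(iv.chrom, max(iv.start - 1000, 0), iv.start), cfg.hmc_flank_fold)
        _apply(intensity, GenomicInterval(iv.chrom, iv.end, iv.end + 1000), cfg.hmc_flank_fold)
        _apply(intensity, iv, cfg.tss_depletion)
    if tp == "t1":
        for iv in truth.regions[NEW_LMR_K]:
            mid = _snap(iv.midpoint)
            _apply(intensity, GenomicInterval(iv.chrom, mid - 500, mid + 500), cfg.hmc_center_fold)
    peak_sets = [truth.regions[COMMON_PEAK_K]]
    peak_sets.append(truth.regions[T1_PEAK_K] if tp == "t1" else truth.regions[T2_PEAK_K])
    for ivs in peak_sets:
        for iv in ivs:
            _apply(intensity, iv, cfg.peak_fold)
    return intensity


def simulate_5hmc_fragments(
    truth: SyntheticTruth, cfg: SimulationConfig
) -> tuple[FragmentSet, FragmentSet]:
    """5hmC capture fragments for both time points.

    Intensity model: baseline 1; gene bodies scaled by expression; TSS
    +/-1 kb depleted; new-LMR centres enriched at t1 only; stable-type LMRs
    (and t2 new LMRs) bimodally enriched at their 1 kb boundary windows with
    a depleted centre; planted peak regions strongly enriched.
    """
    if truth.expression is None:
        raise ValueError("simulate_expression must run before 5hmC fragments")
    rng = _rng(cfg, 4)
    out = []
    for tp in TIMEPOINTS:
        intensity = _hmc_intensity(truth, cfg, tp)
        out.append(
            _sample_fragments(
                intensity, truth.genome, cfg.depth, cfg.fragment_length, rng, f"5hmC_{tp}"
            )
        )
    return out[0], out[1]


def simulate_input_fragments(
    truth: SyntheticTruth, cfg: SimulationConfig
) -> tuple[FragmentSet, FragmentSet]:
    """Matched uniform-coverage input libraries for the two time points."""
    rng = _rng(cfg, 5)
    intensity = _base_intensity(truth.genome)
    return tuple(
        _sample_fragments(
            intensity, truth.genome, cfg.depth, cfg.fragment_length, rng, f"input_{tp}"
        )
        for tp in TIMEPOINTS
    )


def simulate_chip_fragments(
    truth: SyntheticTruth, cfg: SimulationConfig
) -> dict[tuple[str, str], tuple[FragmentSet, FragmentSet]]:
    """H3K4me1/H3K27ac ChIP and matched input fragments per time point.

    ChIP intensity equals the uniform input times the planted fold over
    each enhancer: new enhancers are near input level neonatally and
    strongly enriched in the adult; stable enhancers are equally enriched
    at both time points, for both marks.
    """
    rng = _rng(cfg, 6)
    out = {}
    for mark in MARKS:
        for tp in TIMEPOINTS:
            intensity = _base_intensity(truth.genome)
            new_fold = cfg.enh_new_fold_t1 if tp == "t1" else cfg.enh_new_fold_t2
            for iv in truth.regions[NEW_ENH_K]:
                _apply(intensity, iv, new_fold)
            for iv in truth.regions[STABLE_ENH_K]:
                _apply(intensity, iv, cfg.enh_stable_fold)
            chip = _sample_fragments(
                intensity, truth.genome, cfg.depth, cfg.fragment_length, rng, f"{mark}_{tp}"
            )
            inp = _sample_fragments(
                _base_intensity(truth.genome),
                truth.genome,
                cfg.depth,
                cfg.fragment_length,
                rng,
                f"{mark}_{tp}_input",
            )
            out[(mark, tp)] = (chip, inp)
    return out


# ---------------------------------------------------------------------------
# One-call bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticEpigenome:
    cfg: SimulationConfig
    truth: SyntheticTruth
    cpgs_t1: list[CpGRecord]
    cpgs_t2: list[CpGRecord]
    expression: list[ExpressionRecord]
    hmc: dict[str, FragmentSet]  # t1, t2
    hmc_input: dict[str, FragmentSet]
    chip: dict[tuple[str, str], tuple[FragmentSet, FragmentSet]]


def simulate_all(cfg: SimulationConfig) -> SyntheticEpigenome:
    """Run every generator stage in order and return the full bundle."""
    _genome, _genes, truth = simulate_genome_and_genes(cfg)
    expression = simulate_expression(truth, cfg)
    cpgs_t1, cpgs_t2 = simulate_methylomes(truth, cfg)
    hmc_t1, hmc_t2 = simulate_5hmc_fragments(truth, cfg)
    in_t1, in_t2 = simulate_input_fragments(truth, cfg)
    chip = simulate_chip_fragments(truth, cfg)
    return SyntheticEpigenome(
        cfg=cfg,
        truth=truth,
        cpgs_t1=cpgs_t1,
        cpgs_t2=cpgs_t2,
        expression=expression,
        hmc={"t1": hmc_t1, "t2": hmc_t2},
        hmc_input={"t1": in_t1, "t2": in_t2},
        chip=chip,
    )
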