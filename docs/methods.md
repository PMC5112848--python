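# Methods

`epidyn` implements a two-time-point epigenome integration analysis for
postnatal cardiomyocyte maturation (neonatal P1 vs adult, generically
t1/t2): segmentation of CpG methylomes into unmethylated (UMR),
low-methylated (LMR) and fully methylated (FMR) regions; classification of
dynamic regulatory regions and genes; 5-hydroxymethylcytosine (5hmC) and
histone-ChIP coverage meta-profiles; and the statistics linking regions to
nearby gene expression. Every stage is exercised end-to-end on a synthetic
epigenome with planted ground truth, so the whole analysis is testable
without any sequencing download.

## Coordinate model and interval primitives

All coordinates are 0-based half-open (BED convention); GTF-style input is
shifted on read. The reciprocal-overlap rule for "common" peaks requires
both peaks of a pair to share at least 50% of their own length
(`reciprocal_min`, default 0.5). Peak-to-feature annotation assigns one
label per region by the midpoint, with precedence
promoter > TES > 5'UTR > 3'UTR > exon > intron > intergenic, so feature
compositions sum to 100%. The promoter window is TSS −1,000/+100 bp and the
TES window ±1,000 bp — common annotator defaults, declared here rather than
inferred, and exposed as configuration. Random background regions preserve
the template length multiset exactly and are placed uniformly over valid
start positions (chromosomes weighted accordingly). Gene proximity is
anchored at |region midpoint − TSS| (0 inside the gene body), with ties
broken lexicographically; "next and second-next" genes are the two nearest
within ±100,000 bp.

## Coverage engine

Binned tracks are RPKM-normalised (a fragment increments every bin it
overlaps; value = count · 10⁹ / (bin·total)), which makes the conservation
identity Σ value·bin/1000·total/10⁶ = Σ bins-overlapped exact and testable.
log2(ChIP/Input) tracks use a 0.5 RPKM pseudocount. Meta-profile matrices
(reference-point and scaled-gene-body) are strand-flipped so column 0 is
always 5'-most; positions beyond chromosome ends are NaN and excluded from
column means rather than zero-filled, avoiding edge artefacts in ±100 kb
flanks. Replicate correlation rebins by summation (10 kb / 100 kb are the
conventional choices) and offers both Pearson and Spearman, since both are
standard for replicate heatmaps; the default is Spearman.

### Simplified peak caller

Peak calling is a deliberately simplified stand-in for a full
fragment-model caller, because everything of interest here is downstream of
peak calling. It slides windows (default 300 bp, step 100 bp), counts
*fragment midpoints* per window, and tests each count against a Poisson
null whose rate is the maximum of the genome-wide, 1 kb and 10 kb control
rates scaled to treatment depth (a local-lambda background). Midpoint
counting is load-bearing: it keeps the expected count proportional to
window width, so rates estimated at 1 kb or 10 kb transfer to the test
window without a fragment-length correction; overlap counting inflates
narrow windows and makes the test anti-conservative. Window p-values are
Benjamini–Hochberg corrected, significant windows that overlap or abut are
merged, and each merged peak reports its strongest member window's fold
enrichment and smallest p/q. With an empty control the background is
estimated from the treatment itself (with a warning).

When 5hmC peaks feed the common-peak comparison, the pipeline keeps calls
with fold enrichment ≥ 6. The synthetic epigenome's compact 5hmC peaks are
planted at 10× while the strongest diffuse structures (new-LMR centres at
3×, expression-coupled gene bodies up to ≈2.7×) stay well below; 6 sits in
the gap between those two populations with margin for Poisson noise on
both sides.

## Methylome segmentation

Per-CpG methylation fractions (optionally smoothed by a centred moving
average, span 3 CpGs) are partitioned per chromosome by PELT — exact
penalised change-point optimisation minimising within-segment sum of
squared deviations plus a per-segment penalty β = 2σ̂²·span·ln n, with a
minimum segment size of `min_cpgs_per_segment` (default 4) and hard breaks
at CpG gaps over `max_join_dist` (default 5,000 bp). σ̂ is a robust noise
scale from lag-`span` differences (lagging past the smoothing window keeps
the differences nearly independent; the span factor in β compensates for
the autocorrelation the moving average induces). Adjacent segments whose
coverage-weighted means differ by less than `min_seg_diff` (default 0.10)
are then merged, smallest difference first, so every surviving boundary
reflects a methylation change of at least that size.

A greedy binary-splitting search with the mean-difference rule applied at
each split was considered and rejected: on a whole chromosome a ~25-CpG LMR
embedded in ~10⁵ background CpGs moves the two half-chromosome means by
~10⁻⁴, so the first split can never satisfy a meaningful mean-difference
threshold and the chromosome stays one segment. Exact penalised
partitioning finds embedded segments regardless of context length, and the
mean-difference rule is applied where it is well-posed — between adjacent
final segments. On small fixtures the result provably equals the global
SSE-minimising segmentation (the acceptance suite checks this against
exhaustive enumeration).

Segment means are coverage-weighted (Σ methylated / Σ total), so
low-coverage CpGs do not dominate. Classification: UMR if mean ≤ 0.10 and
≥ 30 CpGs (promoter/CpG-island-like); LMR if mean ≤ 0.50 otherwise (distal
regulatory proxy); FMR else. These thresholds follow the established
UMR/LMR convention and are configuration keys; numerical identity with any
published genome-wide segment count is explicitly not a goal.

## Region classification

* **Common peaks** — a t1 peak is common iff some t2 peak reciprocally
  overlaps ≥ 50% both ways (and symmetrically); each peak pairs with at
  most one partner (largest reciprocal overlap, ties leftmost).
* **LMR dynamics** — an adult LMR is *new* if its mean methylation fell by
  ≥ 30 percentage points since t1; otherwise *stable* if it overlaps
  (≥ 1 bp) any t1 LMR; otherwise unclassified. New takes precedence over
  stable: a region meeting both criteria is reported as new, because the
  dynamic claim is the analysis's focus.
* **Cell-type specificity** — against LMR sets of other cell types
  (embryonic stem cells, fibroblasts, neurons in the real study; three
  auxiliary methylomes here): *specific* = overlaps none, *constitutive* =
  overlaps all.
* **TSS-UMR gene classes** — a gene is *demethylated* when its TSS (but not
  its TES) lies in an adult UMR that lost ≥ 5 points, *hypermethylated*
  symmetrically for a neonatal UMR gaining ≥ 5 points. Genes whose TSS and
  TES both fall in the UMR are excluded and tallied; genes qualifying for
  both classes are flagged, not silently assigned.
* **Enhancers** — candidate regions are adult H3K4me1 peaks (intersected
  with the adult H3K27ac peak when both exist). *New*: adult peaks in both
  marks, every mark < 1.3-fold over input neonatally and > 4-fold in the
  adult. *Stable*: peaks in both marks at both time points with every
  mark's bidirectional fold change below 4/1.3 ≈ 3.077 — the minimal
  possible change of a new enhancer, read as a ratio because enrichments
  are ratios. New takes precedence.

Enrichment over input is the ratio of mean RPKM (chip vs input, pseudocount
0.5) over the candidate region, rescaled by the chip/input ratio over
non-peak bins. That background normalisation matters at desk scale: with a
fixed library size, the mass sitting in enriched regions deflates the
chip track's background, and depth normalisation alone would understate
region enrichment by that factor (~8% in the default simulation).

Every label carries an evidence map holding exactly the quantities its rule
tested; re-applying the rule to the evidence must reproduce the label, and
the tests enforce this.

## Regulation statistics

Expression is consumed as a table (FPKM at both time points plus an
external differential-significance flag and direction); no differential
model is fit here. Genes are binned at 1/10/50/100/250 FPKM (left-closed).
For a region set, the union of next and second-next genes within ±100 kb is
de-duplicated across regions (double counting would inflate n), restricted
to significant genes, and split by direction. Two region sets are compared
with the 2×2 Pearson chi-square, closed margin form
N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)), no Yates correction by default (a flag
enables it). Expression-level comparisons use the Mann–Whitney U with
mid-ranks: exact by full enumeration for combined n ≤ 12 without ties,
otherwise a normal approximation with tie and continuity corrections.
Joint "highest 5hmC and expression" gene selection ranks genes by the sum
of their descending ranks in gene-body 5hmC RPKM and FPKM (ties
lexicographic); how the two criteria combine is not standardised, and
rank-sum is the declared choice. The "stronger upregulation near new LMRs"
comparison is implemented as a one-sided Mann–Whitney on log2 fold changes
of significant neighbour genes and is flagged as an interpretation.

## Synthetic epigenome

The generator emulates the statistical structure the analysis assumes, not
sequence-level realism (no reads, no bisulfite conversion errors, no
copy-number or SNP confounders).

**Genome and genes.** Two chromosomes (11.5 Mb each), 2,500 non-overlapping
genes of 2–5 kb on alternating strands with 2–8 exons and UTRs, separated
by 4.6–6 kb intergenic gaps (80 enlarged to 10 kb to host enhancers). Each
gap hosts at most one planted region; gaps within two positions of a
new-LMR gap are kept free of stable-type LMRs so that the regulated-gene
samples near new and stable LMRs stay disjoint.

**Methylomes.** CpG positions are a genome property shared by all samples:
geometric spacing, mean 100 bp in background, 60 bp inside planted LMRs and
25 bp inside planted UMRs (CpG-island-like density, which also guarantees
the UMR 30-CpG minimum). Per sample, coverage is Poisson(20) (min 1) and
the methylated count Binomial around the planted mean: background 0.80,
LMRs 0.30, UMRs 0.05. Stable/specific/constitutive LMRs are low-methylated
at both time points (constitutive also in all three auxiliary cell types,
specific in none, plain stable in one); new LMRs are background at t1 and
0.30 at t2 (a 50-point loss, comfortably past the 30-point rule);
demethylated-gene UMRs go 0.12 → 0.04 (−8 points) and hypermethylated-gene
promoters 0.04 → 0.65, i.e. the silenced promoter becomes fully methylated
— which also keeps it out of the adult LMR universe, where it would
otherwise contaminate the specificity classes.

**Expression.** ln FPKM ~ Normal(2, 2); 95% of genes carry a significant
differential call. Significant genes that are the next or second-next gene
of a planted new LMR are upregulated with probability 0.624, all other
significant genes with probability 0.491 (the published up-fractions used
as planted parameters). Painting exactly the genes the downstream statistic
samples is deliberate: at this genome scale, ±100 kb windows around every
new LMR would tile nearly the whole genome, so painting *all* genes within
the window would erase the planted contrast rather than embody it. Fold
changes are log-normal (median 2, floor 1.2), applied in the called
direction so directions are always consistent with the FPKM ordering.

**Fragments.** All fragment sets (10⁶ fragments of 200 bp per sample) are
drawn from piecewise-constant intensities on a 100 bp grid (all planted
coordinates snap to it, making planted folds exact). 5hmC: baseline 1, gene
bodies × (1 + 0.6·log10(1+FPKM)), TSS ±1 kb × 0.3, new-LMR centres
(±500 bp) × 3 at t1 only, stable-type LMRs (and t2 new LMRs) × 2 over two
1 kb boundary windows with the region centre × 0.3, planted compact peaks
× 10; matched uniform inputs accompany both time points (the real assay has
inputs, and the peak caller needs a control). ChIP (H3K4me1, H3K27ac):
uniform input; chip intensity = input × planted fold over enhancers — new
enhancers 1.1× at t1 and 5× at t2, stable enhancers 4× at both time points.
Enhancers are 7 kb: at 10⁶ fragments on a 23 Mb genome this gives ≈ 300
input fragments per region, putting the sampling noise of a 1.1× neonatal
enrichment about 2.3 standard deviations below the 1.3× rule, so class
recovery is limited by the planted effect sizes rather than by counting
noise.

All generators are deterministic functions of the seed; each stage draws
from its own child stream.

**What passing on this generator does and does not show.** It demonstrates
that the rules, segmentation, profiles and statistics recover exactly the
structure they define, at realistic noise levels, and that the pipeline's
thresholds are mutually consistent. It does not validate against real
chromatin: real methylomes have autocorrelated, partially methylated
domains, real 5hmC tracks have CpG-density and mappability covariates, and
real enhancer marks are far noisier than a planted two-level intensity.
Genome-wide counts from the original study (peak counts, LMR counts, global
5hmC levels) depend on the deposited sequencing data and are out of reach
by construction.

## Default problem sizes

Module tests run on a 0.6 Mb / 60-gene configuration. The end-to-end
recovery checks and the acceptance script use the full default
configuration (23 Mb, 2,500 genes, ≈2.5×10⁵ CpGs, 10⁶ fragments per
sample), one analysis taking well under a minute of compute per seed; five
seeds are analysed in full, and the chi-square rejection rate is measured
over twenty seeds using an expression-only fast path that skips fragment
simulation (the contingency test depends only on region placement and the
expression table).

## Known limitations

* The peak caller is a stand-in: no fragment-size model, no peak summits,
  no paired-peak shifting. Externally produced peak BED files are accepted
  wherever peaks are consumed.
* Segmentation assumes approximately independent per-CpG noise after
  smoothing; strongly autocorrelated methylation (e.g. partially methylated
  domains) would need a different penalty calibration.
* Whether a gene may belong to both TSS-UMR classes is left open by the
  definitions; such genes are flagged and excluded rather than assigned.
* The chi-square power at the planted effect sizes (0.624 vs 0.491 with
  ~250 vs ~1,600 significant neighbours) is ≈ 0.94 at α = 0.01, so a
  minority of seeds legitimately fail to reject.
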