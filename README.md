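# epidyn

Two-time-point epigenome dynamics analysis for postnatal cardiomyocyte
maturation — and for any paired-condition design with CpG methylomes,
5-hydroxymethylcytosine (5hmC) capture data, histone ChIP data and an
expression table. `epidyn` is aimed at computational biologists who want
the full region-classification pipeline of such a study as a tested,
reusable library rather than a chain of one-off scripts.

## What it computes

Between a neonatal (t1) and an adult (t2) state, the pipeline:

* segments per-CpG methylation fractions into **UMRs** (unmethylated,
  promoter/CpG-island-like), **LMRs** (low-methylated, distal-regulatory
  proxies) and **FMR** background, by exact penalised change-point
  partitioning (PELT, SSE cost, BIC-type penalty) plus a mean-difference
  merge;
* classifies **common 5hmC peaks** (reciprocal overlap ≥ 50% of both
  peaks' lengths), **stable vs new LMRs** (new = mean methylation loss
  ≥ 30 percentage points), **cell-type-specific vs constitutive LMRs**
  (against other cell types' LMR sets), **demethylated / hypermethylated
  TSS-UMR genes** (TSS but not TES inside a UMR changing by ≥ 5 points),
  and **stable vs new enhancers** from H3K4me1/H3K27ac peak presence and
  enrichment over input (< 1.3-fold neonatal and > 4-fold adult defines
  new; bidirectional change < 4/1.3 with peaks at both time points defines
  stable);
* builds RPKM tracks, log2(ChIP/Input) tracks, reference-point and
  scaled-gene-body **meta-profile matrices** (±100 kb flanks, strand-aware,
  edge-masked), binned replicate correlations, and a simplified
  sliding-window Poisson **peak caller** with local-lambda background and
  Benjamini–Hochberg control;
* links regions to expression: the fraction of significantly regulated
  **next and second-next genes** (within ±100 kb, de-duplicated) that are
  upregulated, compared between region sets with a 2×2 **chi-square**
  (statistic `N(ad−bc)²/((a+b)(c+d)(a+c)(b+d))`), plus **Mann–Whitney**
  expression comparisons and joint top-gene selection by 5hmC/expression
  rank sum.

A synthetic-epigenome generator (`epidyn.simulate`) plants every one of
these classes with known ground truth — two-time-point methylomes, 5hmC
fragments with TSS depletion, expression-coupled gene bodies, centre-
vs boundary-enriched LMR patterns, ChIP fragments obeying the enhancer
rules, and an expression table with up-probability 0.624 near new LMRs vs
0.491 elsewhere — so the entire analysis is testable offline. See
`docs/methods.md` for models, parameters and limitations.

## Worked example

```python
from epidyn.simulate import SimulationConfig
from epidyn.pipeline import run_synthetic_analysis

res = run_synthetic_analysis(SimulationConfig(seed=1))
ev = res.class_evals["new_lmr"]
print(f"new LMRs: precision {ev.precision:.3f} recall {ev.recall:.3f}")
print(f"up-fraction near new LMRs:    {res.frac_new.frac_up:.3f} (n={res.frac_new.n})")
print(f"up-fraction near stable LMRs: {res.frac_stable.frac_up:.3f} (n={res.frac_stable.n})")
print(f"chi-square: {res.chi.statistic:.2f}, p = {res.chi.p_value:.2e}")
print(f"P1 5hmC centre/flank at new LMRs: {res.hmc_new_lmr_t1.center_flank_ratio:.2f}")
print(f"adult profile bimodal: {res.hmc_new_lmr_t2.bimodal}")
```

prints

```
new LMRs: precision 1.000 recall 1.000
up-fraction near new LMRs:    0.658 (n=281)
up-fraction near stable LMRs: 0.481 (n=1526)
chi-square: 29.87, p = 4.62e-08
P1 5hmC centre/flank at new LMRs: 1.75
adult profile bimodal: True
```

All 150 planted new LMRs were recovered with no false calls. Genes next to
new LMRs are upregulated far more often (65.8%) than genes next to stable
LMRs (48.1%), and the chi-square comparison rejects equality decisively —
the planted regulatory contrast (62.4% vs 49.1% plus sampling noise) is
recovered. The neonatal 5hmC signal peaks at new-LMR centres (1.75× the
flanking baseline) while the adult signal is bimodal (depleted centre,
enriched boundaries), the qualitative switch the region classes predict.

The same analysis runs from the shell:

```bash
epidyn simulate --seed 1 --outdir sim/        # write all input files + truth
epidyn run-all  --seed 1 --outdir report/     # full analysis + report TSVs
epidyn segment --cpgs sim/cpgs_t2.tsv --out segs_t2.bed
epidyn peaks --treatment sim/hmc_t1.bed --control sim/input_t1.bed \
             --genome sim/genome.tsv --out peaks_t1.bed
```

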