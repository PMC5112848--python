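"""Dynamic-region classification rules: common peaks, LMR dynamics and
specificity, TSS-UMR gene classes, and enhancer definitions, including
brute-force and truth-table oracles and threshold-monotonicity properties."""

import itertools

import numpy as np
import pytest

from epidyn.classify import (
    CONSTITUTIVE_LMR,
    DEMETH_GENE,
    HYPERMETH_GENE,
    NEW_ENHANCER,
    NEW_LMR,
    SPECIFIC_LMR,
    STABLE_ENHANCER,
    STABLE_LMR,
    UNCLASSIFIED_LMR,
    EnhancerEvidence,
    MarkEvidence,
    ThresholdConfig,
    classify_common_peaks,
    enhancer_classes,
    lmr_cell_specificity,
    lmr_dynamics,
    tss_umr_gene_classes,
)
from epidyn.intervals import GeneModel, GenomicInterval, reciprocal_overlap
from epidyn.segmentation import CpGRecord, MethylomeSegment


def non_overlapping_intervals(rng, n, chrom="chr1", max_len=400):
    lens = rng.integers(50, max_len, size=n)
    gaps = rng.integers(1, 600, size=n)
    ends = np.cumsum(lens + gaps)
    return [
        GenomicInterval(chrom, int(e - l), int(e)) for e, l in zip(ends, lens)
    ]


def seg(chrom, start, end, mean=0.3, n=10):
    return MethylomeSegment(GenomicInterval(chrom, start, end), mean, n, "LMR")


def cpgs_at(chrom, start, end, mu, spacing=50, cov=1000):
    return [
        CpGRecord(chrom, p, round(mu * cov), cov) for p in range(start, end, spacing)
    ]


class TestCommonPeaks:
    def test_identical_sets_all_common(self, rng):
        peaks = non_overlapping_intervals(rng, 20)
        t1_only, common, t2_only = classify_common_peaks(peaks, list(peaks))
        assert not t1_only and not t2_only and len(common) == 20

    def test_forty_percent_overlap_not_common(self):
        a = [GenomicInterval("chr1", 0, 100)]
        b = [GenomicInterval("chr1", 60, 160)]
        t1_only, common, t2_only = classify_common_peaks(a, b)
        assert len(t1_only) == 1 and len(t2_only) == 1 and not common

    def test_partition_matches_all_pairs_bruteforce(self, rng):
        set1 = non_overlapping_intervals(rng, 300)
        set2 = non_overlapping_intervals(rng, 300)
        t1_only, common, t2_only = classify_common_peaks(set1, set2)
        assert len(t1_only) + len(common) == len(set1)

        def brute_common(xs, ys):
            out = set()
            for i, x in enumerate(xs):
                for y in ys:
                    fa, fb = reciprocal_overlap(x, y)
                    if fa >= 0.5 and fb >= 0.5:
                        out.add(i)
                        break
            return out

        common_idx = brute_common(set1, set2)
        got_common = {set1.index(c.interval) for c in common}
        assert got_common == common_idx
        brute_only2 = set(range(len(set2))) - brute_common(set2, set1)
        got_only2 = {set2.index(c.interval) for c in t2_only}
        assert got_only2 == brute_only2

    def test_symmetry_under_swap(self, rng):
        set1 = non_overlapping_intervals(rng, 80)
        set2 = non_overlapping_intervals(rng, 80)
        a1, c1, b1 = classify_common_peaks(set1, set2)
        a2, c2, b2 = classify_common_peaks(set2, set1)
        assert len(a1) == len(b2) and len(b1) == len(a2)
        assert len(c1) == len(c2)  # both sides count qualifying t1 members

    def test_overlapping_input_rejected(self):
        bad = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 50, 150)]
        with pytest.raises(ValueError, match="merge"):
            classify_common_peaks(bad, [])


class TestLmrDynamics:
    def _fixture(self, t1_mu, t2_mu, with_t1_lmr):
        region = GenomicInterval("chr1", 1000, 2000)
        t2_lmr = seg("chr1", 1000, 2000, t2_mu)
        t1_lmrs = [seg("chr1", 900, 1900, t1_mu)] if with_t1_lmr else []
        c1 = cpgs_at("chr1", 1000, 2000, t1_mu)
        c2 = cpgs_at("chr1", 1000, 2000, t2_mu)
        return [t2_lmr], t1_lmrs, c1, c2

    def test_identical_lmr_is_stable(self):
        labels = lmr_dynamics(*self._fixture(0.3, 0.3, True))
        assert labels[0].label == STABLE_LMR

    def test_thirty_point_loss_is_new(self):
        labels = lmr_dynamics(*self._fixture(0.65, 0.25, True))
        assert labels[0].label == NEW_LMR
        assert labels[0].evidence["delta_meth"] == pytest.approx(-40.0)

    def test_small_loss_without_t1_partner_unclassified(self):
        labels = lmr_dynamics(*self._fixture(0.40, 0.30, False))
        assert labels[0].label == UNCLASSIFIED_LMR

    def test_missing_cpg_data_warns_and_unclassifies(self):
        t2 = [seg("chr1", 1000, 2000, 0.3)]
        with pytest.warns(UserWarning):
            labels = lmr_dynamics(t2, [], [], [])
        assert labels[0].label == UNCLASSIFIED_LMR

    @pytest.mark.parametrize("overlap", [False, True])
    @pytest.mark.parametrize("delta", [-60, -40, -30.5, -29.5, -20, -10, 0, 10])
    def test_truth_table_over_delta_grid(self, overlap, delta):
        t1_mu = 0.6
        t2_mu = t1_mu + delta / 100
        labels = lmr_dynamics(*self._fixture(t1_mu, t2_mu, overlap))
        if delta < -30:
            want = NEW_LMR
        elif overlap:
            want = STABLE_LMR
        else:
            want = UNCLASSIFIED_LMR
        assert labels[0].label == want


class TestSpecificity:
    @pytest.mark.parametrize("pattern", list(itertools.product([0, 1], repeat=3)))
    def test_all_overlap_patterns(self, pattern):
        target = [seg("chr1", 1000, 2000)]
        others = []
        for k, hit in enumerate(pattern):
            if hit:
                others.append([seg("chr1", 1500, 2500)])
            else:
                others.append([seg("chr1", 50_000 + k * 1000, 50_500 + k * 1000)])
        labels = lmr_cell_specificity(target, others)
        if not any(pattern):
            assert len(labels) == 1 and labels[0].label == SPECIFIC_LMR
        elif all(pattern):
            assert len(labels) == 1 and labels[0].label == CONSTITUTIVE_LMR
        else:
            assert labels == []

    def test_requires_other_sets(self):
        with pytest.raises(ValueError):
            lmr_cell_specificity([seg("chr1", 0, 100)], [])


class TestTssUmrGenes:
    def _gene(self, gid="g1", start=10_000, end=16_000, strand="+"):
        return GeneModel(
            gene_id=gid,
            interval=GenomicInterval("chr1", start, end, strand),
            exons=(GenomicInterval("chr1", start, end, strand),),
        )

    def _umr(self, start, end, mean=0.05):
        return MethylomeSegment(GenomicInterval("chr1", start, end), mean, 40, "UMR")

    def test_adult_umr_with_loss_is_demethylated_gene(self):
        gene = self._gene()
        umr = self._umr(9_500, 11_500)
        c1 = cpgs_at("chr1", 9_500, 11_500, 0.13)
        c2 = cpgs_at("chr1", 9_500, 11_500, 0.05)
        labels, diags = tss_umr_gene_classes([], [umr], [gene], c1, c2)
        assert len(labels) == 1 and labels[0].label == DEMETH_GENE
        assert labels[0].evidence["gene_id"] == "g1"
        assert labels[0].evidence["delta_meth"] == pytest.approx(-8.0)

    def test_neonatal_umr_with_gain_is_hypermethylated_gene(self):
        gene = self._gene()
        umr = self._umr(9_500, 11_500)
        c1 = cpgs_at("chr1", 9_500, 11_500, 0.05)
        c2 = cpgs_at("chr1", 9_500, 11_500, 0.13)
        labels, diags = tss_umr_gene_classes([umr], [], [gene], c1, c2)
        assert len(labels) == 1 and labels[0].label == HYPERMETH_GENE
        assert labels[0].evidence["delta_meth"] == pytest.approx(8.0)

    def test_umr_covering_whole_gene_excluded(self):
        gene = self._gene(start=10_000, end=11_000)
        umr = self._umr(9_500, 11_500)  # spans TSS and TES
        c1 = cpgs_at("chr1", 9_500, 11_500, 0.13)
        c2 = cpgs_at("chr1", 9_500, 11_500, 0.05)
        labels, diags = tss_umr_gene_classes([], [umr], [gene], c1, c2)
        assert labels == [] and diags.excluded_tss_and_tes == 1

    def test_sub_threshold_delta_not_called(self):
        gene = self._gene()
        umr = self._umr(9_500, 11_500)
        c1 = cpgs_at("chr1", 9_500, 11_500, 0.08)
        c2 = cpgs_at("chr1", 9_500, 11_500, 0.05)  # only -3 points
        labels, _ = tss_umr_gene_classes([], [umr], [gene], c1, c2)
        assert labels == []

    def test_conflicting_gene_flagged_not_assigned(self):
        gene = self._gene()
        umr_t1 = self._umr(9_600, 11_400)
        umr_t2 = self._umr(9_500, 11_500)
        # qualifying loss for the t2 UMR, and the same tables give the t1 UMR
        # a qualifying gain is impossible; construct opposing windows instead
        c1 = cpgs_at("chr1", 9_500, 11_500, 0.13)
        c2 = cpgs_at("chr1", 9_500, 11_500, 0.05)
        labels, diags = tss_umr_gene_classes([umr_t1], [umr_t2], [gene], c1, c2)
        # t1 UMR delta is -8 (not a gain) so only the demethylated call remains
        assert len(labels) == 1 and labels[0].label == DEMETH_GENE
        assert diags.conflicting_genes == []


def mark(e1, e2, p1=True, p2=True):
    return MarkEvidence(peak_t1=p1, peak_t2=p2, enrich_t1=e1, enrich_t2=e2)


def evidence(m1, m2, start=0):
    return EnhancerEvidence(
        GenomicInterval("chr1", start, start + 1000), {"H3K4me1": m1, "H3K27ac": m2}
    )


def rule_oracle(marks, cfg):
    """Independent restatement of the published enhancer rules."""
    lo, hi = cfg.enh_low_max, cfg.enh_high_min
    new = all(m.peak_t2 and m.enrich_t1 < lo and m.enrich_t2 > hi for m in marks)
    stable = all(
        m.peak_t1
        and m.peak_t2
        and max(m.enrich_t1 / m.enrich_t2, m.enrich_t2 / m.enrich_t1) < hi / lo
        for m in marks
    )
    if new:
        return NEW_ENHANCER
    if stable:
        return STABLE_ENHANCER
    return None


class TestEnhancers:
    def test_textbook_new_enhancer(self):
        ev = evidence(mark(1.2, 4.5, p1=False), mark(1.2, 4.5, p1=False))
        labels = enhancer_classes([ev])
        assert len(labels) == 1 and labels[0].label == NEW_ENHANCER

    def test_unchanged_peaks_are_stable(self):
        ev = evidence(mark(3.0, 3.0), mark(2.0, 2.0))
        labels = enhancer_classes([ev])
        assert labels[0].label == STABLE_ENHANCER

    def test_fold_change_above_boundary_is_neither(self):
        # 3.2 > 4/1.3 ~ 3.077 for one mark
        ev = evidence(mark(1.5, 4.8), mark(2.0, 2.0))
        assert enhancer_classes([ev]) == []

    def test_grid_enumeration_matches_rule_truth_table(self):
        cfg = ThresholdConfig()
        grid = [0.8, 1.2, 1.29, 1.31, 2.0, 3.9, 4.01, 5.0]
        n_checked = 0
        for e1a, e2a, e1b, e2b in itertools.product(grid, repeat=4):
            for p1 in (True, False):
                ev = evidence(mark(e1a, e2a, p1=p1), mark(e1b, e2b, p1=p1))
                got = enhancer_classes([ev], cfg)
                want = rule_oracle(ev.marks.values(), cfg)
                if want is None:
                    assert got == []
                else:
                    assert got[0].label == want
                n_checked += 1
        assert n_checked == len(grid) ** 4 * 2

    def test_nonpositive_enrichment_rejected(self):
        with pytest.raises(ValueError):
            mark(0.0, 2.0)

    def test_monotone_in_thresholds(self, rng):
        """Raising enh_high_min never grows the new-enhancer set."""
        evs = []
        for i in range(200):
            e = rng.uniform(0.5, 6.0, size=4)
            evs.append(evidence(mark(e[0], e[1]), mark(e[2], e[3]), start=i * 2000))
        prev = None
        for hi in (3.0, 4.0, 5.0):
            cfg = ThresholdConfig(enh_high_min=hi)
            new_set = {
                l.interval.start for l in enhancer_classes(evs, cfg) if l.label == NEW_ENHANCER
            }
            if prev is not None:
                assert new_set <= prev
            prev = new_set

    def test_evidence_suffices_to_recompute_label(self, rng):
        cfg = ThresholdConfig()
        evs = []
        for i in range(100):
            e = rng.uniform(0.5, 6.0, size=4)
            evs.append(evidence(mark(e[0], e[1]), mark(e[2], e[3]), start=i * 2000))
        for lab in enhancer_classes(evs, cfg):
            marks = [
                MarkEvidence(
                    lab.evidence[f"{m}_peak_t1"],
                    lab.evidence[f"{m}_peak_t2"],
                    lab.evidence[f"{m}_e_t1"],
                    lab.evidence[f"{m}_e_t2"],
                )
                for m in ("H3K4me1", "H3K27ac")
            ]
            assert rule_oracle(marks, cfg) == lab.label


def test_new_lmr_threshold_monotone(rng):
    """Raising the loss threshold never grows the new-LMR set."""
    region_sets = []
    for i in range(40):
        start = 1000 + i * 5000
        t2_mu = float(rng.uniform(0.05, 0.5))
        t1_mu = float(rng.uniform(t2_mu, 0.95))
        region_sets.append((start, t1_mu, t2_mu))
    t2_lmrs = [seg("chr1", s, s + 1000, mu2) for s, _, mu2 in region_sets]
    c1 = [c for s, mu1, _ in region_sets for c in cpgs_at("chr1", s, s + 1000, mu1)]
    c2 = [c for s, _, mu2 in region_sets for c in cpgs_at("chr1", s, s + 1000, mu2)]
    prev = None
    for loss_min in (10.0, 30.0, 50.0):
        cfg = ThresholdConfig(new_lmr_loss_min=loss_min)
        labels = lmr_dynamics(t2_lmrs, [], c1, c2, cfg)
        new_set = {l.interval.start for l in labels if l.label == NEW_LMR}
        if prev is not None:
            assert new_set <= prev
        prev = new_set
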