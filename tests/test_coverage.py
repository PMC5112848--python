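"""Coverage engine: RPKM tracks, ratio tracks, meta-profiles, correlation,
peak calling and per-feature summaries, each against an independent oracle
where the value is not forced by construction."""

import numpy as np
import pytest
from scipy import stats as sps

from epidyn.coverage import (
    BinnedTrack,
    CoverageError,
    FragmentSet,
    binned_correlation,
    binned_count_track,
    call_enriched_peaks,
    column_mean_profile,
    feature_coverage_summary,
    log2_ratio_track,
    reference_point_matrix,
    rpkm_track,
    scaled_region_matrix,
)
from epidyn.intervals import GenomeIndex, GenomicInterval, GeneModel


def frags_from_tuples(tuples, total=None):
    return FragmentSet.from_intervals(
        [GenomicInterval(c, s, e) for c, s, e in tuples], total_mapped=total
    )


def loop_bin_counts(tuples, genome, bin_size):
    """Naive per-fragment oracle: each fragment increments every bin it overlaps."""
    counts = {c: np.zeros(-(-genome[c] // bin_size)) for c in genome}
    for c, s, e in tuples:
        for b in range(s // bin_size, (e - 1) // bin_size + 1):
            if b < len(counts[c]):
                counts[c][b] += 1
    return counts


class TestRpkm:
    def test_closed_form_single_bin(self, small_genome):
        tuples = [("chr1", 100, 300)] * 10
        track = rpkm_track(frags_from_tuples(tuples, total=1_000_000), small_genome, 1000)
        assert track.values["chr1"][0] == pytest.approx(10.0)
        assert np.all(track.values["chr2"] == 0)

    def test_random_fixture_matches_loop_oracle(self, small_genome, rng):
        tuples = [
            ("chr1" if rng.random() < 0.6 else "chr2", int(s), int(s) + int(l))
            for s, l in zip(rng.integers(0, 50_000, 200), rng.integers(50, 2500, 200))
        ]
        fs = frags_from_tuples(tuples)
        bin_size = 700
        track = rpkm_track(fs, small_genome, bin_size)
        oracle = loop_bin_counts(tuples, small_genome, bin_size)
        scale = 1e9 / (bin_size * fs.total_mapped)
        for c in small_genome:
            np.testing.assert_allclose(track.values[c], oracle[c] * scale, rtol=1e-12)

    def test_rpkm_conservation_identity(self, small_genome, rng):
        tuples = [
            ("chr1", int(s), int(s) + int(l))
            for s, l in zip(rng.integers(0, 90_000, 200), rng.integers(50, 3000, 200))
        ]
        fs = frags_from_tuples(tuples)
        bin_size = 500
        track = rpkm_track(fs, small_genome, bin_size)
        lhs = sum(track.values[c].sum() for c in small_genome) * (bin_size / 1000) * (
            fs.total_mapped / 1e6
        )
        bins_overlapped = sum(
            (e - 1) // bin_size - s // bin_size + 1 for _, s, e in tuples
        )
        assert lhs == pytest.approx(bins_overlapped, rel=1e-6)

    def test_zero_depth_rejected(self, small_genome):
        empty = FragmentSet({}, total_mapped=0)
        with pytest.raises(CoverageError):
            rpkm_track(empty, small_genome, 100)


class TestLog2Ratio:
    def test_equal_tracks_are_zero(self, small_genome):
        t = rpkm_track(frags_from_tuples([("chr1", 0, 500)] * 5), small_genome, 1000)
        ratio = log2_ratio_track(t, t)
        assert all(np.all(ratio.values[c] == 0) for c in small_genome)

    def test_fourfold_is_two(self, small_genome):
        vals_hi = {c: np.full(-(-small_genome[c] // 1000), 400.0) for c in small_genome}
        vals_lo = {c: np.full(-(-small_genome[c] // 1000), 100.0) for c in small_genome}
        chip = BinnedTrack(small_genome, 1000, vals_hi)
        inp = BinnedTrack(small_genome, 1000, vals_lo)
        ratio = log2_ratio_track(chip, inp, pseudocount=0.5)
        assert ratio.values["chr1"][0] == pytest.approx(2.0, rel=0.01)

    def test_double_zero_is_zero_and_shape_checked(self, small_genome):
        z = {c: np.zeros(-(-small_genome[c] // 1000)) for c in small_genome}
        t = BinnedTrack(small_genome, 1000, z)
        assert np.all(log2_ratio_track(t, t, 0.5).values["chr1"] == 0)
        other = BinnedTrack(
            small_genome, 500, {c: np.zeros(-(-small_genome[c] // 500)) for c in small_genome}
        )
        with pytest.raises(CoverageError):
            log2_ratio_track(t, other)


def constant_track(genome, bin_size, value):
    return BinnedTrack(
        genome, bin_size, {c: np.full(-(-genome[c] // bin_size), float(value)) for c in genome}
    )


class TestReferencePointMatrix:
    def test_constant_track_gives_constant_matrix(self, small_genome):
        track = constant_track(small_genome, 100, 3.5)
        m = reference_point_matrix(
            track, [GenomicInterval("chr1", 40_000, 42_000)], flank=5000, out_bins=20
        )
        np.testing.assert_allclose(m.values, 3.5)

    def test_spike_lands_in_central_column(self, small_genome):
        track = constant_track(small_genome, 100, 1.0)
        track.values["chr1"][410] = 50.0  # spike at 41_000-41_100
        m = reference_point_matrix(
            track, [GenomicInterval("chr1", 40_000, 42_000)], flank=5000, out_bins=20
        )
        assert int(np.argmax(m.values[0])) in (9, 10)

    def test_minus_strand_row_is_mirror_of_plus(self, small_genome):
        track = constant_track(small_genome, 100, 1.0)
        track.values["chr1"][300:320] = 9.0  # signal left of the anchor
        plus = GenomicInterval("chr1", 39_000, 41_000, strand="+")
        minus = GenomicInterval("chr1", 39_000, 41_000, strand="-")
        m = reference_point_matrix(track, [plus, minus], flank=8000, out_bins=40)
        np.testing.assert_allclose(m.values[1], m.values[0][::-1])

    def test_edges_are_masked_not_zero(self, small_genome):
        track = constant_track(small_genome, 100, 2.0)
        m = reference_point_matrix(
            track, [GenomicInterval("chr1", 0, 1000)], flank=5000, out_bins=10
        )
        assert np.isnan(m.values[0][0])
        means = column_mean_profile(m)
        assert np.nansum(means) > 0

    def test_empty_regions_rejected(self, small_genome):
        with pytest.raises(CoverageError):
            reference_point_matrix(constant_track(small_genome, 100, 1.0), [], 1000, 10)


class TestScaledRegionMatrix:
    @staticmethod
    def _gene(gid, start, end, strand="+"):
        return GeneModel(
            gene_id=gid,
            interval=GenomicInterval("chr1", start, end, strand),
            exons=(GenomicInterval("chr1", start, end, strand),),
        )

    def test_constant_track(self, small_genome):
        track = constant_track(small_genome, 100, 2.0)
        m = scaled_region_matrix(
            track, [self._gene("g", 30_000, 40_000)], flank=5000, body_bins=20, flank_bins=5
        )
        np.testing.assert_allclose(m.values, 2.0)

    def test_self_similar_genes_have_identical_body_columns(self, small_genome):
        # both genes carry signal over the first half of their body
        track = constant_track(small_genome, 100, 1.0)
        track.values["chr1"][100:150] = 5.0  # gene A 10k-20k: first half
        track.values["chr2"][100:350] = 5.0  # gene B 10k-60k: first half
        genes = [self._gene("A", 10_000, 20_000)]
        gene_b = GeneModel(
            gene_id="B",
            interval=GenomicInterval("chr2", 10_000, 60_000, "+"),
            exons=(GenomicInterval("chr2", 10_000, 60_000, "+"),),
        )
        m = scaled_region_matrix(track, genes + [gene_b], 2000, body_bins=10, flank_bins=2)
        body_a = m.values[0][2:12]
        body_b = m.values[1][2:12]
        np.testing.assert_allclose(body_a, body_b)

    def test_minus_strand_upstream_signal_lands_left(self, small_genome):
        track = constant_track(small_genome, 100, 0.0)
        track.values["chr1"][400:420] = 7.0  # genomic right of gene = 5' for minus
        g = self._gene("g", 30_000, 39_000, strand="-")
        m = scaled_region_matrix(track, [g], flank=3000, body_bins=10, flank_bins=3)
        left_flank, right_flank = m.values[0][:3], m.values[0][-3:]
        assert left_flank.sum() > 0 and np.allclose(right_flank, 0.0)


class TestColumnMeans:
    def test_single_and_paired_rows(self, small_genome):
        track = constant_track(small_genome, 100, 1.0)
        m = reference_point_matrix(
            track, [GenomicInterval("chr1", 40_000, 42_000)], 2000, 10
        )
        np.testing.assert_allclose(column_mean_profile(m), m.values[0])

    def test_random_matrix_matches_two_loop_oracle(self, rng):
        from epidyn.coverage import MetaProfileMatrix

        vals = rng.random((50, 20))
        vals[rng.random((50, 20)) < 0.1] = np.nan
        m = MetaProfileMatrix(
            [f"r{i}" for i in range(50)], vals, np.arange(20.0), 10, "reference_point"
        )
        got = column_mean_profile(m)
        for j in range(20):
            col = [vals[i, j] for i in range(50) if not np.isnan(vals[i, j])]
            assert got[j] == pytest.approx(sum(col) / len(col))


class TestBinnedCorrelation:
    def _tracks(self, genome, rng, n=2):
        out = []
        for _ in range(n):
            out.append(
                BinnedTrack(
                    genome,
                    1000,
                    {c: rng.random(-(-genome[c] // 1000)) for c in genome},
                )
            )
        return out

    def test_self_correlation_is_one(self, small_genome, rng):
        t = self._tracks(small_genome, rng, 1)[0]
        mat = binned_correlation([t, t], 1000, "pearson")
        np.testing.assert_allclose(mat, 1.0)

    def test_negation_is_minus_one(self, small_genome, rng):
        t = self._tracks(small_genome, rng, 1)[0]
        neg = BinnedTrack(small_genome, 1000, {c: -t.values[c] for c in small_genome})
        mat = binned_correlation([t, neg], 1000, "pearson")
        assert mat[0, 1] == pytest.approx(-1.0)

    def test_matches_textbook_formulas(self, small_genome, rng):
        a, b = self._tracks(small_genome, rng, 2)
        x = np.concatenate([a.values[c] for c in small_genome])
        y = np.concatenate([b.values[c] for c in small_genome])
        pearson_oracle = float(
            ((x - x.mean()) * (y - y.mean())).sum()
            / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        mat = binned_correlation([a, b], 1000, "pearson")
        assert mat[0, 1] == pytest.approx(pearson_oracle, abs=1e-10)
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        spearman_oracle = float(np.corrcoef(rx, ry)[0, 1])
        mat_s = binned_correlation([a, b], 1000, "spearman")
        assert mat_s[0, 1] == pytest.approx(spearman_oracle, abs=1e-10)

    def test_matrix_is_symmetric_psd_unit_diagonal(self, small_genome, rng):
        tracks = self._tracks(small_genome, rng, 4)
        mat = binned_correlation(tracks, 2000, "spearman")
        np.testing.assert_allclose(mat, mat.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(mat), 1.0)
        assert np.linalg.eigvalsh(mat).min() > -1e-9

    def test_too_few_bins_rejected(self, small_genome, rng):
        tracks = self._tracks(small_genome, rng, 2)
        with pytest.raises(CoverageError):
            binned_correlation(tracks, 100_000, "pearson")


class TestPeakCaller:
    def test_planted_enrichment_recovered_once(self):
        genome = GenomeIndex({"c": 200_000})
        rng = np.random.default_rng(5)
        n_bg = 20_000
        bg = rng.integers(0, 200_000, n_bg)
        extra = rng.integers(90_000, 92_000, 1800)  # 10x in a 2 kb region
        treat_mids = np.concatenate([bg, extra])
        ctrl_mids = rng.integers(0, 200_000, n_bg)

        def to_set(mids):
            return FragmentSet({"c": (mids - 50, mids + 50)})

        peaks = call_enriched_peaks(to_set(treat_mids), to_set(ctrl_mids), genome, 300, 100, 0.05)
        hits = [p for p in peaks if p.interval.end > 89_000 and p.interval.start < 93_000]
        assert len(hits) == 1
        iv = hits[0].interval
        inter = min(iv.end, 92_000) - max(iv.start, 90_000)
        union = max(iv.end, 92_000) - min(iv.start, 90_000)
        assert inter / union >= 0.8
        assert hits[0].fold_enrichment > 5
        assert hits[0].q_value >= hits[0].p_value

    def test_qmax_one_merges_covered_blocks(self):
        genome = GenomeIndex({"c": 10_000})
        mids = np.arange(100, 9_900, 10)
        fs = FragmentSet({"c": (mids - 20, mids + 20)})
        peaks = call_enriched_peaks(fs, fs, genome, 300, 100, q_max=1.0)
        assert len(peaks) == 1  # one contiguous covered block
        starts_ends = [(p.interval.start, p.interval.end) for p in peaks]
        assert starts_ends == sorted(starts_ends)

    def test_empty_control_warns(self):
        genome = GenomeIndex({"c": 50_000})
        rng = np.random.default_rng(0)
        mids = rng.integers(0, 50_000, 2000)
        fs = FragmentSet({"c": (mids - 30, mids + 30)})
        with pytest.warns(UserWarning):
            call_enriched_peaks(fs, None, genome, 300, 100, 0.05)


class TestFeatureCoverage:
    def test_constant_track(self, small_genome):
        track = constant_track(small_genome, 100, 4.2)
        out = feature_coverage_summary(
            track,
            {"exon": [GenomicInterval("chr1", 1000, 3000)],
             "intergenic": [GenomicInterval("chr2", 0, 5000)]},
        )
        assert out["exon"] == pytest.approx(4.2)
        assert out["intergenic"] == pytest.approx(4.2)

    def test_two_level_fixture_orders_labels(self, small_genome):
        track = constant_track(small_genome, 100, 1.0)
        track.values["chr1"][10:20] = 10.0
        out = feature_coverage_summary(
            track,
            {"exon": [GenomicInterval("chr1", 1000, 2000)],
             "intergenic": [GenomicInterval("chr1", 50_000, 60_000)]},
        )
        assert out["exon"] > out["intergenic"]

    def test_random_fixture_matches_per_base_oracle(self, small_genome, rng):
        track = BinnedTrack(
            small_genome, 100,
            {c: rng.random(-(-small_genome[c] // 100)) for c in small_genome},
        )
        ivs = [
            GenomicInterval("chr1", int(s), int(s) + int(l))
            for s, l in zip(rng.integers(0, 90_000, 20), rng.integers(30, 5000, 20))
        ]
        got = feature_coverage_summary(track, {"x": ivs})["x"]
        num = den = 0.0
        for iv in ivs:
            for pos in range(iv.start, iv.end):
                num += track.values["chr1"][pos // 100]
                den += 1
        assert got == pytest.approx(num / den, abs=1e-9)
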