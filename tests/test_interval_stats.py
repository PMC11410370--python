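"""Interval statistics: merging, Jaccard (with bedtools as independent
oracle), relative distance, peak classification and Fisher's exact test."""
import itertools
import math
import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ovokit.core import GenomicInterval, IntervalSet, TranscriptModel
from ovokit.interval_stats import (classify_peaks, closest_tss, fisher_exact,
                                   jaccard, merge_intervals, overlap_fisher,
                                   relative_distance)


def iset(spans, chrom="chr1"):
    return IntervalSet([GenomicInterval(chrom, s, e) for s, e in spans])


class TestMerge:
    @pytest.mark.parametrize("spans,expected", [
        ([(0, 10), (5, 15)], [(0, 15)]),
        ([(0, 10), (10, 20)], [(0, 20)]),      # bookended merge
        ([(0, 10), (20, 30)], [(0, 10), (20, 30)]),
    ])
    def test_merge_semantics(self, spans, expected):
        got = [(iv.start, iv.end) for iv in merge_intervals(iset(spans))]
        assert got == expected

    @given(st.lists(st.tuples(st.integers(0, 500), st.integers(1, 50)),
                    min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_merge_never_increases_bp(self, raw):
        ivs = iset([(s, s + w) for s, w in raw])
        merged = merge_intervals(ivs)
        covered = set()
        for s, w in raw:
            covered.update(range(s, s + w))
        assert merged.total_bp() == len(covered)


class TestJaccard:
    def test_basic(self):
        r = jaccard(iset([(0, 100)]), iset([(50, 150)]))
        assert (r.intersection_bp, r.union_bp) == (50, 150)
        assert r.jaccard == pytest.approx(1 / 3)

    def test_self_is_one_and_disjoint_is_zero(self):
        a = iset([(0, 10), (20, 40)])
        assert jaccard(a, a).jaccard == 1.0
        r = jaccard(a, iset([(100, 110)]))
        assert r.jaccard == 0.0 and r.n_overlapping_pairs == 0

    def test_symmetry_and_empty_error(self):
        a, b = iset([(0, 30)]), iset([(10, 50), (60, 70)])
        assert jaccard(a, b).jaccard == jaccard(b, a).jaccard
        with pytest.raises(ValueError):
            jaccard(IntervalSet([]), IntervalSet([]))

    @pytest.mark.skipif(shutil.which("bedtools") is None,
                        reason="bedtools not on PATH")
    def test_against_bedtools(self, tmp_path, rng):
        """bedtools jaccard as an independent oracle on random sets."""
        def rand_bed(path, n):
            rows = sorted((int(s), int(s + w)) for s, w in
                          zip(rng.integers(0, 100_000, n),
                              rng.integers(50, 500, n)))
            path.write_text("".join(f"chr1\t{s}\t{e}\n" for s, e in rows))
            return rows
        a, b = tmp_path / "a.bed", tmp_path / "b.bed"
        spans_a, spans_b = rand_bed(a, 80), rand_bed(b, 60)
        out = subprocess.run(["bedtools", "jaccard", "-a", str(a), "-b", str(b)],
                             capture_output=True, text=True, check=True)
        vals = out.stdout.splitlines()[1].split("\t")
        expected_inter, expected_union = int(vals[0]), int(vals[1])
        r = jaccard(iset(spans_a), iset(spans_b))
        assert r.intersection_bp == expected_inter
        assert r.union_bp == expected_union
        assert r.jaccard == pytest.approx(float(vals[2]), abs=5e-7)


class TestRelativeDistance:
    def test_known_values(self):
        refs = {"chr1": np.array([0, 100])}
        for mid, expect in [(25, 0.25), (50, 0.5), (0, 0.0)]:
            q = iset([(mid, mid + 1)]) if mid else iset([(0, 1)])
            # midpoint of (mid, mid+1) is mid
            r = relative_distance(q, refs)
            assert r.values[0] == pytest.approx(expect)

    def test_outside_references_dropped(self):
        refs = {"chr1": np.array([100, 200])}
        r = relative_distance(iset([(0, 10), (120, 130)]), refs)
        assert r.n_dropped == 1 and len(r.values) == 1

    def test_needs_two_references(self):
        with pytest.raises(ValueError):
            relative_distance(iset([(5, 6)]), {"chr1": np.array([10])})

    def test_affine_invariance(self, rng):
        refs = np.sort(rng.integers(0, 10_000, 50))
        mids = rng.integers(refs[0], refs[-1], 200)
        r1 = relative_distance(iset([(m, m + 1) for m in mids]),
                               {"chr1": refs})
        scale, shift = 7, 13
        r2 = relative_distance(
            iset([(scale * m + shift, scale * m + shift + 1) for m in mids]),
            {"chr1": refs * scale + shift})
        # midpoints of width-1 intervals transform exactly
        assert np.allclose(np.sort(r1.values), np.sort(r2.values))

    def test_flat_under_null(self, rng):
        """Uniform random queries over dense uniform references give a flat
        histogram (max - min bin frequency < 0.01 at 1e4 queries).

        Reference spacing 1000 keeps the discrete statistic fine-grained
        relative to the 0.02 bins (spacing 100 would quantize the edge bins).
        """
        refs = np.arange(0, 1_000_001, 1000)
        mids = rng.integers(0, 1_000_000, 10_000)
        r = relative_distance(iset([(m, m + 1) for m in mids]),
                              {"chr1": refs})
        assert r.histogram.max() - r.histogram.min() < 0.01


def make_tx(gid, chrom, start, end, strand="+"):
    return TranscriptModel(gene_id=gid, transcript_id=gid + "_t",
                           chrom=chrom, start=start, end=end, strand=strand)


class TestClassify:
    def test_three_labels(self):
        tx = [make_tx("g1", "chr1", 100, 500)]
        peaks = iset([(90, 110), (200, 250), (10_000, 10_100)])
        res = classify_peaks(peaks, tx)
        assert res.labels == ["TSS", "gene_body", "intergenic"]
        assert sum(res.counts.values()) == 3
        assert res.assigned_gene == ["g1", "g1", "g1"]

    def test_minus_strand_tss(self):
        tx = [make_tx("g1", "chr1", 100, 500, strand="-")]
        res = classify_peaks(iset([(490, 510)]), tx)
        assert res.labels == ["TSS"]  # tss = 499

    def test_percent_rounding(self):
        tx = [make_tx("g1", "chr1", 100, 500)]
        peaks = iset([(90, 110)] * 1 + [(200, 210)] * 1 + [(5000, 5010)] * 1)
        res = classify_peaks(peaks, tx)
        assert sum(res.percents.values()) in (99, 100, 101)


class TestClosestTss:
    def test_signed_distance(self):
        tx = [make_tx("a", "chr1", 100, 400), make_tx("b", "chr1", 210, 600)]
        gid, d = closest_tss(GenomicInterval("chr1", 140, 160), tx)
        assert (gid, d) == ("a", -50)

    def test_tie_breaks_lexicographically(self):
        tx = [make_tx("zeta", "chr1", 100, 300), make_tx("alpha", "chr1", 200, 900)]
        gid, _ = closest_tss(GenomicInterval("chr1", 149, 151), tx)
        assert gid == "alpha"

    def test_empty_chromosome_errors(self):
        with pytest.raises(ValueError):
            closest_tss(GenomicInterval("chr9", 0, 10),
                        [make_tx("a", "chr1", 0, 10)])


def brute_force_fisher_p(n11, n12, n21, n22):
    """Two-sided Fisher p by exhaustive enumeration over fixed margins."""
    r1, c1, n = n11 + n12, n11 + n21, n11 + n12 + n21 + n22

    def point_p(k):
        return (math.comb(c1, k) * math.comb(n - c1, r1 - k)
                / math.comb(n, r1))

    p_obs = point_p(n11)
    total = 0.0
    for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        pk = point_p(k)
        if pk <= p_obs * (1 + 1e-10):
            total += pk
    return total


class TestFisher:
    def test_reconstructed_study_table(self):
        ct = fisher_exact((666, 1632, 1328, 7178))
        assert ct.odds_ratio == pytest.approx(2.21, abs=0.005)
        assert ct.p_two_sided < 0.01

    def test_symmetric_table(self):
        ct = fisher_exact((5, 5, 5, 5))
        assert ct.odds_ratio == 1.0
        assert ct.p_two_sided == pytest.approx(1.0)

    def test_infinite_and_degenerate_conventions(self):
        assert fisher_exact((5, 1, 0, 4)).odds_ratio == math.inf
        with pytest.warns(UserWarning):
            ct = fisher_exact((0, 0, 3, 4))  # zero margin
        assert math.isnan(ct.odds_ratio) and ct.p_two_sided == 1.0

    def test_matches_enumeration_small_tables(self, rng):
        """p equals brute-force enumeration for random tables with n <= 30."""
        for _ in range(200):
            cells = rng.multinomial(int(rng.integers(1, 31)),
                                    [0.25] * 4)
            n11, n12, n21, n22 = map(int, cells)
            if min(n11 + n12, n21 + n22, n11 + n21, n12 + n22) == 0:
                continue
            ct = fisher_exact((n11, n12, n21, n22))
            assert ct.p_two_sided == pytest.approx(
                brute_force_fisher_p(n11, n12, n21, n22), abs=1e-9)

    def test_conditional_mle_close_to_sample_or(self):
        ct = fisher_exact((666, 1632, 1328, 7178))
        assert ct.conditional_mle_or() == pytest.approx(ct.odds_ratio, rel=0.01)


class TestOverlapFisher:
    def test_identical_sets_infinite_or(self):
        a = iset([(i * 100, i * 100 + 10) for i in range(5)])
        ct = overlap_fisher(a, a, genome_size=1000)
        assert ct.n11 == 5 and ct.n12 == 0 and ct.n21 == 0
        assert ct.odds_ratio == math.inf

    def test_disjoint_sets_zero_or(self):
        a = iset([(0, 10), (50, 60)])
        b = iset([(1000, 1010), (2000, 2010)])
        ct = overlap_fisher(a, b, genome_size=100_000)
        assert ct.n11 == 0 and ct.odds_ratio == 0.0

    def test_null_calibration(self, rng):
        """Independent random sets give a stable, moderately inflated OR.

        The genome-slot n22 construction counts slots of one mean interval
        width while co-overlap of two intervals needs w_a + w_b, so for
        sparse independent sets the sample OR concentrates near 2 rather
        than 1 — a documented bias of this descriptive heuristic.
        """
        ors = []
        for _ in range(60):
            def rand(n):
                starts = rng.integers(0, 1_000_000, n)
                return iset([(int(s), int(s) + 200) for s in starts])
            ct = overlap_fisher(rand(200), rand(200), genome_size=1_000_000)
            if math.isfinite(ct.odds_ratio):
                ors.append(ct.odds_ratio)
        med = float(np.median(ors))
        assert 1.0 <= med <= 3.0

    def test_bad_genome_size(self):
        with pytest.raises(ValueError):
            overlap_fisher(iset([(0, 10)]), iset([(0, 10)]), genome_size=0)
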