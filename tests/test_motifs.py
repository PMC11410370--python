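"""Motif scanning: IUPAC semantics, exact PWM p-values vs enumeration,
peak annotation fractions, mask-and-rescan and positional density."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ovokit.core import GenomicInterval, IntervalSet, revcomp
from ovokit.motifs import (MotifModel, annotate_peak_motifs,
                           default_ovo_catalog, iupac_scan,
                           motif_density_around_points, motif_mask_rescan,
                           pwm_scan, pwm_score_distribution,
                           pwm_threshold_from_pvalue, _discretized_scores)


class TestIupacScan:
    def test_core_motif_plus_hit(self):
        m = MotifModel.from_consensus("core", "TAACNGT")
        hits = iupac_scan("GGTAACAGTGG", m, both_strands=True)
        assert [(h.start, h.strand) for h in hits] == [(2, "+")]

    def test_minus_strand_hit_forward_coordinates(self):
        m = MotifModel.from_consensus("core", "TAACNGT")
        hits = iupac_scan("CCACAGTTACC", m, both_strands=True)
        assert len(hits) == 1 and hits[0].strand == "-"
        # the reported forward window reverse-complements to a match
        assert hits[0].matched_sequence == "ACAGTTA"

    def test_n_in_sequence_matches_nothing(self):
        m = MotifModel.from_consensus("m", "NNNN")
        assert iupac_scan("NNNNNNN", m) == []

    def test_invalid_iupac_rejected(self):
        with pytest.raises(ValueError):
            MotifModel.from_consensus("bad", "TAXGT")

    @given(st.text(alphabet="ACGT", min_size=8, max_size=40))
    @settings(max_examples=60, deadline=None)
    def test_revcomp_invariance(self, seq):
        """Scanning the reverse complement yields mirrored hits."""
        m = MotifModel.from_consensus("core", "TAACNGT")
        fwd = iupac_scan(seq, m, both_strands=True)
        rc = iupac_scan(revcomp(seq), m, both_strands=True)
        n = len(seq)
        L = len(m)
        mapped = sorted((n - h.end, {"+": "-", "-": "+"}[h.strand])
                        for h in rc)
        assert mapped == sorted((h.start, h.strand) for h in fwd)


class TestPwmPvalues:
    def test_exact_match_pwm_closed_form(self):
        """Exact-match PWMs: best-word p = 4^-L under uniform background,
        so L=4 misses alpha=0.003 while L=5 passes."""
        m4 = MotifModel.from_consensus("m4", "ACGT")
        with pytest.warns(UserWarning, match="best-word"):
            pwm_threshold_from_pvalue(m4, 0.003)  # 4^-4 ~ 0.0039 > 0.003
        m5 = MotifModel.from_consensus("m5", "ACGTA")
        thr = pwm_threshold_from_pvalue(m5, 0.003)  # 4^-5 ~ 0.00098 <= 0.003
        grid, probs, _ = pwm_score_distribution(m5)
        assert thr == pytest.approx(grid[probs > 0][-1])

    def test_distribution_sums_to_one(self):
        rng = np.random.default_rng(5)
        for L in (3, 6):
            pwm = rng.dirichlet(np.ones(4) * 2, size=L)
            m = MotifModel("r", "N" * L, pwm=pwm)
            grid, probs, dead = pwm_score_distribution(m)
            assert probs.sum() + dead == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("L", [3, 5, 8])
    def test_dp_equals_word_enumeration(self, L):
        """DP tail probabilities equal exhaustive enumeration over 4^L words."""
        rng = np.random.default_rng(L)
        pwm = rng.dirichlet(np.ones(4), size=L)
        m = MotifModel("r", "N" * L, pwm=pwm)
        _, probs, dead = pwm_score_distribution(m)
        ints, lo, step = _discretized_scores(m)
        enum = np.zeros_like(probs)
        for word in itertools.product(range(4), repeat=L):
            s = sum(int(ints[i, b]) for i, b in enumerate(word))
            enum[s] += 0.25 ** L
        assert np.allclose(probs, enum, atol=1e-12)
        assert dead == pytest.approx(0.0, abs=1e-12)

    def test_background_enters_scores(self):
        pwm = np.tile([0.7, 0.1, 0.1, 0.1], (4, 1))
        skew = MotifModel("s", "NNNN", pwm=pwm,
                          background=np.array([0.4, 0.1, 0.1, 0.4]))
        unif = MotifModel("u", "NNNN", pwm=pwm)
        t_skew = pwm_threshold_from_pvalue(skew, 0.01)
        t_unif = pwm_threshold_from_pvalue(unif, 0.01)
        assert t_skew != t_unif


class TestPwmScan:
    def test_exact_word_single_hit(self):
        m = MotifModel.from_consensus("w", "TAACG")
        hits = pwm_scan("GGGTAACGGG", m, alpha=0.001, both_strands=False)
        assert [(h.start, h.end) for h in hits] == [(3, 8)]

    def test_alpha_one_not_allowed_but_high_alpha_hits_everywhere(self):
        m = MotifModel.from_consensus("w", "NN")
        hits = pwm_scan("ACGTACGT", m, alpha=0.9999, both_strands=False)
        assert len(hits) == 8 - 2 + 1

    def test_matches_naive_threshold_scan(self):
        rng = np.random.default_rng(9)
        pwm = rng.dirichlet(np.ones(4) * 0.5, size=6)
        m = MotifModel("r", "N" * 6, pwm=pwm)
        seq = "".join(rng.choice(list("ACGT"), 400))
        thr = pwm_threshold_from_pvalue(m, 0.01)
        ints, lo, step = _discretized_scores(m)

        def naive(seq_):
            out = []
            for i in range(len(seq_) - 6 + 1):
                w = seq_[i:i + 6]
                s = sum(int(ints[j, "ACGT".index(c)]) for j, c in enumerate(w))
                if s * step + 6 * lo >= thr - 1e-12:
                    out.append(i)
            return out

        got = [(h.start, h.strand) for h in pwm_scan(seq, m, alpha=0.01)]
        expected = sorted([(i, "+") for i in naive(seq)] +
                          [(len(seq) - i - 6, "-") for i in naive(revcomp(seq))])
        assert sorted(got) == expected

    def test_probability_one_pwm_equals_iupac(self):
        m = MotifModel.from_consensus("w", "TAACGG")
        seq = "TTTAACGGAATAACGGC" + revcomp("TAACGG")
        a = {(h.start, h.strand) for h in pwm_scan(seq, m, alpha=0.001)}
        b = {(h.start, h.strand) for h in iupac_scan(seq, m)}
        assert a == b


class TestPeakAnnotation:
    def test_fraction_arithmetic(self, tmp_path):
        fa = tmp_path / "g.fa"
        base = "AT" * 30
        fa.write_text(">c\n" + "TAACGGTAAA".join([base] * 4) + base + "\n")
        peaks = IntervalSet([GenomicInterval("c", i * 70, i * 70 + 70)
                             for i in range(4)])
        cat = [MotifModel.from_consensus("m1", "TAACGGTAAA")]
        ann = annotate_peak_motifs(peaks, fa, cat)
        assert 0.0 < ann.any_motif_fraction <= 1.0
        assert ann.presence.shape == (4, 1)

    def test_empty_peakset_errors(self, tmp_path, tiny_fasta):
        with pytest.raises(ValueError):
            annotate_peak_motifs(IntervalSet([]), tiny_fasta,
                                 default_ovo_catalog())

    def test_planted_fraction_recovered(self, bundle, bundle_dir):
        """Scanning recovers the realized planted fraction within a binomial
        99% CI (background matches can only push the estimate up)."""
        ann = annotate_peak_motifs(bundle.peaks_consensus,
                                   bundle_dir / "genome.fa",
                                   default_ovo_catalog())
        p = bundle.truth["motifs"]["planted_fraction"]
        n = len(bundle.peaks_consensus)
        se = np.sqrt(p * (1 - p) / n)
        assert p - 2.576 * se <= ann.any_motif_fraction <= p + 2.576 * se + 0.05


class TestMaskRescan:
    def test_all_contain_first(self, tmp_path):
        fa = tmp_path / "g.fa"
        fa.write_text(">c\n" + ("AT" * 20 + "TAACGGTAAA" + "AT" * 20) * 3 + "\n")
        w = 90
        peaks = IntervalSet([GenomicInterval("c", i * w, (i + 1) * w)
                             for i in range(3)])
        cat = [MotifModel.from_consensus("m1", "TAACGGTAAA")]
        res = motif_mask_rescan(peaks, fa, cat)
        assert res == [("m1", 1.0, 3)]

    def test_disjoint_halves(self, tmp_path):
        fa = tmp_path / "g.fa"
        pad = "AT" * 25
        seq = pad + "TAACGGTAAA" + pad + pad + "CCCGGGCCCA" + pad
        fa.write_text(">c\n" + seq + "\n")
        half = len(seq) // 2
        peaks = IntervalSet([GenomicInterval("c", 0, half),
                             GenomicInterval("c", half, len(seq))])
        cat = [MotifModel.from_consensus("m1", "TAACGGTAAA"),
               MotifModel.from_consensus("m2", "CCCGGGCCCA")]
        res = motif_mask_rescan(peaks, fa, cat)
        assert [(r[0], r[1]) for r in res] == [("m1", 0.5), ("m2", 1.0)]

    def test_consistent_with_presence_matrix(self, bundle, bundle_dir):
        cat = default_ovo_catalog()
        ann = annotate_peak_motifs(bundle.peaks_consensus,
                                   bundle_dir / "genome.fa", cat)
        res = motif_mask_rescan(bundle.peaks_consensus,
                                bundle_dir / "genome.fa", cat)
        remaining = ann.presence.index.to_numpy()
        for (name, frac, n_before) in res:
            assert n_before == len(remaining)
            has = ann.presence.loc[remaining, name]
            if n_before:
                assert frac == pytest.approx(float(has.mean()))
            remaining = remaining[~has.to_numpy()]


class TestMotifDensity:
    def test_single_hit_center_bin(self):
        from ovokit.motifs import MotifHit
        hits = [MotifHit("m", "c", 98, 103, "+", None, "AAAAA")]
        centers, pct = motif_density_around_points(hits, [("c", 100, "+")],
                                                   window=100, bin=25)
        # offset 0 falls in the [0, 25) bin, centered at 12.5
        assert pct.sum() == 100.0
        assert centers[pct.argmax()] == 12.5

    def test_minus_strand_point_flips_offset(self):
        from ovokit.motifs import MotifHit
        hits = [MotifHit("m", "c", 128, 133, "+", None, "AAAAA")]  # mid 130
        centers, pct = motif_density_around_points(hits, [("c", 100, "-")],
                                                   window=100, bin=25)
        hit_bins = centers[pct > 0]
        assert len(hit_bins) == 1 and hit_bins[0] < 0  # +30 becomes -30

    def test_planted_offsets_peak_at_center(self, bundle):
        truth = bundle.truth["motifs"]["planted"]
        hits = [type("H", (), {})() for _ in ()]
        from ovokit.motifs import MotifHit
        hits = [MotifHit(p["motif"], p["chrom"], p["start"], p["end"],
                         p["strand"], None, p["word"]) for p in truth]
        points = [(iv.chrom, iv.midpoint, "+")
                  for iv in bundle.peaks_consensus]
        centers, pct = motif_density_around_points(hits, points,
                                                   window=500, bin=50)
        assert abs(centers[pct.argmax()]) <= 50
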