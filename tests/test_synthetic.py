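"""Synthetic generator: determinism, statistical calibration of each
sub-generator, and planted-structure bookkeeping."""
import math

import numpy as np
import pytest
from scipy import stats

from ovokit.interval_stats import jaccard
from ovokit.synthetic import (ScenarioConfig, generate_cage_tags,
                              generate_coverage_tracks, generate_de_and_lists,
                              generate_gene_models, generate_genome,
                              generate_peak_replicates, plant_motifs,
                              simulate_scenario, stage_rng)
from ovokit.motifs import MotifModel, iupac_scan


class TestGenome:
    def test_gc_within_three_se(self):
        g = generate_genome(100_000, 1, 0.5, seed=1)
        seq = g["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        se = math.sqrt(0.25 / 100_000)
        assert abs(gc - 0.5) < 3 * se

    def test_deterministic(self):
        assert generate_genome(20_000, 2, 0.4, seed=7) == \
               generate_genome(20_000, 2, 0.4, seed=7)

    def test_gc_zero_rejected(self):
        with pytest.raises(ValueError):
            generate_genome(20_000, 1, 0.0, seed=1)

    def test_minimum_length(self):
        with pytest.raises(ValueError):
            generate_genome(5_000, 1, 0.5, seed=1)


class TestGeneModels:
    def test_nonoverlap_and_spacing(self):
        g = generate_genome(1_000_000, 1, 0.5, seed=2)
        models = generate_gene_models(g, 50, seed=2)
        assert len(models) == 50
        models.sort(key=lambda m: m.start)
        for a, b in zip(models, models[1:]):
            assert b.start - a.end >= 500

    def test_strand_balance(self):
        g = generate_genome(10_000_000, 4, 0.5, seed=3)
        models = generate_gene_models(g, 1000, seed=3)
        n_plus = sum(1 for m in models if m.strand == "+")
        p = stats.binomtest(n_plus, 1000, 0.5).pvalue
        assert p > 0.001

    def test_too_many_genes_rejected(self):
        g = generate_genome(20_000, 1, 0.5, seed=4)
        with pytest.raises(ValueError):
            generate_gene_models(g, 50, seed=4)


class TestPeakReplicates:
    def setup_method(self):
        self.genome = generate_genome(1_200_000, 2, 0.5, seed=5)
        self.sizes = {c: len(s) for c, s in self.genome.items()}
        self.tx = generate_gene_models(self.genome, 200, seed=5)

    def test_target_one_identical_sets(self):
        r1, r2, j = generate_peak_replicates(self.tx, 100, 300, 0.4, 1.0,
                                             seed=5, genome_sizes=self.sizes)
        assert j == 1.0
        assert [iv.start for iv in r1] == [iv.start for iv in r2]

    def test_target_zero_disjoint(self):
        r1, r2, j = generate_peak_replicates(self.tx, 80, 300, 0.4, 0.0,
                                             seed=5, genome_sizes=self.sizes)
        assert j == 0.0
        assert jaccard(r1, r2).intersection_bp == 0

    def test_study_target_within_tolerance(self):
        """The replicate-agreement condition: bp-Jaccard 0.64 +/- 0.05."""
        _, _, j = generate_peak_replicates(self.tx, 200, 300, 0.45, 0.64,
                                           seed=5, genome_sizes=self.sizes)
        assert 0.59 <= j <= 0.69

    def test_realized_equals_recomputed(self):
        r1, r2, j = generate_peak_replicates(self.tx, 150, 300, 0.45, 0.64,
                                             seed=6, genome_sizes=self.sizes)
        assert jaccard(r1, r2).jaccard == j


class TestPlantMotifs:
    def test_full_plant_every_peak_matches(self):
        genome = generate_genome(200_000, 1, 0.5, seed=8)
        sizes = {c: len(s) for c, s in genome.items()}
        tx = generate_gene_models(genome, 30, seed=8)
        r1, _, _ = generate_peak_replicates(tx, 40, 300, 0.5, 1.0, seed=8,
                                            genome_sizes=sizes)
        motif = MotifModel.from_consensus("m", "TAACGGTAAA")
        edited, truth = plant_motifs(genome, r1, motif, 1.0, 10.0, seed=8)
        assert truth["planted_fraction"] == 1.0
        for iv in r1:
            seq = edited[iv.chrom][iv.start:iv.end]
            assert iupac_scan(seq, motif, both_strands=True)

    def test_zero_offset_lands_on_summit(self):
        genome = generate_genome(100_000, 1, 0.5, seed=9)
        sizes = {c: len(s) for c, s in genome.items()}
        tx = generate_gene_models(genome, 10, seed=9)
        r1, _, _ = generate_peak_replicates(tx, 10, 300, 0.5, 1.0, seed=9,
                                            genome_sizes=sizes)
        motif = MotifModel.from_consensus("m", "TAACGGTAAA")
        _, truth = plant_motifs(genome, r1, motif, 1.0, 0.0, seed=9)
        for p in truth["planted"]:
            iv = next(x for x in r1 if x.name == p["peak"])
            center = (p["start"] + p["end"]) // 2
            assert abs(center - iv.midpoint) <= 1

    def test_truth_positions_exact(self):
        genome = generate_genome(100_000, 1, 0.5, seed=10)
        sizes = {c: len(s) for c, s in genome.items()}
        tx = generate_gene_models(genome, 10, seed=10)
        r1, _, _ = generate_peak_replicates(tx, 10, 300, 0.5, 1.0, seed=10,
                                            genome_sizes=sizes)
        motif = MotifModel.from_consensus("m", "TAACGGT")
        edited, truth = plant_motifs(genome, r1, motif, 0.7, 20.0, seed=10)
        for p in truth["planted"]:
            word = edited[p["chrom"]][p["start"]:p["end"]]
            assert word == p["word"]


class TestCageAndCoverage:
    def test_zero_spread_all_tags_at_tss(self):
        genome = generate_genome(100_000, 1, 0.5, seed=11)
        tx = generate_gene_models(genome, 20, seed=11)
        tags = generate_cage_tags(tx, 30.0, 0.0, seed=11)
        tss = {(t.chrom, t.tss(), t.strand) for t in tx}
        assert set(tags) <= tss

    def test_total_tags_poisson_consistent(self):
        genome = generate_genome(500_000, 1, 0.5, seed=12)
        tx = generate_gene_models(genome, 100, seed=12)
        tags = generate_cage_tags(tx, 50.0, 5.0, seed=12)
        total = sum(tags.values())
        mean = 100 * 50
        assert abs(total - mean) < 3 * math.sqrt(mean)

    def test_same_seed_identical(self):
        genome = generate_genome(100_000, 1, 0.5, seed=13)
        tx = generate_gene_models(genome, 20, seed=13)
        assert generate_cage_tags(tx, 20.0, 3.0, seed=13) == \
               generate_cage_tags(tx, 20.0, 3.0, seed=13)

    def test_noiseless_coverage_peaks_at_summit(self):
        genome = generate_genome(100_000, 1, 0.5, seed=14)
        sizes = {c: len(s) for c, s in genome.items()}
        tx = generate_gene_models(genome, 10, seed=14)
        peaks, _, _ = generate_peak_replicates(tx, 1, 400, 0.0, 1.0, seed=14,
                                               genome_sizes=sizes)
        chip, inp = generate_coverage_tracks(peaks, 5.0, 0.0, 25, sizes,
                                             seed=14)
        diff = chip.values["chr1"] - inp.values["chr1"]
        summit_bin = peaks[0].midpoint // 25
        assert abs(int(diff.argmax()) - summit_bin) <= 1

    def test_subtracted_near_zero_outside_peaks(self):
        genome = generate_genome(200_000, 1, 0.5, seed=15)
        sizes = {c: len(s) for c, s in genome.items()}
        tx = generate_gene_models(genome, 10, seed=15)
        peaks, _, _ = generate_peak_replicates(tx, 5, 300, 0.0, 1.0, seed=15,
                                               genome_sizes=sizes)
        chip, inp = generate_coverage_tracks(peaks, 5.0, 0.25, 25, sizes,
                                             seed=15)
        diff = chip.values["chr1"] - inp.values["chr1"]
        in_peak = np.zeros(len(diff), dtype=bool)
        for iv in peaks:
            in_peak[iv.start // 25:iv.end // 25 + 1] = True
        assert np.abs(diff[~in_peak]).mean() < 3 * 0.25


class TestDeGenerator:
    def test_zero_effect_almost_no_de_calls(self):
        """With zero effect size the log2fc of every gene is Normal(0, 0.2),
        so essentially nothing clears |log2fc| > 0.5 (tail mass ~1.2% of the
        regulated-status genes only)."""
        genes = [f"g{i}" for i in range(500)]
        table, _, _ = generate_de_and_lists(genes, set(genes[:100]), 0.0,
                                            2.21, seed=1)
        passes = ((table.df["log2fc"].abs() > 0.5)
                  & (table.df["padj"] < 0.05)).mean()
        assert passes < 0.02

    def test_infeasible_marginal_rejected(self):
        genes = [f"g{i}" for i in range(100)]
        with pytest.raises(ValueError, match="infeasible"):
            generate_de_and_lists(genes, set(genes[:50]), 1.0, 2.21, seed=1,
                                  frac_up=1.0)

    def test_truth_reflects_realized_table(self):
        genes = [f"g{i}" for i in range(1000)]
        table, _, truth = generate_de_and_lists(genes, set(genes[:300]), 1.0,
                                                2.21, seed=2)
        up = set(truth["up_genes"])
        recomputed = ((table.df["log2fc"] > 0.5)
                      & (table.df["padj"] < 0.05))
        assert set(table.df.loc[recomputed, "gene_id"]) == up


class TestScenario:
    def test_bundle_files_written(self, bundle_dir):
        for name in ("genome.fa", "genes.gtf", "peaks_rep1.bed",
                     "peaks_rep2.bed", "peaks_consensus.bed", "chip.bedgraph",
                     "input.bedgraph", "cage.tsv", "de.tsv",
                     "embryo_genes.txt", "truth.yaml"):
            assert (bundle_dir / name).exists(), name

    def test_same_config_byte_identical(self, tmp_path):
        cfg = ScenarioConfig(seed=21, genome_length=200_000, n_genes=60,
                             n_peaks=50)
        a = simulate_scenario(cfg, out_dir=tmp_path / "a")
        b = simulate_scenario(cfg, out_dir=tmp_path / "b")
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes(), f.name

    def test_truth_realized_jaccard_exact(self, bundle):
        assert jaccard(bundle.peaks_rep1, bundle.peaks_rep2).jaccard == \
            bundle.truth["realized_jaccard"]

    def test_stage_rngs_are_independent(self):
        a = stage_rng(1, "genome").integers(0, 2**31)
        b = stage_rng(1, "genes").integers(0, 2**31)
        assert a != b
        assert stage_rng(1, "genome").integers(0, 2**31) == a
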