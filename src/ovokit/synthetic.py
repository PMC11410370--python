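"""Synthetic study-condition generator.

Produces a full desk-scale test bed with known planted structure: an i.i.d.
genome, non-overlapping gene models, two ChIP peak replicates with a
controlled base-pair Jaccard, motif instances written near peak summits,
CAGE tags concentrated at TSSs, enrichment-shaped coverage tracks, and a
differential-expression table with planted bound x regulated odds ratios.

Every generator is a pure function of its inputs and a seed; sub-seeds are
derived by stable hashing of (master seed, stage name).  The ``truth``
mapping records *realized* quantities (Jaccard actually achieved, peaks that
actually carry a motif, the sample odds ratio of the realized table), which
is what downstream estimates are tested against.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core import GenomicInterval, IntervalSet, TranscriptModel
from .interval_stats import jaccard, fisher_exact
from .io import (DETable, write_de_table, write_gene_list, write_gene_models,
                 write_intervals, write_track)
from .motifs import IUPAC, MotifModel, default_ovo_catalog
from .core import CoverageTrack, revcomp

import pandas as pd


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator from a master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(stage.encode()) % 2**31]))


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic bundle.

    Defaults mirror the occupancy study where it states a value (replicate
    Jaccard 0.64, ~45% of peaks at a TSS, 72% of peaks carrying a binding
    motif, bound x up odds ratio 2.21) and a realistic fly-like desk scale
    elsewhere.
    """

    genome_length: int = 1_200_000      # total bp, split over chromosomes
    n_chroms: int = 2
    gc_content: float = 0.43
    n_genes: int = 300
    peak_width_mean: int = 300
    n_peaks: int = 250
    target_jaccard: float = 0.64
    frac_peaks_at_tss: float = 0.45
    motif_catalog: list[MotifModel] = field(default_factory=default_ovo_catalog)
    motif_plant_fraction: float = 0.72
    motif_offset_sd: float = 30.0
    cage_tags_per_gene: float = 50.0
    cage_spread_sd: float = 5.0
    coverage_enrichment: float = 5.0
    coverage_noise_sd: float = 0.25
    coverage_bin_size: int = 25
    de_effect_log2fc: float = 1.0
    planted_bound_up_or: float = 2.21
    planted_bound_down_or: float = 0.85
    planted_embryo_or: float = 2.8
    frac_up: float = 0.1845             # 1994 / 10804
    frac_down: float = 0.2706           # 2924 / 10804
    frac_embryo: float = 0.5074         # 5482 / 10804
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gc_content", "target_jaccard", "frac_peaks_at_tss",
                     "motif_plant_fraction", "frac_up", "frac_down",
                     "frac_embryo"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0,1]")
        if not (0.0 < self.gc_content < 1.0):
            raise ValueError("gc_content must be inside (0,1)")
        if self.planted_bound_up_or <= 0:
            raise ValueError("planted_bound_up_or must be > 0")


@dataclass
class ScenarioBundle:
    genome: dict[str, str]
    genome_sizes: dict[str, int]
    transcripts: list[TranscriptModel]
    peaks_rep1: IntervalSet
    peaks_rep2: IntervalSet
    peaks_consensus: IntervalSet
    coverage_chip: CoverageTrack
    coverage_input: CoverageTrack
    cage_tags: dict[tuple[str, int, str], int]
    de_table: DETable
    embryo_genes: list[str]
    truth: dict
    out_dir: Path | None = None


# ---------------------------------------------------------------- genome

def generate_genome(length: int, n_chroms: int, gc: float,
                    seed: int) -> dict[str, str]:
    """I.i.d. genome with P(G)+P(C)=gc, split evenly over chromosomes."""
    if not (0.0 < gc < 1.0):
        raise ValueError("gc must be in (0,1)")
    per = length // n_chroms
    if per < 10_000:
        raise ValueError("need >= 10 kb per chromosome")
    rng = stage_rng(seed, "genome")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.frombuffer(b"ACGT", dtype="S1")
    out = {}
    for i in range(n_chroms):
        draw = rng.choice(4, size=per, p=p)
        out[f"chr{i + 1}"] = bases[draw].tobytes().decode()
    return out


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------- genes

def generate_gene_models(genome: dict[str, str], n_genes: int,
                         seed: int, min_spacing: int = 500
                         ) -> list[TranscriptModel]:
    """Non-overlapping single-transcript genes, random strand, 1-4 exons."""
    rng = stage_rng(seed, "genes")
    chroms = list(genome)
    lengths = {c: len(genome[c]) for c in chroms}
    total = sum(lengths.values())
    counts = {c: int(round(n_genes * lengths[c] / total)) for c in chroms}
    # fix rounding drift
    drift = n_genes - sum(counts.values())
    counts[chroms[0]] += drift
    models: list[TranscriptModel] = []
    gi = 0
    for chrom in chroms:
        n_c = counts[chrom]
        if n_c == 0:
            continue
        spans = rng.integers(800, 3001, size=n_c)
        required = int(spans.sum()) + min_spacing * (n_c + 1)
        free = lengths[chrom] - required
        if free < 0:
            raise ValueError(
                f"{n_c} genes do not fit on {chrom} with {min_spacing} bp "
                "spacing")
        gaps = rng.dirichlet(np.ones(n_c + 1)) * free
        gaps = np.floor(gaps).astype(int)
        pos = 0
        for k in range(n_c):
            pos += min_spacing + int(gaps[k])
            start = pos
            end = start + int(spans[k])
            pos = end
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(1, 5))
            exons = _random_exons(rng, start, end, n_ex)
            L = end - start
            cds = (start + L // 4, end - L // 4)
            models.append(TranscriptModel(
                gene_id=f"gene_{gi:04d}", transcript_id=f"tx_{gi:04d}",
                chrom=chrom, start=start, end=end, strand=strand,
                exons=exons, cds=cds))
            gi += 1
    return models


def _random_exons(rng: np.random.Generator, start: int, end: int,
                  n_ex: int) -> list[tuple[int, int]]:
    """Split [start, end) into n_ex exons separated by introns, covering the
    span ends (first exon starts at start, last ends at end)."""
    L = end - start
    if n_ex == 1 or L < 2 * n_ex * 50:
        return [(start, end)]
    # 2*n_ex - 1 alternating segments, each >= 50 bp
    n_seg = 2 * n_ex - 1
    cuts = np.sort(rng.choice(np.arange(50, L - 50), size=n_seg - 1,
                              replace=False))
    bounds = np.concatenate([[0], cuts, [L]])
    widths = np.diff(bounds)
    if (widths < 20).any():
        return [(start, end)]
    exons = []
    pos = start
    for i, w in enumerate(widths):
        if i % 2 == 0:
            exons.append((pos, pos + int(w)))
        pos += int(w)
    return exons


# ---------------------------------------------------------------- peaks

def _place_nonoverlapping(rng: np.random.Generator,
                          existing: list[GenomicInterval],
                          genome_sizes: dict[str, int],
                          widths: list[int],
                          centers: list[tuple[str, int] | None],
                          name_prefix: str) -> list[GenomicInterval]:
    """Place intervals of given widths, at the given centers when provided or
    uniformly otherwise, rejecting overlaps with `existing` and each other."""
    placed = list(existing)
    out = []
    chroms = list(genome_sizes)
    sizes = np.array([genome_sizes[c] for c in chroms], dtype=float)
    pchrom = sizes / sizes.sum()
    for i, w in enumerate(widths):
        for _attempt in range(200):
            if centers[i] is not None and _attempt == 0:
                chrom, center = centers[i]
            else:
                chrom = chroms[int(rng.choice(len(chroms), p=pchrom))]
                center = int(rng.integers(w // 2, genome_sizes[chrom] - w // 2))
            s = max(0, center - w // 2)
            e = min(genome_sizes[chrom], s + w)
            if e - s < max(20, w // 2):
                continue
            cand = GenomicInterval(chrom, s, e, name=f"{name_prefix}{i}")
            if not any(cand.overlaps(p) for p in placed):
                placed.append(cand)
                out.append(cand)
                break
        else:
            raise RuntimeError("could not place non-overlapping interval")
    return out


def generate_peak_replicates(transcripts: list[TranscriptModel],
                             n_peaks: int, width: int, frac_at_tss: float,
                             target_jaccard: float, seed: int,
                             genome_sizes: dict[str, int],
                             tss_jitter_sd: float = 50.0,
                             tolerance: float = 0.05
                             ) -> tuple[IntervalSet, IntervalSet, float]:
    """Two replicate peak sets with realized bp-Jaccard near the target.

    Replicate 1 places ``frac_at_tss`` of its peaks on randomly chosen TSSs
    (with jitter); replicate 2 retains whole intervals of replicate 1 and
    adds independent peaks, with the retained fraction f = 2J/(1+J) chosen
    so that the realized base-pair Jaccard lands on the target.  Returns
    (rep1, rep2, realized_jaccard); raises when the realized value misses
    the target by more than ``tolerance``.
    """
    if not (0.0 <= target_jaccard <= 1.0):
        raise ValueError("target_jaccard must be in [0,1]")
    rng = stage_rng(seed, "peaks")
    widths = np.maximum(100, rng.normal(width, width / 4, size=n_peaks)
                        .astype(int)).tolist()
    n_tss = int(round(frac_at_tss * n_peaks))
    tss_pool = [t for t in transcripts]
    rng.shuffle(tss_pool)
    centers: list[tuple[str, int] | None] = []
    for i in range(n_peaks):
        if i < n_tss and i < len(tss_pool):
            t = tss_pool[i]
            jit = int(round(rng.normal(0, tss_jitter_sd)))
            centers.append((t.chrom, t.tss() + jit))
        else:
            centers.append(None)
    rep1_list = _place_nonoverlapping(rng, [], genome_sizes, widths, centers,
                                      "p")
    rep1 = IntervalSet(rep1_list, genome_sizes=dict(genome_sizes))

    if target_jaccard == 1.0:
        rep2 = IntervalSet(list(rep1_list), genome_sizes=dict(genome_sizes))
        return rep1, rep2, 1.0

    f = 2 * target_jaccard / (1 + target_jaccard)
    R = rep1.total_bp()
    order = list(range(n_peaks))
    rng.shuffle(order)
    retained: list[GenomicInterval] = []
    bp = 0
    for i in order:
        if bp >= f * R:
            break
        retained.append(rep1_list[i])
        bp += len(rep1_list[i])
    add_target = (1 - f) * R + (bp - f * R)  # keep |rep2| ~ |rep1| in bp
    add_widths = []
    acc = 0
    while acc < add_target:
        w = max(100, int(rng.normal(width, width / 4)))
        add_widths.append(w)
        acc += w
    added = _place_nonoverlapping(rng, rep1_list, genome_sizes, add_widths,
                                  [None] * len(add_widths), "q")
    rep2 = IntervalSet(sorted(retained + added,
                              key=lambda iv: (iv.chrom, iv.start)),
                       genome_sizes=dict(genome_sizes))
    realized = jaccard(rep1, rep2).jaccard
    if abs(realized - target_jaccard) > tolerance:
        raise RuntimeError(
            f"could not realize target Jaccard {target_jaccard} "
            f"(got {realized:.3f})")
    return rep1, rep2, realized


def consensus_peaks(rep1: IntervalSet, rep2: IntervalSet) -> IntervalSet:
    """Replicate-1 peaks that overlap a replicate-2 peak (the conservative
    intersection used for downstream occupancy analysis)."""
    from .interval_stats import merge_intervals
    mb = merge_intervals(rep2).by_chrom()
    out = []
    for iv in rep1:
        if any(iv.start < x.end and x.start < iv.end
               for x in mb.get(iv.chrom, [])):
            out.append(iv)
    return IntervalSet(out, genome_sizes=rep1.genome_sizes)


# ---------------------------------------------------------------- motifs

def plant_motifs(genome: dict[str, str], peaks: IntervalSet,
                 motifs: MotifModel | list[MotifModel],
                 plant_fraction: float, offset_sd: float, seed: int
                 ) -> tuple[dict[str, str], dict]:
    """Write motif consensus instances near a fraction of peak summits.

    Degenerate IUPAC positions are realized uniformly over their base class;
    instances land at summit + Normal(0, offset_sd) on a random strand.
    Returns the edited genome and a truth record listing exact placements
    (and any skipped peaks where the instance would leave the contig).
    """
    if isinstance(motifs, MotifModel):
        motifs = [motifs]
    rng = stage_rng(seed, "plant_motifs")
    seqs = {c: bytearray(s, "ascii") for c, s in genome.items()}
    n_plant = int(round(plant_fraction * len(peaks)))
    chosen = rng.choice(len(peaks), size=n_plant, replace=False)
    planted = []
    skipped = []
    for idx in sorted(chosen):
        iv = peaks[int(idx)]
        motif = motifs[int(rng.integers(len(motifs)))]
        word = "".join(
            IUPAC[ch][int(rng.integers(len(IUPAC[ch])))]
            for ch in motif.consensus)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            word = revcomp(word)
        summit = iv.midpoint
        pos = summit + int(round(rng.normal(0, offset_sd))) - len(word) // 2
        if pos < 0 or pos + len(word) > len(seqs[iv.chrom]):
            skipped.append(iv.name)
            continue
        seqs[iv.chrom][pos:pos + len(word)] = word.encode()
        planted.append(dict(peak=iv.name, motif=motif.name, chrom=iv.chrom,
                            start=int(pos), end=int(pos + len(word)),
                            strand=strand, word=word))
    truth = dict(planted=planted, skipped=skipped,
                 planted_fraction=len(planted) / len(peaks) if len(peaks) else 0.0,
                 planted_peaks=sorted(p["peak"] for p in planted))
    return {c: bytes(b).decode() for c, b in seqs.items()}, truth


# ---------------------------------------------------------------- CAGE

def generate_cage_tags(transcripts: list[TranscriptModel],
                       tags_per_gene: float, spread_sd: float, seed: int,
                       genome_sizes: dict[str, int] | None = None
                       ) -> dict[tuple[str, int, str], int]:
    """Poisson tag counts per gene, positions Normal(tss, spread_sd)."""
    if spread_sd < 0:
        raise ValueError("spread_sd must be >= 0")
    rng = stage_rng(seed, "cage")
    counts: dict[tuple[str, int, str], int] = {}
    for t in transcripts:
        n = int(rng.poisson(tags_per_gene))
        if n == 0:
            continue
        offs = (np.round(rng.normal(0, spread_sd, size=n)).astype(int)
                if spread_sd > 0 else np.zeros(n, dtype=int))
        for off in offs:
            pos = t.tss() + int(off)
            if genome_sizes is not None:
                pos = min(max(pos, 0), genome_sizes[t.chrom] - 1)
            key = (t.chrom, pos, t.strand)
            counts[key] = counts.get(key, 0) + 1
    return counts


# ---------------------------------------------------------------- coverage

def generate_coverage_tracks(peaks: IntervalSet, enrichment: float,
                             noise_sd: float, bin_size: int,
                             genome_sizes: dict[str, int], seed: int
                             ) -> tuple[CoverageTrack, CoverageTrack]:
    """Input = |Normal(1, noise_sd)| per bin; ChIP adds a triangular bump of
    height ``enrichment`` centered on each peak summit."""
    if enrichment <= 0:
        raise ValueError("enrichment must be > 0")
    rng = stage_rng(seed, "coverage")
    input_vals = {}
    chip_vals = {}
    for chrom, length in genome_sizes.items():
        nbins = int(np.ceil(length / bin_size))
        base = np.abs(rng.normal(1.0, noise_sd, size=nbins))
        input_vals[chrom] = base
        chip_vals[chrom] = base.copy()
    for iv in peaks:
        half = max(1, len(iv) // 2)
        summit = iv.midpoint
        arr = chip_vals[iv.chrom]
        b0 = max(0, (summit - half) // bin_size)
        b1 = min(len(arr) - 1, (summit + half) // bin_size)
        for b in range(b0, b1 + 1):
            center = b * bin_size + bin_size / 2
            bump = max(0.0, 1.0 - abs(center - summit) / half)
            arr[b] += enrichment * bump
    chip = CoverageTrack(bin_size=bin_size, values=chip_vals, normalized="raw")
    inp = CoverageTrack(bin_size=bin_size, values=input_vals, normalized="raw")
    return chip, inp


# ---------------------------------------------------------------- DE

def _solve_rates(or_target: float, marginal: float, frac_row: float
                 ) -> tuple[float, float]:
    """Find (p1, p0) with odds(p1)/odds(p0) = or_target and
    frac_row*p1 + (1-frac_row)*p0 = marginal, by bisection on p0."""
    def p1_of(p0: float) -> float:
        o = or_target * p0 / (1 - p0)
        return o / (1 + o)

    lo, hi = 1e-9, 1 - 1e-9
    f = lambda p0: frac_row * p1_of(p0) + (1 - frac_row) * p0 - marginal
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(
            f"odds ratio {or_target} infeasible for marginal {marginal}")
    for _ in range(200):
        mid = (lo + hi) / 2
        if f(mid) <= 0:
            lo = mid
        else:
            hi = mid
    p0 = (lo + hi) / 2
    return p1_of(p0), p0


def generate_de_and_lists(genes: list[str], bound_genes: set[str],
                          effect_log2fc: float, planted_or: float,
                          seed: int,
                          down_or: float = 0.85,
                          embryo_or: float = 2.8,
                          frac_up: float = 0.1845,
                          frac_down: float = 0.2706,
                          frac_embryo: float = 0.5074,
                          lfc_cut: float = 0.5,
                          padj_cut: float = 0.05
                          ) -> tuple[DETable, list[str], dict]:
    """DE table and embryo reference list with planted odds ratios.

    Up/down status is assigned per gene so the *expected* sample odds ratio
    of bound x up equals ``planted_or`` (and bound x down ``down_or``);
    log2fc ~ Normal(+/-effect, 0.2) for regulated genes, Normal(0, 0.2)
    otherwise; padj below the cut for regulated genes.  The embryo list is
    sampled with its own planted odds ratio against up status.  Truth records
    the realized (post-threshold) contingency tables and sample ORs.
    """
    if planted_or <= 0:
        raise ValueError("planted_or must be > 0")
    rng = stage_rng(seed, "de")
    n = len(genes)
    frac_bound = sum(1 for g in genes if g in bound_genes) / n
    p_up1, p_up0 = _solve_rates(planted_or, frac_up, frac_bound)
    p_dn1, p_dn0 = _solve_rates(down_or, frac_down, frac_bound)
    cls = []
    for g in genes:
        bound = g in bound_genes
        pu = p_up1 if bound else p_up0
        if rng.random() < pu:
            cls.append("up")
            continue
        pd_ = (p_dn1 if bound else p_dn0)
        # conditional probability of down given not up
        if rng.random() < pd_ / (1 - pu):
            cls.append("down")
        else:
            cls.append("ns")
    lfc = np.empty(n)
    padj = np.empty(n)
    for i, c in enumerate(cls):
        if c == "up":
            lfc[i] = rng.normal(effect_log2fc, 0.2)
        elif c == "down":
            lfc[i] = rng.normal(-effect_log2fc, 0.2)
        else:
            lfc[i] = rng.normal(0.0, 0.2)
        padj[i] = (rng.uniform(1e-6, padj_cut * 0.999) if c in ("up", "down")
                   else rng.uniform(padj_cut, 1.0))
    base_mean = np.exp(rng.normal(np.log(100), 1.0, size=n))
    table = DETable(pd.DataFrame(dict(
        gene_id=genes, base_mean=base_mean, log2fc=lfc, padj=padj)))

    p_e1, p_e0 = _solve_rates(embryo_or, frac_embryo, sum(
        1 for c in cls if c == "up") / n)
    embryo = []
    for g, c in zip(genes, cls):
        pe = p_e1 if c == "up" else p_e0
        if rng.random() < pe:
            embryo.append(g)

    # realized (post-threshold) contingency
    up_real = [(l > lfc_cut and p < padj_cut) for l, p in zip(lfc, padj)]
    dn_real = [(l < -lfc_cut and p < padj_cut) for l, p in zip(lfc, padj)]
    bd = [g in bound_genes for g in genes]
    def table4(row, col):
        n11 = sum(1 for r, c in zip(row, col) if r and c)
        n12 = sum(1 for r, c in zip(row, col) if r and not c)
        n21 = sum(1 for r, c in zip(row, col) if not r and c)
        n22 = len(row) - n11 - n12 - n21
        return (n11, n12, n21, n22)
    t_up = table4(bd, up_real)
    t_dn = table4(bd, dn_real)
    emb = set(embryo)
    in_emb = [g in emb for g in genes]
    t_emb = table4(up_real, in_emb)
    truth = dict(
        planted_bound_up_or=planted_or,
        realized_bound_up_table=list(t_up),
        realized_bound_up_or=fisher_exact(t_up).odds_ratio,
        realized_bound_down_table=list(t_dn),
        realized_bound_down_or=fisher_exact(t_dn).odds_ratio,
        realized_up_embryo_table=list(t_emb),
        realized_up_embryo_or=fisher_exact(t_emb).odds_ratio,
        up_genes=[g for g, u in zip(genes, up_real) if u],
        down_genes=[g for g, d in zip(genes, dn_real) if d],
        bound_genes=sorted(bound_genes),
    )
    return table, embryo, truth


# ---------------------------------------------------------------- scenario

def simulate_scenario(config: ScenarioConfig,
                      out_dir: str | Path | None = None) -> ScenarioBundle:
    """Run every generator in a fixed order and optionally write the bundle.

    The bundle directory contains genome.fa, genes.gtf, peaks_rep1.bed,
    peaks_rep2.bed, peaks_consensus.bed, chip.bedgraph, input.bedgraph,
    cage.tsv, de.tsv, embryo_genes.txt and truth.yaml.
    """
    seed = config.seed
    genome = generate_genome(config.genome_length, config.n_chroms,
                             config.gc_content, seed)
    genome_sizes = {c: len(s) for c, s in genome.items()}
    transcripts = generate_gene_models(genome, config.n_genes, seed)
    rep1, rep2, realized_j = generate_peak_replicates(
        transcripts, config.n_peaks, config.peak_width_mean,
        config.frac_peaks_at_tss, config.target_jaccard, seed, genome_sizes)
    consensus = consensus_peaks(rep1, rep2)
    genome, motif_truth = plant_motifs(
        genome, consensus, config.motif_catalog,
        config.motif_plant_fraction, config.motif_offset_sd, seed)
    chip, inp = generate_coverage_tracks(
        consensus, config.coverage_enrichment, config.coverage_noise_sd,
        config.coverage_bin_size, genome_sizes, seed)
    cage = generate_cage_tags(transcripts, config.cage_tags_per_gene,
                              config.cage_spread_sd, seed, genome_sizes)
    from .integration import gene_binding_status
    binding = gene_binding_status(transcripts, consensus)
    bound = {g for g, (any_, _) in binding.items() if any_}
    genes = [t.gene_id for t in transcripts]
    de_table, embryo, de_truth = generate_de_and_lists(
        genes, bound, config.de_effect_log2fc, config.planted_bound_up_or,
        seed, down_or=config.planted_bound_down_or,
        embryo_or=config.planted_embryo_or, frac_up=config.frac_up,
        frac_down=config.frac_down, frac_embryo=config.frac_embryo)
    truth = dict(
        realized_jaccard=float(realized_j),
        target_jaccard=config.target_jaccard,
        n_peaks_rep1=len(rep1), n_peaks_rep2=len(rep2),
        n_peaks_consensus=len(consensus),
        motifs=motif_truth, **de_truth)

    bundle = ScenarioBundle(
        genome=genome, genome_sizes=genome_sizes, transcripts=transcripts,
        peaks_rep1=rep1, peaks_rep2=rep2, peaks_consensus=consensus,
        coverage_chip=chip, coverage_input=inp, cage_tags=cage,
        de_table=de_table, embryo_genes=embryo, truth=truth)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(genome, out / "genome.fa")
        write_gene_models(transcripts, out / "genes.gtf")
        write_intervals(rep1, out / "peaks_rep1.bed")
        write_intervals(rep2, out / "peaks_rep2.bed")
        write_intervals(consensus, out / "peaks_consensus.bed")
        write_track(chip, out / "chip.bedgraph")
        write_track(inp, out / "input.bedgraph")
        with open(out / "cage.tsv", "w") as fh:
            for (chrom, pos, strand), cnt in sorted(cage.items()):
                fh.write(f"{chrom}\t{pos}\t{strand}\t{cnt}\n")
        write_de_table(de_table, out / "de.tsv")
        write_gene_list(embryo, out / "embryo_genes.txt")
        with open(out / "truth.yaml", "w") as fh:
            yaml.safe_dump(truth, fh, sort_keys=True)
        bundle.out_dir = out
    return bundle
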