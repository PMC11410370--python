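"""Interval-association statistics for peak sets.

Implements the statistics used to relate ChIP peak sets to each other and to
gene models: base-pair Jaccard similarity, the relative-distance statistic
(uniform on [0, 0.5] under spatial independence), peak-to-gene classification
(TSS / gene body / intergenic), closest-TSS assignment, and Fisher's exact
enrichment of genome-wide peak overlap.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import GenomicInterval, IntervalSet, TranscriptModel, percent


# ---------------------------------------------------------------- merging

def merge_intervals(intervals: IntervalSet) -> IntervalSet:
    """Sort and merge overlapping or bookended intervals per chromosome."""
    merged: list[GenomicInterval] = []
    for chrom in sorted(intervals.by_chrom()):
        ivs = sorted(intervals.by_chrom()[chrom], key=lambda iv: (iv.start, iv.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:  # overlap or bookended
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return IntervalSet(merged, genome_sizes=intervals.genome_sizes)


def _intersect_bp(a: list[GenomicInterval], b: list[GenomicInterval]) -> int:
    """Intersection bp of two per-chromosome merged, sorted lists."""
    i = j = 0
    total = 0
    while i < len(a) and j < len(b):
        lo = max(a[i].start, b[j].start)
        hi = min(a[i].end, b[j].end)
        if hi > lo:
            total += hi - lo
        if a[i].end <= b[j].end:
            i += 1
        else:
            j += 1
    return total


def count_overlapping(a: IntervalSet, b: IntervalSet) -> int:
    """Number of intervals in ``a`` overlapping >= 1 interval of merged ``b``."""
    mb = merge_intervals(b).by_chrom()
    starts = {c: [x.start for x in ivs] for c, ivs in mb.items()}
    n = 0
    for iv in a:
        blist = mb.get(iv.chrom, [])
        if not blist:
            continue
        # merged b is sorted and disjoint: the only possible overlap partner
        # is the interval with the largest start < iv.end
        k = int(np.searchsorted(starts[iv.chrom], iv.end, side="left"))
        if k > 0 and blist[k - 1].end > iv.start:
            n += 1
    return n


@dataclass
class JaccardResult:
    intersection_bp: int
    union_bp: int
    jaccard: float
    n_overlapping_pairs: int


def jaccard(a: IntervalSet, b: IntervalSet) -> JaccardResult:
    """Base-pair Jaccard index (intersection/union) of two interval sets."""
    if len(a) == 0 and len(b) == 0:
        raise ValueError("jaccard undefined for two empty sets (0/0)")
    ma, mb = merge_intervals(a), merge_intervals(b)
    ma_by, mb_by = ma.by_chrom(), mb.by_chrom()
    inter = sum(_intersect_bp(ma_by.get(c, []), mb_by.get(c, []))
                for c in set(ma_by) | set(mb_by))
    union = ma.total_bp() + mb.total_bp() - inter
    return JaccardResult(intersection_bp=inter, union_bp=union,
                         jaccard=inter / union if union else 0.0,
                         n_overlapping_pairs=count_overlapping(a, b))


# ---------------------------------------------------------------- reldist

@dataclass
class RelDistResult:
    values: np.ndarray          # each in [0, 0.5]
    histogram: np.ndarray       # frequencies over bins of width bin_width
    bin_width: float
    n_dropped: int


def relative_distance(queries: IntervalSet,
                      references: dict[str, np.ndarray] | list[tuple[str, int]],
                      bin_width: float = 0.02) -> RelDistResult:
    """Relative distance of query midpoints to flanking reference points.

    For a query midpoint q with flanking references b_prev <= q <= b_next,
    the statistic is min(q - b_prev, b_next - q) / (b_next - b_prev); uniform
    on [0, 0.5] when queries are placed independently of the references.
    Queries outside the outermost references on their chromosome are dropped
    and counted.
    """
    if not isinstance(references, dict):
        by: dict[str, list[int]] = {}
        for chrom, pos in references:
            by.setdefault(chrom, []).append(pos)
        references = {c: np.array(sorted(p)) for c, p in by.items()}
    else:
        references = {c: np.sort(np.asarray(p)) for c, p in references.items()}

    queried_chroms = set(iv.chrom for iv in queries)
    if all(len(references.get(c, ())) < 2 for c in queried_chroms):
        raise ValueError("need >= 2 reference points on at least one queried "
                         "chromosome")
    values: list[float] = []
    dropped = 0
    for iv in queries:
        refs = references.get(iv.chrom)
        if refs is None or len(refs) < 2:
            dropped += 1
            continue
        q = iv.midpoint
        k = int(np.searchsorted(refs, q, side="right"))
        if q < refs[0] or q > refs[-1]:
            dropped += 1
            continue
        if k > 0 and refs[k - 1] == q:
            values.append(0.0)
            continue
        b_prev, b_next = refs[k - 1], refs[k]
        values.append(min(q - b_prev, b_next - q) / (b_next - b_prev))
    vals = np.array(values)
    nbins = int(round(0.5 / bin_width))
    hist, _ = np.histogram(vals, bins=nbins, range=(0.0, 0.5 + 1e-12))
    freq = hist / len(vals) if len(vals) else hist.astype(float)
    return RelDistResult(values=vals, histogram=freq, bin_width=bin_width,
                         n_dropped=dropped)


# ---------------------------------------------------------------- classification

@dataclass
class PeakClassification:
    labels: list[str]                  # per peak: TSS | gene_body | intergenic
    assigned_gene: list[str]           # closest-TSS gene per peak
    counts: dict[str, int] = field(default_factory=dict)
    fractions: dict[str, float] = field(default_factory=dict)
    percents: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.labels)
        for lab in ("TSS", "gene_body", "intergenic"):
            c = self.labels.count(lab)
            self.counts[lab] = c
            self.fractions[lab] = c / n if n else 0.0
            self.percents[lab] = percent(c, n) if n else 0


def _tss_index(transcripts: list[TranscriptModel]) -> dict[str, list[tuple[int, str]]]:
    idx: dict[str, list[tuple[int, str]]] = {}
    for t in transcripts:
        idx.setdefault(t.chrom, []).append((t.tss(), t.gene_id))
    for c in idx:
        idx[c].sort()
    return idx


def closest_tss(peak: GenomicInterval,
                transcripts: list[TranscriptModel] | dict[str, list[tuple[int, str]]]
                ) -> tuple[str, int]:
    """Gene with the TSS closest to the peak midpoint.

    Returns (gene_id, signed distance tss - midpoint).  Ties break to the
    lexicographically smaller gene_id.
    """
    idx = transcripts if isinstance(transcripts, dict) else _tss_index(transcripts)
    entries = idx.get(peak.chrom)
    if not entries:
        raise ValueError(f"no transcript on chromosome {peak.chrom!r}")
    mid = peak.midpoint
    best: tuple[int, str] | None = None
    positions = [p for p, _ in entries]
    k = int(np.searchsorted(positions, mid))
    for pos, gid in entries[max(0, k - 1):k + 1] or entries:
        cand = (abs(pos - mid), gid, pos)
        if best is None or (cand[0], cand[1]) < (best[0], best[1]):
            best = cand
    # the two neighbours of the insertion point cover the minimum, but ties
    # among equal TSS coordinates need the full run of equal-distance entries
    d0 = best[0]
    for pos, gid in entries:
        if abs(pos - mid) == d0 and gid < best[1]:
            best = (d0, gid, pos)
    return best[1], best[2] - mid


def classify_peaks(peaks: IntervalSet,
                   transcripts: list[TranscriptModel]) -> PeakClassification:
    """Label each peak TSS / gene_body / intergenic against gene models.

    TSS: the peak contains some transcript's TSS coordinate; gene_body: it
    overlaps a transcript span but no TSS; intergenic otherwise.  Every peak is
    also assigned its closest-TSS gene.
    """
    tss_idx = _tss_index(transcripts)
    spans: dict[str, list[tuple[int, int, str]]] = {}
    for t in transcripts:
        spans.setdefault(t.chrom, []).append((t.start, t.end, t.gene_id))
    for c in spans:
        spans[c].sort()
    labels: list[str] = []
    assigned: list[str] = []
    for iv in peaks:
        label = "intergenic"
        for pos, _gid in tss_idx.get(iv.chrom, []):
            if iv.start <= pos < iv.end:
                label = "TSS"
                break
        if label != "TSS":
            for (s, e, _gid) in spans.get(iv.chrom, []):
                if s < iv.end and iv.start < e:
                    label = "gene_body"
                    break
        labels.append(label)
        gid, _d = closest_tss(iv, tss_idx)
        assigned.append(gid)
    return PeakClassification(labels=labels, assigned_gene=assigned)


# ---------------------------------------------------------------- Fisher

@dataclass
class ContingencyTable:
    """A 2x2 table with the sample odds ratio and Fisher exact p.

    The sample OR is (n11*n22)/(n12*n21), reported as +inf when the
    denominator is 0 with a positive numerator, and NaN (with a warning and
    p = 1) when a margin is zero.  A conditional-MLE OR is exposed separately.
    """

    n11: int
    n12: int
    n21: int
    n22: int
    odds_ratio: float = field(init=False)
    p_two_sided: float = field(init=False)

    def __post_init__(self) -> None:
        for v in (self.n11, self.n12, self.n21, self.n22):
            if v < 0 or int(v) != v:
                raise ValueError("contingency cells must be non-negative integers")
        row1, row2 = self.n11 + self.n12, self.n21 + self.n22
        col1, col2 = self.n11 + self.n21, self.n12 + self.n22
        if 0 in (row1, row2, col1, col2):
            warnings.warn("degenerate 2x2 table (zero margin): OR undefined",
                          stacklevel=2)
            self.odds_ratio = float("nan")
            self.p_two_sided = 1.0
            return
        num, den = self.n11 * self.n22, self.n12 * self.n21
        if den == 0:
            self.odds_ratio = float("inf") if num > 0 else float("nan")
        else:
            self.odds_ratio = num / den
        _or, p = stats.fisher_exact(
            [[self.n11, self.n12], [self.n21, self.n22]], alternative="two-sided")
        self.p_two_sided = float(p)

    def conditional_mle_or(self) -> float:
        res = stats.contingency.odds_ratio(
            [[self.n11, self.n12], [self.n21, self.n22]], kind="conditional")
        return float(res.statistic)

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.n11, self.n12, self.n21, self.n22)


def fisher_exact(table: tuple[int, int, int, int] | list[list[int]]) -> ContingencyTable:
    """Fisher's exact test on a 2x2 table (two-sided, hypergeometric)."""
    if isinstance(table[0], (list, tuple)):
        (n11, n12), (n21, n22) = table  # type: ignore[misc]
    else:
        n11, n12, n21, n22 = table  # type: ignore[misc]
    return ContingencyTable(int(n11), int(n12), int(n21), int(n22))


def overlap_fisher(a: IntervalSet, b: IntervalSet,
                   genome_size: int) -> ContingencyTable:
    """Genome-wide Fisher enrichment of interval overlap between two sets.

    The table counts overlapping vs non-overlapping intervals of each merged
    set; the no/no cell is estimated from the number of genome "slots" of the
    mean interval width, genome_size / mean_width, minus the other three
    cells.  The slot construction is a heuristic; treat the OR as descriptive.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    ma, mb = merge_intervals(a), merge_intervals(b)
    o_a = count_overlapping(ma, mb)
    o_b = count_overlapping(mb, ma)
    n11 = o_a
    n12 = len(ma) - o_a
    n21 = len(mb) - o_b
    total_iv = len(ma) + len(mb)
    mean_width = (ma.total_bp() + mb.total_bp()) / total_iv if total_iv else 1.0
    n22 = max(0, int(genome_size // mean_width) - n11 - n12 - n21)
    return ContingencyTable(n11, n12, n21, n22)
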