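"""Motif models and scanning.

Two scanning modes: exact IUPAC consensus-class matching (the published
OVO-binding motifs are consensus strings), and PWM log-likelihood scanning
with an exact p-value threshold computed by dynamic programming over a
discretized score grid — the FIMO-style "score whose null tail probability is
below alpha" semantics.

The default catalog carries the OVO-binding motifs: the four motifs recovered
de novo from ovary ChIP peaks plus the two in-vitro motifs (SELEX footprinting
literature), all sharing the 5'-TAACNGT-3' core recognized by the OVO zinc
fingers.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenomicInterval, IntervalSet, revcomp
from .io import fetch_sequence

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

BASES = "ACGT"


@dataclass
class MotifModel:
    """An IUPAC consensus and/or position weight matrix with background."""

    name: str
    consensus: str
    pwm: np.ndarray | None = None      # shape (L, 4), columns A,C,G,T sum to 1
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        for ch in self.consensus:
            if ch not in IUPAC:
                raise ValueError(
                    f"motif {self.name}: invalid IUPAC character {ch!r}")
        if self.pwm is not None:
            self.pwm = np.asarray(self.pwm, dtype=float)
            if self.pwm.shape != (len(self.consensus), 4):
                raise ValueError(f"motif {self.name}: PWM length mismatch")
            if not np.allclose(self.pwm.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"motif {self.name}: PWM rows must sum to 1")
        self.background = np.asarray(self.background, dtype=float)

    def __len__(self) -> int:
        return len(self.consensus)

    @classmethod
    def from_consensus(cls, name: str, consensus: str) -> "MotifModel":
        """Build a PWM spreading probability uniformly within IUPAC classes."""
        L = len(consensus)
        pwm = np.zeros((L, 4))
        for i, ch in enumerate(consensus.upper()):
            if ch not in IUPAC:
                raise ValueError(f"motif {name}: invalid IUPAC character {ch!r}")
            allowed = IUPAC[ch]
            for b in allowed:
                pwm[i, BASES.index(b)] = 1.0 / len(allowed)
        return cls(name=name, consensus=consensus.upper(), pwm=pwm)


def default_ovo_catalog() -> list[MotifModel]:
    """The six published OVO-binding consensus motifs."""
    return [
        MotifModel.from_consensus("ovo_motif_one", "TAACGGTAAA"),
        MotifModel.from_consensus("ovo_motif_two", "RWMTAACGGV"),
        MotifModel.from_consensus("ovo_motif_three", "TAACTGTTTT"),
        MotifModel.from_consensus("ovo_motif_four", "TTACSGTAA"),
        MotifModel.from_consensus("garfinkel_ovo_motif", "AGTAACNGT"),
        MotifModel.from_consensus("oliver_ovo_motif", "TGTAACNGT"),
    ]


@dataclass(frozen=True)
class MotifHit:
    motif_name: str
    chrom: str
    start: int
    end: int
    strand: str
    score: float | None
    matched_sequence: str


# ---------------------------------------------------------------- IUPAC scan

def _iupac_match_positions(sequence: str, consensus: str) -> list[int]:
    L = len(consensus)
    classes = [IUPAC[c] for c in consensus]
    out = []
    for i in range(len(sequence) - L + 1):
        window = sequence[i:i + L]
        if all(window[j] in classes[j] for j in range(L)):
            out.append(i)
    return out


def iupac_scan(sequence: str, motif: MotifModel, both_strands: bool = True,
               chrom: str = ".", offset: int = 0) -> list[MotifHit]:
    """All exact IUPAC-class matches of the consensus in ``sequence``.

    "N" in the *sequence* matches nothing.  Minus-strand hits are found by
    scanning with the reverse-complemented consensus and reported in forward
    coordinates.  ``offset`` shifts reported coordinates (genomic placement).
    """
    sequence = sequence.upper()
    hits: list[MotifHit] = []
    L = len(motif.consensus)
    for i in _iupac_match_positions(sequence, motif.consensus):
        hits.append(MotifHit(motif.name, chrom, offset + i, offset + i + L,
                             "+", None, sequence[i:i + L]))
    if both_strands:
        rc = revcomp(motif.consensus)
        for i in _iupac_match_positions(sequence, rc):
            hits.append(MotifHit(motif.name, chrom, offset + i, offset + i + L,
                                 "-", None, sequence[i:i + L]))
    return sorted(hits, key=lambda h: (h.start, h.strand))


# ---------------------------------------------------------------- PWM scan

_GRID = 1000  # score discretization: 1/1000 of the finite score range

_NEG = -1  # sentinel bucket index for -inf scores


def _discretized_scores(motif: MotifModel) -> tuple[np.ndarray, float, float]:
    """Per-position integer score grid for the log-likelihood ratio.

    Returns (int_scores[L,4] with -1 marking -inf, grid_min, grid_step); a
    finite score s maps to round((s - grid_min)/step) summed over positions.
    """
    if motif.pwm is None:
        raise ValueError(f"motif {motif.name} has no PWM")
    with np.errstate(divide="ignore"):
        llr = np.log2(motif.pwm) - np.log2(motif.background[None, :])
    finite = llr[np.isfinite(llr)]
    lo, hi = float(finite.min()), float(finite.max())
    step = (hi - lo) / _GRID if hi > lo else 1.0
    ints = np.full(llr.shape, _NEG, dtype=int)
    mask = np.isfinite(llr)
    ints[mask] = np.round((llr[mask] - lo) / step).astype(int)
    return ints, lo, step


def pwm_score_distribution(motif: MotifModel) -> tuple[np.ndarray, np.ndarray, float]:
    """Exact null distribution of the discretized PWM score.

    Returns (grid_scores, probabilities, dead_mass) where dead_mass is the
    null probability of words containing a zero-probability base (score -inf).
    Probabilities + dead_mass sum to 1.
    """
    ints, lo, step = _discretized_scores(motif)
    L = ints.shape[0]
    max_sum = int(ints[ints >= 0].reshape(L, -1).max(axis=-1).sum()) if L else 0
    # position-wise convolution over achievable integer sums; words hitting a
    # zero-probability base (-inf score) simply drop out of the live mass
    probs = np.zeros(max_sum + 1)
    probs[0] = 1.0
    cur_max = 0
    bg = motif.background
    for pos in range(L):
        new = np.zeros(max_sum + 1)
        for b in range(4):
            s = ints[pos, b]
            if s != _NEG:
                new[s:cur_max + s + 1] += bg[b] * probs[:cur_max + 1]
        probs = new
        cur_max = int(cur_max + ints[pos][ints[pos] >= 0].max(initial=0))
    dead_mass = 1.0 - probs.sum()
    grid = np.arange(max_sum + 1) * step + L * lo
    return grid, probs, dead_mass


def pwm_threshold_from_pvalue(motif: MotifModel, alpha: float) -> float:
    """Smallest grid score s with null P(score >= s) <= alpha.

    When alpha is below the probability of the single best word, the
    best-word score is returned with a warning (no threshold attains alpha).
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0,1)")
    grid, probs, _dead = pwm_score_distribution(motif)
    tail = np.cumsum(probs[::-1])[::-1]
    ok = np.nonzero(tail <= alpha)[0]
    if len(ok) == 0:
        warnings.warn(
            f"motif {motif.name}: best-word p-value "
            f"{tail[probs > 0][-1] if (probs > 0).any() else 1.0:.3g} exceeds "
            f"alpha={alpha}; threshold set to the best-word score",
            stacklevel=2)
        best = np.nonzero(probs > 0)[0][-1]
        return float(grid[best])
    return float(grid[ok[0]])


def pwm_window_score(motif: MotifModel, window: str) -> float:
    """Discretized log-likelihood score of one window (-inf for dead bases)."""
    ints, lo, step = _discretized_scores(motif)
    total = 0
    for j, ch in enumerate(window):
        if ch not in BASES:
            return float("-inf")
        s = ints[j, BASES.index(ch)]
        if s == _NEG:
            return float("-inf")
        total += s
    return total * step + len(window) * lo


def pwm_scan(sequence: str, motif: MotifModel, alpha: float = 0.0002,
             both_strands: bool = True, chrom: str = ".",
             offset: int = 0) -> list[MotifHit]:
    """PWM hits whose score meets the exact-p threshold for ``alpha``.

    Scores are computed on the same discretized grid as the threshold so the
    comparison is self-consistent.  Overlapping hits are all reported.
    """
    sequence = sequence.upper()
    thr = pwm_threshold_from_pvalue(motif, alpha)
    ints, lo, step = _discretized_scores(motif)
    L = len(motif)

    def score(window: str) -> float:
        total = 0
        for j, ch in enumerate(window):
            if ch not in BASES:
                return float("-inf")
            s = ints[j, BASES.index(ch)]
            if s == _NEG:
                return float("-inf")
            total += s
        return total * step + L * lo

    hits: list[MotifHit] = []
    strands = [("+", sequence)]
    if both_strands:
        strands.append(("-", revcomp(sequence)))
    n = len(sequence)
    for strand, seq in strands:
        for i in range(n - L + 1):
            sc = score(seq[i:i + L])
            if sc >= thr - 1e-12:
                if strand == "+":
                    s0 = i
                else:
                    s0 = n - (i + L)
                hits.append(MotifHit(motif.name, chrom, offset + s0,
                                     offset + s0 + L, strand, sc,
                                     sequence[s0:s0 + L]))
    return sorted(hits, key=lambda h: (h.start, h.strand))


# ---------------------------------------------------------------- peak annotation

@dataclass
class PeakMotifAnnotation:
    presence: pd.DataFrame          # index peak name, columns motif names, bool
    per_motif_fraction: pd.Series
    any_motif_fraction: float
    per_motif_percent: pd.Series
    any_motif_percent: int


def _peak_name(iv: GenomicInterval, i: int) -> str:
    return iv.name if iv.name is not None else f"peak_{i}"


def annotate_peak_motifs(peaks: IntervalSet, genome, catalog: list[MotifModel],
                         mode: str = "iupac",
                         alpha: float = 0.0002) -> PeakMotifAnnotation:
    """Per-peak presence/absence of each catalog motif within peak sequence."""
    if len(catalog) == 0:
        raise ValueError("empty motif catalog")
    if len(peaks) == 0:
        raise ValueError("empty peak set")
    names = [_peak_name(iv, i) for i, iv in enumerate(peaks)]
    data = {}
    seqs = [fetch_sequence(genome, iv) for iv in peaks]
    for motif in catalog:
        col = []
        for seq in seqs:
            if mode == "iupac":
                hits = iupac_scan(seq, motif, both_strands=True)
            elif mode == "pwm":
                hits = pwm_scan(seq, motif, alpha=alpha, both_strands=True)
            else:
                raise ValueError(f"unknown scan mode {mode!r}")
            col.append(len(hits) > 0)
        data[motif.name] = col
    presence = pd.DataFrame(data, index=names)
    frac = presence.mean(axis=0)
    any_frac = float(presence.any(axis=1).mean())
    from .core import round_half_away
    return PeakMotifAnnotation(
        presence=presence,
        per_motif_fraction=frac,
        any_motif_fraction=any_frac,
        per_motif_percent=frac.map(lambda f: round_half_away(100 * f)),
        any_motif_percent=round_half_away(100 * any_frac))


def motif_mask_rescan(peaks: IntervalSet, genome,
                      catalog: list[MotifModel],
                      mode: str = "iupac") -> list[tuple[str, float, int]]:
    """Iterative mask-and-rescan: report each motif's fraction among the peaks
    remaining after removing peaks containing earlier catalog motifs.

    Returns [(motif_name, fraction_among_remaining, n_remaining_before)].
    """
    ann = annotate_peak_motifs(peaks, genome, catalog, mode=mode)
    remaining = ann.presence.index.to_numpy()
    out: list[tuple[str, float, int]] = []
    for motif in catalog:
        if len(remaining) == 0:
            out.append((motif.name, float("nan"), 0))
            continue
        has = ann.presence.loc[remaining, motif.name]
        out.append((motif.name, float(has.mean()), len(remaining)))
        remaining = remaining[~has.to_numpy()]
    return out


def motif_density_around_points(hits: list[MotifHit],
                                points: list[tuple[str, int, str]],
                                window: int = 1500,
                                bin: int = 25) -> tuple[np.ndarray, np.ndarray]:
    """Percent of points with >= 1 hit per offset bin around the points.

    Offsets are hit midpoint - point position, sign-flipped for "-" strand
    points so that positive always means downstream of the feature.
    Returns (bin_centers, percent_per_bin).
    """
    if window % bin:
        raise ValueError("window must be divisible by bin")
    nbins = 2 * window // bin
    edges = np.arange(-window, window + bin, bin)
    centers = (edges[:-1] + edges[1:]) / 2
    counts = np.zeros(nbins)
    by_chrom: dict[str, list[MotifHit]] = {}
    for h in hits:
        by_chrom.setdefault(h.chrom, []).append(h)
    n_points = len(points)
    for (chrom, pos, strand) in points:
        seen = np.zeros(nbins, dtype=bool)
        for h in by_chrom.get(chrom, []):
            off = (h.start + h.end) // 2 - pos
            if strand == "-":
                off = -off
            b = int(np.floor((off + window) / bin))
            if 0 <= b < nbins:
                seen[b] = True
        counts += seen
    pct = 100.0 * counts / n_points if n_points else counts
    return centers, pct


# ---------------------------------------------------------------- catalog I/O

def read_motif_catalog(path) -> list[MotifModel]:
    """Tab-separated (name, consensus) catalog file."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, consensus = line.split("\t")[:2]
            out.append(MotifModel.from_consensus(name, consensus))
    return out


def write_hits(hits: list[MotifHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("motif\tchrom\tstart\tend\tstrand\tscore\tmatched\n")
        for h in hits:
            sc = "" if h.score is None else f"{h.score:.4f}"
            fh.write(f"{h.motif_name}\t{h.chrom}\t{h.start}\t{h.end}\t"
                     f"{h.strand}\t{sc}\t{h.matched_sequence}\n")
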