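"""CAGE tag aggregation, TPM normalization, TSS clustering and promoter
window extraction.

Two clustering modes mirror the common CAGE toolchain: ``distclu`` merges
same-strand CTSS within a fixed maximum gap; ``paraclu`` reports maximal-
scoring segments of the parametric density clustering across all density
thresholds.  Singleton clusters are removed unless their raw tag count
exceeds a floor — the keep-singletons-above convention operates on raw tag
counts, not TPM.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenomicInterval, revcomp
from .io import fetch_sequence


@dataclass
class CtssTable:
    """Per-position CAGE tag counts: (chrom, position, strand) unique rows."""

    df: pd.DataFrame  # columns chrom, pos, strand, count[, tpm]

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "strand", "count"}
        if required - set(self.df.columns):
            raise ValueError("CTSS table requires chrom, pos, strand, count")
        if (self.df["count"] < 1).any():
            raise ValueError("CTSS counts must be >= 1")
        if self.df.duplicated(["chrom", "pos", "strand"]).any():
            raise ValueError("duplicate (chrom, pos, strand) rows")

    def __len__(self) -> int:
        return len(self.df)


def ctss_from_tags(tags) -> CtssTable:
    """Aggregate an iterable of ((chrom, pos, strand), count) or a DataFrame
    of per-tag records into one row per position."""
    if isinstance(tags, pd.DataFrame):
        df = tags
    else:
        rows = [(c, p, s, n) for ((c, p, s), n) in tags]
        df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "count"])
    if len(df) == 0:
        return CtssTable(pd.DataFrame(
            columns=["chrom", "pos", "strand", "count"]).astype(
                {"pos": int, "count": int}))
    if (df["count"] < 0).any():
        raise ValueError("negative tag count")
    agg = (df.groupby(["chrom", "pos", "strand"], as_index=False)["count"]
             .sum()
             .sort_values(["chrom", "strand", "pos"], ignore_index=True))
    agg = agg[agg["count"] >= 1].reset_index(drop=True)
    return CtssTable(agg)


def tpm_normalize(ctss: CtssTable) -> CtssTable:
    """Tags-per-million: count / library total * 1e6."""
    if len(ctss) == 0:
        raise ValueError("cannot TPM-normalize an empty CTSS table")
    df = ctss.df.copy()
    total = df["count"].sum()
    df["tpm"] = df["count"] / total * 1e6
    return CtssTable(df)


@dataclass
class TagCluster:
    chrom: str
    strand: str
    start: int
    end: int                      # half-open
    positions: list[tuple[int, float, int]]  # (pos, tpm, raw_count)
    total_tpm: float = field(init=False)
    dominant_pos: int = field(init=False)
    dominant_tpm: float = field(init=False)
    min_density: float = 0.0
    max_density: float = 0.0

    def __post_init__(self) -> None:
        if not self.positions:
            raise ValueError("empty tag cluster")
        self.total_tpm = float(sum(t for _, t, _ in self.positions))
        pos, tpm = dominant_tss(self)
        self.dominant_pos = pos
        self.dominant_tpm = tpm

    def n_positions(self) -> int:
        return len(self.positions)

    def raw_total(self) -> int:
        return sum(c for _, _, c in self.positions)


def dominant_tss(cluster: "TagCluster | list[tuple[int, float, int]]",
                 strand: str | None = None) -> tuple[int, float]:
    """Member position with maximal TPM; ties break to the 5'-most position
    (lowest coordinate on "+", highest on "-")."""
    if isinstance(cluster, TagCluster):
        members, strand = cluster.positions, cluster.strand
    else:
        members = cluster
    best_tpm = max(t for _, t, _ in members)
    tied = [p for p, t, _ in members if t == best_tpm]
    pos = min(tied) if strand != "-" else max(tied)
    return pos, best_tpm


# ---------------------------------------------------------------- paraclu

def paraclu_segments(positions: list[tuple[int, float]],
                     min_stability: float = 1.0) -> list[dict]:
    """Parametric (maximal-density) segmentation of weighted positions.

    Recursively reports each segment with its density bounds: ``max_density``
    = total weight / span; the break point is the proper prefix or suffix
    boundary of minimal density and becomes the segment's ``min_density``.
    A single position is reported with min_density 0 (sentinel) and
    max_density = its weight.  Segments with max_density/min_density below
    ``min_stability`` are discarded (1 keeps everything).
    """
    if not positions:
        raise ValueError("paraclu requires >= 1 position")
    pts = sorted(positions)
    if any(w <= 0 for _, w in pts):
        raise ValueError("paraclu weights must be > 0")
    out: list[dict] = []

    def recurse(lo: int, hi: int, inherited: float) -> None:
        # inclusive indices; ``inherited`` is the break density of the
        # enclosing segment -- this segment is maximal only for thresholds
        # in (inherited, own break], so an empty interval is not reported
        total = sum(w for _, w in pts[lo:hi + 1])
        span = pts[hi][0] - pts[lo][0] + 1
        max_d = total / span
        if lo == hi:
            out.append(dict(start=pts[lo][0], end=pts[lo][0] + 1,
                            min_density=0.0, max_density=pts[lo][1],
                            members=[pts[lo]]))
            return
        # weakest boundary: density of the prefix [lo..k] measured over the
        # distance to the next retained site (and the suffix symmetrically) --
        # the level below which trimming that end no longer pays
        best = None  # (density, split index): sub-segments [lo..k], [k+1..hi]
        acc = 0.0
        for k in range(lo, hi):
            acc += pts[k][1]
            d = acc / (pts[k + 1][0] - pts[lo][0])
            if best is None or d < best[0]:
                best = (d, k)
        acc = 0.0
        for k in range(hi, lo, -1):
            acc += pts[k][1]
            d = acc / (pts[hi][0] - pts[k - 1][0])
            if d < best[0]:
                best = (d, k - 1)
        min_d = best[0]
        if min_d > inherited and max_d / min_d >= min_stability:
            out.append(dict(start=pts[lo][0], end=pts[hi][0] + 1,
                            min_density=min_d, max_density=max_d,
                            members=list(pts[lo:hi + 1])))
        nxt = max(inherited, min_d)
        recurse(lo, best[1], nxt)
        recurse(best[1] + 1, hi, nxt)

    recurse(0, len(pts) - 1, 0.0)
    return out


# ---------------------------------------------------------------- clustering

def cluster_ctss(ctss: CtssTable, method: str = "distclu",
                 max_dist: int = 20, tpm_threshold: float = 1.0,
                 remove_singletons: bool = True,
                 keep_singletons_above: int = 5,
                 max_cluster_length: int = 500,
                 min_stability: float = 1.0) -> list[TagCluster]:
    """Cluster TPM-filtered CTSS into tag clusters.

    CTSS below ``tpm_threshold`` TPM are discarded first.  ``distclu`` merges
    surviving same-strand CTSS within ``max_dist`` bp transitively;
    ``paraclu`` takes the maximal-density segments, keeps those no longer
    than ``max_cluster_length`` and resolves overlaps by max_density.
    Single-position clusters are dropped unless their raw tag count is at
    least ``keep_singletons_above``.
    """
    if method not in ("distclu", "paraclu"):
        raise ValueError(f"unknown clustering method {method!r}")
    if "tpm" not in ctss.df.columns:
        raise ValueError("run tpm_normalize first")
    df = ctss.df[ctss.df["tpm"] >= tpm_threshold]
    clusters: list[TagCluster] = []
    for (chrom, strand), grp in df.groupby(["chrom", "strand"], sort=True):
        grp = grp.sort_values("pos")
        members = list(zip(grp["pos"].astype(int), grp["tpm"].astype(float),
                           grp["count"].astype(int)))
        if not members:
            continue
        if method == "distclu":
            runs: list[list[tuple[int, float, int]]] = [[members[0]]]
            for m in members[1:]:
                if m[0] - runs[-1][-1][0] <= max_dist:
                    runs[-1].append(m)
                else:
                    runs.append([m])
            for run in runs:
                clusters.append(TagCluster(
                    chrom=chrom, strand=strand, start=run[0][0],
                    end=run[-1][0] + 1, positions=run))
        else:
            segs = paraclu_segments([(p, t) for p, t, _ in members],
                                    min_stability=min_stability)
            tpm_by_pos = {p: (t, c) for p, t, c in members}
            segs = [s for s in segs if s["end"] - s["start"] <= max_cluster_length]
            # resolve overlaps: highest max_density wins
            segs.sort(key=lambda s: -s["max_density"])
            taken: list[tuple[int, int]] = []
            for s in segs:
                if any(s["start"] < e and t0 < s["end"] for t0, e in taken):
                    continue
                taken.append((s["start"], s["end"]))
                run = [(p, *tpm_by_pos[p]) for p, _w in s["members"]]
                clusters.append(TagCluster(
                    chrom=chrom, strand=strand, start=s["start"], end=s["end"],
                    positions=run, min_density=s["min_density"],
                    max_density=s["max_density"]))
    if remove_singletons:
        clusters = [c for c in clusters
                    if c.n_positions() > 1
                    or c.raw_total() >= keep_singletons_above]
    clusters.sort(key=lambda c: (c.chrom, c.start, c.strand))
    return clusters


# ---------------------------------------------------------------- promoters

@dataclass
class PromoterWindow:
    interval: GenomicInterval        # clipped genomic window
    sequence: str                    # oriented 5'->3', TSS at index tss_index
    tss_index: int
    clipped: bool


def promoter_windows(dominant: list[tuple[str, int, str]], genome,
                     flank: int = 200) -> list[PromoterWindow]:
    """Extract [pos-flank, pos+flank+1) windows around dominant TSSs.

    Sequences are oriented 5'->3' (reverse-complemented on "-") so index
    ``flank`` is the TSS base unless clipping at a contig edge shifted it;
    the effective index is recorded per window.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    from pyfaidx import Fasta
    fa = genome if isinstance(genome, Fasta) else Fasta(str(genome))
    out = []
    for (chrom, pos, strand) in dominant:
        contig_len = len(fa[chrom])
        lo, hi = pos - flank, pos + flank + 1
        clipped = lo < 0 or hi > contig_len
        lo_c, hi_c = max(lo, 0), min(hi, contig_len)
        iv = GenomicInterval(chrom, lo_c, hi_c, strand=strand)
        seq = fetch_sequence(fa, iv, orient_by_strand=True)
        tss_index = pos - lo_c if strand != "-" else hi_c - 1 - pos
        out.append(PromoterWindow(interval=iv, sequence=seq,
                                  tss_index=tss_index, clipped=clipped))
    return out


# ---------------------------------------------------------------- I/O

def read_ctss(path) -> CtssTable:
    df = pd.read_csv(path, sep="\t",
                     names=["chrom", "pos", "strand", "count"],
                     dtype={"chrom": str, "pos": int, "strand": str,
                            "count": int},
                     comment="#")
    return CtssTable(df)


def write_ctss(ctss: CtssTable, path) -> None:
    ctss.df[["chrom", "pos", "strand", "count"]].to_csv(
        path, sep="\t", header=False, index=False)


def write_clusters(clusters: list[TagCluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\ttotal_tpm\tstrand\t"
                 "dominant_pos\tdominant_tpm\n")
        for i, c in enumerate(clusters):
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\tcluster_{i}\t"
                     f"{c.total_tpm:.4f}\t{c.strand}\t{c.dominant_pos}\t"
                     f"{c.dominant_tpm:.4f}\n")
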