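"""Readers/writers for the plain-text genomics formats the pipeline touches.

BED is natively 0-based half-open and passes straight through; GTF's 1-based
inclusive coordinates are converted at this boundary.  bedGraph stands in for
binary coverage formats: records are resampled onto fixed-width bins with
uncovered bins set to zero.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .core import CoverageTrack, GenomicInterval, IntervalSet, TranscriptModel, revcomp


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------- BED

def read_intervals(path: str | Path, format: str = "BED",
                   genome_sizes: dict[str, int] | None = None) -> IntervalSet:
    """Read a BED3+ file into an IntervalSet, preserving record order."""
    if format != "BED":
        raise ValueError(f"unsupported interval format {format!r}")
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(GenomicInterval(fields[0], start, end,
                                                 name=name, score=score,
                                                 strand=strand))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return IntervalSet(intervals, genome_sizes=genome_sizes)


def write_intervals(intervals: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand != ".":
                fields.append(iv.name if iv.name is not None else ".")
                fields.append(_fmt_score(iv.score))
                fields.append(iv.strand)
            fh.write("\t".join(fields) + "\n")


def _fmt_score(score: float | None) -> str:
    if score is None:
        return "."
    if float(score).is_integer():
        return str(int(score))
    return repr(float(score))


# ---------------------------------------------------------------- GTF

def _parse_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in attr.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " in chunk:
            key, _, val = chunk.partition(" ")
            out[key] = val.strip().strip('"')
        elif "=" in chunk:  # GFF3 style
            key, _, val = chunk.partition("=")
            out[key] = val.strip()
    return out


def read_gene_models(path: str | Path, format: str = "GTF") -> list[TranscriptModel]:
    """Parse transcript/exon/CDS features into TranscriptModels.

    GTF/GFF3 1-based inclusive coordinates become internal 0-based half-open
    (start-1, end).  Transcripts lacking a strand raise; exons outside their
    transcript span raise (via TranscriptModel validation).
    """
    if format not in ("GTF", "GFF3"):
        raise ValueError(f"unsupported gene-model format {format!r}")
    spans: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: fewer than 9 GTF columns")
            chrom, _, feature, start_s, end_s, _, strand, _, attr = fields[:9]
            if feature not in ("transcript", "mRNA", "exon", "CDS"):
                continue
            try:
                start, end = int(start_s) - 1, int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            attrs = _parse_attributes(attr)
            tid = attrs.get("transcript_id") or attrs.get("ID") or attrs.get("Parent")
            gid = attrs.get("gene_id", tid)
            if tid is None:
                raise ParseError(f"{path}:{lineno}: no transcript_id")
            if feature in ("transcript", "mRNA"):
                if strand not in ("+", "-"):
                    raise ParseError(
                        f"{path}:{lineno}: transcript {tid} lacks strand")
                spans[tid] = dict(gene_id=gid, chrom=chrom, start=start,
                                  end=end, strand=strand)
                if tid not in order:
                    order.append(tid)
            elif feature == "exon":
                exons.setdefault(tid, []).append((start, end))
                if tid not in spans and tid not in order:
                    order.append(tid)
            elif feature == "CDS":
                cds.setdefault(tid, []).append((start, end))
    models: list[TranscriptModel] = []
    for tid in order:
        if tid not in spans:
            # exon-only input: infer the span, but strand must be consistent
            raise ParseError(f"{path}: transcript {tid} has exons but no "
                             "transcript feature line")
        info = spans[tid]
        tx_exons = exons.get(tid, [])
        tx_cds = None
        if tid in cds:
            cs = sorted(cds[tid])
            tx_cds = (cs[0][0], cs[-1][1])
        models.append(TranscriptModel(
            gene_id=info["gene_id"], transcript_id=tid, chrom=info["chrom"],
            start=info["start"], end=info["end"], strand=info["strand"],
            exons=tx_exons, cds=tx_cds))
    return models


def write_gene_models(models: list[TranscriptModel], path: str | Path,
                      source: str = "ovokit") -> None:
    """Write models as GTF (1-based inclusive)."""
    with open(path, "w") as fh:
        for m in models:
            attr = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            fh.write("\t".join([m.chrom, source, "transcript",
                                str(m.start + 1), str(m.end), ".", m.strand,
                                ".", attr]) + "\n")
            for (s, e) in m.exons:
                fh.write("\t".join([m.chrom, source, "exon", str(s + 1),
                                    str(e), ".", m.strand, ".", attr]) + "\n")
            if m.cds is not None:
                fh.write("\t".join([m.chrom, source, "CDS", str(m.cds[0] + 1),
                                    str(m.cds[1]), ".", m.strand, "0", attr])
                         + "\n")


# ---------------------------------------------------------------- FASTA

def fetch_sequence(genome: str | Path | Fasta, interval: GenomicInterval,
                   orient_by_strand: bool = False) -> str:
    """Extract the uppercase sequence of an interval from a FASTA genome.

    With ``orient_by_strand`` a "-" interval returns the reverse complement,
    i.e. the sequence read 5'->3' on the feature strand.
    """
    fa = genome if isinstance(genome, Fasta) else Fasta(str(genome))
    if interval.chrom not in fa:
        raise KeyError(f"chromosome {interval.chrom!r} not in FASTA")
    contig = fa[interval.chrom]
    if interval.end > len(contig):
        raise ValueError(
            f"interval {interval.chrom}:{interval.start}-{interval.end} "
            f"exceeds contig length {len(contig)}")
    seq = str(contig[interval.start:interval.end]).upper()
    if orient_by_strand and interval.strand == "-":
        seq = revcomp(seq)
    return seq


# ---------------------------------------------------------------- bedGraph

def read_track(path: str | Path, bin_size: int,
               genome_sizes: dict[str, int]) -> CoverageTrack:
    """Resample a bedGraph onto fixed bins (coverage-weighted mean per bin).

    Uncovered base pairs contribute 0 (missing-data-as-zero convention).
    Overlapping records are an error.
    """
    sums: dict[str, np.ndarray] = {
        c: np.zeros(math.ceil(length / bin_size))
        for c, length in genome_sizes.items()}
    last_end: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: fewer than 4 bedGraph columns")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom not in sums:
                raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if start < last_end.get(chrom, 0):
                raise ParseError(f"{path}:{lineno}: overlapping bedGraph records")
            last_end[chrom] = end
            # distribute value over covered bp of each bin
            b0, b1 = start // bin_size, (end - 1) // bin_size
            arr = sums[chrom]
            for b in range(b0, min(b1, len(arr) - 1) + 1):
                lo = max(start, b * bin_size)
                hi = min(end, (b + 1) * bin_size)
                arr[b] += value * (hi - lo)
    values = {c: arr / bin_size for c, arr in sums.items()}
    # trailing partial bin: mean over its actual width
    for c, length in genome_sizes.items():
        rem = length % bin_size
        if rem and len(values[c]):
            values[c][-1] = sums[c][-1] / rem
    return CoverageTrack(bin_size=bin_size, values=values, normalized="raw")


def write_track(track: CoverageTrack, path: str | Path) -> None:
    """Write a binned track as bedGraph, merging equal-valued adjacent bins."""
    with open(path, "w") as fh:
        for chrom, arr in track.values.items():
            i = 0
            n = len(arr)
            while i < n:
                j = i
                while j + 1 < n and arr[j + 1] == arr[i]:
                    j += 1
                if arr[i] != 0.0:
                    fh.write(f"{chrom}\t{i * track.bin_size}"
                             f"\t{(j + 1) * track.bin_size}\t{arr[i]:g}\n")
                i = j + 1


# ---------------------------------------------------------------- DE table

@dataclass
class DETable:
    """A differential-expression table (DESeq2-style results)."""

    df: pd.DataFrame  # columns: gene_id, base_mean, log2fc, padj (padj may be NaN)

    def __post_init__(self) -> None:
        required = {"gene_id", "log2fc", "padj"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"DE table missing columns {sorted(missing)}")
        if self.df["gene_id"].duplicated().any():
            dup = self.df.loc[self.df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene_id {dup!r} in DE table")
        bad = self.df["padj"].dropna()
        if ((bad < 0) | (bad > 1)).any():
            raise ValueError("padj outside [0,1]")

    def __len__(self) -> int:
        return len(self.df)

    def genes(self) -> list[str]:
        return self.df["gene_id"].tolist()


def read_de_table(path: str | Path,
                  gene_col: str = "gene",
                  lfc_col: str = "log2FoldChange",
                  padj_col: str = "padj",
                  base_mean_col: str = "baseMean") -> DETable:
    df = pd.read_csv(path, sep="\t")
    for col in (gene_col, lfc_col, padj_col):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    out = pd.DataFrame({
        "gene_id": df[gene_col].astype(str),
        "log2fc": pd.to_numeric(df[lfc_col]),
        "padj": pd.to_numeric(df[padj_col], errors="coerce"),
    })
    if base_mean_col in df.columns:
        out.insert(1, "base_mean", pd.to_numeric(df[base_mean_col]))
    return DETable(out)


def write_de_table(table: DETable, path: str | Path) -> None:
    df = table.df.rename(columns={"gene_id": "gene", "log2fc": "log2FoldChange",
                                  "base_mean": "baseMean"})
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: list[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(g + "\n")
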