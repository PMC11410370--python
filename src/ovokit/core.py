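"""Core genomic value types shared across the toolkit.

All coordinates are 0-based half-open throughout the package; formats that use
other conventions (GTF) are converted at the I/O boundary.  Chromosome names are
matched as exact strings — no "chr" prefix normalisation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

STRANDS = ("+", "-", ".")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-aware half-open genomic span [start, end)."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


@dataclass
class IntervalSet:
    """An ordered collection of intervals, optionally bounded by genome sizes."""

    intervals: list[GenomicInterval] = field(default_factory=list)
    genome_sizes: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        if self.genome_sizes is not None:
            for iv in self.intervals:
                size = self.genome_sizes.get(iv.chrom)
                if size is not None and iv.end > size:
                    raise ValueError(
                        f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                        f"chromosome length {size}"
                    )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self.intervals:
            seen.setdefault(iv.chrom, None)
        return list(seen)

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def total_bp(self) -> int:
        return sum(len(iv) for iv in self.intervals)


@dataclass
class TranscriptModel:
    """A gene/transcript model with exon structure on a 0-based half-open span.

    ``tss()`` is the biological 5' end: ``start`` on "+", ``end - 1`` on "-";
    ``tes()`` is the 3' end symmetrically.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"transcript {self.transcript_id}: strand must be + or -"
            )
        if not (0 <= self.start < self.end):
            raise ValueError(f"transcript {self.transcript_id}: bad span")
        self.exons = sorted(self.exons)
        prev_end = None
        for (s, e) in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exon ({s},{e}) outside "
                    f"span ({self.start},{self.end})"
                )
            if prev_end is not None and s < prev_end:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )
            prev_end = e

    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end,
                               name=self.transcript_id, strand=self.strand)

    def cds_midpoint(self) -> int | None:
        if self.cds is None:
            return None
        return (self.cds[0] + self.cds[1]) // 2


@dataclass
class CoverageTrack:
    """Binned per-chromosome signal values.

    ``values[chrom][i]`` covers the bp range [i*bin_size, (i+1)*bin_size).
    """

    bin_size: int
    values: dict[str, np.ndarray]
    normalized: str = "raw"  # raw | BPM | subtracted

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if self.normalized not in ("raw", "BPM", "subtracted"):
            raise ValueError(f"unknown normalization label {self.normalized!r}")
        self.values = {c: np.asarray(v, dtype=float)
                       for c, v in self.values.items()}

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def value_at(self, chrom: str, pos: int) -> float:
        """Signal of the bin containing bp position ``pos`` (0 outside)."""
        arr = self.values.get(chrom)
        if arr is None:
            return 0.0
        i = pos // self.bin_size
        if pos < 0 or i >= len(arr):
            return 0.0
        return float(arr[i])


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (R/report style)."""
    return int(np.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def percent(numer: int, denom: int) -> int:
    """Integer percent with round-half-away-from-zero."""
    if denom == 0:
        raise ZeroDivisionError("percent of empty denominator")
    return round_half_away(100.0 * numer / denom)


def as_interval_list(x: IntervalSet | Sequence[GenomicInterval]) -> list[GenomicInterval]:
    if isinstance(x, IntervalSet):
        return list(x.intervals)
    return list(x)
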