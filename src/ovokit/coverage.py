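"""Coverage metaprofile machinery: BPM scaling, track subtraction,
reference-point and scale-regions matrices, row ordering and column profiles.

Semantics follow the usual ChIP metaprofile conventions: missing data is zero,
minus-strand rows are flipped so columns always run 5'->3' along the feature,
and subtraction keeps negative values (no clipping).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CoverageTrack, TranscriptModel


@dataclass
class ProfileMatrix:
    values: np.ndarray            # rows x columns
    row_ids: list[str]
    mode: str                     # reference_point | scale_regions
    bin_bp: int
    flank_bp: int = 0
    body_bp: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.row_ids):
            raise ValueError("matrix shape does not match row ids")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        if self.mode == "reference_point":
            cols = np.arange(-self.flank_bp, self.flank_bp, self.bin_bp)
        else:
            cols = np.arange(0, self.body_bp, self.bin_bp)
        return pd.DataFrame(self.values, index=self.row_ids, columns=cols)


def bpm_normalize(track: CoverageTrack) -> CoverageTrack:
    """Scale bins so they sum to 1e6 (bins-per-million)."""
    total = track.total()
    if total == 0:
        raise ValueError("cannot BPM-normalize an all-zero track")
    values = {c: v * (1e6 / total) for c, v in track.values.items()}
    return CoverageTrack(bin_size=track.bin_size, values=values,
                         normalized="BPM")


def subtract_tracks(chip: CoverageTrack, input_: CoverageTrack) -> CoverageTrack:
    """Per-bin chip - input; negative values are kept."""
    if chip.bin_size != input_.bin_size:
        raise ValueError("bin_size mismatch between tracks")
    if set(chip.values) != set(input_.values):
        raise ValueError("chromosome namespace mismatch between tracks")
    values = {}
    for c in chip.values:
        a, b = chip.values[c], input_.values[c]
        if len(a) != len(b):
            raise ValueError(f"bin count mismatch on {c}")
        values[c] = a - b
    return CoverageTrack(bin_size=chip.bin_size, values=values,
                         normalized="subtracted")


def pool_tracks(tracks: list[CoverageTrack]) -> CoverageTrack:
    """Sum raw replicate tracks bin-wise (pre-step before BPM)."""
    first = tracks[0]
    values = {c: v.copy() for c, v in first.values.items()}
    for t in tracks[1:]:
        if t.bin_size != first.bin_size:
            raise ValueError("bin_size mismatch")
        for c, v in t.values.items():
            values[c] = values.get(c, 0) + v
    return CoverageTrack(bin_size=first.bin_size, values=values,
                         normalized="raw")


def _mean_signal(track: CoverageTrack, chrom: str, start: int, end: int) -> float:
    """Mean per-bp signal over [start, end), out-of-contig bp counted as 0."""
    if end <= start:
        return 0.0
    arr = track.values.get(chrom)
    width = end - start
    if arr is None:
        return 0.0
    bs = track.bin_size
    lo = max(start, 0)
    hi = min(end, len(arr) * bs)
    if hi <= lo:
        return 0.0
    b0, b1 = lo // bs, (hi - 1) // bs
    total = 0.0
    for b in range(b0, b1 + 1):
        s = max(lo, b * bs)
        e = min(hi, (b + 1) * bs)
        total += arr[b] * (e - s)
    return total / width


def reference_point_matrix(track: CoverageTrack,
                           points: list[tuple[str, int, str]],
                           flank: int = 2000, bin: int = 25,
                           row_ids: list[str] | None = None) -> ProfileMatrix:
    """Signal matrix over [pos-flank, pos+flank) around each point.

    Rows of "-" strand points are reversed so columns run 5'->3' along the
    feature; bins outside the contig are zero.
    """
    if flank % bin:
        raise ValueError("flank must be divisible by bin")
    ncols = 2 * flank // bin
    if row_ids is None:
        row_ids = [f"{c}:{p}:{s}" for (c, p, s) in points]
    mat = np.zeros((len(points), ncols))
    for r, (chrom, pos, strand) in enumerate(points):
        for j in range(ncols):
            s = pos - flank + j * bin
            mat[r, j] = _mean_signal(track, chrom, s, s + bin)
        if strand == "-":
            mat[r] = mat[r, ::-1]
    return ProfileMatrix(values=mat, row_ids=row_ids, mode="reference_point",
                         bin_bp=bin, flank_bp=flank)


def _region_bp_signal(track: CoverageTrack, chrom: str,
                      segments: list[tuple[int, int]]) -> np.ndarray:
    """Per-bp signal over concatenated segments (genomic order)."""
    parts = []
    for (s, e) in segments:
        vals = np.zeros(e - s)
        arr = track.values.get(chrom)
        if arr is not None:
            bs = track.bin_size
            pos = np.arange(max(s, 0), min(e, len(arr) * bs))
            if len(pos):
                vals[pos - s] = arr[pos // bs]
        parts.append(vals)
    return np.concatenate(parts) if parts else np.zeros(0)


def scale_regions_matrix(track: CoverageTrack,
                         regions: list[TranscriptModel],
                         body: int = 4000, bin: int = 25,
                         mode: str = "metagene") -> ProfileMatrix:
    """Each region's signal linearly rescaled onto body/bin columns.

    ``metagene`` mode concatenates exons (introns excluded); ``span`` mode
    uses the whole gene span.  Minus-strand rows are reversed.
    """
    if body % bin:
        raise ValueError("body must be divisible by bin")
    if mode not in ("span", "metagene"):
        raise ValueError(f"unknown mode {mode!r}")
    ncols = body // bin
    mat = np.zeros((len(regions), ncols))
    row_ids = []
    for r, t in enumerate(regions):
        row_ids.append(t.transcript_id)
        segs = t.exons if (mode == "metagene" and t.exons) else [(t.start, t.end)]
        sig = _region_bp_signal(track, t.chrom, segs)
        n = len(sig)
        if n == 0:
            continue
        if n < bin:
            warnings.warn(f"region {t.transcript_id} shorter than one bin; "
                          "row set to its mean", stacklevel=2)
            mat[r] = sig.mean()
        else:
            # average-pool via linear interpolation of the cumulative signal
            cum = np.concatenate([[0.0], np.cumsum(sig)])
            edges = np.linspace(0, n, ncols + 1)
            ce = np.interp(edges, np.arange(n + 1), cum)
            mat[r] = np.diff(ce) / np.diff(edges)
        if t.strand == "-":
            mat[r] = mat[r, ::-1]
    return ProfileMatrix(values=mat, row_ids=row_ids, mode="scale_regions",
                         bin_bp=bin, body_bp=body)


def order_rows(matrix: ProfileMatrix, stat: str = "max") -> ProfileMatrix:
    """Sort rows descending by a row statistic; ties by row_id ascending."""
    fns = {"max": np.max, "mean": np.mean, "sum": np.sum}
    if stat not in fns:
        raise ValueError(f"unknown stat {stat!r}")
    keys = fns[stat](matrix.values, axis=1)
    order = sorted(range(matrix.n_rows),
                   key=lambda i: (-keys[i], matrix.row_ids[i]))
    return ProfileMatrix(values=matrix.values[order],
                         row_ids=[matrix.row_ids[i] for i in order],
                         mode=matrix.mode, bin_bp=matrix.bin_bp,
                         flank_bp=matrix.flank_bp, body_bp=matrix.body_bp)


def column_profile(matrix: ProfileMatrix) -> np.ndarray:
    """Per-column arithmetic mean (the aggregate metaprofile)."""
    if matrix.n_rows == 0:
        raise ValueError("empty matrix")
    return matrix.values.mean(axis=0)


def save_matrix(matrix: ProfileMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="row_id")
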