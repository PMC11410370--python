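"""ChIP x RNA integration: differential-expression thresholds, gene binding
status, Fisher enrichment of bound x regulated genes, cross-reference against
an external gene list (e.g. maternally deposited embryo transcripts), and the
bound-at-TSS-and-upregulated target-gene report.

The expressed-gene universe is the set of DE-table rows; genes with no
detectable expression are excluded upstream.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import IntervalSet, TranscriptModel
from .interval_stats import ContingencyTable, fisher_exact
from .io import DETable


@dataclass
class GeneStatus:
    gene_id: str
    de_class: str              # up | down | ns
    bound_any: bool
    bound_at_tss: bool
    in_reference_list: bool = False
    log2fc: float = float("nan")
    padj: float = float("nan")


def apply_de_thresholds(table: DETable, lfc_cut: float = 0.5,
                        padj_cut: float = 0.05) -> dict[str, str]:
    """Classify genes as up / down / ns with strict inequalities.

    up: log2fc > lfc_cut and padj < padj_cut; down symmetric; missing padj
    is never significant.
    """
    out: dict[str, str] = {}
    for row in table.df.itertuples(index=False):
        cls = "ns"
        if pd.notna(row.padj) and row.padj < padj_cut:
            if row.log2fc > lfc_cut:
                cls = "up"
            elif row.log2fc < -lfc_cut:
                cls = "down"
        out[row.gene_id] = cls
    return out


def gene_binding_status(transcripts: list[TranscriptModel],
                        peaks: IntervalSet) -> dict[str, tuple[bool, bool]]:
    """Per gene: (bound_any, bound_at_tss) against a peak set.

    bound_at_tss: some peak contains some transcript TSS of the gene;
    bound_any: some peak overlaps some transcript span (TSS implies any).
    """
    peaks_by = peaks.by_chrom()
    for c in peaks_by:
        peaks_by[c].sort(key=lambda iv: iv.start)
    out: dict[str, tuple[bool, bool]] = {}
    for t in transcripts:
        bound_any, bound_tss = out.get(t.gene_id, (False, False))
        tss = t.tss()
        for iv in peaks_by.get(t.chrom, []):
            if iv.start >= t.end and iv.start > tss:
                break
            if iv.start <= tss < iv.end:
                bound_tss = True
                bound_any = True
            elif iv.start < t.end and t.start < iv.end:
                bound_any = True
        out[t.gene_id] = (bound_any, bound_tss)
    return out


def build_gene_status(table: DETable,
                      transcripts: list[TranscriptModel] | None = None,
                      peaks: IntervalSet | None = None,
                      reference_list: list[str] | None = None,
                      lfc_cut: float = 0.5,
                      padj_cut: float = 0.05) -> list[GeneStatus]:
    """Assemble per-gene status over the expressed universe (DE-table rows)."""
    de = apply_de_thresholds(table, lfc_cut=lfc_cut, padj_cut=padj_cut)
    binding = (gene_binding_status(transcripts, peaks)
               if transcripts is not None and peaks is not None else {})
    ref = set(reference_list or ())
    out = []
    for row in table.df.itertuples(index=False):
        ba, bt = binding.get(row.gene_id, (False, False))
        out.append(GeneStatus(
            gene_id=row.gene_id, de_class=de[row.gene_id],
            bound_any=ba, bound_at_tss=bt,
            in_reference_list=row.gene_id in ref,
            log2fc=float(row.log2fc),
            padj=float(row.padj) if pd.notna(row.padj) else float("nan")))
    return out


def enrichment_2x2(status: list[GeneStatus], row, col) -> ContingencyTable:
    """Fisher table over the expressed universe for two gene predicates.

    ``row`` and ``col`` are predicates on GeneStatus; cells are
    (row&col, row&~col, ~row&col, ~row&~col).
    """
    if not status:
        raise ValueError("empty gene universe")
    n11 = n12 = n21 = n22 = 0
    for s in status:
        r, c = bool(row(s)), bool(col(s))
        if r and c:
            n11 += 1
        elif r:
            n12 += 1
        elif c:
            n21 += 1
        else:
            n22 += 1
    return fisher_exact((n11, n12, n21, n22))


def crossref_gene_list(status: list[GeneStatus], reference_list: list[str],
                       ) -> tuple[list[GeneStatus], ContingencyTable, ContingencyTable]:
    """Set in_reference_list and emit (up x list, down x list) Fisher tables."""
    if not reference_list:
        raise ValueError("empty reference list")
    ref = set(reference_list)
    universe = {s.gene_id for s in status}
    if not (ref & universe):
        import warnings
        warnings.warn("reference list does not intersect the gene universe",
                      stacklevel=2)
    for s in status:
        s.in_reference_list = s.gene_id in ref
    up_tab = enrichment_2x2(status, lambda s: s.de_class == "up",
                            lambda s: s.in_reference_list)
    down_tab = enrichment_2x2(status, lambda s: s.de_class == "down",
                              lambda s: s.in_reference_list)
    return status, up_tab, down_tab


def target_gene_report(status: list[GeneStatus],
                       motif_presence: pd.DataFrame | None = None,
                       peak_assignment: dict[str, list[str]] | None = None
                       ) -> pd.DataFrame:
    """Bound-at-TSS and upregulated genes, sorted by log2fc descending."""
    rows = []
    for s in status:
        if s.bound_at_tss and s.de_class == "up":
            rec = dict(gene_id=s.gene_id, log2fc=s.log2fc, padj=s.padj)
            if peak_assignment is not None:
                rec["peaks"] = ",".join(peak_assignment.get(s.gene_id, []))
            rows.append(rec)
    df = pd.DataFrame(rows, columns=["gene_id", "log2fc", "padj"]
                      + (["peaks"] if peak_assignment is not None else []))
    if motif_presence is not None and len(df):
        for col in motif_presence.columns:
            df[f"motif_{col}"] = df["gene_id"].map(
                lambda g: bool(motif_presence[col].get(g, False)))
    return df.sort_values("log2fc", ascending=False, ignore_index=True)
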