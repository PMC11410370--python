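"""Core-promoter element scanning of oriented promoter windows.

Scans each promoter window (TSS-centered, 5'->3') for core promoter elements
— TATA, initiator (INR), DPE, MTE, M1BP/Ohler-1 — plus any extra motifs (the
OVO catalog), records hit offsets relative to the dominant TSS, builds
positional histograms, and tests element enrichment between promoter classes
with Fisher's exact test.

The default element consensus strings are transcribed from the Drosophila
core-promoter literature and are configuration, not fixed truths: swap in
PWMs or different consensus definitions via ``ElementCatalog``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cage import PromoterWindow
from .interval_stats import ContingencyTable, fisher_exact
from .motifs import MotifModel, iupac_scan, pwm_scan


@dataclass
class ElementDef:
    name: str
    motif: MotifModel
    strand_rule: str = "sense_only"   # sense_only | both
    alpha: float = 0.003              # used in pwm mode only

    def __post_init__(self) -> None:
        if self.strand_rule not in ("sense_only", "both"):
            raise ValueError(f"bad strand_rule {self.strand_rule!r}")


@dataclass
class ElementCatalog:
    entries: list[ElementDef]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("duplicate element names in catalog")

    def names(self) -> list[str]:
        return [e.name for e in self.entries]


def default_element_catalog(include_ovo: bool = True) -> ElementCatalog:
    """Drosophila core-promoter elements plus (optionally) the OVO motifs.

    Element consensus definitions follow the fly core-promoter literature:
    TATA box (~ -31), initiator spanning the TSS, MTE (+18..+29),
    DPE (+28..+33), and the M1BP/Ohler-1 motif.  Core elements are scanned on
    the sense strand only; OVO motifs on both strands with a stricter alpha.
    """
    entries = [
        ElementDef("TATA", MotifModel.from_consensus("TATA", "STATAWAWR")),
        ElementDef("INR", MotifModel.from_consensus("INR", "TCAKTY")),
        ElementDef("MTE", MotifModel.from_consensus("MTE", "CSARCSSAACGS")),
        ElementDef("DPE", MotifModel.from_consensus("DPE", "KCGGTTSK")),
        ElementDef("M1BP", MotifModel.from_consensus("M1BP", "GGTCACACTG")),
    ]
    if include_ovo:
        from .motifs import default_ovo_catalog
        for m in default_ovo_catalog():
            entries.append(ElementDef(m.name, m, strand_rule="both",
                                      alpha=0.0002))
    return ElementCatalog(entries)


@dataclass
class PromoterElementMatrix:
    presence: pd.DataFrame                 # promoters x elements, bool
    offsets: dict[str, dict[str, list[int]]]  # promoter -> element -> offsets
    flank: int

    def promoter_ids(self) -> list[str]:
        return list(self.presence.index)

    def elements(self) -> list[str]:
        return list(self.presence.columns)


def scan_promoters(windows: list[PromoterWindow], catalog: ElementCatalog,
                   mode: str = "iupac",
                   ids: list[str] | None = None) -> PromoterElementMatrix:
    """Scan oriented promoter windows for every catalog element.

    ``sense_only`` elements are scanned on the oriented (sense) sequence
    only; ``both`` elements on both strands.  Hit offsets are recorded as
    hit start - TSS index.
    """
    if ids is None:
        ids = [f"prom_{i}" for i in range(len(windows))]
    flank = max((w.tss_index for w in windows), default=0)
    presence = {}
    offsets: dict[str, dict[str, list[int]]] = {pid: {} for pid in ids}
    for elem in catalog.entries:
        col = []
        for pid, w in zip(ids, windows):
            if len(w.sequence) < len(elem.motif):
                col.append(False)
                offsets[pid][elem.name] = []
                continue
            both = elem.strand_rule == "both"
            if mode == "pwm" and elem.motif.pwm is not None:
                hits = pwm_scan(w.sequence, elem.motif, alpha=elem.alpha,
                                both_strands=both)
            else:
                hits = iupac_scan(w.sequence, elem.motif, both_strands=both)
            offs = [h.start - w.tss_index for h in hits]
            offsets[pid][elem.name] = offs
            col.append(len(offs) > 0)
        presence[elem.name] = col
    return PromoterElementMatrix(
        presence=pd.DataFrame(presence, index=ids),
        offsets=offsets, flank=flank)


def element_positional_histogram(matrix: PromoterElementMatrix,
                                 bin: int = 5) -> pd.DataFrame:
    """Percent of promoters with >= 1 hit of each element per offset bin.

    Returns a DataFrame indexed by bin start offset, one column per element.
    """
    if bin < 1:
        raise ValueError("bin must be >= 1")
    flank = matrix.flank
    edges = np.arange(-flank, flank + bin + 1, bin)
    n_prom = len(matrix.presence)
    data = {}
    for elem in matrix.elements():
        counts = np.zeros(len(edges) - 1)
        for pid in matrix.promoter_ids():
            offs = matrix.offsets[pid].get(elem, [])
            if not offs:
                continue
            bins_hit = set()
            for off in offs:
                b = int(np.searchsorted(edges, off, side="right")) - 1
                if 0 <= b < len(counts):
                    bins_hit.add(b)
            for b in bins_hit:
                counts[b] += 1
        data[elem] = 100.0 * counts / n_prom if n_prom else counts
    return pd.DataFrame(data, index=edges[:-1])


def element_class_enrichment(matrix_a: PromoterElementMatrix,
                             matrix_b: PromoterElementMatrix,
                             bonferroni: bool = False) -> pd.DataFrame:
    """Per-element Fisher enrichment of presence in class a vs class b.

    Table per element: rows = promoter class (a, b), columns = element
    present/absent.  Returns a DataFrame with counts, sample OR and p
    (optionally Bonferroni-corrected across elements).
    """
    shared = [e for e in matrix_a.elements() if e in set(matrix_b.elements())]
    rows = []
    for elem in shared:
        a_yes = int(matrix_a.presence[elem].sum())
        a_no = len(matrix_a.presence) - a_yes
        b_yes = int(matrix_b.presence[elem].sum())
        b_no = len(matrix_b.presence) - b_yes
        ct = fisher_exact((a_yes, a_no, b_yes, b_no))
        rows.append(dict(element=elem, a_present=a_yes, a_absent=a_no,
                         b_present=b_yes, b_absent=b_no,
                         odds_ratio=ct.odds_ratio, p=ct.p_two_sided))
    df = pd.DataFrame(rows)
    if bonferroni and len(df):
        df["p_bonferroni"] = (df["p"] * len(df)).clip(upper=1.0)
    return df
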