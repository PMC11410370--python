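"""Published summary counts from the OVO ovary occupancy study.

The genome-scale analyses in this package were originally run on ovary
ChIP-seq / RNA-seq / CAGE-seq libraries; the study's summary tables survive
as printed marginal counts.  This module records those counts as *inputs*
so the contingency statistics and percentage arithmetic can be recomputed
from scratch with the package's own Fisher machinery.

All counts refer to gene/peak tallies over the expressed-gene universe
(10,804 genes with detectable expression) and the 3,094 consensus ChIP
peaks (intersection of the HA- and GFP-tagged pulldowns).
"""
from __future__ import annotations

# peak-set agreement between the two tagged pulldowns
N_PEAKS_HA = 3393          # significant peaks, HA-tagged pulldown
N_PEAKS_GFP = 7235         # significant peaks, GFP-tagged pulldown
N_PEAKS_CONSENSUS = 3094   # HA peaks also found in the GFP set

# peak-to-gene classification of the consensus peaks
N_PEAKS_AT_TSS = 1394
N_PEAKS_GENE_BODY = 1339
N_PEAKS_INTERGENIC = 366

# expressed-gene universe and DE margins (|log2FC| > 0.5, p-adj < 0.05)
N_EXPRESSED = 10804
N_UP = 1994                # increased with rescue OVO
N_DOWN = 2924              # decreased with rescue OVO
N_BOUND = 2298             # expressed genes overlapping a consensus peak
N_BOUND_UP = 666
N_BOUND_DOWN = 564

# moderately expressed in 0-2 hr embryos (maternal deposition reference list)
N_UP_IN_EMBRYO = 1409
N_DOWN_IN_EMBRYO = 625
N_NS_IN_EMBRYO = 3448


def bound_up_table() -> tuple[int, int, int, int]:
    """2x2 of bound x upregulated over the expressed universe."""
    n11 = N_BOUND_UP
    n12 = N_BOUND - N_BOUND_UP
    n21 = N_UP - N_BOUND_UP
    n22 = N_EXPRESSED - n11 - n12 - n21
    return n11, n12, n21, n22


def bound_down_table() -> tuple[int, int, int, int]:
    """2x2 of bound x downregulated over the expressed universe."""
    n11 = N_BOUND_DOWN
    n12 = N_BOUND - N_BOUND_DOWN
    n21 = N_DOWN - N_BOUND_DOWN
    n22 = N_EXPRESSED - n11 - n12 - n21
    return n11, n12, n21, n22


def _n_embryo() -> int:
    return N_UP_IN_EMBRYO + N_DOWN_IN_EMBRYO + N_NS_IN_EMBRYO


def up_embryo_table() -> tuple[int, int, int, int]:
    """2x2 of upregulated x embryo-expressed over the expressed universe."""
    n11 = N_UP_IN_EMBRYO
    n12 = N_UP - N_UP_IN_EMBRYO
    n21 = _n_embryo() - N_UP_IN_EMBRYO
    n22 = N_EXPRESSED - n11 - n12 - n21
    return n11, n12, n21, n22


def down_embryo_table() -> tuple[int, int, int, int]:
    """2x2 of downregulated x embryo-expressed over the expressed universe."""
    n11 = N_DOWN_IN_EMBRYO
    n12 = N_DOWN - N_DOWN_IN_EMBRYO
    n21 = _n_embryo() - N_DOWN_IN_EMBRYO
    n22 = N_EXPRESSED - n11 - n12 - n21
    return n11, n12, n21, n22
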