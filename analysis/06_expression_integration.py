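#!/usr/bin/env python
"""Does binding predict activation?  ChIP x RNA Fisher integration.

Thresholds the DE table (|log2FC| > 0.5, p-adj < 0.05, strict), computes
per-gene binding status against the consensus peaks, tests bound x up and
bound x down enrichment over the expressed universe, cross-references the
embryo-expressed gene list, writes the bound-at-TSS-and-upregulated target
report, and recomputes the published contingency statistics from the
study's printed marginal counts for side-by-side comparison.
"""
import argparse
from pathlib import Path

import pandas as pd

from ovokit import study_tables as st
from ovokit.integration import (build_gene_status, crossref_gene_list,
                                enrichment_2x2, target_gene_report)
from ovokit.interval_stats import fisher_exact
from ovokit.io import (read_de_table, read_gene_list, read_gene_models,
                       read_intervals)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--bundle", type=Path, default=ROOT / "results" / "bundle")
    ap.add_argument("--out", type=Path,
                    default=ROOT / "results" / "integration")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    table = read_de_table(args.bundle / "de.tsv")
    models = read_gene_models(args.bundle / "genes.gtf")
    peaks = read_intervals(args.bundle / "peaks_consensus.bed")
    embryo = read_gene_list(args.bundle / "embryo_genes.txt")

    status = build_gene_status(table, models, peaks)
    n_up = sum(s.de_class == "up" for s in status)
    n_down = sum(s.de_class == "down" for s in status)
    n_bound = sum(s.bound_any for s in status)
    print(f"universe {len(status)} genes: {n_up} up, {n_down} down, "
          f"{n_bound} bound")

    rows = []
    for name, row_pred, col_pred in [
        ("bound_x_up", lambda s: s.bound_any, lambda s: s.de_class == "up"),
        ("bound_x_down", lambda s: s.bound_any,
         lambda s: s.de_class == "down"),
    ]:
        ct = enrichment_2x2(status, row_pred, col_pred)
        rows.append((name, *ct.as_tuple(), ct.odds_ratio, ct.p_two_sided))
        print(f"{name}: OR={ct.odds_ratio:.3f} p={ct.p_two_sided:.3g} "
              f"table={ct.as_tuple()}")

    _, up_tab, down_tab = crossref_gene_list(status, embryo)
    rows.append(("up_x_embryo", *up_tab.as_tuple(), up_tab.odds_ratio,
                 up_tab.p_two_sided))
    rows.append(("down_x_embryo", *down_tab.as_tuple(), down_tab.odds_ratio,
                 down_tab.p_two_sided))
    print(f"up_x_embryo: OR={up_tab.odds_ratio:.3f}; "
          f"down_x_embryo: OR={down_tab.odds_ratio:.3f}")

    for name, tab in [("published_bound_x_up", st.bound_up_table()),
                      ("published_bound_x_down", st.bound_down_table()),
                      ("published_up_x_embryo", st.up_embryo_table()),
                      ("published_down_x_embryo", st.down_embryo_table())]:
        ct = fisher_exact(tab)
        rows.append((name, *tab, ct.odds_ratio, ct.p_two_sided))
        print(f"{name}: OR={ct.odds_ratio:.3f}")

    pd.DataFrame(rows, columns=["comparison", "n11", "n12", "n21", "n22",
                                "odds_ratio", "p"]).to_csv(
        args.out / "contingency.tsv", sep="\t", index=False)

    pd.DataFrame([s.__dict__ for s in status]).to_csv(
        args.out / "gene_status.tsv", sep="\t", index=False)
    report = target_gene_report(status)
    report.to_csv(args.out / "targets.tsv", sep="\t", index=False)
    print(f"{len(report)} bound-at-TSS and upregulated target genes; "
          f"tables -> {args.out}")


if __name__ == "__main__":
    main()
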