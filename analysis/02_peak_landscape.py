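#!/usr/bin/env python
"""Where do the ChIP peaks sit relative to genes?

Computes replicate agreement (bp Jaccard), classifies consensus peaks as
TSS / gene-body / intergenic, measures the relative-distance statistic of
peaks to TSS / ORF midpoints / transcription-end sites (TSS association
shows up as mass near 0), and assigns every peak its closest TSS.
"""
import argparse
from pathlib import Path

import pandas as pd

from ovokit.interval_stats import (classify_peaks, closest_tss, jaccard,
                                   relative_distance)
from ovokit.io import read_gene_models, read_intervals

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--bundle", type=Path, default=ROOT / "results" / "bundle")
    ap.add_argument("--out", type=Path,
                    default=ROOT / "results" / "peak_landscape")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    rep1 = read_intervals(args.bundle / "peaks_rep1.bed")
    rep2 = read_intervals(args.bundle / "peaks_rep2.bed")
    peaks = read_intervals(args.bundle / "peaks_consensus.bed")
    models = read_gene_models(args.bundle / "genes.gtf")

    j = jaccard(rep1, rep2)
    print(f"replicate agreement: Jaccard {j.jaccard:.4f} "
          f"({j.intersection_bp}/{j.union_bp} bp), "
          f"{j.n_overlapping_pairs}/{len(rep1)} rep1 peaks overlap rep2")

    cls = classify_peaks(peaks, models)
    print("peak classes: " + ", ".join(
        f"{lab} {cls.counts[lab]} ({cls.percents[lab]}%)"
        for lab in ("TSS", "gene_body", "intergenic")))
    pd.DataFrame(dict(
        chrom=[iv.chrom for iv in peaks],
        start=[iv.start for iv in peaks],
        end=[iv.end for iv in peaks],
        name=[iv.name for iv in peaks],
        label=cls.labels, closest_gene=cls.assigned_gene,
    )).to_csv(args.out / "peak_classes.tsv", sep="\t", index=False)

    refs = {
        "tss": [(t.chrom, t.tss()) for t in models],
        "orf": [(t.chrom, t.cds_midpoint()) for t in models
                if t.cds is not None],
        "tts": [(t.chrom, t.tes()) for t in models],
    }
    hist = {}
    for element, pts in refs.items():
        r = relative_distance(peaks, pts)
        hist[element] = r.histogram
        near = float(r.histogram[:5].sum())
        print(f"reldist to {element}: {near:.0%} of peaks within "
              f"relative distance 0.1 (dropped {r.n_dropped})")
    df = pd.DataFrame(hist)
    df.insert(0, "bin_start", [i * 0.02 for i in range(len(df))])
    df.to_csv(args.out / "reldist_histograms.tsv", sep="\t", index=False)

    rows = []
    for iv in peaks:
        gid, d = closest_tss(iv, models)
        rows.append((iv.name, gid, d))
    pd.DataFrame(rows, columns=["peak", "gene", "signed_distance"]).to_csv(
        args.out / "closest_tss.tsv", sep="\t", index=False)
    print(f"tables -> {args.out}")


if __name__ == "__main__":
    main()
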