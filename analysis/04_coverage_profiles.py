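#!/usr/bin/env python
"""ChIP signal metaprofiles: does the subtracted coverage pile up on TSSs
and peak summits?

BPM-normalizes the ChIP and input tracks, subtracts them, builds
reference-point matrices centered on TSSs and on peak summits (2 kb flanks,
25 bp bins), a scale-regions metagene matrix for bound genes, orders
heatmap rows by max, and writes the column-mean profiles.
"""
import argparse
from pathlib import Path

import pandas as pd

from ovokit.coverage import (bpm_normalize, column_profile, order_rows,
                             reference_point_matrix, save_matrix,
                             scale_regions_matrix, subtract_tracks)
from ovokit.integration import gene_binding_status
from ovokit.io import read_gene_models, read_intervals, read_track

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--bundle", type=Path, default=ROOT / "results" / "bundle")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "profiles")
    ap.add_argument("--bin", type=int, default=25)
    ap.add_argument("--flank", type=int, default=2000)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    models = read_gene_models(args.bundle / "genes.gtf")
    peaks = read_intervals(args.bundle / "peaks_consensus.bed")
    sizes = {}
    from pyfaidx import Fasta
    for name, contig in Fasta(str(args.bundle / "genome.fa")).items():
        sizes[name] = len(contig)
    chip = read_track(args.bundle / "chip.bedgraph", args.bin, sizes)
    inp = read_track(args.bundle / "input.bedgraph", args.bin, sizes)
    diff = subtract_tracks(bpm_normalize(chip), bpm_normalize(inp))

    tss_points = [(t.chrom, t.tss(), t.strand) for t in models]
    m_tss = reference_point_matrix(diff, tss_points, flank=args.flank,
                                   bin=args.bin,
                                   row_ids=[t.gene_id for t in models])
    save_matrix(order_rows(m_tss, "max"), args.out / "tss_matrix.tsv")
    prof = column_profile(m_tss)
    pd.DataFrame({"offset": range(-args.flank, args.flank, args.bin),
                  "mean_signal": prof}).to_csv(
        args.out / "tss_profile.tsv", sep="\t", index=False)
    center = len(prof) // 2
    print(f"TSS profile: argmax at column {prof.argmax()} "
          f"(center {center}), center/edge ratio "
          f"{prof[center] / max(prof[0], 1e-9):.1f}")

    summit_points = [(iv.chrom, iv.midpoint, "+") for iv in peaks]
    m_summit = reference_point_matrix(diff, summit_points, flank=args.flank,
                                      bin=args.bin)
    prof_s = column_profile(m_summit)
    pd.DataFrame({"offset": range(-args.flank, args.flank, args.bin),
                  "mean_signal": prof_s}).to_csv(
        args.out / "summit_profile.tsv", sep="\t", index=False)
    print(f"summit profile: argmax at column {prof_s.argmax()} "
          f"(center {len(prof_s) // 2})")

    binding = gene_binding_status(models, peaks)
    bound_models = [t for t in models if binding[t.gene_id][0]]
    m_body = scale_regions_matrix(diff, bound_models, body=4000, bin=args.bin,
                                  mode="metagene")
    save_matrix(order_rows(m_body, "max"), args.out / "metagene_matrix.tsv")
    print(f"metagene matrix over {len(bound_models)} bound genes; "
          f"tables -> {args.out}")


if __name__ == "__main__":
    main()
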