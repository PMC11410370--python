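#!/usr/bin/env python
"""Generate the synthetic study bundle every downstream driver consumes.

Simulates desk-scale study conditions — two ChIP peak replicates at
bp-Jaccard 0.64, ~45% of peaks on TSSs, OVO-motif instances planted in 72%
of consensus peaks, TSS-concentrated CAGE tags, enrichment-shaped coverage
and a DE table with a planted bound x up odds ratio of 2.21 — and writes
the bundle plus its ground truth under results/bundle/.
"""
import argparse
from pathlib import Path

from ovokit.synthetic import ScenarioConfig, simulate_scenario

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "bundle")
    args = ap.parse_args()

    bundle = simulate_scenario(ScenarioConfig(seed=args.seed), out_dir=args.out)
    t = bundle.truth
    print(f"bundle -> {args.out}")
    print(f"  peaks: rep1={t['n_peaks_rep1']} rep2={t['n_peaks_rep2']} "
          f"consensus={t['n_peaks_consensus']}")
    print(f"  realized Jaccard {t['realized_jaccard']:.4f} "
          f"(target {t['target_jaccard']})")
    print(f"  motif planted fraction {t['motifs']['planted_fraction']:.3f}")
    print(f"  realized bound x up OR {t['realized_bound_up_or']:.3f}")


if __name__ == "__main__":
    main()
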