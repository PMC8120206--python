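#!/usr/bin/env python
"""Immune landscape of the cohort: heterogeneity and instability indices
(MATH, wGII/CIN, multiregion branch proportions), the 8-axis immunogram,
TMIT quadrants and Treg/CD8, M2/M1 ratios — all from the pipeline outputs.

Writes results/immune_landscape_summary.tsv.
"""

import json
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    het = pd.read_csv(ROOT / "pipeline" / "heterogeneity.tsv", sep="\t")
    ith = pd.read_csv(ROOT / "pipeline" / "ith.tsv", sep="\t")
    tmit = pd.read_csv(ROOT / "pipeline" / "tmit_ratios.tsv", sep="\t")
    radar = json.loads((ROOT / "pipeline" / "immunogram_radar.json").read_text())

    print(f"MATH score: median {het['math'].median():.1f} "
          f"(range {het['math'].min():.1f}-{het['math'].max():.1f})")
    cin = het["cin_positive"].mean()
    print(f"wGII: median {het['wgii'].median():.3f}; "
          f"CIN+ (wGII > 0.2) in {100 * cin:.1f}% of samples")
    if len(ith):
        print("multiregion ITH (branch proportions):")
        for r in ith.itertuples():
            print(f"  {r.patient_id}: neoantigen {r.neoantigen_ith:.2f}, "
                  f"TCR {r.tcr_ith:.2f}")

    counts = tmit["tmit"].value_counts().reindex(["I", "II", "III", "IV"], fill_value=0)
    print("TMIT quadrants (CD8A x PD-L1 median splits): "
          + ", ".join(f"{k}: {v}" for k, v in counts.items()))
    print(f"Treg/CD8 ratio median {tmit['treg_cd8_ratio'].median():.2f}; "
          f"M2/M1 median {tmit['m2_m1_ratio'].median():.2f}")

    sample, axes = next(iter(radar.items()))
    print(f"immunogram for {sample} (IGS, 3 = cohort average):")
    for name, value in axes["igs"].items():
        print(f"  {name:28s} {value:.2f}")

    het.describe().to_csv(ROOT / "immune_landscape_summary.tsv", sep="\t")


if __name__ == "__main__":
    main()
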