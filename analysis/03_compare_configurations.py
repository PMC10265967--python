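#!/usr/bin/env python
"""Paired configuration comparisons: can side, coil position, extra coils.

Reads the sweep table and reports, for each study comparison, the paired
medians with interquartile ranges and the Wilcoxon signed-rank p-value
(pairing within model). Also renders Tukey-style boxplots of DFT energy
and impedance per configuration.

Output: results/comparisons.csv, results/boxplots.png
"""

import argparse
import os

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from torsodft.study import STUDY_PAIRS, compare_configurations

ORDER = ["left_apical", "right_apical", "right_apical_svc", "right_apical_cs",
         "right_apical_svc_cs", "left_septal", "right_septal",
         "right_septal_svc", "right_septal_cs", "right_septal_svc_cs"]


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--metrics", default="results/metrics.csv")
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    df = pd.read_csv(args.metrics)
    tables = []
    for metric in ("dft_energy_J", "impedance_ohm", "mean_e_field_V_per_mm"):
        tables.append(compare_configurations(df, STUDY_PAIRS, metric))
    cmp = pd.concat(tables, ignore_index=True)
    os.makedirs(args.out, exist_ok=True)
    cmp.to_csv(os.path.join(args.out, "comparisons.csv"), index=False)

    print("paired comparisons (DFT energy):")
    sub = cmp[cmp.metric == "dft_energy_J"]
    for _, r in sub.iterrows():
        sig = "*" if r.p_value < 0.05 else " "
        print(f"  {r.config_a:22s} vs {r.config_b:22s}: "
              f"{r.median_a:5.1f} ({r.q1_a:.1f}, {r.q3_a:.1f}) J vs "
              f"{r.median_b:5.1f} ({r.q1_b:.1f}, {r.q3_b:.1f}) J, "
              f"p={r.p_value:.4f}{sig}")

    fig, axes = plt.subplots(1, 2, figsize=(13, 4.5))
    for ax, metric, label in zip(
            axes, ("dft_energy_J", "impedance_ohm"),
            ("DFT energy (J)", "Impedance (Ohm)")):
        data = [df[df.configuration == c][metric] for c in ORDER]
        ax.boxplot(data, tick_labels=ORDER)
        ax.set_ylabel(label)
        ax.tick_params(axis="x", rotation=60)
    fig.tight_layout()
    fig.savefig(os.path.join(args.out, "boxplots.png"), dpi=120)
    print(f"\nwrote {args.out}/comparisons.csv and {args.out}/boxplots.png")


if __name__ == "__main__":
    main()
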