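#!/usr/bin/env python
"""Compute relative fitness W_ij and mixing effects C_i(j) per replicate.

Reads estimates from 02, pairs each mixed sample with its matching-history
pure-culture reference, and writes fitness.csv per scenario.  Prints the
cross-replicate mean W of each cheater cell and mean C of each focal strain,
alongside the generator's ground truth for comparison.
"""
import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
import myxofit as mf

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main() -> None:
    for scenario in ("cheater_pairs", "natural_isolates"):
        base = OUT / scenario
        est = pd.read_csv(base / "estimates.csv").fillna({"partner_strain": "", "history_partner": ""})
        design = mf.load_design(base / "design.yaml")
        fit, diag = mf.build_fitness_table(est, design)
        fit.to_csv(base / "fitness.csv", index=False)
        truth = json.loads((base / "ground_truth.json").read_text())
        col, stat = ("W_ij", "W") if scenario == "cheater_pairs" else ("C_i_of_j", "C")
        print(f"{scenario} ({len(fit)} records, {len(diag)} diagnostics):")
        means = fit.groupby(["pair_id", "strain_i", "cell"])[col].mean()
        for (pair, strain, cell), m in means.items():
            if scenario == "cheater_pairs" and not strain.startswith("Ch"):
                continue
            t = truth[stat]["|".join((pair, strain, cell))]
            print(f"  {pair} {strain} {cell}: mean {stat} {m:+.2f} (truth {t:+.2f})")


if __name__ == "__main__":
    main()
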