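#!/usr/bin/env python
"""Run the testing protocol and print the qualitative outcome grids.

Reads fitness tables from 03; runs the factorial ANOVA, Holm-corrected
one-sample t-tests per history cell and Dunnett contrasts against H/H; writes
anova.csv / tests.csv / outcomes.csv per scenario and prints the cheating /
exploitation grid in the style of the study's qualitative summary.
"""
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
import myxofit as mf

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main() -> None:
    for scenario in ("cheater_pairs", "natural_isolates"):
        base = OUT / scenario
        fit = pd.read_csv(base / "fitness.csv")
        design = mf.load_design(base / "design.yaml")
        res = mf.analyze_experiment(fit, design)
        for name in ("anova", "tests", "outcomes"):
            res[name].to_csv(base / f"{name}.csv", index=False)
        print(f"== {scenario} ==")
        anova = res["anova"]
        head = anova[anova["family"].str.startswith("cheater")] if scenario == "cheater_pairs" else anova.head(0)
        for r in head.itertuples():
            if r.term != "residual":
                print(f"  ANOVA {r.term}: F({r.df1:.0f},{r.df2:.0f}) = {r.F:.2f}, p = {r.p:.4f}")
        print(mf.render_outcome_grid(res["outcomes"]))
        print()


if __name__ == "__main__":
    main()
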