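#!/usr/bin/env python
"""Re-analyse a local copy of the study's deposited dataset (optional).

The original plate-count data are archived on Zenodo (DOI
10.5281/zenodo.10469400).  This driver does not download anything: point it
at a local CSV already mapped to the canonical schema (see
`myxofit.io.SCHEMA_COLUMNS`) plus a design YAML, and it runs the full
pipeline — including the three-factor cheater ANOVA whose term layout
mirrors the published table (cheater, nutrients[Ch], nutrients[WT] and their
interactions, each on 1 df).

Usage:
    python analysis/06_deposited_data.py <counts.csv> <design.yaml> [out_dir]
"""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
import myxofit as mf


def main(argv: list[str]) -> int:
    if len(argv) < 2:
        print(__doc__)
        return 2
    counts_path, design_path = argv[0], argv[1]
    out_dir = argv[2] if len(argv) > 2 else "results/analysis/deposited"
    cfg = mf.RunConfig(counts=counts_path, design=design_path, out_dir=out_dir)
    summary = mf.run_pipeline(cfg)
    print(summary["outcome_grid"])
    print(f"bundle written to {out_dir}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main(sys.argv[1:]))
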