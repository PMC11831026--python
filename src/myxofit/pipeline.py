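"""End-to-end orchestration: counts → estimates → fitness → tests → outcomes.

Every run serialises its configuration (plus a SHA-256 of the canonical
config JSON) into ``summary.json`` alongside the tabular artifacts, so any
output bundle is traceable to exactly one configuration.  Re-running with
identical config and inputs rewrites identical content.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, model_validator

from . import cfu, fitness, inference, io, synthetic

ARTIFACTS = (
    "estimates.csv",
    "fitness.csv",
    "anova.csv",
    "tests.csv",
    "outcomes.csv",
    "summary.json",
)

VERDICT_SYMBOLS = {
    "+": "+",
    "-": "-",
    "reduced-but-present": "(+)",
    "antagonized": "x",
}
GRID_LEGEND = (
    "+ cheating/exploitation; - none; (+) present but reduced vs H/H; x antagonized"
)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


class RunConfig(BaseModel):
    """One pipeline run: either a counts CSV + design file, or a preset simulation."""

    counts: Optional[str] = None
    design: Optional[str] = None
    preset: Optional[str] = None
    noise_mode: str = "full"
    seed: int = 0
    alpha: float = inference.DEFAULT_ALPHA
    log_base: float = 10.0
    holm_family: str = "per-pair"
    out_dir: str = "results/run"

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if (self.counts is None) == (self.preset is None):
            raise ValueError("exactly one of counts/preset must be given")
        if self.counts is not None and self.design is None:
            raise ValueError("a design file is required with a counts file")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        return self

    def sha256(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def load_run_config(path: str | Path) -> RunConfig:
    import yaml

    data = yaml.safe_load(Path(path).read_text())
    return RunConfig.model_validate(data)


def render_outcome_grid(outcomes: pd.DataFrame) -> str:
    """Markdown grid of pairs × history cells with the qualitative verdicts."""
    if outcomes is None or len(outcomes) == 0:
        return "(no outcomes to report)"
    cells = [c for c in io.HISTORY_CELLS if c in set(outcomes["cell"])]
    header = "| pair | focal | stat | " + " | ".join(cells) + " |"
    sep = "|" + "---|" * (3 + len(cells))
    lines = [header, sep]
    for (pair_id, focal, stat), grp in outcomes.groupby(
        ["pair_id", "focal_strain", "statistic"], sort=True
    ):
        by_cell = {r.cell: VERDICT_SYMBOLS.get(r.verdict, "?") for r in grp.itertuples()}
        lines.append(
            f"| {pair_id} | {focal} | {stat} | "
            + " | ".join(by_cell.get(c, "") for c in cells)
            + " |"
        )
    lines.append("")
    lines.append(GRID_LEGEND)
    return "\n".join(lines)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the artifact bundle to ``config.out_dir``.

    Returns a summary dict (also written as ``summary.json``).  Stage
    failures are re-raised as :class:`PipelineError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    diagnostics: list[str] = []

    try:
        if config.preset is not None:
            scfg = synthetic.preset_paper_like(config.preset)
            scfg = scfg.model_copy(
                update={"noise_mode": config.noise_mode, "seed": config.seed}
            )
            counts, _gt = synthetic.generate_experiment(scfg)
            design = scfg.design
            counts = io.read_counts(counts)
            io.write_counts(counts, out / "counts.csv")
        else:
            design = io.load_design(config.design)
            counts = io.read_counts(config.counts)
        report = io.validate_design(counts, design)
        if not report.complete:
            diagnostics.append(report.summary())
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("counts_io", exc) from exc

    try:
        estimates = cfu.estimate_samples(counts, design)
        estimates.to_csv(out / "estimates.csv", index=False)
    except Exception as exc:
        raise PipelineError("cfu_estimation", exc) from exc

    try:
        fit, fit_diag = fitness.build_fitness_table(estimates, design, config.log_base)
        diagnostics.extend(fit_diag)
        fit.to_csv(out / "fitness.csv", index=False)
    except Exception as exc:
        raise PipelineError("fitness_metrics", exc) from exc

    try:
        results = inference.analyze_experiment(
            fit, design, alpha=config.alpha, holm_family=config.holm_family
        )
        results["anova"].to_csv(out / "anova.csv", index=False)
        results["tests"].to_csv(out / "tests.csv", index=False)
        results["outcomes"].to_csv(out / "outcomes.csv", index=False)
    except Exception as exc:
        raise PipelineError("inference", exc) from exc

    grid = render_outcome_grid(results["outcomes"])
    summary = {
        "config": config.model_dump(),
        "config_sha256": config.sha256(),
        "artifacts": [a for a in ARTIFACTS if a != "summary.json"],
        "n_estimates": int(len(estimates)),
        "n_fitness_records": int(len(fit)),
        "diagnostics": diagnostics,
        "outcome_grid": grid,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str) + "\n")
    return summary
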