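"""Synthetic developmental-competition experiments with known ground truth.

The generator emulates the structure of the wet-lab assays: pure cultures of
every strain under both nutrient histories plus every pair × history-cell
mix, each replicated, harvested, diluted and plated on selective and
non-selective agar.  The latent model is deliberately minimal:

    log10 D (strain, spot) = base_log10_D[strain][history]
                             + interaction delta (mixes only)
                             + Normal(0, sigma_rep)            [replicate noise]
    spores = initial cells × 10^latent
    plate counts ~ Poisson(spores × plated_fraction)           per dilution

Interaction deltas act additively on the focal strain's log10 efficiency, so
the true statistics are linear in them: W is the difference of the two mix
latents and C_i(j) is exactly strain i's delta.  ``expectation`` mode turns
off both noise sources and emits exact (real-valued) expected counts, giving
closed-form oracles for end-to-end pipeline identity; ``full`` mode is the
stochastic study condition.  Plates whose sampled count exceeds the
countability cap are recorded as uncountable lawns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .cfu import estimate_samples, initial_cells
from .fitness import build_fitness_table
from .inference import analyze_experiment
from .io import (
    HISTORIES,
    HISTORY_CELLS,
    NO_SELECTION,
    PURE_PAIR_ID,
    SCHEMA_COLUMNS,
    DesignConfig,
    MixDesign,
)


class PlatingScheme(BaseModel):
    """Dilution series and volume bookkeeping shared by all samples."""

    # half-log series plated in duplicate: always 4-6 countable plates per sample
    dilutions: list[float] = Field(
        default_factory=lambda: [10**-e for e in (2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0, 5.5, 6.0)]
    )
    plates_per_dilution: int = 2
    volume_ml: float = 0.1
    harvest_volume_ml: float = 1.0
    countable_max: float = 400.0  # colonies above this are an uncountable lawn

    @model_validator(mode="after")
    def _check(self) -> "PlatingScheme":
        if not self.dilutions or any(d <= 0 or d > 1 for d in self.dilutions):
            raise ValueError("dilutions must be fractions in (0, 1]")
        if self.plates_per_dilution < 1:
            raise ValueError("plates_per_dilution must be >= 1")
        if self.volume_ml <= 0 or self.harvest_volume_ml <= 0:
            raise ValueError("volumes must be positive")
        return self

    @property
    def plated_fractions(self) -> list[float]:
        return [d * self.volume_ml / self.harvest_volume_ml for d in self.dilutions]


class InteractionDelta(BaseModel):
    """Additive shift on the focal strain's log10 efficiency in one mix cell."""

    focal: str
    partner: str
    history_focal: str
    history_partner: str
    delta: float


class SyntheticConfig(BaseModel):
    """Complete specification of one simulated experiment."""

    design: DesignConfig
    base_log10_D: dict[str, dict[str, float]]
    interactions: list[InteractionDelta] = Field(default_factory=list)
    sigma_rep: float = 0.2
    plating: PlatingScheme = Field(default_factory=PlatingScheme)
    seed: int = 0
    noise_mode: Literal["full", "expectation"] = "full"

    @model_validator(mode="after")
    def _check(self) -> "SyntheticConfig":
        for strain in self.design.strains:
            hist = self.base_log10_D.get(strain)
            if hist is None or set(hist) != set(HISTORIES):
                raise ValueError(f"base_log10_D must give H and L values for {strain!r}")
        if self.sigma_rep < 0:
            raise ValueError("sigma_rep must be >= 0")
        for d in self.interactions:
            if d.focal not in self.design.strains or d.partner not in self.design.strains:
                raise ValueError(f"interaction references unknown strain: {d}")
        return self

    def delta(self, focal: str, partner: str, hf: str, hp: str) -> float:
        for d in self.interactions:
            if (d.focal, d.partner, d.history_focal, d.history_partner) == (
                focal,
                partner,
                hf,
                hp,
            ):
                return d.delta
        return 0.0


@dataclass(frozen=True)
class GroundTruth:
    """Closed-form true values implied by a config (no sampling involved).

    Keys use the focal strain's own history first in the cell label, so they
    align directly with the pipeline's fitness rows.
    """

    w: dict[tuple[str, str, str], float] = field(default_factory=dict)
    c: dict[tuple[str, str, str], float] = field(default_factory=dict)
    spores_mix: dict[tuple[str, str, str], float] = field(default_factory=dict)
    spores_pure: dict[tuple[str, str], float] = field(default_factory=dict)


def ground_truth(config: SyntheticConfig) -> GroundTruth:
    """Noise-free W, C and spore totals implied by the latent model."""
    design = config.design
    gt = GroundTruth()
    for strain in sorted(design.strains):
        for hist in HISTORIES:
            gt.spores_pure[(strain, hist)] = (
                design.initial_cells_total * 10 ** config.base_log10_D[strain][hist]
            )
    for pair in design.pairs:
        a, b = pair.strains
        for cell in HISTORY_CELLS:
            hf, _, hp = cell.partition("/")
            la = config.base_log10_D[a][hf] + config.delta(a, b, hf, hp)
            lb = config.base_log10_D[b][hp] + config.delta(b, a, hp, hf)
            rev = f"{hp}/{hf}"
            gt.w[(pair.pair_id, a, cell)] = la - lb
            gt.w[(pair.pair_id, b, rev)] = lb - la
            gt.c[(pair.pair_id, a, cell)] = config.delta(a, b, hf, hp)
            gt.c[(pair.pair_id, b, rev)] = config.delta(b, a, hp, hf)
            gt.spores_mix[(pair.pair_id, a, cell)] = (
                initial_cells(design, a, pair.pair_id) * 10**la
            )
            gt.spores_mix[(pair.pair_id, b, cell)] = (
                initial_cells(design, b, pair.pair_id) * 10**lb
            )
    return gt


def _emit_series(
    rows: list[dict],
    meta: dict,
    selection: str,
    spores: float,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> None:
    plating = config.plating
    lams = [spores * pf for pf in plating.plated_fractions]
    if config.noise_mode == "full" and all(l > plating.countable_max for l in lams):
        warnings.warn(
            f"sample {meta} ({selection}): every plate expects > countable_max colonies; "
            "dilution series too concentrated",
            stacklevel=3,
        )
    for dilution, lam in zip(plating.dilutions, lams):
      for _ in range(plating.plates_per_dilution):
        if config.noise_mode == "expectation":
            colonies, countable = float(lam), True
        else:
            count = int(rng.poisson(lam))
            countable = count <= plating.countable_max
            colonies = float(count) if countable else np.nan
        rows.append(
            {
                **meta,
                "selection": selection,
                "dilution": dilution,
                "volume_ml": plating.volume_ml,
                "harvest_volume_ml": plating.harvest_volume_ml,
                "colonies": colonies,
                "countable": countable,
            }
        )


def generate_experiment(
    config: SyntheticConfig, seed: Optional[int] = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one complete experiment in the canonical counts schema.

    Iteration order is fixed (sorted strains/pairs, cells, replicates), so a
    given (config, seed) reproduces the table byte-for-byte.
    """
    design = config.design
    rng = np.random.default_rng(config.seed if seed is None else seed)
    full = config.noise_mode == "full"
    rows: list[dict] = []

    for strain in sorted(design.strains):
        for hist in HISTORIES:
            for rep in range(1, design.n_replicates + 1):
                latent = config.base_log10_D[strain][hist]
                if full:
                    latent += rng.normal(0.0, config.sigma_rep)
                spores = design.initial_cells_total * 10**latent
                meta = {
                    "pair_id": PURE_PAIR_ID,
                    "focal_strain": strain,
                    "partner_strain": "",
                    "history_focal": hist,
                    "history_partner": "",
                    "replicate": rep,
                }
                _emit_series(rows, meta, NO_SELECTION, spores, config, rng)

    for pair in sorted(design.pairs, key=lambda p: p.pair_id):
        a, b = pair.strains
        for cell in HISTORY_CELLS:
            hf, _, hp = cell.partition("/")
            for rep in range(1, design.n_replicates + 1):
                la = config.base_log10_D[a][hf] + config.delta(a, b, hf, hp)
                lb = config.base_log10_D[b][hp] + config.delta(b, a, hp, hf)
                if full:
                    la += rng.normal(0.0, config.sigma_rep)
                    lb += rng.normal(0.0, config.sigma_rep)
                spores_a = initial_cells(design, a, pair.pair_id) * 10**la
                spores_b = initial_cells(design, b, pair.pair_id) * 10**lb
                meta = {
                    "pair_id": pair.pair_id,
                    "focal_strain": a,
                    "partner_strain": b,
                    "history_focal": hf,
                    "history_partner": hp,
                    "replicate": rep,
                }
                _emit_series(rows, meta, NO_SELECTION, spores_a + spores_b, config, rng)
                for strain, marker in sorted(pair.markers.items()):
                    spores = spores_a if strain == a else spores_b
                    _emit_series(rows, meta, marker, spores, config, rng)

    counts = pd.DataFrame(rows, columns=SCHEMA_COLUMNS)
    return counts, ground_truth(config)


def _cheater_interactions(cheater: str, w_by_cell: dict[str, float], wt: str = "WT"):
    """Deltas giving the cheater the target W in each cell (WT latent fixed at base)."""
    out = []
    for cell, w in w_by_cell.items():
        hf, _, hp = cell.partition("/")
        # latent_ch = W + latent_WT; delta = latent_ch - base_ch with base_ch = -6, WT = -2
        out.append(
            InteractionDelta(
                focal=cheater, partner=wt, history_focal=hf, history_partner=hp, delta=w + 4.0
            )
        )
    return out


def preset_paper_like(scenario: str) -> SyntheticConfig:
    """Documented configs reproducing the study's qualitative structure.

    ``cheater_pairs``: two obligate defectors mixed 1:9 with a cooperator.
    Ch1 cheats only while the cooperator has a high-nutrient history (H/H and
    L/H cells); Ch2 cheats everywhere except L/L, with its L/H cell positive
    but reduced relative to H/H.  Cheater pure-culture efficiency (1e-6)
    puts clonal spore counts near the detection floor.  Effect sizes keep
    mix efficiencies below 1 and the cooperator a substantial share of total
    spores, so its by-subtraction estimate stays well conditioned — as in
    the wet assays, where W of order 1 leaves both strains countable.

    ``natural_isolates``: three proficient strains mixed 1:1 with a
    dominance hierarchy; strain G is suppressed below 0.01% of total spores
    in every mix, D exploits G only under H/H, and I exploits G in three of
    the four history cells.
    """
    if scenario == "cheater_pairs":
        design = DesignConfig(
            strains={"WT": "cooperator", "Ch1": "defector", "Ch2": "defector"},
            pairs=[
                MixDesign(
                    pair_id="Ch1:WT",
                    strain_a="Ch1",
                    strain_b="WT",
                    ratio=(1, 9),
                    markers={"Ch1": "rifampicin"},
                    subtraction_strain="WT",
                ),
                MixDesign(
                    pair_id="Ch2:WT",
                    strain_a="Ch2",
                    strain_b="WT",
                    ratio=(1, 9),
                    markers={"Ch2": "rifampicin"},
                    subtraction_strain="WT",
                ),
            ],
        )
        interactions = _cheater_interactions(
            "Ch1", {"H/H": 1.1, "H/L": -1.2, "L/H": 1.1, "L/L": -1.2}
        ) + _cheater_interactions(
            "Ch2", {"H/H": 1.1, "H/L": 1.05, "L/H": 1.0, "L/L": -1.2}
        )
        return SyntheticConfig(
            design=design,
            base_log10_D={
                "WT": {"H": -2.0, "L": -2.0},
                "Ch1": {"H": -6.0, "L": -6.0},
                "Ch2": {"H": -6.0, "L": -6.0},
            },
            interactions=interactions,
        )
    if scenario == "natural_isolates":
        design = DesignConfig(
            strains={"D": "isolate", "I": "isolate", "G": "isolate"},
            pairs=[
                MixDesign(
                    pair_id="D:G",
                    strain_a="D",
                    strain_b="G",
                    markers={"D": "kanamycin", "G": "novobiocin"},
                ),
                MixDesign(
                    pair_id="D:I",
                    strain_a="D",
                    strain_b="I",
                    markers={"D": "kanamycin"},
                    subtraction_strain="I",
                ),
                MixDesign(
                    pair_id="I:G",
                    strain_a="I",
                    strain_b="G",
                    markers={"G": "novobiocin"},
                    subtraction_strain="I",
                ),
            ],
        )

        def deltas(focal: str, partner: str, by_cell: dict[str, float]):
            return [
                InteractionDelta(
                    focal=focal,
                    partner=partner,
                    history_focal=cell[0],
                    history_partner=cell[2],
                    delta=v,
                )
                for cell, v in by_cell.items()
            ]

        suppressed = {"H/H": -4.5, "H/L": -4.5, "L/H": -4.5, "L/L": -4.5}
        interactions = (
            deltas("G", "D", suppressed)
            + deltas("G", "I", suppressed)
            + deltas("D", "G", {"H/H": 0.6, "H/L": -0.1, "L/H": -0.1, "L/L": -0.4})
            + deltas("D", "I", {"H/H": 0.2, "H/L": -0.2, "L/H": -0.2, "L/L": -0.3})
            + deltas("I", "D", {"H/H": -0.1, "H/L": -0.2, "L/H": -0.8, "L/L": -0.2})
            + deltas("I", "G", {"H/H": 0.5, "H/L": 0.5, "L/H": 0.1, "L/L": 0.5})
        )
        return SyntheticConfig(
            design=design,
            base_log10_D={
                "D": {"H": -2.0, "L": -2.0},
                "I": {"H": -1.5, "L": -1.5},
                "G": {"H": -2.0, "L": -2.0},
            },
            interactions=interactions,
        )
    raise ValueError(f"unknown scenario {scenario!r}")


@dataclass
class RecoveryReport:
    """Bias/RMSE of recovered statistics and empirical call rates per cell."""

    n_sims: int
    per_cell: pd.DataFrame

    def to_text(self) -> str:
        lines = [f"parameter recovery over {self.n_sims} simulated experiment(s)"]
        for row in self.per_cell.itertuples(index=False):
            lines.append(
                f"{row.pair_id} {row.focal_strain} {row.statistic} {row.cell}: "
                f"truth {row.truth:+.3f}, mean est {row.mean_estimate:+.3f}, "
                f"bias {row.bias:+.4f}, rmse {row.rmse:.4f}, '+' rate {row.plus_rate:.3f}"
            )
        return "\n".join(lines)


def parameter_recovery_report(
    config: SyntheticConfig, n_sims: int, seed: int = 0
) -> RecoveryReport:
    """Generate → full pipeline ``n_sims`` times; compare with ground truth.

    Per (pair, focal, statistic, cell): bias and RMSE of the cross-replicate
    mean estimate vs truth, and the fraction of runs in which the cell was
    called "+" (significantly positive, Holm-corrected) — empirical power
    under a true effect, empirical type-I error under a null.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rng = np.random.default_rng(seed)
    gt = ground_truth(config)
    estimates: dict[tuple, list[float]] = {}
    plus: dict[tuple, int] = {}
    stat_col = {"W": "W_ij", "C": "C_i_of_j"}
    for _ in range(n_sims):
        child = int(rng.integers(0, 2**31 - 1))
        counts, _ = generate_experiment(config, seed=child)
        fit, _diag = build_fitness_table(estimate_samples(counts, config.design), config.design)
        res = analyze_experiment(fit, config.design, with_anova=False)
        for row in res["outcomes"].itertuples(index=False):
            key = (row.pair_id, row.focal_strain, row.statistic, row.cell)
            plus[key] = plus.get(key, 0) + (
                1 if row.verdict in ("+", "reduced-but-present") else 0
            )
        means = fit.groupby(["pair_id", "strain_i", "cell"])[["W_ij", "C_i_of_j"]].mean()
        for key in plus:
            pair_id, focal, stat, cell = key
            est = float(means.loc[(pair_id, focal, cell), stat_col[stat]])
            estimates.setdefault(key, []).append(est)
    rows = []
    for key in sorted(plus):
        pair_id, focal, stat, cell = key
        truth_map = gt.w if stat == "W" else gt.c
        truth = truth_map[(pair_id, focal, cell)]
        est = np.asarray(estimates[key], dtype=float)
        rows.append(
            {
                "pair_id": pair_id,
                "focal_strain": focal,
                "statistic": stat,
                "cell": cell,
                "truth": truth,
                "mean_estimate": float(est.mean()),
                "bias": float(est.mean() - truth),
                "rmse": float(np.sqrt(np.mean((est - truth) ** 2))),
                "plus_rate": plus[key] / n_sims,
            }
        )
    return RecoveryReport(n_sims=n_sims, per_cell=pd.DataFrame(rows))
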