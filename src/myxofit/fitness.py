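"""Sporulation-efficiency, relative-fitness and mixing-effect statistics.

For a strain *i* that enters development with ``N_i(t0)`` viable cells and
leaves it with ``N_i(t5)`` viable spores, the sporulation efficiency is
``D_i = N_i(t5) / N_i(t0)`` (pure culture) or ``D_i(j)`` (in a mix with *j*).

Two strains co-developing in one spot are compared by the log-ratio relative
fitness

    W_ij = log10(N_i(t5) / N_i(t0)) − log10(N_j(t5) / N_j(t0)),

positive when the focal strain converts its cells into spores proportionally
better than its partner.  The effect of being mixed at all is the mixing
effect

    C_i(j) = log(D_i(j)) − log(D_i),

positive when strain *i* sporulates proportionally better with *j* than
alone (the signature of social exploitation), negative when it is
antagonized.  The logarithm base for C defaults to 10 for consistency with
W; every sign-based conclusion is base-invariant.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd

from .cfu import initial_cells
from .io import PURE_PAIR_ID, DesignConfig

FITNESS_COLUMNS = [
    "pair_id",
    "replicate",
    "strain_i",
    "strain_j",
    "history_i",
    "history_j",
    "cell",
    "spores_i",
    "spores_j",
    "D_i_pure",
    "D_i_mix",
    "W_ij",
    "C_i_of_j",
    "lod_any",
    "pure_ref_fallback",
]


def sporulation_efficiency(spores: float, initial: float) -> float:
    """Fraction of initial viable cells recovered as viable spores."""
    if spores <= 0 or initial <= 0:
        raise ValueError("spores and initial cells must be positive")
    return spores / initial


def relative_fitness(
    spores_i: float, init_i: float, spores_j: float, init_j: float
) -> float:
    """W_ij: difference of log10 per-capita spore yields of two mixed strains."""
    if min(spores_i, init_i, spores_j, init_j) <= 0:
        raise ValueError("all spore and initial-cell quantities must be positive")
    return math.log10(spores_i / init_i) - math.log10(spores_j / init_j)


def mixing_effect(d_mix: float, d_pure: float, log_base: float = 10.0) -> float:
    """C_i(j): log of the mix-to-pure sporulation-efficiency ratio."""
    if d_mix <= 0 or d_pure <= 0:
        raise ValueError("efficiencies must be positive")
    if log_base <= 1:
        raise ValueError("log_base must exceed 1")
    return math.log(d_mix / d_pure, log_base)


def _pure_reference(
    pure: pd.DataFrame, strain: str, history: str, replicate: int
) -> Optional[tuple[float, bool, bool]]:
    """(pure spores, lod flag, mean-fallback flag) for a strain/history/replicate.

    Prefers the same-replicate pure culture (the replicates were temporally
    separate experiments); falls back to the geometric mean across available
    replicates, flagged.  Returns None when no pure culture exists at all.
    """
    sel = pure[(pure["strain"] == strain) & (pure["history_focal"] == history)]
    if sel.empty:
        return None
    same = sel[sel["replicate"] == replicate]
    if not same.empty:
        row = same.iloc[0]
        return float(row["spores_total"]), bool(row["lod_imputed"]), False
    spores = float(10 ** np.log10(sel["spores_total"].to_numpy()).mean())
    return spores, bool(sel["lod_imputed"].any()), True


def build_fitness_table(
    estimates: pd.DataFrame,
    design: DesignConfig,
    log_base: float = 10.0,
) -> tuple[pd.DataFrame, list[str]]:
    """Assemble per-replicate fitness records from per-strain spore estimates.

    Emits one row per ordered focal strain per mixed spot (so both partners'
    mixing effects are first-class; the two W values of a spot are exact
    negations of each other).  The pure-culture reference for C matches the
    focal strain's nutrient history in the mix.  Returns the table plus
    row-level diagnostics for spots that had to be skipped.
    """
    mix = estimates[estimates["pair_id"] != PURE_PAIR_ID]
    pure = estimates[estimates["pair_id"] == PURE_PAIR_ID]
    rows: list[dict] = []
    diagnostics: list[str] = []
    spot_cols = ["pair_id", "history_focal", "history_partner", "replicate"]
    for (pair_id, hf, hp, rep), grp in mix.groupby(spot_cols, sort=True):
        pair = design.pair(pair_id)
        by_strain = {r["strain"]: r for _, r in grp.iterrows()}
        missing = [s for s in pair.strains if s not in by_strain]
        if missing:
            diagnostics.append(
                f"spot ({pair_id}, {hf}/{hp}, rep {rep}): no estimate for {missing}; skipped"
            )
            continue
        hist = {pair.strain_a: hf, pair.strain_b: hp}
        ordered = [(pair.strain_a, pair.strain_b), (pair.strain_b, pair.strain_a)]
        for focal, partner in ordered:
            rf, rp = by_strain[focal], by_strain[partner]
            init_f = initial_cells(design, focal, pair_id)
            init_p = initial_cells(design, partner, pair_id)
            ref = _pure_reference(pure, focal, hist[focal], int(rep))
            if ref is None:
                diagnostics.append(
                    f"spot ({pair_id}, {hf}/{hp}, rep {rep}): no pure-culture reference for "
                    f"{focal} under history {hist[focal]}; record skipped"
                )
                continue
            pure_spores, pure_lod, fallback = ref
            d_pure = sporulation_efficiency(pure_spores, design.initial_cells_total)
            d_mix = sporulation_efficiency(float(rf["spores_total"]), init_f)
            rows.append(
                {
                    "pair_id": pair_id,
                    "replicate": int(rep),
                    "strain_i": focal,
                    "strain_j": partner,
                    "history_i": hist[focal],
                    "history_j": hist[partner],
                    "cell": f"{hist[focal]}/{hist[partner]}",
                    "spores_i": float(rf["spores_total"]),
                    "spores_j": float(rp["spores_total"]),
                    "D_i_pure": d_pure,
                    "D_i_mix": d_mix,
                    "W_ij": relative_fitness(
                        float(rf["spores_total"]), init_f, float(rp["spores_total"]), init_p
                    ),
                    "C_i_of_j": mixing_effect(d_mix, d_pure, log_base),
                    "lod_any": bool(
                        rf["lod_imputed"]
                        or rp["lod_imputed"]
                        or rf["subtraction_clamped"]
                        or rp["subtraction_clamped"]
                        or pure_lod
                    ),
                    "pure_ref_fallback": fallback,
                }
            )
    return pd.DataFrame(rows, columns=FITNESS_COLUMNS), diagnostics
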