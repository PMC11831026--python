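"""Spore-total estimation from dilution-plate colony counts.

Counts from several dilutions of the same harvested spot are pooled with the
Poisson maximum-likelihood estimator N̂ = Σ colonies / Σ plated_fraction
(each plate's count is Poisson with mean N × plated_fraction, so the summed
count is Poisson with mean N × Σ fractions).  Samples in which every
countable plate shows zero colonies are assigned 0.9 spores — the
limit-of-detection substitute — rather than zero, so downstream log-ratio
statistics stay finite.  Mixed samples are deconvolved through selective
markers: directly marked strains take their marker-plate estimate and the
one unmarked strain is obtained by subtracting marker counts from the
non-selective total, clamped at the same 0.9-spore floor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io import (
    NO_SELECTION,
    PURE_PAIR_ID,
    SPOT_COLUMNS,
    DesignConfig,
    MixDesign,
)

#: Spores assigned when zero colonies are observed at the limit of detection.
LOD_SPORES = 0.9


class EstimationError(ValueError):
    """A sample cannot be estimated (e.g. no countable plates)."""


class ConfigurationError(ValueError):
    """Counts reference a selection marker absent from the design."""


@dataclass(frozen=True)
class SampleEstimate:
    """Estimated viable spores for one strain in one harvested spot."""

    spores_total: float
    lod_imputed: bool
    detection_floor: float
    n_plates: int = 0
    subtraction_clamped: bool = False

    def __post_init__(self):
        if self.spores_total < LOD_SPORES:
            raise ValueError("spores_total below the 0.9-spore detection substitute")


def pool_dilutions(
    colonies: Sequence[float],
    plated_fraction: Sequence[float],
    countable: Optional[Sequence[bool]] = None,
) -> SampleEstimate:
    """Pool plates of one sample + selection into a single spore estimate.

    Parameters are parallel per-plate arrays.  Uncountable plates (lawns)
    are excluded; at least one countable plate is required.  Zero total
    colonies trigger the 0.9-spore imputation with ``lod_imputed`` set.
    ``detection_floor`` is the spore count corresponding to one colony on
    the most concentrated countable plate.
    """
    colonies = np.asarray(colonies, dtype=float)
    fractions = np.asarray(plated_fraction, dtype=float)
    mask = (
        np.ones(len(colonies), dtype=bool)
        if countable is None
        else np.asarray(countable, dtype=bool)
    )
    if colonies.shape != fractions.shape or colonies.shape != mask.shape:
        raise ValueError("colonies, plated_fraction and countable must be parallel")
    if not mask.any():
        raise EstimationError("no countable plates for this sample")
    c = colonies[mask]
    f = fractions[mask]
    if np.any(np.isnan(c)) or np.any(c < 0):
        raise ValueError("countable plates must carry non-negative colony counts")
    if np.any(f <= 0) or np.any(f > 1):
        raise ValueError("plated fractions must lie in (0, 1]")
    floor = 1.0 / f.max()
    total = float(c.sum())
    if total == 0.0:
        return SampleEstimate(LOD_SPORES, True, floor, n_plates=int(mask.sum()))
    return SampleEstimate(
        max(total / float(f.sum()), LOD_SPORES), False, floor, n_plates=int(mask.sum())
    )


def deconvolve_mix(
    total: Optional[SampleEstimate],
    marked: Mapping[str, SampleEstimate],
    design: MixDesign,
) -> dict[str, SampleEstimate]:
    """Split a mixed-spot estimate into per-strain estimates via selective markers.

    Directly marked strains pass their marker-plate estimate through.  The
    by-subtraction strain (if the pair has one) receives
    ``max(total − Σ marked, 0.9)``; when the clamp fires, the result is
    flagged both ``subtraction_clamped`` and ``lod_imputed``.
    """
    for strain in marked:
        if strain not in design.markers:
            raise ConfigurationError(
                f"marker estimate for strain {strain!r} not declared in pair {design.pair_id}"
            )
    out: dict[str, SampleEstimate] = {}
    for strain in design.markers:
        if strain in marked:
            out[strain] = marked[strain]
    sub = design.subtraction_strain
    if sub is not None:
        if total is None:
            raise EstimationError(
                f"pair {design.pair_id}: non-selective total required to estimate {sub!r} by subtraction"
            )
        missing = [s for s in design.markers if s not in marked]
        if missing:
            raise EstimationError(
                f"pair {design.pair_id}: marker estimate(s) missing for {missing}; "
                f"cannot estimate {sub!r} by subtraction"
            )
        remainder = total.spores_total - sum(m.spores_total for m in marked.values())
        clamped = remainder < LOD_SPORES
        out[sub] = SampleEstimate(
            spores_total=max(remainder, LOD_SPORES),
            lod_imputed=clamped,
            detection_floor=total.detection_floor,
            n_plates=total.n_plates,
            subtraction_clamped=clamped,
        )
    return out


def initial_cells(design: DesignConfig, strain: str, pair_id: Optional[str] = None) -> float:
    """Viable cells of ``strain`` deposited at t0 in one developmental spot.

    Pure culture (``pair_id`` None or ``"pure"``): spot volume × density.
    Mixes: that total split by the pair's mixing ratio.
    """
    total = design.initial_cells_total
    if pair_id is None or pair_id == PURE_PAIR_ID:
        if strain not in design.strains:
            raise KeyError(f"strain {strain!r} not in design")
        return total
    pair = design.pair(pair_id)
    return total * pair.fraction_of(strain)


ESTIMATE_COLUMNS = SPOT_COLUMNS + [
    "strain",
    "spores_total",
    "initial_cells",
    "lod_imputed",
    "subtraction_clamped",
    "detection_floor",
]


def estimate_samples(counts: pd.DataFrame, design: DesignConfig) -> pd.DataFrame:
    """Turn a validated counts table into per-(spot, strain) spore estimates.

    Each spot's plates are grouped by selection and pooled; mixed spots are
    then deconvolved per the pair's counting scheme.  Returns one row per
    strain per spot (``ESTIMATE_COLUMNS``).
    """
    if "plated_fraction" not in counts.columns:
        counts = counts.assign(
            plated_fraction=counts["dilution"]
            * counts["volume_ml"]
            / counts["harvest_volume_ml"]
        )
    rows: list[dict] = []
    for key, spot in counts.groupby(SPOT_COLUMNS, sort=True):
        meta = dict(zip(SPOT_COLUMNS, key))
        by_sel = {
            sel: pool_dilutions(
                grp["colonies"].to_numpy(),
                grp["plated_fraction"].to_numpy(),
                grp["countable"].to_numpy(),
            )
            for sel, grp in spot.groupby("selection")
        }
        if meta["pair_id"] == PURE_PAIR_ID:
            est = by_sel.get(NO_SELECTION)
            if est is None:
                if len(by_sel) != 1:
                    raise EstimationError(
                        f"pure spot {key}: ambiguous selections {sorted(by_sel)}"
                    )
                est = next(iter(by_sel.values()))
            per_strain = {meta["focal_strain"]: est}
        else:
            pair = design.pair(meta["pair_id"])
            marker_to_strain = {m: s for s, m in pair.markers.items()}
            unknown = set(by_sel) - set(marker_to_strain) - {NO_SELECTION}
            if unknown:
                raise ConfigurationError(
                    f"spot {key}: selection(s) {sorted(unknown)} not declared for pair {pair.pair_id}"
                )
            marked = {
                marker_to_strain[sel]: est
                for sel, est in by_sel.items()
                if sel != NO_SELECTION
            }
            per_strain = deconvolve_mix(by_sel.get(NO_SELECTION), marked, pair)
        for strain, est in per_strain.items():
            rows.append(
                {
                    **meta,
                    "strain": strain,
                    "spores_total": est.spores_total,
                    "initial_cells": initial_cells(design, strain, meta["pair_id"]),
                    "lod_imputed": est.lod_imputed,
                    "subtraction_clamped": est.subtraction_clamped,
                    "detection_floor": est.detection_floor,
                }
            )
    return pd.DataFrame(rows, columns=ESTIMATE_COLUMNS)
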