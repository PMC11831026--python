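"""Tabular data model for dilution-plate counts from developmental sporulation assays.

The canonical input is a long-format CSV with one agar plate per row.  Each
plate belongs to one harvested developmental spot, identified by the strain
pair (or ``"pure"`` for single-genotype controls), the nutrient history of
each partner (``H`` = high, ``L`` = low Casitone during pre-starvation
growth), and the replicate.  The ``selection`` column names the antibiotic in
the agar (``none`` for non-selective plates); dilution and volume bookkeeping
is converted on read to a single ``plated_fraction`` — the fraction of the
harvested spore sample represented on the plate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

PURE_PAIR_ID = "pure"
NO_SELECTION = "none"
HISTORIES = ("H", "L")
#: The four nutrient-history cells of a mixed spot, focal strain's history first.
HISTORY_CELLS = ("H/H", "H/L", "L/H", "L/L")

SCHEMA_COLUMNS = [
    "pair_id",
    "focal_strain",
    "partner_strain",
    "history_focal",
    "history_partner",
    "replicate",
    "selection",
    "dilution",
    "volume_ml",
    "harvest_volume_ml",
    "colonies",
    "countable",
]

#: Columns that identify one harvested developmental spot.
SPOT_COLUMNS = [
    "pair_id",
    "focal_strain",
    "partner_strain",
    "history_focal",
    "history_partner",
    "replicate",
]


class SchemaError(ValueError):
    """The input table does not conform to the documented column schema."""


class CountsValidationError(ValueError):
    """One or more rows failed validation; ``diagnostics`` lists each offence."""

    def __init__(self, diagnostics: list[str]):
        self.diagnostics = list(diagnostics)
        super().__init__(
            f"{len(self.diagnostics)} invalid row(s): " + "; ".join(self.diagnostics[:5])
            + ("; ..." if len(self.diagnostics) > 5 else "")
        )


@dataclass(frozen=True)
class TreatmentKey:
    """Identity of one developmental spot: pair, per-partner history, replicate."""

    pair_id: str
    focal_strain: str
    partner_strain: Optional[str]
    history_focal: str
    history_partner: Optional[str]
    replicate: int

    def __post_init__(self):
        if (self.partner_strain is None) != (self.history_partner is None):
            raise ValueError(
                "partner_strain and history_partner must both be set (mix) or both absent (pure)"
            )
        if self.history_focal not in HISTORIES:
            raise ValueError(f"history_focal must be one of {HISTORIES}")
        if self.history_partner is not None and self.history_partner not in HISTORIES:
            raise ValueError(f"history_partner must be one of {HISTORIES}")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")

    @property
    def is_pure(self) -> bool:
        return self.partner_strain is None

    @property
    def cell(self) -> str:
        """History cell label, focal first (e.g. ``"H/L"``); bare history for pure spots."""
        if self.is_pure:
            return self.history_focal
        return f"{self.history_focal}/{self.history_partner}"


@dataclass(frozen=True)
class PlateObservation:
    """One agar plate: what was plated and how many colonies grew."""

    treatment: TreatmentKey
    selection: str
    plated_fraction: float
    colonies: Optional[float]
    countable: bool = True

    def __post_init__(self):
        if not (0.0 < self.plated_fraction <= 1.0):
            raise ValueError("plated_fraction must lie in (0, 1]")
        if self.countable and (self.colonies is None or self.colonies < 0):
            raise ValueError("countable plates need a non-negative colony count")


class MixDesign(BaseModel):
    """How one strain pair was mixed and how each strain is counted.

    ``markers`` maps strain label -> antibiotic used to count it directly;
    at most one strain per pair may instead be counted by subtracting the
    summed marker counts from the non-selective total.
    """

    pair_id: str
    strain_a: str
    strain_b: str
    ratio: tuple[int, int] = (1, 1)
    markers: dict[str, str] = Field(default_factory=dict)
    subtraction_strain: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "MixDesign":
        strains = {self.strain_a, self.strain_b}
        if len(strains) != 2:
            raise ValueError(f"pair {self.pair_id}: strains must be distinct")
        if any(r <= 0 for r in self.ratio):
            raise ValueError(f"pair {self.pair_id}: ratio parts must be positive")
        unknown = set(self.markers) - strains
        if unknown:
            raise ValueError(f"pair {self.pair_id}: markers for unknown strains {sorted(unknown)}")
        if self.subtraction_strain is not None:
            if self.subtraction_strain not in strains:
                raise ValueError(f"pair {self.pair_id}: subtraction strain not in pair")
            if self.subtraction_strain in self.markers:
                raise ValueError(f"pair {self.pair_id}: subtraction strain cannot also carry a marker")
        uncounted = strains - set(self.markers) - {self.subtraction_strain}
        if uncounted:
            raise ValueError(
                f"pair {self.pair_id}: strains {sorted(uncounted)} neither marked nor by-subtraction"
            )
        return self

    @property
    def strains(self) -> tuple[str, str]:
        return (self.strain_a, self.strain_b)

    def fraction_of(self, strain: str) -> float:
        """The strain's share of the initial mixed population."""
        total = sum(self.ratio)
        if strain == self.strain_a:
            return self.ratio[0] / total
        if strain == self.strain_b:
            return self.ratio[1] / total
        raise KeyError(f"strain {strain!r} not in pair {self.pair_id}")


class DesignConfig(BaseModel):
    """Full experimental design: strains, pairs, densities, replication."""

    strains: dict[str, str]  # label -> role: cooperator | defector | isolate
    pairs: list[MixDesign] = Field(default_factory=list)
    density_cells_per_ml: float = 5e9
    spot_volume_ml: float = 0.1
    n_replicates: int = 4

    @model_validator(mode="after")
    def _check(self) -> "DesignConfig":
        for p in self.pairs:
            for s in p.strains:
                if s not in self.strains:
                    raise ValueError(f"pair {p.pair_id} references unknown strain {s!r}")
        if self.density_cells_per_ml <= 0 or self.spot_volume_ml <= 0:
            raise ValueError("density and spot volume must be positive")
        return self

    @property
    def initial_cells_total(self) -> float:
        """Viable cells deposited per developmental spot."""
        return self.density_cells_per_ml * self.spot_volume_ml

    def pair(self, pair_id: str) -> MixDesign:
        for p in self.pairs:
            if p.pair_id == pair_id:
                return p
        raise KeyError(f"no pair {pair_id!r} in design")


def load_design(source: str | Path | dict) -> DesignConfig:
    """Load a design config from YAML/JSON file or an in-memory mapping."""
    if isinstance(source, dict):
        return DesignConfig.model_validate(source)
    path = Path(source)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return DesignConfig.model_validate(data)


def compute_plated_fraction(dilution: float, volume_ml: float, harvest_volume_ml: float) -> float:
    """Fraction of the harvested sample represented on one plate.

    ``volume_ml`` of a ``dilution``-fold-diluted aliquot (dilution expressed
    as a fraction, e.g. 1e-4) from a spot harvested into ``harvest_volume_ml``.
    """
    if dilution <= 0 or dilution > 1:
        raise ValueError("dilution must be a fraction in (0, 1]")
    if volume_ml <= 0 or harvest_volume_ml <= 0:
        raise ValueError("volumes must be positive")
    return dilution * volume_ml / harvest_volume_ml


def read_counts(source: str | Path | pd.DataFrame) -> pd.DataFrame:
    """Read and validate a plate-count table; returns it with ``plated_fraction`` added.

    Raises :class:`SchemaError` for missing columns and
    :class:`CountsValidationError` with per-row diagnostics for invalid rows.
    Pure-culture rows leave ``partner_strain``/``history_partner`` empty.
    Duplicate (treatment, selection, dilution) rows are legitimate (multiple
    plates) and retained.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source)
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    df = df[SCHEMA_COLUMNS].copy()
    for col in ("partner_strain", "history_partner"):
        df[col] = df[col].fillna("").astype(str).replace("nan", "")
    for col in ("pair_id", "focal_strain", "history_focal", "selection"):
        df[col] = df[col].astype(str)
    df["countable"] = df["countable"].astype(bool)

    diagnostics: list[str] = []

    def flag(mask, message):
        for idx in df.index[mask]:
            diagnostics.append(f"row {idx}: {message}")

    flag(~df["history_focal"].isin(HISTORIES), "history_focal must be H or L")
    flag(
        (df["partner_strain"] != "") & ~df["history_partner"].isin(HISTORIES),
        "history_partner must be H or L for mixed spots",
    )
    flag(
        (df["partner_strain"] == "") != (df["history_partner"] == ""),
        "partner_strain and history_partner must be jointly present or absent",
    )
    flag((df["partner_strain"] == "") & (df["pair_id"] != PURE_PAIR_ID),
         f"pure-culture rows must use pair_id {PURE_PAIR_ID!r}")
    flag(df["replicate"].astype(float) < 1, "replicate must be >= 1")
    flag((df["dilution"] <= 0) | (df["dilution"] > 1), "dilution must be a fraction in (0, 1]")
    flag(df["volume_ml"] <= 0, "volume_ml must be positive")
    flag(df["harvest_volume_ml"] <= 0, "harvest_volume_ml must be positive")
    flag(df["countable"] & df["colonies"].isna(), "countable plate lacks a colony count")
    flag(df["countable"] & (df["colonies"] < 0), "colonies must be non-negative")
    if diagnostics:
        raise CountsValidationError(diagnostics)

    df["replicate"] = df["replicate"].astype(int)
    df["plated_fraction"] = df["dilution"] * df["volume_ml"] / df["harvest_volume_ml"]
    bad_pf = ~((df["plated_fraction"] > 0) & (df["plated_fraction"] <= 1))
    if bad_pf.any():
        raise CountsValidationError(
            [f"row {i}: plated_fraction outside (0, 1]" for i in df.index[bad_pf]]
        )
    return df


def write_counts(df: pd.DataFrame, path: str | Path) -> None:
    """Write the canonical plate-count columns to CSV (UTF-8, header row)."""
    df[SCHEMA_COLUMNS].to_csv(path, index=False)


def to_observations(df: pd.DataFrame) -> list[PlateObservation]:
    """Typed view of a validated counts table."""
    out = []
    for row in df.itertuples(index=False):
        key = TreatmentKey(
            pair_id=row.pair_id,
            focal_strain=row.focal_strain,
            partner_strain=row.partner_strain or None,
            history_focal=row.history_focal,
            history_partner=row.history_partner or None,
            replicate=int(row.replicate),
        )
        out.append(
            PlateObservation(
                treatment=key,
                selection=row.selection,
                plated_fraction=float(row.plated_fraction)
                if "plated_fraction" in df.columns
                else compute_plated_fraction(row.dilution, row.volume_ml, row.harvest_volume_ml),
                colonies=None if pd.isna(row.colonies) else float(row.colonies),
                countable=bool(row.countable),
            )
        )
    return out


@dataclass
class DesignReport:
    """Completeness report of an observed design against the expected factorial."""

    missing_cells: list[tuple[str, str]] = field(default_factory=list)
    replicate_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    missing_pure: list[tuple[str, str]] = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return not self.missing_cells and not self.missing_pure

    def summary(self) -> str:
        lines = ["design complete" if self.complete else "design incomplete"]
        for pair_id, cell in self.missing_cells:
            lines.append(f"missing mix cell: pair {pair_id}, histories {cell}")
        for strain, hist in self.missing_pure:
            lines.append(
                f"missing pure culture: strain {strain}, history {hist} "
                f"(C_i(j) uncomputable for this strain/history)"
            )
        return "\n".join(lines)


def validate_design(counts: pd.DataFrame, design: DesignConfig) -> DesignReport:
    """Check a counts table against the expected full-factorial design.

    Reports missing (pair × history-cell) mixes, replicate counts per cell,
    and strains lacking the pure-culture control that their mixing-effect
    statistic requires under a matching nutrient history.  Reporting only —
    downstream stages decide what to refuse.
    """
    report = DesignReport()
    mix = counts[counts["pair_id"] != PURE_PAIR_ID]
    pure = counts[counts["pair_id"] == PURE_PAIR_ID]
    observed_cells = {
        (pid, f"{hf}/{hp}"): reps["replicate"].nunique()
        for (pid, hf, hp), reps in mix.groupby(["pair_id", "history_focal", "history_partner"])
    }
    pure_present = set(zip(pure["focal_strain"], pure["history_focal"]))

    needed_pure: set[tuple[str, str]] = set()
    for pair in design.pairs:
        for cell in HISTORY_CELLS:
            hf, _, hp = cell.partition("/")
            key = (pair.pair_id, cell)
            if key in observed_cells:
                report.replicate_counts[key] = observed_cells[key]
            else:
                report.missing_cells.append(key)
            needed_pure.add((pair.strain_a, hf))
            needed_pure.add((pair.strain_b, hp))
    report.missing_pure = sorted(needed_pure - pure_present)
    return report
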