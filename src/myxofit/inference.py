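"""Hypothesis-testing protocol for fitness and mixing-effect statistics.

Two questions are asked of every (strain pair, focal strain, statistic)
family, mirroring how competition assays of this design are analysed:

a) Did exploitation/cheating occur — is the statistic different from zero in
   each nutrient-history cell?  (two-sided one-sample t per cell, Holm
   step-down correction over the family's four cells)
b) Does nutrient history affect the interaction — do cells differ from each
   other (Tukey HSD) or from the standard-condition H/H reference (Dunnett)?

A full-factorial Gaussian ANOVA (cheater genotype × focal history × partner
history for defector pairs; history × history per focal strain for natural
isolate pairs) summarises the design-level effects.  Qualitative outcome
calls combine (a) and (b): "+" for a significantly positive statistic,
"antagonized" for significantly negative, "reduced-but-present" for cells
that are still "+" but significantly below the H/H reference.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

from .io import DesignConfig

DEFAULT_ALPHA = 0.05
REFERENCE_CELL = "H/H"


@dataclass(frozen=True)
class TestResult:
    """One test: a cell vs zero, a pairwise contrast, or an ANOVA term."""

    family: str
    scope: str
    method: str
    statistic: float
    df: float
    mean: float
    p_raw: float
    p_adjusted: float
    significant: bool
    degenerate: bool = False


@dataclass(frozen=True)
class OutcomeCall:
    """Qualitative verdict for one (pair, focal strain, history cell)."""

    pair_id: str
    focal_strain: str
    statistic: str  # "W" or "C"
    cell: str
    verdict: str  # "+", "-", "reduced-but-present", "antagonized"
    mean: float
    p_zero_raw: float
    p_zero_adjusted: float
    p_vs_reference: float  # NaN when no reference contrast was run


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, >= raw)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def test_vs_zero(
    groups: Mapping[str, Sequence[float]],
    alpha: float = DEFAULT_ALPHA,
    family: str = "",
) -> list[TestResult]:
    """Two-sided one-sample t vs zero per cell, Holm-corrected over the family.

    A zero-variance cell is degenerate: no t or p is defined, and its
    significance is decided by the exact sign of its constant value (four
    identical nonzero replicates leave no ambiguity; this is the
    expectation-mode path of the synthetic generator).  Degenerate cells
    enter the Holm ordering as p = 0 (nonzero mean) or p = 1 (zero mean).
    """
    labels = sorted(groups)
    stats_rows = []
    surrogate = []
    for label in labels:
        x = np.asarray(groups[label], dtype=float)
        if x.size < 2:
            raise ValueError(f"cell {label!r}: need >= 2 finite values")
        if not np.all(np.isfinite(x)):
            raise ValueError(f"cell {label!r}: non-finite values")
        mean = float(x.mean())
        if float(x.std(ddof=1)) == 0.0:
            stats_rows.append((label, np.nan, float(x.size - 1), mean, np.nan, True))
            surrogate.append(0.0 if mean != 0.0 else 1.0)
        else:
            t, p = stats.ttest_1samp(x, 0.0)
            stats_rows.append((label, float(t), float(x.size - 1), mean, float(p), False))
            surrogate.append(float(p))
    adjusted = holm_adjust(surrogate)
    out = []
    for (label, t, df, mean, p_raw, degenerate), p_adj in zip(stats_rows, adjusted):
        out.append(
            TestResult(
                family=family,
                scope=label,
                method="one-sample t (Holm)",
                statistic=t,
                df=df,
                mean=mean,
                p_raw=p_raw,
                p_adjusted=np.nan if degenerate else float(p_adj),
                significant=bool(p_adj < alpha),
                degenerate=degenerate,
            )
        )
    return out


def compare_histories(
    groups: Mapping[str, Sequence[float]],
    mode: str = "vs-reference",
    control: str = REFERENCE_CELL,
    alpha: float = DEFAULT_ALPHA,
    family: str = "",
) -> list[TestResult]:
    """Between-cell contrasts: Tukey HSD over all pairs or Dunnett vs a control.

    ``mean`` on each result is the difference of cell means (first-listed
    minus second-listed).  When every cell has zero within-cell variance
    (expectation-mode data) the contrasts are decided exactly by whether the
    constant means differ, reported as degenerate.
    """
    labels = sorted(groups)
    if len(labels) < 2:
        raise ValueError("need >= 2 cells to contrast")
    samples = {lab: np.asarray(groups[lab], dtype=float) for lab in labels}
    for lab, x in samples.items():
        if x.size < 2:
            raise ValueError(f"cell {lab!r}: need >= 2 values")
    if mode not in ("all-pairs", "vs-reference"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "vs-reference" and control not in samples:
        raise ValueError(f"reference cell {control!r} absent")

    degenerate = all(float(x.std(ddof=1)) == 0.0 for x in samples.values())

    def result(a: str, b: str, stat: float, p: float, method: str) -> TestResult:
        diff = float(samples[a].mean() - samples[b].mean())
        if degenerate:
            p_val = np.nan
            signif = diff != 0.0
        else:
            p_val = float(p)
            signif = bool(p < alpha)
        return TestResult(
            family=family,
            scope=f"{a} vs {b}",
            method=method,
            statistic=float(stat) if not degenerate else np.nan,
            df=float(sum(x.size for x in samples.values()) - len(samples)),
            mean=diff,
            p_raw=p_val,
            p_adjusted=p_val,  # Tukey/Dunnett p-values are family-adjusted
            significant=signif,
            degenerate=degenerate,
        )

    out: list[TestResult] = []
    if mode == "all-pairs":
        if degenerate:
            for i, a in enumerate(labels):
                for b in labels[i + 1 :]:
                    out.append(result(a, b, np.nan, np.nan, "Tukey HSD"))
        else:
            res = stats.tukey_hsd(*(samples[lab] for lab in labels))
            for i, a in enumerate(labels):
                for j in range(i + 1, len(labels)):
                    out.append(
                        result(a, labels[j], res.statistic[i, j], res.pvalue[i, j], "Tukey HSD")
                    )
    else:
        treatments = [lab for lab in labels if lab != control]
        if degenerate:
            for lab in treatments:
                out.append(result(lab, control, np.nan, np.nan, "Dunnett"))
        else:
            res = stats.dunnett(
                *(samples[lab] for lab in treatments), control=samples[control]
            )
            for lab, stat_val, p in zip(treatments, res.statistic, res.pvalue):
                out.append(result(lab, control, stat_val, p, "Dunnett"))
    return out


_TERM_LABELS_3WAY = {
    "strain_i": "cheater",
    "history_i": "nutrients[Ch]",
    "history_j": "nutrients[WT]",
}


def _decode_term(term: str, labels: Mapping[str, str]) -> str:
    parts = []
    for piece in term.split(":"):
        m = re.search(r"Q\('([^']+)'\)", piece)
        if m:
            name = m.group(1)
        elif piece.startswith("C(") and piece.endswith(")"):
            name = piece[2:-1].split(",")[0]
        else:
            name = piece
        parts.append(labels.get(name, name))
    return " × ".join(parts)


def factorial_anova(
    data: pd.DataFrame,
    response: str,
    factors: Sequence[str],
    labels: Optional[Mapping[str, str]] = None,
    typ: int = 2,
    family: str = "",
) -> pd.DataFrame:
    """Full-factorial Gaussian ANOVA (main effects + all interactions).

    Refuses to fit when any factor-level combination has no observations
    (the full-factorial model would be unidentifiable), naming the empty
    cells.  Returns a tidy table: term, df1, df2, sum_sq, F, p.  On balanced
    designs the sums-of-squares type is immaterial.
    """
    labels = dict(labels or {})
    if not np.all(np.isfinite(data[response].to_numpy(dtype=float))):
        raise ValueError("response contains non-finite values")
    levels = [sorted(data[f].unique()) for f in factors]
    sizes = data.groupby(list(factors)).size()
    expected = int(np.prod([len(l) for l in levels]))
    if len(sizes) < expected:
        observed = set(sizes.index if len(factors) > 1 else [(i,) for i in sizes.index])
        import itertools

        empty = [combo for combo in itertools.product(*levels) if combo not in observed]
        raise ValueError(f"empty design cell(s) {empty}: full-factorial fit refused")

    # Type III is only meaningful under sum-to-zero contrasts; with them, all
    # three SS types coincide on balanced designs
    coding = ", Sum" if typ == 3 else ""
    formula = f"Q('{response}') ~ " + "*".join(f"C(Q('{f}'){coding})" for f in factors)
    model = ols(formula, data=data).fit()
    table = anova_lm(model, typ=typ)
    resid_df = float(table.loc["Residual", "df"])
    resid_ms = float(table.loc["Residual", "sum_sq"]) / max(resid_df, 1.0)
    scale = float(np.var(data[response].to_numpy(dtype=float))) or 1.0
    rows = []
    for term, row in table.iterrows():
        if term in ("Residual", "Intercept"):
            continue
        f_val, p_val = float(row["F"]), float(row["PR(>F)"])
        if resid_ms <= 1e-12 * scale:  # expectation-mode data: exact cell means
            big = float(row["sum_sq"]) > 1e-12 * scale
            f_val, p_val = (np.inf, 0.0) if big else (0.0, 1.0)
        rows.append(
            {
                "family": family,
                "term": _decode_term(str(term), labels),
                "df1": float(row["df"]),
                "df2": resid_df,
                "sum_sq": float(row["sum_sq"]),
                "F": f_val,
                "p": p_val,
            }
        )
    rows.append(
        {
            "family": family,
            "term": "residual",
            "df1": resid_df,
            "df2": np.nan,
            "sum_sq": float(table.loc["Residual", "sum_sq"]),
            "F": np.nan,
            "p": np.nan,
        }
    )
    return pd.DataFrame(rows)


def classify_outcomes(
    zero_tests: Sequence[TestResult],
    reference_contrasts: Optional[Sequence[TestResult]] = None,
    pair_id: str = "",
    focal_strain: str = "",
    statistic: str = "",
    reference: str = REFERENCE_CELL,
) -> list[OutcomeCall]:
    """Turn per-cell tests into qualitative verdicts.

    "+" requires a significantly positive mean; "antagonized" a significantly
    negative one; everything else is "-".  A "+" cell whose Dunnett contrast
    shows a significant decrease vs the reference becomes
    "reduced-but-present".  Pure function of its inputs.
    """
    drop_by_cell: dict[str, bool] = {}
    p_ref: dict[str, float] = {}
    for c in reference_contrasts or []:
        cell = c.scope.split(" vs ")[0]
        drop_by_cell[cell] = bool(c.significant and c.mean < 0)
        p_ref[cell] = c.p_raw
    calls = []
    for t in zero_tests:
        if t.significant and t.mean > 0:
            verdict = "+"
            if t.scope != reference and drop_by_cell.get(t.scope, False):
                verdict = "reduced-but-present"
        elif t.significant and t.mean < 0:
            verdict = "antagonized"
        else:
            verdict = "-"
        calls.append(
            OutcomeCall(
                pair_id=pair_id,
                focal_strain=focal_strain,
                statistic=statistic,
                cell=t.scope,
                verdict=verdict,
                mean=t.mean,
                p_zero_raw=t.p_raw,
                p_zero_adjusted=t.p_adjusted,
                p_vs_reference=p_ref.get(t.scope, np.nan),
            )
        )
    return calls


def _families(fitness: pd.DataFrame, design: DesignConfig) -> list[tuple[str, str, str, str]]:
    """(pair_id, focal strain, statistic name, response column) per test family.

    Defector pairs are scored by the defector's relative fitness W; pairs of
    sporulation-proficient strains by each partner's mixing effect C.
    """
    fams = []
    for pair in design.pairs:
        if fitness[fitness["pair_id"] == pair.pair_id].empty:
            continue
        defectors = [s for s in pair.strains if design.strains.get(s) == "defector"]
        if defectors:
            for d in defectors:
                fams.append((pair.pair_id, d, "W", "W_ij"))
        else:
            for s in pair.strains:
                fams.append((pair.pair_id, s, "C", "C_i_of_j"))
    return fams


def analyze_experiment(
    fitness: pd.DataFrame,
    design: DesignConfig,
    alpha: float = DEFAULT_ALPHA,
    with_contrasts: bool = True,
    with_anova: bool = True,
    holm_family: str = "per-pair",
) -> dict[str, pd.DataFrame]:
    """Run the full testing protocol over a fitness table.

    ``holm_family`` controls the correction family for the zero-tests:
    "per-pair" (default: the four history cells of one pair/focal/statistic)
    or "global" (one Holm family across all such cells in the experiment).
    Returns tidy ``tests``, ``outcomes`` and ``anova`` tables.
    """
    if holm_family not in ("per-pair", "global"):
        raise ValueError(f"unknown holm_family {holm_family!r}")
    all_tests: list[TestResult] = []
    outcomes: list[OutcomeCall] = []
    per_family: list[tuple[tuple[str, str, str], list[TestResult], Optional[list[TestResult]]]] = []

    for pair_id, focal, stat_name, column in _families(fitness, design):
        sub = fitness[(fitness["pair_id"] == pair_id) & (fitness["strain_i"] == focal)]
        groups = {
            cell: grp[column].to_numpy()
            for cell, grp in sub.groupby("cell")
            if len(grp) >= 2
        }
        if not groups:
            continue
        fam_label = f"{pair_id}|{focal}|{stat_name}"
        zero = test_vs_zero(groups, alpha=alpha, family=fam_label)
        contrasts = None
        if with_contrasts and REFERENCE_CELL in groups and len(groups) >= 2:
            contrasts = compare_histories(
                groups, "vs-reference", control=REFERENCE_CELL, alpha=alpha, family=fam_label
            )
            all_tests.extend(contrasts)
        per_family.append(((pair_id, focal, stat_name), zero, contrasts))

    if holm_family == "global" and per_family:
        # re-adjust the zero-tests in one pooled Holm family
        flat = [t for _, zero, _ in per_family for t in zero]
        surrogate = [
            (0.0 if t.mean != 0 else 1.0) if t.degenerate else t.p_raw for t in flat
        ]
        adjusted = holm_adjust(surrogate)
        it = iter(adjusted)
        per_family = [
            (
                meta,
                [
                    dataclasses.replace(
                        t,
                        p_adjusted=np.nan if t.degenerate else float(p_adj),
                        significant=bool(p_adj < alpha),
                    )
                    for t, p_adj in zip(zero, [next(it) for _ in zero])
                ],
                contrasts,
            )
            for (meta, zero, contrasts) in per_family
        ]

    for (pair_id, focal, stat_name), zero, contrasts in per_family:
        all_tests.extend(zero)
        outcomes.extend(
            classify_outcomes(
                zero, contrasts, pair_id=pair_id, focal_strain=focal, statistic=stat_name
            )
        )

    anova_tables = []
    if with_anova:
        fams = _families(fitness, design)
        defector_fams = [f for f in fams if f[2] == "W"]
        isolate_fams = [f for f in fams if f[2] == "C"]
        if defector_fams:
            rows = pd.concat(
                [
                    fitness[(fitness["pair_id"] == p) & (fitness["strain_i"] == f)]
                    for p, f, _, _ in defector_fams
                ]
            )
            factors = (
                ["strain_i", "history_i", "history_j"]
                if rows["strain_i"].nunique() > 1
                else ["history_i", "history_j"]
            )
            anova_tables.append(
                factorial_anova(
                    rows, "W_ij", factors, labels=_TERM_LABELS_3WAY, family="cheater W_ij"
                )
            )
        for pair_id, focal, _, _ in isolate_fams:
            rows = fitness[(fitness["pair_id"] == pair_id) & (fitness["strain_i"] == focal)]
            anova_tables.append(
                factorial_anova(
                    rows,
                    "C_i_of_j",
                    ["history_i", "history_j"],
                    labels={
                        "history_i": f"nutrients[{focal}]",
                        "history_j": "nutrients[partner]",
                    },
                    family=f"{pair_id}|{focal}|C",
                )
            )

    tests_df = pd.DataFrame([dataclasses.asdict(t) for t in all_tests])
    outcomes_df = pd.DataFrame([dataclasses.asdict(o) for o in outcomes])
    anova_df = (
        pd.concat(anova_tables, ignore_index=True) if anova_tables else pd.DataFrame()
    )
    return {"tests": tests_df, "outcomes": outcomes_df, "anova": anova_df}
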