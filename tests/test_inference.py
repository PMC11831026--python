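"""Zero-tests, Holm, Tukey/Dunnett contrasts, factorial ANOVA, outcome calls."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import myxofit as mf
from myxofit.inference import TestResult as TResult


def brute_force_holm(p_values):
    """Closed-testing oracle: reject H_i iff every subset containing i passes
    its Bonferroni test; adjusted p_i = max over subsets S∋i of min_j |S|·p_j."""
    p = list(p_values)
    m = len(p)
    adjusted = []
    for i in range(m):
        worst = 0.0
        for r in range(1, m + 1):
            for subset in itertools.combinations(range(m), r):
                if i in subset:
                    local = min(len(subset) * p[j] for j in subset)
                    worst = max(worst, local)
        adjusted.append(min(worst, 1.0))
    return adjusted


class TestVsZero:
    def test_textbook_t_oracle(self):
        res = mf.test_vs_zero({"H/H": [0.8, 1.0, 1.2, 1.0]})
        (r,) = res
        # t = 1.0 / (sqrt(0.08/3)/2) = 12.2474..., df 3
        assert r.statistic == pytest.approx(12.2474, abs=1e-3)
        assert r.df == 3
        assert r.p_raw == pytest.approx(0.00117, abs=2e-5)
        assert r.significant

    def test_symmetric_values_give_t_zero(self):
        (r,) = mf.test_vs_zero({"c": [-1.0, 1.0, -1.0, 1.0]})
        assert r.statistic == 0.0
        assert r.p_raw == pytest.approx(1.0)
        assert not r.significant

    def test_holm_worked_example(self):
        # step-down by hand: 4*0.01, 3*0.02, then monotonicity caps the tail
        adj = mf.holm_adjust([0.01, 0.02, 0.20, 0.30])
        assert list(np.round(adj, 10)) == [0.04, 0.06, 0.40, 0.40]

    def test_degenerate_constant_cells(self):
        res = mf.test_vs_zero({"a": [0.5, 0.5, 0.5, 0.5], "b": [0.0, 0.0, 0.0, 0.0]})
        by = {r.scope: r for r in res}
        assert by["a"].degenerate and by["a"].significant and np.isnan(by["a"].p_raw)
        assert by["b"].degenerate and not by["b"].significant

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            mf.test_vs_zero({"a": [1.0]})

    @given(
        st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=6),
    )
    def test_holm_matches_closed_testing_enumeration(self, ps):
        adj = mf.holm_adjust(ps)
        oracle = brute_force_holm(ps)
        assert np.allclose(adj, oracle, atol=1e-12)

    def test_holm_monotone_and_at_least_raw(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=6)
        adj = mf.holm_adjust(p)
        assert np.all(adj >= p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestCompareHistories:
    def test_two_group_tukey_equals_pooled_t(self):
        a, b = [1.0, 1.3, 0.9, 1.1], [0.2, 0.5, 0.1, 0.4]
        (res,) = mf.compare_histories({"A": a, "B": b}, mode="all-pairs")
        t_p = stats.ttest_ind(a, b, equal_var=True).pvalue
        assert res.p_adjusted == pytest.approx(t_p, rel=1e-6)

    def test_separated_cell_significant_in_every_contrast(self):
        rng = np.random.default_rng(0)
        groups = {c: rng.normal(0, 1, 4) for c in ("H/H", "H/L", "L/H")}
        groups["L/L"] = rng.normal(10, 1, 4)
        res = mf.compare_histories(groups, mode="all-pairs")
        involving = [r for r in res if "L/L" in r.scope]
        assert all(r.significant for r in involving)

    def test_dunnett_reference_mode(self):
        rng = np.random.default_rng(1)
        groups = {
            "H/H": rng.normal(1.0, 0.2, 4),
            "H/L": rng.normal(1.0, 0.2, 4),
            "L/L": rng.normal(-2.0, 0.2, 4),
        }
        res = mf.compare_histories(groups, mode="vs-reference", control="H/H")
        by = {r.scope.split(" vs ")[0]: r for r in res}
        assert set(by) == {"H/L", "L/L"}
        assert by["L/L"].significant and by["L/L"].mean < 0
        assert not by["H/L"].significant

    def test_missing_reference_cell_is_error(self):
        with pytest.raises(ValueError, match="reference"):
            mf.compare_histories({"a": [1, 2], "b": [2, 3]}, mode="vs-reference", control="H/H")

    def test_degenerate_zero_variance_decided_by_means(self):
        res = mf.compare_histories(
            {"H/H": [1.0, 1.0], "H/L": [1.0, 1.0], "L/L": [0.5, 0.5]},
            mode="vs-reference",
            control="H/H",
        )
        by = {r.scope.split(" vs ")[0]: r for r in res}
        assert by["L/L"].significant and by["L/L"].degenerate
        assert not by["H/L"].significant


class TestFactorialAnova:
    @staticmethod
    def _synthetic(shift_wt=0.0, sigma=0.2, n=4, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for ch in ("Ch1", "Ch2"):
            for hi in ("H", "L"):
                for hj in ("H", "L"):
                    mu = 1.0 + (shift_wt if hj == "L" else 0.0)
                    for _ in range(n):
                        rows.append(
                            {
                                "strain_i": ch,
                                "history_i": hi,
                                "history_j": hj,
                                "W_ij": mu + rng.normal(0, sigma),
                            }
                        )
        return pd.DataFrame(rows)

    def test_balanced_design_ss_types_agree(self):
        df = self._synthetic(shift_wt=0.5, seed=2)
        tables = [
            mf.factorial_anova(df, "W_ij", ["strain_i", "history_i", "history_j"], typ=t)
            for t in (1, 2, 3)
        ]
        for other in tables[1:]:
            assert np.allclose(
                tables[0]["sum_sq"].to_numpy(), other["sum_sq"].to_numpy(), atol=1e-9
            )

    def test_partner_history_shift_detected(self):
        """A 1.0 log10 shift tied to partner history dominates at sigma 0.2, n 4."""
        df = self._synthetic(shift_wt=-1.0, seed=3)
        table = mf.factorial_anova(
            df,
            "W_ij",
            ["strain_i", "history_i", "history_j"],
            labels={"strain_i": "cheater", "history_i": "nutrients[Ch]", "history_j": "nutrients[WT]"},
        )
        by = {r.term: r for r in table.itertuples()}
        assert by["nutrients[WT]"].p < 1e-6
        assert by["nutrients[Ch]"].p > 0.01

    def test_empty_cell_refused_with_cell_named(self):
        df = self._synthetic()
        df = df[~((df.history_i == "L") & (df.history_j == "L"))]
        with pytest.raises(ValueError, match="empty design cell"):
            mf.factorial_anova(df, "W_ij", ["strain_i", "history_i", "history_j"])

    def test_term_structure_and_df(self):
        df = self._synthetic()
        table = mf.factorial_anova(df, "W_ij", ["strain_i", "history_i", "history_j"])
        terms = [t for t in table["term"] if t != "residual"]
        assert len(terms) == 7  # 3 mains, 3 two-way, 1 three-way
        assert (table[table.term != "residual"]["df1"] == 1.0).all()
        assert table[table.term != "residual"]["df2"].iloc[0] == 32 - 8


class TestClassifyOutcomes:
    @staticmethod
    def _zero(cell, mean, sig):
        return TResult("f", cell, "one-sample t (Holm)", 5.0, 3, mean, 0.01, 0.02, sig)

    @staticmethod
    def _contrast(cell, diff, sig):
        return TResult("f", f"{cell} vs H/H", "Dunnett", -3.0, 12, diff, 0.01, 0.01, sig)

    def test_all_positive_significant_without_reduction(self):
        zero = [self._zero(c, 1.0, True) for c in mf.HISTORY_CELLS]
        calls = mf.classify_outcomes(zero, [], pair_id="p", focal_strain="f", statistic="W")
        assert [c.verdict for c in calls] == ["+"] * 4

    def test_reduced_but_present_needs_plus_and_significant_drop(self):
        zero = [self._zero("H/H", 2.0, True), self._zero("L/H", 0.8, True)]
        contrasts = [self._contrast("L/H", -1.2, True)]
        calls = {c.cell: c.verdict for c in mf.classify_outcomes(zero, contrasts)}
        assert calls == {"H/H": "+", "L/H": "reduced-but-present"}

    def test_significantly_negative_is_antagonized(self):
        calls = mf.classify_outcomes([self._zero("L/L", -0.9, True)])
        assert calls[0].verdict == "antagonized"

    def test_non_significant_is_minus_even_if_positive(self):
        calls = mf.classify_outcomes([self._zero("H/L", 0.4, False)])
        assert calls[0].verdict == "-"

    def test_pure_function_of_inputs(self):
        zero = [self._zero("H/H", 1.0, True)]
        a = mf.classify_outcomes(zero, [], pair_id="p", focal_strain="s", statistic="W")
        b = mf.classify_outcomes(zero, [], pair_id="p", focal_strain="s", statistic="W")
        assert a == b


def test_analyze_experiment_emits_all_tables(cheater_cfg):
    counts, _ = mf.generate_experiment(cheater_cfg, seed=11)
    fit, _ = mf.build_fitness_table(
        mf.estimate_samples(mf.read_counts(counts), cheater_cfg.design), cheater_cfg.design
    )
    res = mf.analyze_experiment(fit, cheater_cfg.design)
    assert set(res) == {"tests", "outcomes", "anova"}
    assert set(res["outcomes"]["cell"]) == set(mf.HISTORY_CELLS)
    # cheater pairs analysed on W only, one family per cheater
    assert set(res["outcomes"].query("statistic == 'W'")["focal_strain"]) == {"Ch1", "Ch2"}
    assert (res["tests"]["p_adjusted"].dropna() >= res["tests"]["p_raw"].dropna() - 1e-12).all()


def test_global_holm_family_is_more_conservative(cheater_cfg):
    counts, _ = mf.generate_experiment(cheater_cfg, seed=12)
    fit, _ = mf.build_fitness_table(
        mf.estimate_samples(mf.read_counts(counts), cheater_cfg.design), cheater_cfg.design
    )
    per_pair = mf.analyze_experiment(fit, cheater_cfg.design, with_anova=False)
    global_ = mf.analyze_experiment(
        fit, cheater_cfg.design, with_anova=False, holm_family="global"
    )
    key = ["family", "scope"]
    a = per_pair["tests"].query("method == 'one-sample t (Holm)'").set_index(key)
    b = global_["tests"].query("method == 'one-sample t (Holm)'").set_index(key)
    joined = a.join(b, rsuffix="_g").dropna(subset=["p_adjusted", "p_adjusted_g"])
    assert (joined["p_adjusted_g"] >= joined["p_adjusted"] - 1e-12).all()
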