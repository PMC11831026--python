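"""CFU pooling, LOD imputation, mix deconvolution, initial-cell bookkeeping."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import myxofit as mf
from myxofit.cfu import ConfigurationError, EstimationError


class TestPoolDilutions:
    def test_single_plate_closed_form(self):
        est = mf.pool_dilutions([50], [1e-5])
        assert est.spores_total == pytest.approx(5e6, rel=1e-12)
        assert not est.lod_imputed
        assert est.detection_floor == pytest.approx(1e5)

    def test_pooled_mle_across_dilutions(self):
        est = mf.pool_dilutions([50, 5], [1e-5, 1e-6])
        assert est.spores_total == pytest.approx(55 / 1.1e-5, rel=1e-12)

    def test_all_zero_counts_imputed_at_lod(self):
        est = mf.pool_dilutions([0, 0, 0], [1e-3, 1e-4, 1e-5])
        assert est.spores_total == 0.9
        assert est.lod_imputed
        assert est.detection_floor == pytest.approx(1e3)

    def test_uncountable_plates_excluded(self):
        est = mf.pool_dilutions(
            [np.nan, 50], [1e-4, 1e-5], countable=[False, True]
        )
        assert est.spores_total == pytest.approx(5e6)
        assert est.n_plates == 1

    def test_no_countable_plates_is_error(self):
        with pytest.raises(EstimationError):
            mf.pool_dilutions([np.nan], [1e-4], countable=[False])

    @given(
        counts=st.lists(st.integers(0, 500), min_size=1, max_size=5),
        split=st.floats(0.1, 0.9),
    )
    def test_invariant_to_splitting_a_plate(self, counts, split):
        """Splitting one plate into two fictitious half-fraction plates changes nothing."""
        fractions = [1e-5] * len(counts)
        base = mf.pool_dilutions(counts, fractions)
        c0 = counts[0]
        split_counts = [int(c0 * split), c0 - int(c0 * split)] + counts[1:]
        split_fracs = [1e-5 * split, 1e-5 * (1 - split)] + fractions[1:]
        alt = mf.pool_dilutions(split_counts, split_fracs)
        assert alt.spores_total == pytest.approx(base.spores_total, rel=1e-9)

    def test_unbiased_in_poisson_simulation(self):
        """Brute-force oracle: mean of the estimator over Poisson draws hits truth."""
        rng = np.random.default_rng(42)
        n_true = 2.0e6
        fractions = np.array([1.5e-5, 1e-5])  # expected counts 30 and 20
        draws = rng.poisson(n_true * fractions, size=(2000, 2))
        estimates = draws.sum(axis=1) / fractions.sum()
        assert abs(estimates.mean() / n_true - 1) < 0.01


class TestDeconvolveMix:
    @pytest.fixture()
    def pair(self):
        return mf.MixDesign(
            pair_id="Ch:WT",
            strain_a="Ch",
            strain_b="WT",
            ratio=(1, 9),
            markers={"Ch": "rifampicin"},
            subtraction_strain="WT",
        )

    def _est(self, spores, floor=1e3):
        return mf.SampleEstimate(spores, False, floor, n_plates=2)

    def test_subtraction(self, pair):
        out = mf.deconvolve_mix(self._est(1e6), {"Ch": self._est(1e5)}, pair)
        assert out["Ch"].spores_total == pytest.approx(1e5)
        assert out["WT"].spores_total == pytest.approx(9e5, rel=1e-12)
        assert not out["WT"].subtraction_clamped

    def test_marked_exceeding_total_clamps_to_floor(self, pair):
        out = mf.deconvolve_mix(self._est(1e5), {"Ch": self._est(1.2e5)}, pair)
        assert out["WT"].spores_total == 0.9
        assert out["WT"].subtraction_clamped and out["WT"].lod_imputed

    def test_conservation_without_clamp(self, pair):
        out = mf.deconvolve_mix(self._est(7.7e6), {"Ch": self._est(2.2e6)}, pair)
        assert sum(e.spores_total for e in out.values()) == pytest.approx(7.7e6, rel=1e-12)

    def test_unknown_marker_strain_is_configuration_error(self, pair):
        with pytest.raises(ConfigurationError):
            mf.deconvolve_mix(self._est(1e6), {"Zed": self._est(1e5)}, pair)

    def test_missing_total_with_subtraction_strain_is_error(self, pair):
        with pytest.raises(EstimationError):
            mf.deconvolve_mix(None, {"Ch": self._est(1e5)}, pair)


class TestInitialCells:
    @pytest.fixture()
    def design(self):
        return mf.DesignConfig(
            strains={"WT": "cooperator", "Ch": "defector", "A": "isolate", "B": "isolate"},
            pairs=[
                mf.MixDesign(
                    pair_id="Ch:WT",
                    strain_a="Ch",
                    strain_b="WT",
                    ratio=(1, 9),
                    markers={"Ch": "rifampicin"},
                    subtraction_strain="WT",
                ),
                mf.MixDesign(
                    pair_id="A:B",
                    strain_a="A",
                    strain_b="B",
                    markers={"A": "kanamycin", "B": "novobiocin"},
                ),
            ],
        )

    def test_pure_culture_is_spot_volume_times_density(self, design):
        assert mf.initial_cells(design, "WT") == pytest.approx(5e8)

    def test_one_to_one_mix_splits_evenly(self, design):
        assert mf.initial_cells(design, "A", "A:B") == pytest.approx(2.5e8)
        assert mf.initial_cells(design, "B", "A:B") == pytest.approx(2.5e8)

    def test_one_to_nine_mix(self, design):
        assert mf.initial_cells(design, "Ch", "Ch:WT") == pytest.approx(5e7)
        assert mf.initial_cells(design, "WT", "Ch:WT") == pytest.approx(4.5e8)

    def test_unknown_strain_raises(self, design):
        with pytest.raises(KeyError):
            mf.initial_cells(design, "nope")


def test_estimate_samples_pure_and_mix(counts_frame):
    design = mf.DesignConfig(
        strains={"Ch": "defector", "WT": "cooperator"},
        pairs=[
            mf.MixDesign(
                pair_id="Ch:WT",
                strain_a="Ch",
                strain_b="WT",
                ratio=(1, 9),
                markers={"Ch": "rifampicin"},
                subtraction_strain="WT",
            )
        ],
    )
    mix_meta = dict(
        pair_id="Ch:WT",
        focal_strain="Ch",
        partner_strain="WT",
        history_partner="L",
    )
    counts = counts_frame(
        [
            {"focal_strain": "WT", "colonies": 50, "dilution": 1e-4},
            {**mix_meta, "selection": "none", "colonies": 100, "dilution": 1e-4},
            {**mix_meta, "selection": "rifampicin", "colonies": 10, "dilution": 1e-4},
        ]
    )
    est = mf.estimate_samples(mf.read_counts(counts), design)
    by = {(r.pair_id, r.strain): r for r in est.itertuples()}
    assert by[("pure", "WT")].spores_total == pytest.approx(5e6)
    assert by[("Ch:WT", "Ch")].spores_total == pytest.approx(1e6)
    assert by[("Ch:WT", "WT")].spores_total == pytest.approx(9e6)
    assert by[("Ch:WT", "WT")].initial_cells == pytest.approx(4.5e8)
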