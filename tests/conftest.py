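import hypothesis
import pandas as pd
import pytest

import myxofit as mf

hypothesis.settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=50
)
hypothesis.settings.load_profile("suite")


@pytest.fixture(scope="session")
def cheater_cfg() -> mf.SyntheticConfig:
    return mf.preset_paper_like("cheater_pairs")


@pytest.fixture(scope="session")
def isolates_cfg() -> mf.SyntheticConfig:
    return mf.preset_paper_like("natural_isolates")


@pytest.fixture(scope="session")
def null_pair_cfg() -> mf.SyntheticConfig:
    """Two equally proficient strains, no interaction effects: a true null."""
    design = mf.DesignConfig(
        strains={"X": "isolate", "Y": "isolate"},
        pairs=[
            mf.MixDesign(
                pair_id="X:Y",
                strain_a="X",
                strain_b="Y",
                markers={"X": "kanamycin"},
                subtraction_strain="Y",
            )
        ],
    )
    return mf.SyntheticConfig(
        design=design,
        base_log10_D={"X": {"H": -2.0, "L": -2.0}, "Y": {"H": -2.0, "L": -2.0}},
    )


def make_counts_row(
    pair_id="pure",
    focal_strain="WT",
    partner_strain="",
    history_focal="H",
    history_partner="",
    replicate=1,
    selection="none",
    dilution=1e-4,
    volume_ml=0.1,
    harvest_volume_ml=1.0,
    colonies=50,
    countable=True,
) -> dict:
    return dict(
        pair_id=pair_id,
        focal_strain=focal_strain,
        partner_strain=partner_strain,
        history_focal=history_focal,
        history_partner=history_partner,
        replicate=replicate,
        selection=selection,
        dilution=dilution,
        volume_ml=volume_ml,
        harvest_volume_ml=harvest_volume_ml,
        colonies=colonies,
        countable=countable,
    )


@pytest.fixture()
def counts_frame():
    def build(rows: list[dict]) -> pd.DataFrame:
        return pd.DataFrame([make_counts_row(**r) for r in rows])

    return build
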