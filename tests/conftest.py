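import pandas as pd
import pytest

from g2screen import hit_selection as hs
from g2screen import plate_normalization as pn
from g2screen import synthetic_data as sd


@pytest.fixture(scope="session")
def small_library() -> sd.ReagentLibrary:
    """60-gene library with every planted effect class."""
    return sd.generate_library(
        60,
        [
            sd.EffectAssignment("icrf_selective_abrogator", count=4),
            sd.EffectAssignment("icrf_selective_abrogator", count=1, n_on_target=1),
            sd.EffectAssignment("toxic", count=3),
            sd.EffectAssignment("mitotic_accumulator", count=2),
            sd.EffectAssignment("pan_checkpoint_abrogator", count=2),
        ],
        seed=7,
    )


@pytest.fixture(scope="session")
def small_campaign(small_library) -> pd.DataFrame:
    return sd.simulate_campaign(small_library, seed=7)


@pytest.fixture(scope="session")
def normalized_campaign(small_campaign):
    return pn.normalize_wells(small_campaign)


@pytest.fixture(scope="session")
def aggregated(normalized_campaign) -> pd.DataFrame:
    normalized, _ = normalized_campaign
    return pn.aggregate_genes(normalized)


@pytest.fixture(scope="session")
def duplex_campaign(small_library) -> pd.DataFrame:
    design = sd.PlateDesign(conditions=(sd.ICRF,), instruments=(sd.ARRAYSCAN,))
    return sd.simulate_campaign(small_library, design, seed=1007, reagents="duplexes")


@pytest.fixture(scope="session")
def hit_table(normalized_campaign, duplex_campaign) -> pd.DataFrame:
    normalized, _ = normalized_campaign
    dnorm, _ = pn.normalize_wells(duplex_campaign)
    return hs.analyze_campaign(normalized, dnorm)
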