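"""Shared fixtures: small simulated datasets reused across test modules."""

import warnings

import pytest

from droughtdemog.prep import build_analysis_table
from droughtdemog.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def capuchin_sim():
    """A small capuchin study with one severe drought year."""
    cfg = SimulationConfig(
        seed=42,
        n_years=12,
        n_mothers=25,
        drought_years={2011},
        tree_params={"n_trees": 80, "n_species": 12},
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def capuchin_pm(capuchin_sim):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_analysis_table(
            capuchin_sim.biography,
            capuchin_sim.tenures,
            capuchin_sim.fruit_daily,
            capuchin_sim.spei_monthly,
            "capuchin",
        )
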