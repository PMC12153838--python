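import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

from rapscore import (  # noqa: E402
    Cohort,
    SimulationConfig,
    Species,
    TrophyRecord,
    simulate_all,
)
from rapscore.registry import SideMeasurements  # noqa: E402


def make_record(
    trophy_id="T1",
    age=8,
    cohort=Cohort.TRCG,
    brow=(20.0, 21.0),
    beam=(70.0, 71.0),
    pedicle=None,
    marks=(),
    species=Species.DD,
):
    sides = []
    for i in range(2):
        kwargs = {"brow_tine_len": brow[i] if brow else None,
                  "main_beam_len": beam[i] if beam else None}
        if pedicle:
            kwargs["pedicle_D"], kwargs["pedicle_d"] = pedicle[i]
        sides.append(SideMeasurements(**kwargs))
    return TrophyRecord(
        trophy_id=trophy_id, species=species, age_years=age, cohort=cohort,
        left=sides[0], right=sides[1], harvest_age_years=age, marks=frozenset(marks),
    )


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=20260920)


@pytest.fixture(scope="session")
def study(sim_config):
    """One synthetic study at the default (paper-sized) conditions."""
    return simulate_all(sim_config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
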