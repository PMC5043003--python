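import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from cagestat.synthetic_data import make_panel_fixture
from cagestat.trial_model import DEFAULT_DESIGN, TrialDesign, cage_aggregate


@pytest.fixture(scope="session")
def design() -> TrialDesign:
    return DEFAULT_DESIGN


@pytest.fixture(scope="session")
def small_design() -> TrialDesign:
    """Reduced design for fast unit tests: 2 groups, 1 gender, 5 cages."""
    return TrialDesign(
        groups=("control", "33 % GMO"),
        genders=("male",),
        cages_per_group_per_gender=5,
        subsample_n=4,
    )


@pytest.fixture(scope="session")
def panel_cage_table(design) -> pd.DataFrame:
    """Cage-aggregated default synthetic null trial (shared across tests)."""
    return cage_aggregate(make_panel_fixture(seed=3), design)


@pytest.fixture()
def measurement_rows() -> pd.DataFrame:
    """Six well-formed per-animal records: one cage per group, two groups."""
    rows = [
        ("A1", "M-control-01", "male", "control", "WBC", 12, 4.0),
        ("A2", "M-control-01", "male", "control", "WBC", 12, 6.0),
        ("A3", "M-treat-01", "male", "33 % GMO", "WBC", 12, 5.5),
        ("A4", "M-treat-01", "male", "33 % GMO", "WBC", 12, 6.5),
        ("A1", "M-control-01", "male", "control", "RBC", 12, 8.1),
        ("A2", "M-control-01", "male", "control", "RBC", 12, 8.3),
    ]
    return pd.DataFrame(
        rows,
        columns=["animal_id", "cage_id", "gender", "group", "endpoint", "time", "value"],
    )
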