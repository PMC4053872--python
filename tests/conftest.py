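import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import greyscan as gs

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def hand_panel():
    """Two equal-population districts over two years, cases [[10,10],[10,30]]:
    the only high-rate window is {B} x {year 2} with O=30 against E=15."""
    return pd.DataFrame(
        [("A", 1, 1000, 10), ("A", 2, 1000, 10), ("B", 1, 1000, 10), ("B", 2, 1000, 30)],
        columns=["district", "year", "population", "admissions"],
    )


@pytest.fixture
def hand_district_info():
    return pd.DataFrame(
        [("A", 0.0, 0.0, 1), ("B", 10.0, 0.0, 1)],
        columns=["district", "x", "y", "hospitals"],
    )


@pytest.fixture(scope="session")
def null_panel_cylinders():
    """Scan windows of the default ten-district geometry (shared across
    calibration seeds: the geography does not vary with the seed)."""
    panel = gs.generate_panel(gs.null_config(seed=0), with_points=False)
    return gs.enumerate_cylinders(panel.district_info, panel.records)


#: Worked-example GM(1,1) validation rows for a ten-district application:
#: (label, s1, s2, printed c, printed p, printed degree).  The incidence-rate
#: fits (per 1,000) and the admission-count fits exercise the c = s2/s1
#: arithmetic at two very different scales.
GREY_VALIDATION_IR_ROWS = [
    ("Baoan", 0.2509, 0.0757, 0.301714, 1.0, "excellent"),
    ("Dapeng", 0.3704, 0.1053, 0.284287, 1.0, "excellent"),
    ("Futian", 0.4803, 0.1176, 0.244847, 1.0, "excellent"),
    ("Guangming", 0.2585, 0.059, 0.22824, 1.0, "excellent"),
    ("Longgang", 0.3451, 0.112, 0.324544, 1.0, "excellent"),
    ("Longhua", 0.0938, 0.0373, 0.397655, 0.8889, "good"),
    ("Luohu", 0.4903, 0.1273, 0.259637, 1.0, "excellent"),
    ("Nanshan", 0.3005, 0.1163, 0.387022, 0.8889, "good"),
    ("Pingshan", 0.1775, 0.0729, 0.410704, 0.8889, "good"),
    ("Yantian", 0.341, 0.0802, 0.235191, 1.0, "excellent"),
]

GREY_VALIDATION_ADMISSION_ROWS = [
    ("Baoan", 739.5386, 157.6849, 0.213221, 1.0, "excellent"),
    ("Dapeng", 51.1903, 12.7783, 0.249623, 1.0, "excellent"),
    ("Futian", 773.7296, 164.6242, 0.212767, 1.0, "excellent"),
    ("Guangming", 144.2794, 35.003, 0.242606, 1.0, "excellent"),
    ("Longgang", 762.7598, 168.6213, 0.221067, 1.0, "excellent"),
    ("Longhua", 182.3981, 37.1975, 0.203936, 1.0, "excellent"),
    ("Luohu", 492.6384, 112.5286, 0.22842, 1.0, "excellent"),
    ("Nanshan", 415.7689, 85.9678, 0.206768, 1.0, "excellent"),
    ("Pingshan", 81.8777, 17.2176, 0.210284, 1.0, "excellent"),
    ("Yantian", 73.9185, 16.0493, 0.217122, 1.0, "excellent"),
]
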