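from datetime import datetime, timezone

import pytest

from iaq.reference_tables import default_bundle
from iaq.weightage import default_weights


@pytest.fixture(scope="session")
def bundle():
    return default_bundle()


@pytest.fixture(scope="session")
def weights(bundle):
    return default_weights(bundle)


@pytest.fixture
def t0():
    return datetime(2021, 1, 4, 0, 0, tzinfo=timezone.utc)


# Published per-level weightage worksheets, frozen verbatim:
# (iaqi_level, representation, printed_weight) per pollutant, plus the
# printed final (arithmetic-mean) weightage.
PRINTED_WORKSHEETS = {
    "pm10": {
        "levels": [
            (50, 50, 1),
            (100, 150, 0.666666667),
            (150, 250, 0.6),
            (200, 350, 0.571428571),
            (300, 420, 0.714285714),
            (400, 500, 0.8),
            (500, 600, 0.833333333),
        ],
        "final": 0.740816327,
    },
    "co": {
        "levels": [
            (50, 5, 10),
            (100, 10, 10),
            (150, 35, 4.28571429),
            (200, 60, 3.33333333),
            (300, 90, 3.33333333),
            (400, 120, 3.33333333),
            (500, 150, 3.33333333),
        ],
        "final": 5.37414966,
    },
    "o3": {
        "levels": [
            (50, 160, 0.3125),
            (100, 200, 0.5),
            (150, 300, 0.5),
            (200, 400, 0.5),
            (300, 800, 0.375),
            (400, 1000, 0.4),
            (500, 1200, 0.416666667),
        ],
        "final": 0.429166667,
    },
    "pm25": {
        "levels": [
            (50, 35, 1.428571429),
            (100, 75, 1.333333333),
            (150, 115, 1.304347826),
            (200, 150, 1.333333333),
            (300, 250, 1.2),
            (400, 350, 1.142857143),
            (500, 500, 1),
        ],
        "final": 1.248920438,
    },
    "tvoc": {
        "levels": [
            (50, 100, 0.5),
            (100, 275, 0.363636364),
            (250, 425, 0.588235294),
            (400, 628, 0.636942675),
        ],
        "final": 0.522203583,
    },
    "co2": {
        "levels": [
            (50, 341, 0.146627566),
            (100, 747, 0.133868809),
            (150, 1305, 0.114942529),
            (200, 5400, 0.037037037),
            (300, 31500, 0.00952381),
            (400, 63000, 0.006349206),
        ],
        "final": 0.074724826,
    },
}
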