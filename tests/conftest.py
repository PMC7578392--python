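import numpy as np
import pytest

from prosentrain import SimConfig, simulate_cohort
from prosentrain.pipeline import DyadData, cohort_to_dyads


LONG_TEXTGRID = """File type = "ooTextFile"
Object class = "TextGrid"

xmin = 0
xmax = 2.5
tiers? <exists>
size = 2
item []:
    item [1]:
        class = "IntervalTier"
        name = "P1"
        xmin = 0
        xmax = 2.5
        intervals: size = 3
        intervals [1]:
            xmin = 0
            xmax = 1
            text = "hello"
        intervals [2]:
            xmin = 1
            xmax = 1.5
            text = ""
        intervals [3]:
            xmin = 1.5
            xmax = 2.5
            text = "again"
    item [2]:
        class = "IntervalTier"
        name = "P2"
        xmin = 0
        xmax = 2.5
        intervals: size = 2
        intervals [1]:
            xmin = 0
            xmax = 1.2
            text = "laughter"
        intervals [2]:
            xmin = 1.2
            xmax = 2.5
            text = "yes"
"""

SHORT_TEXTGRID = """File type = "ooTextFile"
Object class = "TextGrid"

0
2.5
<exists>
2
"IntervalTier"
"P1"
0
2.5
2
0
1
"hello"
1
2.5
""
"IntervalTier"
"P2"
0
2.5
1
0
2.5
"laughter"
"""


@pytest.fixture
def long_textgrid():
    return LONG_TEXTGRID


@pytest.fixture
def short_textgrid():
    return SHORT_TEXTGRID


@pytest.fixture(scope="session")
def small_config():
    """A fast cohort: 4 dyads per group, 4-minute conversations."""
    return SimConfig(n_per_group=4, duration=240.0, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_dyads(small_cohort):
    return cohort_to_dyads(small_cohort)
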