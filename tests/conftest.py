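from pathlib import Path

import pandas as pd
import pytest

from cns_screen.registry import compound_library, get_compound
from cns_screen.descriptors import compute_descriptors

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def library():
    return compound_library()


@pytest.fixture(scope="session")
def hr67():
    return get_compound("HR67")


@pytest.fixture(scope="session")
def hr67_descriptors(hr67):
    return compute_descriptors(hr67)


@pytest.fixture(scope="session")
def bbb_oracle():
    """Frozen table of hand-evaluated BBB-score components."""
    return pd.read_csv(DATA / "bbb_score_oracle.csv")


@pytest.fixture(scope="session")
def hr_screen_oracle():
    """Frozen HR candidate score table with independently evaluated flags."""
    return pd.read_csv(DATA / "hr_screen_oracle.csv", index_col="compound_id")
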