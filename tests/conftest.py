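import numpy as np
import pandas as pd
import pytest

from aromastat.datasets import SAMPLES, load_gco_table, load_important_compounds


def make_events(rows):
    """Event log from (panellist, sample, onset_ri, intensity) tuples."""
    return pd.DataFrame(
        [
            {
                "panellist": p,
                "sample": s,
                "onset_ri": float(ri),
                "descriptor": "odour",
                "intensity": int(i),
            }
            for p, s, ri, i in rows
        ]
    )


@pytest.fixture(scope="session")
def gco_table():
    return load_gco_table()


@pytest.fixture(scope="session")
def important_table():
    return load_important_compounds()


@pytest.fixture(scope="session")
def samples():
    return SAMPLES


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
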