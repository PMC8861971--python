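import numpy as np
import pandas as pd
import pytest

from tumorkit import ctdna


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def bait_table():
    """Small bait-candidate table spanning the eligibility boundaries."""
    return pd.DataFrame(
        {
            "variant_id": ["v1", "v2", "v3", "v4", "v5"],
            "tumor_vaf": [0.06, 0.05, 0.30, 0.20, 0.10],
            "normal_vaf": [0.01, 0.00, 0.02, 0.01, 0.00],
            "tumor_depth": [40, 100, 100, 30, 80],
            "normal_depth": [20, 50, 50, 40, 15],
        }
    )


def make_family(reads, umi="u1", window="w"):
    return ctdna.ReadFamily(umi=umi, site_window=window, reads=tuple(reads))
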