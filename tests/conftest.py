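import numpy as np
import pandas as pd
import pytest

from fracatten.containers import SOA_LEVELS
from fracatten.synthetic_data import simulate_study_ikis


@pytest.fixture(scope="session")
def balanced_design():
    """Small complete 8×2×3 behavioral design with persistent series."""
    return simulate_study_ikis(8, n=512, seed=42)


@pytest.fixture()
def alpha_long_table():
    """Deterministic long-format table for the 2×3 within ANOVA."""
    rng = np.random.default_rng(11)
    rows = []
    for i in range(9):
        subj_off = rng.normal(scale=0.5)
        for prod in ("MA", "MO"):
            for soa in SOA_LEVELS:
                val = 0.7 + 0.05 * (prod == "MA") + 0.04 * np.log2(soa / 0.8)
                rows.append((f"S{i}", prod, soa,
                             val + subj_off + rng.normal(scale=0.1)))
    return pd.DataFrame(rows, columns=["participant", "production", "soa", "value"])
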