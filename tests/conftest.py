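import numpy as np
import pytest

from relint import synthetic as syn


@pytest.fixture(scope="session")
def small_table():
    """Complete (no missingness) synthetic table, n=4000, with recodes."""
    cfg = syn.GeneratorConfig(n_records=4000, seed=42)
    return syn.recode_outcomes(syn.generate_table(cfg, missingness=False))


@pytest.fixture(scope="session")
def big_table():
    """n=50 000 table with missingness and recodes (margin checks)."""
    cfg = syn.GeneratorConfig(n_records=50_000, seed=7)
    return syn.recode_outcomes(syn.generate_table(cfg))


@pytest.fixture
def rng():
    return np.random.default_rng(20241005)
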