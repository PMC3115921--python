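import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from pairback import PairedTable

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def mortality_table() -> PairedTable:
    """The reconstructed hospital-mortality table: 60 matched pairs of septic
    patients with/without invasive fungal infection."""
    return PairedTable(a=10, b=8, c=20, d=22)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20110512)


def random_tables(rng: np.random.Generator, count: int, max_n: int = 400):
    """Random valid paired tables with both discordant cells >= 1 and b != c."""
    out = []
    while len(out) < count:
        n = int(rng.integers(4, max_n))
        cells = rng.multinomial(n, rng.dirichlet(np.ones(4)))
        a, b, c, d = (int(x) for x in cells)
        if b >= 1 and c >= 1 and b != c:
            out.append(PairedTable(a, b, c, d))
    return out


# hypothesis strategy: arbitrary valid table with informative discordant cells
tables_strategy = st.builds(
    PairedTable,
    a=st.integers(0, 200),
    b=st.integers(1, 200),
    c=st.integers(1, 200),
    d=st.integers(0, 200),
).filter(lambda t: t.b != t.c)
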