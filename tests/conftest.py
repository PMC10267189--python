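import numpy as np
import pandas as pd
import pytest

from foodwebedm.preprocess import AbundanceTable, TrophicAssignment


def make_table(values: np.ndarray, species, site="s1", temperature=None):
    """Build a seasonal AbundanceTable from a (time, species) array."""
    n = values.shape[0]
    years = np.repeat(np.arange(1, n // 4 + 2), 4)[:n]
    seasons = np.tile(["winter", "spring", "summer", "autumn"], n // 4 + 1)[:n]
    index = pd.MultiIndex.from_arrays(
        [[site] * n, years, seasons], names=["site", "year", "season"])
    data = pd.DataFrame(values, index=index, columns=list(species))
    if temperature is None:
        temperature = 10.0 + 5.0 * np.sin(np.arange(n))
    temp = pd.Series(np.asarray(temperature, dtype=float)[:n], index=index,
                     name="temperature_C")
    return AbundanceTable(data=data, temperature=temp)


@pytest.fixture
def small_table():
    rng = np.random.default_rng(42)
    values = rng.lognormal(0.0, 0.5, size=(24, 3))
    return make_table(values, ["P1", "H1", "C1"])


@pytest.fixture
def trophic():
    return TrophicAssignment(
        {"P1": "producer", "P2": "producer", "H1": "herbivore",
         "H2": "herbivore", "O1": "omnivore", "C1": "predator"})


@pytest.fixture
def logistic_series():
    x = np.empty(200)
    x[0] = 0.3
    for t in range(199):
        x[t + 1] = 3.8 * x[t] * (1.0 - x[t])
    return (x - x.mean()) / x.std(ddof=1)
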