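import numpy as np
import pandas as pd
import pytest

from teacat import CATECHINS, FACTORS, Dataset, GeneratorConfig, load_table1
from teacat.synth import generate_catechins, generate_meteo

ZERO_NOISE = {m: 0.0 for m in CATECHINS}


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def noise_free_dataset():
    """30 records, catechins exactly on the published equations."""
    ds = generate_meteo(GeneratorConfig(seed=11))
    return generate_catechins(ds, noise_sd=ZERO_NOISE, seed=12)


@pytest.fixture(scope="session")
def noisy_dataset():
    """30 records with the default (RMSEC x 10) noise."""
    ds = generate_meteo(GeneratorConfig(seed=21))
    return generate_catechins(ds, seed=22)


@pytest.fixture()
def small_frame():
    """Minimal hand-built two-record dataset frame."""
    rows = []
    for site, season, bump in (("GD", "spring", 0.0), ("BM", "summer", 1.0)):
        row = {"site": site, "season": season}
        row.update(
            {
                "rainfall": 5.0 + bump,
                "temp_avg": 20.0 + bump,
                "eat": 300.0 + bump,
                "temp_max": 30.0 + bump,
                "temp_min": 10.0 + bump,
                "humidity": 80.0 + bump,
                "ground_temp": 22.0 + bump,
                "irradiance": 5000.0 + bump,
            }
        )
        row.update({m: 1.0 + 0.1 * k + bump for k, m in enumerate(CATECHINS)})
        rows.append(row)
    return pd.DataFrame(rows)


def meteo_frame_at(x, n=1):
    """Dataset frame whose meteorological block repeats the vector x."""
    rows = []
    for i in range(n):
        row = {"site": f"S{i+1:02d}", "season": "spring"}
        row.update(dict(zip(FACTORS, x)))
        rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture()
def dataset_at_vector():
    def _make(x, n=1):
        return Dataset(meteo_frame_at(x, n), provenance="test vector")

    return _make
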