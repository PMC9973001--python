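import numpy as np
import pandas as pd
import pytest

from corepair.data_io import OtuTable
from corepair.synthetic import StudyDesign, default_structure, generate_study


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study (4 zones x 3 fields x 11 samples,
    200 OTUs, 10 planted between-group core pairs), shared across tests."""
    return generate_study(seed=20240101 % (2**31))


@pytest.fixture()
def small_table():
    """Deterministic 6-sample x 5-OTU relative-abundance table."""
    rng = np.random.default_rng(7)
    counts = rng.integers(1, 50, size=(6, 5)).astype(float)
    rel = counts / counts.sum(axis=1, keepdims=True)
    samples = [f"S{i}" for i in range(1, 7)]
    otus = ["arc_1", "bac_1", "bac_2", "fun_1", "alg_1"]
    taxonomy = {"arc_1": "archaea", "bac_1": "bacteria",
                "bac_2": "bacteria", "fun_1": "fungi", "alg_1": "algae"}
    return OtuTable(pd.DataFrame(rel, index=samples, columns=otus),
                    taxonomy)


@pytest.fixture()
def tiny_metadata():
    rows = []
    zones = ["midtemperate", "warm-temperate", "subtropical", "tropical"]
    k = 0
    for f in range(4):
        for s in range(3):
            rows.append({"sample_id": f"F{f}_S{s}", "field_id": f"F{f}",
                         "region_id": f"R{f}", "zone": zones[f],
                         "mat": 2.0 + 6.0 * f, "ph": 6.5, "doc": 130.0,
                         "cec": 15.0})
            k += 1
    return pd.DataFrame(rows)
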