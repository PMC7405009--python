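import numpy as np
import pandas as pd
import pytest

from nirchem import SpectraSet, default_truffle_config, generate
from nirchem.spectra_io import make_meta


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_set(rng):
    """A 6-spectrum (2 samples x 3 replicates) set on a 20-point axis."""
    w = np.linspace(4000.0, 9500.0, 20)
    X = rng.normal(0.5, 0.1, size=(6, 20))
    meta = make_meta(
        sample_ids=["A", "A", "A", "B", "B", "B"],
        species=["sp1"] * 3 + ["sp2"] * 3,
        origins=["Italy"] * 3 + ["unknown"] * 3,
        harvest_years=[2018] * 6,
        replicates=[1, 2, 3, 1, 2, 3],
    )
    return SpectraSet(wavenumbers=w, absorbance=X, meta=meta)


@pytest.fixture(scope="session")
def truffle_data():
    """One default synthetic study (75 samples x 3 replicates), shared."""
    return generate(default_truffle_config(seed=1))


# Accumulated confusion matrices as printed in the study's report tables.
TABLE5 = {
    "labels": ["T. indicum", "T. aestivum", "T. melanosporum"],
    "counts": [[1073, 1, 26], [3, 2897, 0], [1, 0, 999]],
}
TABLE7 = {
    "labels": ["Italian", "non-Italian"],
    "counts": [[1247, 153], [141, 459]],
}
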