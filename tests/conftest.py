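import numpy as np
import pandas as pd
import pytest

from trnaflux import load_published_ratios, simulate_all


@pytest.fixture(scope="session")
def published_ratios():
    return load_published_ratios()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def preset_dir(tmp_path_factory):
    """One default synthetic preset shared across tests."""
    outdir = tmp_path_factory.mktemp("preset")
    simulate_all(outdir=outdir, seed=7)
    return outdir


@pytest.fixture()
def random_counts(rng):
    """A random 20-row compartment count table."""
    names = [f"tRNA-Gly-GCC-{i + 1}-1" for i in range(20)]
    data = rng.integers(50, 5000, size=(20, 4))
    return pd.DataFrame(
        data,
        index=pd.Index(names, name="trna_id"),
        columns=[
            "nucleus_control",
            "cytoplasm_control",
            "nucleus_knockdown",
            "cytoplasm_knockdown",
        ],
    ).astype(float)
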