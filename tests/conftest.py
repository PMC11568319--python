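import numpy as np
import pytest

from meatmech import discovery, synthetic


@pytest.fixture(scope="session")
def reference_datasets():
    """Noiseless stand-in mean curves for all eight products, built from
    the published two-term models."""
    return {pid: synthetic.reference_dataset(pid) for pid in synthetic.PRODUCTS}


@pytest.fixture(scope="session")
def reference_sweeps(reference_datasets):
    """Full one-/two-term sweeps of the noiseless datasets (36 fits each)."""
    out = {}
    for pid, ds in reference_datasets.items():
        out[pid] = discovery.sweep_best_in_class(ds)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(20241115)
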