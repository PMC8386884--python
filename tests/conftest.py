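import numpy as np
import pytest

from cartrelax.ilt2d import InversionOptions, default_grid, invert
from cartrelax.synthetic import (
    RelaxationComponent,
    d1_components,
    default_scheme,
    simulate_ir_fidcpmg,
)


@pytest.fixture(scope="session")
def d1_dataset():
    """Noiseless two-pool FID-CPMG dataset at the full acquisition scheme."""
    return simulate_ir_fidcpmg(d1_components(), default_scheme())


@pytest.fixture(scope="session")
def d1_map(d1_dataset):
    """Default-grid inversion of the noiseless two-pool dataset (shared: ~4 s)."""
    return invert(d1_dataset, default_grid(), InversionOptions())


@pytest.fixture
def small_scheme():
    """Reduced acquisition scheme for fast inversion tests."""
    return default_scheme(n_recovery=16, n_echoes=200, fid_spacing=4.0)


@pytest.fixture
def single_component():
    return [RelaxationComponent(T1=100.0, T2=10.0, amplitude=1.0)]
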