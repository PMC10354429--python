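import numpy as np
import pytest
from hypothesis import settings

from evmp.align import make_record

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from evmp.simulate import LibrarySpec, generate_library


@pytest.fixture(scope="session")
def small_library():
    """120-variant noiseless library with a recoverable additive ground
    truth (shared across tests; treat as read-only)."""
    lib, truth = generate_library(
        LibrarySpec(n_variants=120, seed=7, noise_sigma=0.0))
    return lib, truth


@pytest.fixture(scope="session")
def small_records(small_library):
    lib, _ = small_library
    return [make_record(lib.base, v, 3, lib.pad_length) for v in lib.variants]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
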