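import numpy as np
import pytest

from pairdiff.design import (
    DesignSpec,
    make_scan_sequence,
    make_stimulus_set,
)


@pytest.fixture(scope="session")
def default_spec() -> DesignSpec:
    return DesignSpec(seed=11)


@pytest.fixture(scope="session")
def default_stimset(default_spec):
    return make_stimulus_set(default_spec)


@pytest.fixture(scope="session")
def default_sequence(default_spec, default_stimset):
    return make_scan_sequence(default_stimset, default_spec)


@pytest.fixture(scope="session")
def small_spec() -> DesignSpec:
    """Reduced design: 6 pairs, 2 runs — fast enough for GLM chains."""
    return DesignSpec(
        n_pairs_total=6,
        n_pairs_per_condition=2,
        n_runs=2,
        n_null_interleaved=4,
        n_lead_in=1,
        n_lead_out=1,
        seed=5,
    )


@pytest.fixture(scope="session")
def small_stimset(small_spec):
    return make_stimulus_set(small_spec)


@pytest.fixture(scope="session")
def small_sequence(small_spec, small_stimset):
    return make_scan_sequence(small_stimset, small_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
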