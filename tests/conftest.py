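import numpy as np
import pytest

from autoreg import (
    RunConfig,
    SimulationConfig,
    block_average,
    generate_recording,
    run_cohort,
)


@pytest.fixture(scope="session")
def default_recording():
    """One default synthetic recording with its ground truth."""
    return generate_recording(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def default_series(default_recording):
    rec, _ = default_recording
    return block_average(rec)


@pytest.fixture(scope="session")
def cohort30(tmp_path_factory):
    """The 30-animal synthetic cohort used for the directional statistics."""
    out = tmp_path_factory.mktemp("cohort30")
    run = RunConfig(
        n_animals=30,
        seed=7,
        outdir=str(out),
        make_figures=False,
        write_per_animal=False,
    )
    return run_cohort(run)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
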