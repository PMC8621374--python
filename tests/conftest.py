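import numpy as np
import pytest

from mirpipe.pipeline import RunConfig, run_pipeline
from mirpipe.simulate import SimulationConfig


@pytest.fixture(scope="session")
def tiny_config():
    """A small but complete experiment: 10 miRNAs, 6k reads per library."""
    return RunConfig(
        sim=SimulationConfig(
            seed=11,
            n_true_mirnas=10,
            known_fraction=0.5,
            reads_per_library=6000,
            genome_length=30_000,
            n_transcripts=40,
            abundance_dispersion=0.0,
        )
    )


@pytest.fixture(scope="session")
def tiny_run(tiny_config, tmp_path_factory):
    """One full pipeline run shared across tests (deterministic, seed 11)."""
    outdir = tmp_path_factory.mktemp("tiny_run")
    summary = run_pipeline(tiny_config, outdir)
    return tiny_config, outdir, summary


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
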