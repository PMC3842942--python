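import numpy as np
import pytest

from venomtx import simulate


@pytest.fixture(scope="session")
def small_sim():
    """A small deterministic synthetic run shared across tests."""
    cfg = simulate.SimulationConfig(
        seed=11,
        n_transcripts=30,
        n_toxin_genes=8,
        divergence=0.1,
        n_reads=10000,
        read_length=50,
    )
    transcripts, references, ref_meta, gt = simulate.generate_transcriptome(cfg)
    return cfg, transcripts, references, ref_meta, gt


@pytest.fixture(scope="session")
def zero_divergence_sim():
    cfg = simulate.SimulationConfig(
        seed=7,
        n_transcripts=25,
        n_toxin_genes=6,
        divergence=0.0,
        n_reads=8000,
    )
    transcripts, references, ref_meta, gt = simulate.generate_transcriptome(cfg)
    return cfg, transcripts, references, ref_meta, gt


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
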