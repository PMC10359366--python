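import numpy as np
import pytest

from spex import SynthConfig, generate, track_predictor

TINY_CHROMS = {"chr1": 2_500_000, "chr2": 2_500_000, "chr8": 2_500_000}


def tiny_config(**overrides) -> SynthConfig:
    """Desk-scale study conditions: 90 genes on three short chromosomes."""
    kwargs = dict(
        n_genes=90,
        chrom_lengths=dict(TINY_CHROMS),
        loop_distance=(30_000, 150_000),
        seed=7,
    )
    kwargs.update(overrides)
    return SynthConfig(**kwargs)


@pytest.fixture(scope="session")
def tiny_dataset():
    return generate(tiny_config())


@pytest.fixture(scope="session")
def tiny_predictor(tiny_dataset):
    return track_predictor(tiny_dataset.store)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
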