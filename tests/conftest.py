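import numpy as np
import pytest

from polybackmap.synth import GeneratorParams, pack_frames


@pytest.fixture(scope="session")
def small_params():
    return GeneratorParams(n_chains=3, n_monomers=6, box_length=3.0, seed=42)


@pytest.fixture(scope="session")
def small_ensemble(small_params):
    """3 chains x 6 monomers x 5 frames, mixed stereo sequence."""
    seqs = [list("LLDLDL")] * 3
    return pack_frames(small_params, sequences=seqs, n_frames=5)


@pytest.fixture(scope="session")
def homopolymer_ensemble():
    params = GeneratorParams(n_chains=4, n_monomers=8, box_length=3.5, seed=7)
    return pack_frames(params, n_frames=6)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
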