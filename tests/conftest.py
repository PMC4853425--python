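import numpy as np
import pytest

from c60kit import geometry, synth


@pytest.fixture(scope="session")
def default_config():
    return synth.GeneratorConfig(seed=11)


@pytest.fixture(scope="session")
def bundle(default_config):
    """Standard 4 x 30-residue antiparallel bundle."""
    return synth.generate_helix_bundle(default_config)


@pytest.fixture(scope="session")
def binding_motif(bundle):
    """Four-segment binding-site query: residues 2-9 on one chain pair,
    19-24 on the opposing pair (112 backbone atoms)."""
    return geometry.extract_motif(
        bundle, [("A", 2, 9), ("B", 2, 9), ("C", 19, 24), ("D", 19, 24)])


@pytest.fixture(scope="session")
def small_bundle():
    """4 x 15 residues = 60 residues total, for brute-force oracle work."""
    return synth.generate_helix_bundle(synth.GeneratorConfig(seed=5, n_residues=15))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
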