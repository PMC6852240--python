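import warnings

import pytest

from surfpatch.fixtures import SyntheticComplexSpec, make_complex
from surfpatch.sasa import compute_rasa


@pytest.fixture(scope="session")
def lattice_complex():
    """Two-slab complex with a contiguous planted interface (seed 0)."""
    return make_complex(SyntheticComplexSpec(rng_seed=0))


@pytest.fixture(scope="session")
def helix_complex():
    """Two antiparallel ideal helices; sparse facing-stripe interface."""
    spec = SyntheticComplexSpec(
        geometry="helix", n_residues=(40, 40), separation=13.0, rng_seed=0
    )
    return make_complex(spec)


@pytest.fixture(scope="session")
def lattice_surface_a(lattice_complex):
    structure, _ = lattice_complex
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return compute_rasa(structure, context=["A"])
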