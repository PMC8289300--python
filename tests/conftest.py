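import numpy as np
import pytest

from cdx import synthetic
from cdx.reweight import MetaDParams


@pytest.fixture(scope="session")
def helix12():
    return synthetic.make_ideal_helix(12)


@pytest.fixture(scope="session")
def cd_z():
    """Pseudo-CD with its cavity axis along +z."""
    return synthetic.make_cd_molecule(center=(2.0, 2.0, 2.0),
                                      axis_unit_vector=(0.0, 0.0, 1.0))


@pytest.fixture(scope="session")
def metad_run():
    """One well-tempered toy run at the production bias parameters
    (bias factor 15, 2 kJ/mol initial height, 1 hill/ps)."""
    return synthetic.sample_metad_double_well(MetaDParams(), n_steps=100_000, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
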