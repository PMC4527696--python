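import numpy as np
import pytest

from cagtrace import CohortConfig, GenotypeSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Two carrier genotypes, one age group — fast end-to-end fixture."""
    return CohortConfig(
        seed=11,
        animals_per_cell=4,
        age_groups=((5, 10),),
        genotypes=(GenotypeSpec("Q150/wt", "+/+"), GenotypeSpec("Q150/Q150", "-/-")),
    )


@pytest.fixture
def phenotype_config():
    """All six focus genotypes, phenotype only (no tissues)."""
    return CohortConfig(
        seed=7,
        animals_per_cell=6,
        age_groups=((5, 10), (11, 20), (21, 30)),
        tissues=(),
    )
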