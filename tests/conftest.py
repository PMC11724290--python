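import numpy as np
import pytest

from ttwas.synthetic_cohort import make_variant_layout, simulate_genotypes


@pytest.fixture(scope="session")
def small_cohort():
    """600 samples x (50 cis + 3 trans regions of 20) with mild LD."""
    layout = make_variant_layout(
        [("chr1", 1_000_000, 50)] + [(f"chr{i + 2}", 2_000_000, 20) for i in range(3)],
        seed=11,
    )
    gm = simulate_genotypes(600, layout, ld_rho=0.2, seed=12)
    return layout, gm


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
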