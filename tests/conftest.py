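import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from mrmr_eqtl import SimulationSpec, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A seeded 100-sample, 8-SNP, 30-gene dataset with strong planted effects."""
    spec = SimulationSpec(
        n_samples=100,
        n_snps=8,
        n_genes=30,
        n_chromosomes=2,
        marker_spacing_bp=10_000_000,
        cis_fraction=1 / 6,
        trans_fraction=1 / 6,
        pleiotropy=5,
        cis_additive=3.0,
        trans_additive=3.0,
        seed=11,
    )
    return simulate_dataset(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
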