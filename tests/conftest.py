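import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from lofburden.simulate import SimulationConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240815)


@pytest.fixture(scope="session")
def small_synth():
    """A small mixed cohort: one causal gene, clean and spurious sites."""
    cfg = SimulationConfig(
        n_cases=400, n_controls=400, n_genes=5, variants_per_gene=4,
        maf_range=(2e-4, 2e-3), lof_fraction=0.75,
        burden_log_or=[1.5, 0.0, 0.0, 0.0, 0.0],
        spurious_site_fraction=0.25, seed=11)
    return simulate_cohort(cfg)
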