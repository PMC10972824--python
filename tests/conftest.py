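import numpy as np
import pandas as pd
import pytest

from depresist import synthetic


@pytest.fixture(scope="session")
def panel():
    """Default synthetic panel: 300 lines, 1000 genes, planted structure."""
    return synthetic.generate_panel(seed=11)


@pytest.fixture(scope="session")
def perturbation():
    return synthetic.generate_perturbation_experiment(seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_expression(rng):
    """60 genes x 20 samples of log-scale noise."""
    genes = [f"G{i:03d}" for i in range(60)]
    samples = [f"S{i:02d}" for i in range(20)]
    return pd.DataFrame(5 + rng.standard_normal((60, 20)), index=genes, columns=samples)
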