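import numpy as np
import pytest

from coexpnet import Network, SimulationConfig, generate_dataset

ONE_STRATUM = {"FY": 100, "FM": 0, "FE": 0, "MY": 0, "MM": 0, "ME": 0}


@pytest.fixture(scope="session")
def strong_module_dataset():
    """One 20-gene module at beta=1.5 in a 100-gene, 100-sample stratum:
    the parameter-recovery benchmark condition."""
    cfg = SimulationConfig(
        n_genes=100, group_sizes=dict(ONE_STRATUM), n_modules=1, module_size=20,
        beta=1.5, stratum_specific_fraction=0.0, seed=1,
    )
    return cfg, generate_dataset(cfg)


@pytest.fixture
def random_network():
    """Deterministic 100-edge random network on 60 genes."""
    rng = np.random.default_rng(42)
    genes = [f"G{i:03d}" for i in range(60)]
    pairs = set()
    while len(pairs) < 100:
        a, b = rng.choice(60, 2, replace=False)
        pairs.add(tuple(sorted((genes[a], genes[b]))))
    return Network.from_pairs("parent", pairs, 1.0)
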