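import numpy as np
import pytest

from slslogit.netadj import NetworkConfig, build_network
from slslogit.simulate import SimulationConfig, make_dataset
from slslogit.solver import standardize_columns


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_problem():
    """A 200 x 40 standardized SNP problem with a correlated-cluster truth."""
    cfg = SimulationConfig(n=200, p=40, cluster_size=5, structure="ar",
                           rho=0.8, data_type="snp", seed=7)
    train, val = make_dataset(cfg)
    Xtr, mu, sd = standardize_columns(train.X)
    Xva = (val.X - mu) / sd
    net = build_network(Xtr, NetworkConfig(n_obs=cfg.n))
    return {"config": cfg, "train": train, "val": val,
            "X": Xtr, "y": train.y.astype(float),
            "X_val": Xva, "y_val": val.y.astype(float), "net": net}
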