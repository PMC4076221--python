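import numpy as np
import pytest

from enaflow import (
    CurrencyNetwork,
    GeneratorParams,
    IOTable,
    generate_currency_network,
)

# 2-sector worked example used throughout: internal block [[1,1],[0,2]],
# no boundary flows.  H = 1.5 bits, AMI = 0.311278 bits, A = 1.245112.
EX1 = np.array([[1.0, 1.0], [0.0, 2.0]])


@pytest.fixture
def ex1_network():
    return CurrencyNetwork(
        sector_labels=("S1", "S2"),
        internal=EX1,
        inflow=np.zeros(2),
        value_added=np.zeros(2),
        outflow=np.zeros(2),
        end_use=np.zeros(2),
    )


@pytest.fixture
def one_sector_table():
    """Single-sector I-O table whose accounting identity holds (supply=demand=4)."""
    return IOTable(
        sector_labels=("S1",),
        intermediate=[[2.0]],
        imports=[1.0],
        value_added=[1.0],
        final_use_domestic=[1.0],
        exports=[1.0],
    )


def random_network(seed: int, n: int = 5) -> CurrencyNetwork:
    """A random balanced synthetic network for property suites."""
    rng = np.random.default_rng(seed)
    return generate_currency_network(GeneratorParams(
        n_sectors=n,
        organization=float(rng.uniform(0.0, 1.0)),
        target_tst=float(rng.uniform(10.0, 1e4)),
        boundary_share=float(rng.uniform(0.1, 0.5)),
        seed=seed,
    ))


def random_flow_matrix(seed: int, shape=(5, 5), sparsity: float = 0.3) -> np.ndarray:
    """A random non-negative flow matrix with some structural zeros."""
    rng = np.random.default_rng(seed)
    m = rng.gamma(1.0, 10.0, size=shape)
    m[rng.random(shape) < sparsity] = 0.0
    if m.sum() == 0:
        m[0, 0] = 1.0
    return m
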