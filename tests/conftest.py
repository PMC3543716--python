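import numpy as np
import pandas as pd
import pytest

from aclandscape.synthetic import ModuleSpec, SimulationConfig
from aclandscape.types import CorrelationMatrix, ExpressionMatrix


def random_correlation_matrix(n: int, rs: int) -> CorrelationMatrix:
    """Random positive-definite correlation matrix via scipy."""
    from scipy.stats import random_correlation

    rng = np.random.default_rng(rs)
    ev = rng.random(n) + 0.05
    ev = ev / ev.sum() * n
    r = random_correlation.rvs(ev, random_state=np.random.RandomState(rs))
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix([f"g{i:02d}" for i in range(n)], r)


def expr_from_array(values: np.ndarray, genes=None, samples=None,
                    detection=None, groups=None) -> ExpressionMatrix:
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    vals = pd.DataFrame(values, index=genes, columns=samples)
    if detection is None:
        det = pd.DataFrame("P", index=genes, columns=samples)
    else:
        det = pd.DataFrame(detection, index=genes, columns=samples)
    return ExpressionMatrix(vals, det, groups or {})


@pytest.fixture
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=0)


@pytest.fixture
def one_group_config() -> SimulationConfig:
    return SimulationConfig(
        n_genes=30,
        groups=(("G1", 40),),
        modules=(ModuleSpec(size=6, loading=1.0),),
        flat_gene_fraction=0.2,
        noise_sd=0.5,
        detection_missing_fraction=0.0,
        seed=3,
    )
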