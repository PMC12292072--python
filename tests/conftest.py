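import numpy as np
import pandas as pd
import pytest

from trimciv.expression import MS, ExpressionDataset
from trimciv.synthetic_data import SimConfig, gen_docking, gen_expression, gen_family


@pytest.fixture
def small_config() -> SimConfig:
    """Desk-scale cohort for fast end-to-end exercises."""
    return SimConfig(
        seed=11,
        n_civ=4,
        n_noncivil=4,
        n_targets=24,
        cancers=("AAA", "BBB"),
        n_tumor=30,
        n_normal=15,
        n_background=40,
        n_decoys=10,
    )


@pytest.fixture
def small_family(small_config):
    return gen_family(small_config)


@pytest.fixture
def small_world(small_config, small_family):
    registry, pairs = small_family
    datasets = gen_expression(small_config, registry, pairs)
    docking = gen_docking(small_config, pairs)
    return registry, pairs, datasets, docking


def make_ms_dataset(matrix: np.ndarray, n_tumor: int, n_normal: int,
                    genes=None, cancer: str = "AAA") -> ExpressionDataset:
    """Wrap a complete log-scale matrix as an MS ExpressionDataset."""
    n_genes = matrix.shape[0]
    genes = genes if genes is not None else [f"G{i:04d}" for i in range(n_genes)]
    samples = [f"T{i}" for i in range(n_tumor)] + [f"N{i}" for i in range(n_normal)]
    group = pd.Series(["tumor"] * n_tumor + ["normal"] * n_normal, index=samples)
    return ExpressionDataset(
        pd.DataFrame(matrix, index=genes, columns=samples), group, cancer, MS
    )
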