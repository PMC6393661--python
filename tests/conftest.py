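import numpy as np
import pandas as pd
import pytest

from lnctrans import ExpressionMatrix, SimConfig, generate_dataset


@pytest.fixture()
def small_matrix() -> ExpressionMatrix:
    """10 genes x 6 samples (3 case / 3 control), deterministic values."""
    rng = np.random.default_rng(7)
    samples = ["case1", "case2", "case3", "ctrl1", "ctrl2", "ctrl3"]
    genes = [f"g{i}" for i in range(10)]
    values = pd.DataFrame(
        rng.uniform(0.0, 50.0, size=(10, 6)), index=genes, columns=samples
    )
    return ExpressionMatrix(
        values=values,
        groups={s: ("case" if s.startswith("case") else "control") for s in samples},
        biotype={g: "mRNA" for g in genes},
    )


@pytest.fixture(scope="session")
def clean_dataset():
    """Near-noiseless planted dataset: signal dominates, structure fully visible."""
    cfg = SimConfig(
        n_case=10, n_control=10, n_mrna=200, n_lncrna=10, n_tf=5,
        regulon_size=10, n_planted_triads=3, noise_sd=1e-6,
        activity_weight=1.0, de_log2fc=1.5, seed=11,
    )
    return cfg, generate_dataset(cfg)
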