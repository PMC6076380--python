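import numpy as np
import pandas as pd
import pytest

from mirprospect.matrix import ExpressionMatrix
from mirprospect.synth import SynthConfig, generate


def make_log2_matrix(arr, feature_prefix="mir", sample_prefix="s") -> ExpressionMatrix:
    """Wrap a 2-d array (features x samples) as a log2 ExpressionMatrix."""
    arr = np.asarray(arr, float)
    idx = [f"{feature_prefix}-{i + 1:04d}" for i in range(arr.shape[0])]
    cols = [f"{sample_prefix}{j + 1:03d}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=idx, columns=cols), state="log2")


@pytest.fixture(scope="session")
def planted_small():
    """Small matched cohort with strong planted markers (deterministic)."""
    cfg = SynthConfig(
        n_mirnas=300,
        n_cases=20,
        n_controls=80,
        frac_de=0.1,
        effect_size_d=1.5,
        frac_down=0.7,
        n_replicates_per_probe=2,
        seed=42,
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def null_small():
    """Small matched cohort with no planted effects (deterministic)."""
    cfg = SynthConfig(
        n_mirnas=300,
        n_cases=20,
        n_controls=80,
        frac_de=0.0,
        n_replicates_per_probe=2,
        seed=7,
    )
    return generate(cfg)
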