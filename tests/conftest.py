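import warnings

import numpy as np
import pandas as pd
import pytest

from pmutual.panel import PanelDataset

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", module="sklearn")


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_panel():
    """3 subjects x 2 waves x 2 variables, fully observed."""
    values = np.arange(12, dtype=float).reshape(3, 2, 2)
    return PanelDataset(["a", "b", "c"], [14, 15], ["x", "y"], values)


def one_factor_data(rng, n=2000, loadings=(0.7, 0.6, 0.5, 0.8, 0.6, 0.7),
                    mean=0.0):
    lam = np.asarray(loadings)
    F = rng.standard_normal(n)
    X = F[:, None] * lam + rng.standard_normal((n, len(lam))) \
        * np.sqrt(1 - lam ** 2) + mean
    return pd.DataFrame(X, columns=[f"i{j}" for j in range(len(lam))]), lam
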