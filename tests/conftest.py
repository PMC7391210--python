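import numpy as np
import pandas as pd
import pytest

from exomir.containers import CtMatrix, ExpressionMatrix


def make_expression(values, groups, unit="count", features=None, samples=None):
    """Build an ExpressionMatrix from a plain array and group list."""
    arr = np.asarray(values, dtype=float)
    features = features or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{i}" for i in range(arr.shape[1])]
    df = pd.DataFrame(arr, index=features, columns=samples)
    grp = pd.Series(list(groups), index=samples)
    return ExpressionMatrix(df, grp, unit=unit)


def make_ct(values, groups, assays=None, samples=None):
    arr = np.asarray(values, dtype=float)
    assays = assays or [f"a{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{i}" for i in range(arr.shape[1])]
    df = pd.DataFrame(arr, index=assays, columns=samples)
    grp = pd.Series(list(groups), index=samples)
    return CtMatrix(df, grp)


@pytest.fixture
def genorm_toy():
    """Three-gene toy panel: two perfectly parallel genes plus one constant."""
    return make_ct(
        [[20.0, 21.0, 22.0, 23.0], [20.0, 21.0, 22.0, 23.0], [20.0, 20.0, 20.0, 20.0]],
        ["case", "case", "control", "control"],
        assays=["G1", "G2", "G3"],
    )


@pytest.fixture
def random_ct_panel():
    """Factory for seeded random Ct panels (complete, no missing values)."""

    def _make(seed, n_assays=5, n_samples=10, base=25.0, spread=3.0, noise=1.0):
        rng = np.random.default_rng(seed)
        means = base + rng.uniform(-spread, spread, size=n_assays)
        vals = means[:, None] + rng.normal(0, noise, size=(n_assays, n_samples))
        groups = ["case"] * (n_samples // 2) + ["control"] * (n_samples - n_samples // 2)
        return make_ct(vals, groups)

    return _make
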