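import numpy as np
import pytest

from metimpute import MetaboliteMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, runday=None, mask=None, scale="log"):
    """Build a MetaboliteMatrix from a plain array (NaN = missing)."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if mask is None:
        mask = np.isnan(values)
    if runday is None:
        runday = np.array(["D1"] * n, dtype=object)
    return MetaboliteMatrix(
        values,
        np.asarray(mask, dtype=bool),
        [f"S{i}" for i in range(n)],
        [f"X{j}" for j in range(p)],
        np.asarray(runday, dtype=object),
        scale=scale,
    )


@pytest.fixture
def random_incomplete():
    """30% MCAR missingness on a correlated 60x5 log-scale matrix."""
    gen = np.random.default_rng(7)
    base = gen.standard_normal((60, 1))
    vals = 0.6 * base + 0.8 * gen.standard_normal((60, 5))
    mask = gen.random((60, 5)) < 0.3
    # keep at least 4 observed per column so every method can fit
    for j in range(5):
        obs = np.nonzero(~mask[:, j])[0]
        if obs.size < 4:
            mask[:4, j] = False
    vals = vals.copy()
    vals[mask] = np.nan
    runday = np.array(["D1", "D2", "D3"] * 20, dtype=object)
    return make_matrix(vals, runday=runday, mask=mask)
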