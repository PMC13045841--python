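import numpy as np
import pytest

from crossbind.simulate import SyntheticConfig, make_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small labeled pair table with a planted noise-free binding rule."""
    cfg = SyntheticConfig(n_tcr=240, n_pep=16, seed=7)
    dataset, rule = make_dataset(cfg, pairs_per_peptide=12)
    return dataset, rule


def numeric_grad(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of a scalar function of an array."""
    g = np.zeros_like(x, dtype=float)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        hi = f()
        x[i] = orig - eps
        lo = f()
        x[i] = orig
        g[i] = (hi - lo) / (2 * eps)
        it.iternext()
    return g
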