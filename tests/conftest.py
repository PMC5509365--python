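import numpy as np
import pytest

from divnorm.basis import FeatureBasis
from divnorm.estimators import poisson_loglik


@pytest.fixture
def two_input_basis() -> FeatureBasis:
    """Minimal network: one feature driving two inputs at weight 40, w0=1."""
    return FeatureBasis(np.full((2, 1), 40.0), 1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_basis(rng, m: int, n: int, background: float = 1.0) -> FeatureBasis:
    """Random dense nonnegative basis with weights U(0, 40)."""
    return FeatureBasis(rng.uniform(0.0, 40.0, size=(m, n)), background)


def random_poisson_instance(rng, m: int, n: int, background: float = 1.0):
    """A random estimation problem: basis, generating features, noisy input."""
    basis = random_basis(rng, m, n, background)
    x_true = rng.uniform(0.5, 2.0, size=n)
    s = rng.poisson(basis.mean_input(x_true)).astype(float)
    return basis, x_true, s


def grid_search_ml(basis: FeatureBasis, s: np.ndarray, x_max: float,
                   n_pts: int = 13, n_rounds: int = 8) -> np.ndarray:
    """Brute-force Poisson-ML oracle: iteratively refined grid search over
    the nonnegative box [0, x_max]^n.  Independent of the package's own
    solvers (uses only the likelihood)."""
    n = basis.n_features
    lo = np.zeros(n)
    hi = np.full(n, float(x_max))
    best = lo.copy()
    for _ in range(n_rounds):
        axes = [np.linspace(lo[i], hi[i], n_pts) for i in range(n)]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, n)
        ll = poisson_loglik(basis, grid, s)
        best = grid[int(np.argmax(ll))]
        span = (hi - lo) / (n_pts - 1)
        lo = np.maximum(best - 2 * span, 0.0)
        hi = best + 2 * span
    return best
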