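import numpy as np
import pytest

from entrace.decomposition import ALSParams


def dense_als_oracle(y: np.ndarray, params: ALSParams) -> np.ndarray:
    """Naive dense reference ALS solver.

    Solves the penalised normal equations (W + lam * D^T D) z = W y with
    full dense linear algebra and the same fixed-point weight iteration and
    reflection padding as the production banded solver. Kept deliberately
    independent of the production code path (numpy.linalg.solve on an
    explicitly assembled matrix).
    """
    y = np.asarray(y, dtype=float)
    pad = min(params.edge_pad, y.shape[0] - 1)
    if pad > 0:
        y_ext = np.concatenate([y[pad:0:-1], y, y[-2 : -pad - 2 : -1]])
    else:
        y_ext = y
    n = y_ext.shape[0]
    d = np.eye(n)
    for _ in range(params.difference_order):
        d = np.diff(d, axis=0)
    penalty = params.smoothness_lambda * d.T @ d
    w = np.ones(n)
    z = y_ext
    for _ in range(params.max_iterations):
        z = np.linalg.solve(np.diag(w) + penalty, w * y_ext)
        w_new = np.where(y_ext > z, params.asymmetry_p, 1.0 - params.asymmetry_p)
        if np.max(np.abs(w_new - w)) <= params.weight_tolerance:
            break
        w = w_new
    return z[pad : pad + y.shape[0]] if pad > 0 else z


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture(scope="session")
def small_field():
    """A small default-condition field reused by read-only tests."""
    from entrace import GeneratorConfig, simulate_field

    return simulate_field(GeneratorConfig(n_cells=10, seed=42))
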