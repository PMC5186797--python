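import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from panelflux.simulate import (
    generate_cell_line_panel,
    generate_patient_cohort,
    generate_toy_model,
    make_ground_truth,
)


@pytest.fixture(scope="session")
def truth():
    return make_ground_truth(seed=0)


@pytest.fixture(scope="session")
def panel(truth):
    """A 57-line training panel over 500 genes."""
    matrix, rates = generate_cell_line_panel(500, 57, truth, seed=100)
    return matrix, rates


@pytest.fixture(scope="session")
def noise_free_truth():
    return make_ground_truth(seed=3, noise_sd=0.0)


@pytest.fixture(scope="session")
def noise_free_cohort(noise_free_truth):
    """A cohort with all observation noise off: measurements are exact affine
    images of the latent expression (biological across-sample variation only)."""
    return generate_patient_cohort(
        noise_free_truth,
        panels=[("panelA", 20, 0.0), ("panelB", 16, 0.0)],
        dual_platform_fraction=0.5,
        seed=11,
        platform_noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def toy_models():
    return generate_toy_model(3, seed=7)


def enumerate_pfba_vertices(S: np.ndarray, p: int, r_p: float) -> float:
    """Independent oracle: minimal total flux over all vertices of the slice
    {v >= 0, S v = 0, v_p = r_p}, found by exhaustive basis enumeration.

    Only usable for tiny models (combinatorial in the number of reactions).
    """
    from itertools import combinations

    m, n = S.shape
    A = np.vstack([S, np.eye(n)[p]])
    b = np.concatenate([np.zeros(m), [r_p]])
    rank = np.linalg.matrix_rank(A)
    best = np.inf
    for basis in combinations(range(n), rank):
        Ab = A[:, basis]
        if np.linalg.matrix_rank(Ab) < rank:
            continue
        x_b, *_ = np.linalg.lstsq(Ab, b, rcond=None)
        if np.max(np.abs(Ab @ x_b - b)) > 1e-9:
            continue
        if np.min(x_b) < -1e-9:
            continue
        v = np.zeros(n)
        v[list(basis)] = np.clip(x_b, 0.0, None)
        if np.max(np.abs(S @ v)) > 1e-8 or abs(v[p] - r_p) > 1e-9:
            continue
        best = min(best, float(v.sum()))
    return best
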