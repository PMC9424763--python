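import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from mc2s import WavenumberAxis, unfold
from mc2s.synthetic import make_preset


AXIS200 = WavenumberAxis(np.linspace(2500.0, 3200.0, 200))


def matched_components(S_est: np.ndarray, S_true: np.ndarray):
    """Hungarian matching of estimated to true spectra by cosine similarity.

    Returns (cosines, permutation) where permutation[k] is the estimated
    component assigned to true component k.
    """
    n1 = np.linalg.norm(S_est, axis=1, keepdims=True)
    n2 = np.linalg.norm(S_true, axis=1, keepdims=True)
    cos = (S_est / np.maximum(n1, 1e-300)) @ (S_true / np.maximum(n2, 1e-300)).T
    rows, cols = linear_sum_assignment(-cos)
    perm = np.empty(len(rows), dtype=int)
    perm[cols] = rows
    return cos[rows, cols][np.argsort(cols)], perm


def concentration_pearson(C_est: np.ndarray, C_true: np.ndarray, perm) -> list[float]:
    return [float(np.corrcoef(C_est[:, perm[k]], C_true[:, k])[0, 1])
            for k in range(C_true.shape[1])]


def disc_image(size: int = 64, radius: int = 10, center=None) -> np.ndarray:
    c = (size // 2, size // 2) if center is None else center
    x, y = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    return (((x - c[0]) ** 2 + (y - c[1]) ** 2) <= radius**2)


def boundary_length(mask_values: np.ndarray) -> int:
    m = mask_values
    return int(np.sum(m[:-1, :] != m[1:, :]) + np.sum(m[:, :-1] != m[:, 1:]))


@pytest.fixture(scope="session")
def rank3_phantom():
    """Noiseless rank-3 32x32x200 phantom with exact bilinear truth."""
    cube, truth = make_preset("three-compartment", shape=(32, 32), seed=1,
                              axis=AXIS200)
    return unfold(cube), truth


@pytest.fixture(scope="session")
def rank3_noisy_phantom():
    """Same construction at 2% shot-like noise."""
    cube, truth = make_preset("three-compartment", shape=(32, 32), seed=2,
                              gaussian_frac=0.02, axis=AXIS200)
    return unfold(cube), truth


@pytest.fixture(scope="session")
def single_cell_phantom():
    cube, truth = make_preset("single-cell", shape=(48, 48), seed=11,
                              gaussian_frac=0.02)
    return unfold(cube), truth
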