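import numpy as np
import pytest

from tomopipe.phantom import (asymmetric_phantom, forward_project,
                              shepp_logan, simulate_scan, smooth_phantom)


def masked_nrmse(a: np.ndarray, b: np.ndarray,
                 mask: np.ndarray) -> float:
    """RMSE over a mask, normalized by the reference dynamic range."""
    return float(np.sqrt(np.mean((a[mask] - b[mask]) ** 2))
                 / (b[mask].max() - b[mask].min()))


def circle_mask(n: int, fraction: float = 0.46) -> np.ndarray:
    c = (n - 1) / 2.0
    y, x = np.mgrid[0:n, 0:n]
    return (x - c) ** 2 + (y - c) ** 2 <= (fraction * n) ** 2


def embed(grid: np.ndarray, n: int) -> np.ndarray:
    """Embed a square phantom grid centered in an n x n slice."""
    m = grid.shape[0]
    off = (n - m) // 2
    out = np.zeros((n, n))
    out[off:off + m, off:off + m] = grid
    return out


@pytest.fixture(scope="session")
def sl64():
    return shepp_logan(64)


@pytest.fixture(scope="session")
def sl128():
    return shepp_logan(128)


@pytest.fixture(scope="session")
def asym128():
    return asymmetric_phantom(128)


@pytest.fixture(scope="session")
def smooth128():
    return smooth_phantom(128)


@pytest.fixture(scope="session")
def sino96(sl64):
    """Noise-free Shepp-Logan sinogram on a 96-column detector."""
    angles = np.linspace(0.0, 180.0, 120, endpoint=False)
    sino = forward_project(sl64, angles, detector_width=96)[:, 0, :]
    return sino, angles


@pytest.fixture(scope="session")
def small_scan(sl64):
    """Small noiseless multi-row scan + ground truth (shared, read-only)."""
    return simulate_scan(sl64, n_proj=80, n_rows=4, poisson=False)


@pytest.fixture(scope="session")
def noisy_scan(sl64):
    return simulate_scan(sl64, n_proj=80, n_rows=2, poisson=True, seed=11)
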