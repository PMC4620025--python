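import numpy as np
import pytest

from topocode.synthetic import (
    SynthImageConfig,
    SynthTscConfig,
    generate_cell_frames,
    generate_tsc_instance,
)
from topocode.tsc import TscConfig, build_grouping_matrix


@pytest.fixture(scope="session")
def small_scenes():
    """Eight small frames with 6 nuclei each; session-scoped for speed."""
    cfg = SynthImageConfig(
        frame_height=192, frame_width=192, n_cells_per_frame=6, n_frames=8, seed=11
    )
    return generate_cell_frames(cfg)


@pytest.fixture(scope="session")
def tiny_tsc_instance():
    cfg = SynthTscConfig(d=16, k=16, N=200, atoms_active_per_sample=3, noise_sd=0.01, seed=3)
    return generate_tsc_instance(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def grouping_3x3():
    return build_grouping_matrix(3, 3, 3, wraparound=True)


def brute_force_penalty(s: np.ndarray, V: np.ndarray, eps: float) -> float:
    """Independent triple-loop oracle for the smoothed group penalty."""
    G, k = V.shape
    _, N = s.shape
    total = 0.0
    for g in range(G):
        for n in range(N):
            e = 0.0
            for j in range(k):
                if V[g, j]:
                    e += s[j, n] ** 2
            total += (e + eps) ** 0.5
    return total


def finite_difference_grad(f, X: np.ndarray, h: float = 1e-6) -> np.ndarray:
    """Central finite differences of a scalar function of a matrix."""
    g = np.zeros_like(X, dtype=float)
    it = np.nditer(X, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        Xp = X.copy()
        Xm = X.copy()
        Xp[idx] += h
        Xm[idx] -= h
        g[idx] = (f(Xp) - f(Xm)) / (2 * h)
        it.iternext()
    return g
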