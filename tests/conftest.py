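import numpy as np
import pytest

from dcepnms import PhantomSpec, TimeGrid, make_aif, simulate_study


@pytest.fixture(scope="session")
def grid():
    """Full default acquisition grid: 400 frames, 1.55 s apart."""
    return TimeGrid()


@pytest.fixture(scope="session")
def aif(grid):
    return make_aif(grid)


@pytest.fixture(scope="session")
def small_grid():
    """Short grid for oracle comparisons that would be slow at full length."""
    return TimeGrid(n_frames=120, dt=1.0, injection_index=20, retained_start=10)


@pytest.fixture(scope="session")
def small_aif(small_grid):
    return make_aif(small_grid)


@pytest.fixture(scope="session")
def noiseless_study_small():
    """Small noiseless phantom shared across recovery tests."""
    spec = PhantomSpec(shape=(12, 12, 1), tumor_radius=4.0, core_radius=2.5,
                       noise_sd=0.0, seed=42)
    return simulate_study(spec)


def dense_riemann_convolution(values, grid, kep, dt_dense=1e-3):
    """Independent brute-force oracle for the exponential convolution.

    Linearly interpolates the curve onto a dt_dense grid and accumulates
    the midpoint Riemann sum of c(u) * exp(-kep_s * (t - u)); evaluated at
    the frame times by exp-weighted running summation.
    """
    t = grid.timepoints
    k = kep / 60.0
    td = np.arange(t[0], t[-1] + dt_dense / 2, dt_dense)
    cd = np.interp(td, t, np.asarray(values, dtype=float))
    mid_t = 0.5 * (td[:-1] + td[1:])
    mid_c = 0.5 * (cd[:-1] + cd[1:])
    # running sum of c(u) e^{k u} du, then discount by e^{-k t}
    inc = mid_c * np.exp(k * (mid_t - t[-1])) * dt_dense
    csum = np.concatenate([[0.0], np.cumsum(inc)])
    out = np.interp(t, td, csum) * np.exp(k * (t[-1] - t))
    out[0] = 0.0
    return out
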