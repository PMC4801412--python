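import numpy as np
import pytest

import betascape as bs


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_grid():
    """4x5 all-land grid at 0.5 degrees."""
    return bs.build_grid(lat_max=0.0, lon_min=0.0, n_rows=4, n_cols=5, cell_size=0.5)


@pytest.fixture
def random_pam(rng, small_grid):
    inc = rng.random((small_grid.n_land, 7)) < 0.4
    ids = [f"sp{j}" for j in range(7)]
    return bs.PAMatrix(grid=small_grid, species_ids=ids, incidence=inc)


def brute_force_morans_i(x, W):
    """Dense double-sum Moran's I oracle (W a dense symmetric matrix)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    z = x - x.mean()
    num = 0.0
    for i in range(n):
        for j in range(n):
            num += W[i, j] * z[i] * z[j]
    return (n / W.sum()) * num / (z @ z)


def queen_neighbors(grid, r, c):
    out = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == dc == 0:
                continue
            rr, cc = r + dr, c + dc
            if 0 <= rr < grid.n_rows and 0 <= cc < grid.n_cols and grid.land_mask[rr, cc]:
                out.append((rr, cc))
    return out
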