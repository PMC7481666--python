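import math

import numpy as np
import pandas as pd
import pytest

from glideropt.synth import FrontScenario, synth_glider_deployment


NOISE_FREE = {
    "temp_C": 0.0,
    "sal_psu": 0.0,
    "chl_fl_mg_m3": 0.0,
    "bbp700_m1": 0.0,
    "cdom_fl": 0.0,
}


@pytest.fixture(scope="session")
def noise_free_scenario():
    return FrontScenario(noise=dict(NOISE_FREE), spike_rate=0.0, seed=1)


@pytest.fixture(scope="session")
def noise_free_deployment(noise_free_scenario):
    return synth_glider_deployment(noise_free_scenario)


@pytest.fixture(scope="session")
def small_deployment():
    """A short noisy deployment for fast I/O and CLI tests."""
    scenario = FrontScenario(spike_rate=0.005, seed=7)
    return synth_glider_deployment(
        scenario, n_profiles=8, samples_per_profile=30, dive_depth=60.0,
        end_lat=76.2,
    )


def barnes_oracle(x, z, v, x_grid, z_grid, radii, passes=2, gamma=0.3, cutoff=3.0):
    """Brute-force successive-correction analysis (plain Python loops).

    Independent reference for the vectorized Barnes implementation:
    Gaussian weights exp(-d2) truncated at normalized distance `cutoff`,
    correction pass p with length scales scaled by gamma**(p-1).
    """
    lx, lz = radii
    c2 = cutoff * cutoff
    x = list(map(float, x))
    z = list(map(float, z))
    v = list(map(float, v))

    def estimate(xt, zt, vals, lx_, lz_):
        num = 0.0
        den = 0.0
        for xs, zs, vv in zip(x, z, vals):
            d2 = ((xt - xs) / lx_) ** 2 + ((zt - zs) / lz_) ** 2
            if d2 <= c2:
                w = math.exp(-d2)
                num += w * vv
                den += w
        return num / den if den > 0 else math.nan

    grid = [
        [estimate(xg, zg, v, lx, lz) for xg in x_grid] for zg in z_grid
    ]
    obs_est = [estimate(xi, zi, v, lx, lz) for xi, zi in zip(x, z)]
    for p in range(2, passes + 1):
        s = gamma ** (p - 1)
        resid = [vv - ee for vv, ee in zip(v, obs_est)]
        for i, zg in enumerate(z_grid):
            for j, xg in enumerate(x_grid):
                corr = estimate(xg, zg, resid, lx * s, lz * s)
                if math.isnan(corr):
                    if not math.isnan(grid[i][j]):
                        corr = 0.0
                grid[i][j] += corr
        if p < passes:
            new = []
            for xi, zi in zip(x, z):
                corr = estimate(xi, zi, resid, lx * s, lz * s)
                new.append(corr if not math.isnan(corr) else 0.0)
            obs_est = [e + c for e, c in zip(obs_est, new)]
    return np.asarray(grid, dtype=float)
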