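import numpy as np
import pytest

from fuzzyhab.raster_core import GridRaster
from fuzzyhab.synthetic_data import SyntheticScenario, build_end_to_end_scenario


def separable_clouds(seed: int = 0, n: int = 200, d: int = 4,
                     separation: float = 5.0):
    """Two Gaussian clouds whose means are ``separation`` SDs apart."""
    rng = np.random.default_rng(seed)
    shift = separation / np.sqrt(d)
    presence = rng.standard_normal((n, d)) + shift
    reference = rng.standard_normal((n, d))
    return presence, reference


def brute_force_window_mean(values: np.ndarray, nodata: float,
                            window_px: int) -> np.ndarray:
    """Reference double-loop focal mean with border truncation."""
    nrows, ncols = values.shape
    half = window_px // 2
    out = np.full_like(values, nodata, dtype=float)
    for i in range(nrows):
        for j in range(ncols):
            if values[i, j] == nodata or np.isnan(values[i, j]):
                continue
            acc, cnt = 0.0, 0
            for di in range(-half, half + 1):
                for dj in range(-half, half + 1):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < nrows and 0 <= jj < ncols:
                        v = values[ii, jj]
                        if v != nodata and not np.isnan(v):
                            acc += v
                            cnt += 1
            if cnt:
                out[i, j] = acc / cnt
    return out


@pytest.fixture
def small_raster():
    """5x4 suitability raster with one nodata cell, 100 m cells."""
    vals = np.array([
        [0.1, 0.2, 0.3, 0.4],
        [0.5, -1.0, 0.7, 0.8],
        [0.9, 1.0, 0.0, 0.1],
        [0.2, 0.3, 0.4, 0.5],
        [0.6, 0.7, 0.8, 0.9],
    ])
    return GridRaster(vals, 100.0, (1000.0, 2000.0), nodata=-1.0,
                      semantics="suitability")


@pytest.fixture(scope="session")
def e2e_bundle():
    """The default seed-42 end-to-end scenario, built once per session."""
    return build_end_to_end_scenario(SyntheticScenario())


@pytest.fixture(scope="session")
def small_bundle():
    """A faster 80x80 scenario for tests that only need structure."""
    scn = SyntheticScenario(seed=7, nrows=80, ncols=80, n_patches=80,
                            n_presences=200)
    return build_end_to_end_scenario(scn)
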