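import numpy as np
import pytest

from stagetx import SyntheticConfig, generate_dataset, make_grid


@pytest.fixture(scope="session")
def small_dataset():
    """One shared synthetic dataset with a clear planted signal."""
    cfg = SyntheticConfig(
        grid_shape=(20, 20, 20),
        voxel_size=3.0,
        smoothing_length=6.0,
        n_samples=150,
        n_genes=100,
        n_shared=10,
        n_stage_specific=5,
        coupling=0.5,
        seed=2024,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def tiny_grid():
    return make_grid((8, 8, 8), voxel_size=2.0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def brute_force_sphere_means(stat_map, samples, radius_mm):
    """Oracle: test the distance inequality for every in-mask voxel."""
    grid = stat_map.grid
    idx = grid.mask_indices()
    centers = grid.voxel_to_mm(idx)
    vals = stat_map.values
    out, included = [], []
    for coord in samples.coords:
        d = np.sqrt(((centers - coord) ** 2).sum(axis=1))
        inside = d <= radius_mm + 1e-9
        if inside.any():
            out.append(vals[inside].mean())
            included.append(True)
        else:
            out.append(np.nan)
            included.append(False)
    return np.array(out), np.array(included)


def brute_force_bh(p):
    """O(m^2) step-up oracle for Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, i in enumerate(order, start=1):
        # adjusted value = min over ranks >= this one of p_(j) * m / j
        candidates = [
            p[order[j - 1]] * m / j for j in range(rank_pos, m + 1)
        ]
        q[i] = min(1.0, min(candidates))
    return q


def brute_force_variogram(values, coords, edges):
    """Exhaustive pair-loop Matheron estimator on the given bin edges."""
    n = len(values)
    n_bins = len(edges) - 1
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d = np.sqrt(((coords[i] - coords[j]) ** 2).sum())
            if d > edges[-1] + 1e-12:
                continue
            b = min(int(np.searchsorted(edges, d, side="right") - 1), n_bins - 1)
            if d == 0.0:
                b = 0
            sums[b] += 0.5 * (values[i] - values[j]) ** 2
            counts[b] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = sums / counts
    return gamma, counts
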