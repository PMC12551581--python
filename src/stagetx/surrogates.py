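"""Variogram-matched spatial surrogates at sample locations.

A surrogate is a randomized copy of a spatial value vector that preserves the
empirical variogram (the spatial-autocorrelation signature) while scrambling
the topography. The algorithm follows the kernel-smoothed-permutation idea:
permute the values, smooth the permutation over each point's nearest
neighbors at several candidate bandwidths, and fit scale/offset so the
smoothed field's variogram matches the original's; unexplained variance is
refilled with white noise. Surrogates are generated at the sample-coordinate
level - the vectors that actually enter the gene-map correlations - which
keeps a 1000-iteration null ensemble cheap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import InvalidConfigError, InvalidInputError
from .neuro_maps import SampleTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SurrogateSpec:
    """Tuning knobs for variogram-matched surrogate generation.

    bandwidths
        Candidate Gaussian smoothing scales in mm. ``None`` derives a grid
        spanning 0.5x-4x the median nearest-neighbor distance in 5 steps
        (the sampling-resolution analogue of the voxel size).
    n_neighbors
        Neighbors per point used in kernel smoothing (capped at n-1).
    max_distance_fraction
        Variograms are fitted only up to this fraction of the maximum
        pairwise distance; long-range bins are noisy.
    resample_values
        If True, rank-remap each surrogate onto the original value multiset.
    """

    n_bins: int = 15
    max_distance_fraction: float = 0.5
    bandwidths: tuple[float, ...] | None = None
    n_neighbors: int = 50
    resample_values: bool = False
    seed: int | None = None

    def __post_init__(self):
        if self.n_bins < 3:
            raise InvalidConfigError(f"n_bins must be >= 3, got {self.n_bins}")
        if not (0 < self.max_distance_fraction <= 1):
            raise InvalidConfigError("max_distance_fraction must be in (0, 1]")
        if self.bandwidths is not None:
            bw = tuple(float(b) for b in self.bandwidths)
            if len(bw) == 0 or any(b <= 0 for b in bw):
                raise InvalidConfigError("bandwidths must be non-empty and positive")
            object.__setattr__(self, "bandwidths", bw)
        if self.n_neighbors < 1:
            raise InvalidConfigError("n_neighbors must be >= 1")


@dataclass
class Variogram:
    """Matheron empirical variogram: semivariance per distance bin."""

    bin_centers: np.ndarray  # mm
    semivariance: np.ndarray  # value^2 units; NaN for empty bins
    counts: np.ndarray  # pairs per bin

    def __post_init__(self):
        if np.any(np.diff(self.bin_centers) <= 0):
            raise InvalidInputError("variogram bins must be strictly ascending")
        with np.errstate(invalid="ignore"):
            if np.any(self.semivariance[self.counts > 0] < 0):
                raise InvalidInputError("semivariance must be non-negative")


def pairwise_distances(samples: "SampleTable | np.ndarray") -> np.ndarray:
    """Symmetric Euclidean mm distance matrix between sample coordinates."""
    coords = samples.coords if isinstance(samples, SampleTable) else np.asarray(samples, float)
    if coords.ndim != 2 or coords.shape[0] < 2:
        raise InvalidInputError("need at least 2 samples with coordinate rows")
    d = cdist(coords, coords)
    np.fill_diagonal(d, 0.0)
    return d


def _bin_edges(distances: np.ndarray, spec: SurrogateSpec) -> np.ndarray:
    dmax = float(distances.max()) * spec.max_distance_fraction
    if dmax <= 0:
        raise InvalidInputError("all pairwise distances are zero")
    return np.linspace(0.0, dmax, spec.n_bins + 1)


def _pair_bins(distances: np.ndarray, edges: np.ndarray):
    """Condensed pair indices and their bin assignment (-1 = beyond range)."""
    iu, ju = np.triu_indices(distances.shape[0], k=1)
    d = distances[iu, ju]
    idx = np.searchsorted(edges, d, side="right") - 1
    idx[d == 0.0] = 0
    # pairs at or beyond the last edge: keep exact-boundary pairs, drop the rest
    over = idx == len(edges) - 1
    idx[over] = np.where(np.isclose(d[over], edges[-1]), len(edges) - 2, -1)
    return iu, ju, idx


def _binned_semivariance(values, iu, ju, bin_idx, n_bins) -> np.ndarray:
    sq = 0.5 * (values[iu] - values[ju]) ** 2
    ok = bin_idx >= 0
    counts = np.bincount(bin_idx[ok], minlength=n_bins)
    sums = np.bincount(bin_idx[ok], weights=sq[ok], minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = sums / counts
    return gamma, counts


def empirical_variogram(
    values: np.ndarray,
    distances: np.ndarray,
    spec: SurrogateSpec | None = None,
) -> Variogram:
    """Matheron estimator on equal-width bins up to a fraction of max distance.

    Per bin b: semivariance = mean over pairs (i, j) in b of (v_i - v_j)^2 / 2.
    Empty bins carry NaN semivariance and zero count.
    """
    spec = spec or SurrogateSpec()
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise InvalidInputError("values must be finite")
    if values.shape[0] != distances.shape[0]:
        raise InvalidInputError("values length does not match distance matrix")
    edges = _bin_edges(distances, spec)
    iu, ju, bin_idx = _pair_bins(distances, edges)
    gamma, counts = _binned_semivariance(values, iu, ju, bin_idx, spec.n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return Variogram(bin_centers=centers, semivariance=gamma, counts=counts)


class SurrogateGenerator:
    """Reusable generator for surrogates of one value vector at fixed locations.

    All distance-dependent quantities (bin assignment of every pair, the
    target variogram, and the per-bandwidth kernel smoothing operators) are
    precomputed once, so each draw costs a permutation, a handful of
    matrix-vector products, and one least-squares fit per bandwidth.
    """

    def __init__(
        self,
        values: np.ndarray,
        distances: np.ndarray,
        spec: SurrogateSpec | None = None,
    ):
        self.spec = spec or SurrogateSpec()
        values = np.asarray(values, dtype=float)
        distances = np.asarray(distances, dtype=float)
        n = values.shape[0]
        if distances.shape != (n, n):
            raise InvalidInputError("distance matrix shape mismatch")
        self.n = n
        self.values = values
        self.mean = float(values.mean())
        self.sd = float(values.std())
        self.sorted_values = np.sort(values)

        off_diag = distances[~np.eye(n, dtype=bool)]
        self.degenerate = self.sd == 0.0 or np.ptp(off_diag) < 1e-12
        if self.sd == 0.0:
            return
        if self.degenerate:
            logger.warning(
                "degenerate distances (all equal): surrogates fall back to "
                "pure permutation"
            )
            return

        self.z = (values - self.mean) / self.sd
        edges = _bin_edges(distances, self.spec)
        self._iu, self._ju, self._bin_idx = _pair_bins(distances, edges)
        gamma, counts = _binned_semivariance(
            self.z, self._iu, self._ju, self._bin_idx, self.spec.n_bins
        )
        self._fit_bins = counts > 0
        self._target = gamma[self._fit_bins]

        if self.spec.bandwidths is None:
            d_off = distances + np.diag(np.full(n, np.inf))
            nn = np.min(d_off, axis=1)
            scale = float(np.median(nn))
            # geometric spacing resolves the short scales where the
            # variogram rises fastest
            bandwidths = tuple(scale * f for f in np.geomspace(0.5, 4.0, 5))
        else:
            bandwidths = self.spec.bandwidths
        self.bandwidths = bandwidths

        k = min(self.spec.n_neighbors, n - 1) + 1
        # row-wise k nearest neighbors including the point itself (so the
        # small-bandwidth limit degenerates to a pure permutation), then one
        # dense normalized kernel operator per candidate bandwidth
        order = np.argsort(distances, axis=1)[:, :k]
        rows = np.repeat(np.arange(n), k)
        cols = order.ravel()
        self._operators: list[np.ndarray] = []
        for h in bandwidths:
            w = np.zeros((n, n))
            w[rows, cols] = np.exp(-distances[rows, cols] ** 2 / (2.0 * h * h))
            norm = w.sum(axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            self._operators.append(w / norm)

    def __call__(self, rng: np.random.Generator) -> np.ndarray:
        """Draw one surrogate; mean and sd match the original's exactly."""
        if self.sd == 0.0:
            return self.values.copy()
        if self.degenerate:
            return rng.permutation(self.values)
        perm = rng.permutation(self.z)
        best = None
        for op in self._operators:
            smoothed = op @ perm
            gamma_s, _ = _binned_semivariance(
                smoothed, self._iu, self._ju, self._bin_idx, self.spec.n_bins
            )
            gs = gamma_s[self._fit_bins]
            design = np.column_stack([gs, np.ones_like(gs)])
            (beta, alpha), _, *_ = np.linalg.lstsq(design, self._target, rcond=None)
            if alpha < 0:
                # the offset is the white-noise (nugget) variance added to
                # the surrogate, so it cannot be negative; refit without it
                beta = float(gs @ self._target / (gs @ gs))
                alpha = 0.0
            rss = float(np.sum((beta * gs + alpha - self._target) ** 2))
            if best is None or rss < best[0]:
                best = (rss, beta, alpha, smoothed)
        _, beta, alpha, smoothed = best
        surr = np.sqrt(abs(beta)) * smoothed + np.sqrt(alpha) * rng.standard_normal(self.n)
        ssd = surr.std()
        if ssd == 0.0:
            surr = rng.permutation(self.z)
            ssd = surr.std()
        surr = (surr - surr.mean()) / ssd * self.sd + self.mean
        if self.spec.resample_values:
            ranks = np.argsort(np.argsort(surr))
            surr = self.sorted_values[ranks]
        return surr


def generate_surrogate(
    values: np.ndarray,
    distances: np.ndarray,
    spec: SurrogateSpec | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One variogram-matched surrogate of ``values`` at the given locations."""
    spec = spec or SurrogateSpec()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    return SurrogateGenerator(values, distances, spec)(rng)


def generate_surrogates(
    values: np.ndarray,
    distances: np.ndarray,
    n: int,
    spec: SurrogateSpec | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """(n, n_samples) matrix of independent surrogates from one seed."""
    spec = spec or SurrogateSpec()
    if n < 1:
        raise InvalidConfigError("need n >= 1 surrogates")
    gen = SurrogateGenerator(values, distances, spec)
    rng = np.random.default_rng(seed if seed is not None else spec.seed)
    return np.array([gen(rng) for _ in range(n)])
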