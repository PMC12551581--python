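"""Synthetic study data: smooth stage maps, samples, and planted expression.

Stands in for the study's raw inputs (case-control z-maps and an
AHBA-style expression matrix) so every downstream stage is testable with a
known ground truth. Stage maps are Gaussian random fields (kernel-smoothed
white noise); tissue samples sit at in-mask voxel centers; expression rows
are either pure noise or coupled to a map with a known variance fraction,
then squashed to [0, 1] by a scaled robust sigmoid to emulate normalized
microarray output.

Shared planted genes must track all three stage maps at once. Because a
single expression vector cannot correlate at full strength with three
independent fields, shared genes are coupled to the standardized mean of
the three standardized stage vectors; each stage then sees a correlation of
about sqrt(coupling / 3) at the planted gene. Stage-specific genes couple
to their own stage's vector at sqrt(coupling).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .association import ExpressionMatrix
from .errors import InvalidConfigError, InvalidInputError
from .neuro_maps import (
    STAGES,
    BrainGrid,
    SampleTable,
    StatMap,
    write_stat_map,
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition parameters for one synthetic dataset.

    Defaults are desk-scale analogues of the study's conditions: a smooth
    z-map per illness stage (6 mm smoothing on a ~96 mm brain-scale box at
    the standard 3 mm MNI resolution), a few hundred tissue samples, and a
    gene panel with a minority of genes coupled to the maps at a moderate
    effect size. The box must be large relative to the smoothing length so
    the field has enough spatial degrees of freedom for the three stage
    maps to be near-orthogonal, as the planted-coupling model assumes.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size: float = 3.0  # mm
    smoothing_length: float = 6.0  # mm, Gaussian kernel sigma of the maps
    n_samples: int = 300
    n_genes: int = 500
    n_shared: int = 20  # genes coupled to all three stage maps
    n_stage_specific: int = 10  # per stage, coupled to one map only
    coupling: float = 0.5  # fraction of a planted gene's variance from the map
    noise_sd: float = 1.0
    seed: int = 0
    ellipsoid_mask: bool = False
    jitter: bool = False  # sub-voxel jitter of sample coordinates

    def __post_init__(self):
        shape = tuple(int(s) for s in self.grid_shape)
        object.__setattr__(self, "grid_shape", shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise InvalidConfigError("grid_shape must be 3 positive ints")
        if self.voxel_size <= 0:
            raise InvalidConfigError("voxel_size must be positive")
        if self.smoothing_length < 0:
            raise InvalidConfigError("smoothing_length must be >= 0")
        for name in ("n_samples", "n_genes", "n_shared", "n_stage_specific"):
            if getattr(self, name) < 0 or (
                name in ("n_samples", "n_genes") and getattr(self, name) <= 0
            ):
                raise InvalidConfigError(f"{name} must be positive")
        if self.n_shared + 3 * self.n_stage_specific > self.n_genes:
            raise InvalidConfigError(
                "n_shared + 3 * n_stage_specific must not exceed n_genes"
            )
        if not (0.0 <= self.coupling <= 1.0):
            raise InvalidConfigError(f"coupling must be in [0, 1], got {self.coupling}")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GroundTruth:
    """Which genes were planted where, and the map values they were built from."""

    planted_shared: frozenset[str]
    planted_per_stage: dict[str, frozenset[str]]
    signs: dict[str, int]  # planted gene -> +1 / -1 coupling sign
    map_values_at_samples: dict[str, np.ndarray]  # stage -> standardized vector

    def __post_init__(self):
        sets = [self.planted_shared, *self.planted_per_stage.values()]
        total = sum(len(s) for s in sets)
        if len(frozenset().union(*sets)) != total:
            raise InvalidInputError("planted gene sets must be disjoint")

    @property
    def all_planted(self) -> frozenset[str]:
        return frozenset().union(self.planted_shared, *self.planted_per_stage.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in sorted(self.planted_shared):
            rows.append({"gene_id": g, "role": "shared", "sign": self.signs[g]})
        for stage, genes in self.planted_per_stage.items():
            for g in sorted(genes):
                rows.append({"gene_id": g, "role": stage, "sign": self.signs[g]})
        return pd.DataFrame(rows, columns=["gene_id", "role", "sign"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def make_grid(
    grid_shape: tuple[int, int, int],
    voxel_size: float,
    ellipsoid_mask: bool = False,
) -> BrainGrid:
    """Isotropic grid with a diagonal affine; mask all-true or ellipsoidal.

    Voxel (0, 0, 0) is centered at mm (0, 0, 0). The optional ellipsoid mask
    keeps voxels whose index lies inside the inscribed ellipsoid
    sum(((i - c) / a)^2) <= 1 with center and semi-axes (shape - 1) / 2.
    """
    shape = tuple(int(s) for s in grid_shape)
    if len(shape) != 3 or any(s <= 0 for s in shape):
        raise InvalidConfigError(f"grid shape must be 3 positive ints, got {shape}")
    if voxel_size <= 0:
        raise InvalidConfigError(f"voxel_size must be positive, got {voxel_size}")
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    if ellipsoid_mask:
        idx = np.indices(shape, dtype=float)
        terms = np.zeros(shape)
        for ax in range(3):
            c = (shape[ax] - 1) / 2.0
            a = max((shape[ax] - 1) / 2.0, 1e-12)
            terms += ((idx[ax] - c) / a) ** 2
        mask = terms <= 1.0
    else:
        mask = np.ones(shape, dtype=bool)
    return BrainGrid(shape=shape, affine=affine, mask=mask)


def simulate_smooth_map(
    grid: BrainGrid,
    smoothing_length: float,
    seed,
    stage_label: str | None = None,
) -> StatMap:
    """Gaussian random field: white noise smoothed by an isotropic kernel.

    ``smoothing_length`` is the Gaussian sigma in mm; 0 leaves the noise
    unsmoothed. In-mask values are standardized to mean 0, sd 1.
    """
    if smoothing_length < 0:
        raise InvalidConfigError("smoothing_length must be >= 0")
    if grid.n_mask == 0:
        raise InvalidInputError("grid mask is empty")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(grid.shape)
    voxel = float(np.abs(grid.affine[0, 0]))
    if smoothing_length > 0:
        # periodic boundaries keep the field stationary: every voxel has the
        # same smoothing support, so the marginal stays exactly Gaussian
        noise = gaussian_filter(noise, sigma=smoothing_length / voxel, mode="wrap")
    vals = noise[grid.mask]
    sd = vals.std()
    if sd == 0:
        raise InvalidInputError("degenerate field: zero variance over the mask")
    data = np.full(grid.shape, np.nan)
    data[grid.mask] = (vals - vals.mean()) / sd
    return StatMap(grid, data, stage_label=stage_label)


def place_samples(
    grid: BrainGrid,
    n_samples: int,
    seed,
    jitter: bool = False,
) -> SampleTable:
    """Samples at distinct in-mask voxel centers, uniform without replacement.

    With ``jitter`` the coordinates get sub-voxel uniform offsets (within
    +/- half a voxel per axis); the default keeps them at exact centers so
    sphere extraction has an exact brute-force oracle.
    """
    if n_samples <= 0:
        raise InvalidConfigError("n_samples must be positive")
    n_mask = grid.n_mask
    if n_samples > n_mask:
        raise InvalidConfigError(
            f"n_samples={n_samples} exceeds in-mask voxel count {n_mask}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n_mask, size=n_samples, replace=False)
    coords = grid.voxel_to_mm(grid.mask_indices()[chosen])
    if jitter:
        voxel = float(np.abs(grid.affine[0, 0]))
        coords = coords + rng.uniform(-voxel / 2, voxel / 2, size=coords.shape)
    width = len(str(n_samples))
    ids = [f"s{i + 1:0{width}d}" for i in range(n_samples)]
    return SampleTable(sample_ids=ids, coords=coords)


def _map_values_at_sample_voxels(stat_map: StatMap, samples: SampleTable) -> np.ndarray:
    """Map value at the voxel containing each sample (nearest-voxel lookup)."""
    vox = np.rint(stat_map.grid.mm_to_voxel(samples.coords)).astype(int)
    shape = stat_map.grid.shape
    if np.any(vox < 0) or np.any(vox >= np.asarray(shape)):
        raise InvalidInputError("sample coordinates fall outside the map grid")
    vals = stat_map.data[vox[:, 0], vox[:, 1], vox[:, 2]]
    if not np.all(np.isfinite(vals)):
        raise InvalidInputError("some samples fall on out-of-mask voxels")
    return vals


def robust_sigmoid(row: np.ndarray) -> np.ndarray:
    """Scaled robust sigmoid: squash via median/IQR, then min-max to [0, 1].

    Mirrors the normalization interface of AHBA-style preprocessing: outlier
    resistant (median and IQR rather than mean and sd) and bounded. A
    zero-IQR row maps to all 0.5. Strictly monotone wherever the IQR is
    positive, so gene-map Pearson correlations keep their sign and most of
    their magnitude; with the raw IQR as the sigmoid scale the transform is
    nearly linear over the bulk of a unimodal row (|r| to the input > 0.99
    for Gaussian-like data), squashing only the tails.
    """
    row = np.asarray(row, dtype=float)
    med = np.median(row)
    q75, q25 = np.percentile(row, [75, 25])
    iqr = q75 - q25
    if iqr <= 0:
        return np.full_like(row, 0.5)
    s = 1.0 / (1.0 + np.exp(-(row - med) / iqr))
    lo, hi = s.min(), s.max()
    if hi == lo:
        return np.full_like(row, 0.5)
    return (s - lo) / (hi - lo)


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise InvalidInputError("cannot standardize a constant vector")
    return (v - v.mean()) / sd


def simulate_expression(
    samples: SampleTable,
    stage_maps: dict[str, StatMap],
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Expression matrix with planted gene-map couplings and known truth.

    A planted gene's pre-normalization profile is
    ``sign * sqrt(coupling) * target + sqrt(1 - coupling) * noise`` where
    ``target`` is the standardized stage vector (stage-specific genes) or
    the standardized mean of the three stage vectors (shared genes), noise
    is N(0, noise_sd^2), and sign is +/-1 with equal probability per gene.
    Null genes are pure noise. Every row is then rescaled to [0, 1] by
    :func:`robust_sigmoid`.
    """
    missing = [s for s in STAGES if s not in stage_maps]
    if missing:
        raise InvalidInputError(f"missing stage maps: {missing}")
    n_samples = len(samples)
    stage_vecs = {
        s: _standardize(_map_values_at_sample_voxels(stage_maps[s], samples))
        for s in STAGES
    }
    shared_target = _standardize(np.mean([stage_vecs[s] for s in STAGES], axis=0))

    rng = np.random.default_rng(config.seed)
    width = len(str(config.n_genes))
    gene_ids = [f"g{i + 1:0{width}d}" for i in range(config.n_genes)]
    n_planted = config.n_shared + 3 * config.n_stage_specific
    planted_idx = rng.choice(config.n_genes, size=n_planted, replace=False)
    shared_idx = planted_idx[: config.n_shared]
    stage_idx = {
        s: planted_idx[
            config.n_shared + k * config.n_stage_specific:
            config.n_shared + (k + 1) * config.n_stage_specific
        ]
        for k, s in enumerate(STAGES)
    }
    signs_arr = rng.choice([-1, 1], size=n_planted)
    sign_of = {int(i): int(s) for i, s in zip(planted_idx, signs_arr)}

    sq_c = np.sqrt(config.coupling)
    sq_n = np.sqrt(1.0 - config.coupling)
    values = config.noise_sd * rng.standard_normal((config.n_genes, n_samples))
    for i in shared_idx:
        values[i] = sign_of[int(i)] * sq_c * shared_target + sq_n * values[i]
    for s in STAGES:
        for i in stage_idx[s]:
            values[i] = sign_of[int(i)] * sq_c * stage_vecs[s] + sq_n * values[i]
    values = np.apply_along_axis(robust_sigmoid, 1, values)

    expr = ExpressionMatrix(
        gene_ids=gene_ids, sample_ids=list(samples.sample_ids), values=values
    )
    truth = GroundTruth(
        planted_shared=frozenset(gene_ids[int(i)] for i in shared_idx),
        planted_per_stage={
            s: frozenset(gene_ids[int(i)] for i in stage_idx[s]) for s in STAGES
        },
        signs={gene_ids[int(i)]: sign_of[int(i)] for i in planted_idx},
        map_values_at_samples=stage_vecs,
    )
    return expr, truth


@dataclass
class SyntheticDataset:
    """Everything one synthetic run produces, in memory."""

    config: SyntheticConfig
    grid: BrainGrid
    stage_maps: dict[str, StatMap]
    samples: SampleTable
    expression: ExpressionMatrix
    truth: GroundTruth


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Deterministically generate maps, samples, and expression from one seed.

    The config seed fans out to independent child streams (one per stage
    map, one for sample placement, one for expression) via a fixed
    ``SeedSequence`` spawn order, so the whole dataset is reproducible from
    the single seed.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(5)
    grid = make_grid(config.grid_shape, config.voxel_size, config.ellipsoid_mask)
    stage_maps = {
        s: simulate_smooth_map(grid, config.smoothing_length, children[k], stage_label=s)
        for k, s in enumerate(STAGES)
    }
    samples = place_samples(grid, config.n_samples, children[3], jitter=config.jitter)
    expr_config = dataclasses.replace(
        config, seed=int(children[4].generate_state(1, dtype=np.uint32)[0])
    )
    expr, truth = simulate_expression(samples, stage_maps, expr_config)
    return SyntheticDataset(
        config=config,
        grid=grid,
        stage_maps=stage_maps,
        samples=samples,
        expression=expr,
        truth=truth,
    )


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict:
    """Write maps (NIfTI), tables (TSV), and a JSON run manifest; return it."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for stage, m in ds.stage_maps.items():
        p = out / f"map_{stage}.nii.gz"
        write_stat_map(m, p)
        paths[f"map_{stage}"] = str(p)
    ds.samples.to_tsv(out / "samples.tsv")
    paths["samples"] = str(out / "samples.tsv")
    ds.expression.to_tsv(out / "expression.tsv")
    paths["expression"] = str(out / "expression.tsv")
    ds.truth.to_tsv(out / "ground_truth.tsv")
    paths["ground_truth"] = str(out / "ground_truth.tsv")
    manifest = {"config": ds.config.to_dict(), "paths": paths}
    # the on-disk copy stores paths relative to the dataset directory so the
    # file is location-independent (and byte-identical across reruns)
    rel = {k: str(Path(p).name) for k, p in paths.items()}
    with open(out / "synthetic_manifest.json", "w") as fh:
        json.dump({"config": ds.config.to_dict(), "paths": rel}, fh, indent=2)
    return manifest
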