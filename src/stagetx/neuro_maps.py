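"""Statistical brain maps, tissue-sample tables, and sphere-based value extraction.

Maps live on a voxel grid with a NIfTI-style affine mapping 0-based voxel
indices to millimetre coordinates (MNI space for real data). All user-facing
coordinates are in mm; voxel indexing is internal. Out-of-mask voxels are
stored as NaN so a map and its mask round-trip through a single NIfTI file.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import FormatError, InvalidConfigError, InvalidInputError

#: Illness-stage labels used throughout the pipeline, in canonical order.
STAGES: tuple[str, str, str] = ("high_risk", "first_episode", "chronic")

#: FWHM of a Gaussian = GAUSSIAN_FWHM_TO_SIGMA * sigma.
GAUSSIAN_FWHM_TO_SIGMA = float(np.sqrt(8.0 * np.log(2.0)))  # 2.35482


@dataclass(frozen=True)
class BrainGrid:
    """A 3D voxel grid with an invertible voxel-to-mm affine and a boolean mask."""

    shape: tuple[int, int, int]
    affine: np.ndarray  # 4x4, voxel index -> mm
    mask: np.ndarray  # boolean, same shape as grid

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise InvalidConfigError(f"grid shape must be 3 positive ints, got {shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise InvalidConfigError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise InvalidConfigError("affine is not invertible")
        object.__setattr__(self, "affine", affine)
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != shape:
            raise InvalidConfigError(
                f"mask shape {mask.shape} does not match grid shape {shape}"
            )
        object.__setattr__(self, "mask", mask)

    @property
    def n_mask(self) -> int:
        return int(self.mask.sum())

    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        """Map (n, 3) voxel indices to (n, 3) mm coordinates of voxel centers."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def mm_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map mm coordinates to (fractional) voxel indices."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def mask_indices(self) -> np.ndarray:
        """(n_mask, 3) voxel indices of in-mask voxels, C order."""
        return np.argwhere(self.mask)

    def mask_centers_mm(self) -> np.ndarray:
        """(n_mask, 3) mm coordinates of in-mask voxel centers."""
        return self.voxel_to_mm(self.mask_indices())

    def same_grid(self, other: "BrainGrid", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.affine, other.affine, atol=atol)
            and np.array_equal(self.mask, other.mask)
        )


@dataclass
class StatMap:
    """A per-voxel statistic map (z units) on a :class:`BrainGrid`.

    ``data`` is the full 3D array; out-of-mask voxels are NaN. ``values``
    exposes the in-mask vector in C order of the mask indices.
    """

    grid: BrainGrid
    data: np.ndarray
    stage_label: str | None = None

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.shape != self.grid.shape:
            raise FormatError(
                f"data shape {data.shape} does not match grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(data[self.grid.mask])):
            raise InvalidInputError("non-finite values at in-mask voxels")
        out = data.copy()
        out[~self.grid.mask] = np.nan
        self.data = out

    @property
    def values(self) -> np.ndarray:
        return self.data[self.grid.mask]

    def with_values(self, values: np.ndarray, stage_label: str | None = None) -> "StatMap":
        """New map on the same grid with the given in-mask values."""
        values = np.asarray(values, dtype=float)
        if values.shape != (self.grid.n_mask,):
            raise InvalidInputError("value vector length does not match mask size")
        data = np.full(self.grid.shape, np.nan)
        data[self.grid.mask] = values
        return StatMap(self.grid, data, stage_label or self.stage_label)


@dataclass
class SampleTable:
    """Tissue samples: unique string ids and mm coordinates in map space."""

    sample_ids: list[str]
    coords: np.ndarray  # (n, 3) mm

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise InvalidInputError("sample ids are not unique")
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape != (len(self.sample_ids), 3):
            raise InvalidInputError(
                f"coords must be (n_samples, 3); got {coords.shape} for "
                f"{len(self.sample_ids)} ids"
            )
        self.coords = coords

    def __len__(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "mni_x": self.coords[:, 0],
                "mni_y": self.coords[:, 1],
                "mni_z": self.coords[:, 2],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleTable":
        df = pd.read_csv(path, sep="\t")
        required = {"sample_id", "mni_x", "mni_y", "mni_z"}
        if not required.issubset(df.columns):
            raise FormatError(
                f"sample table {path} must have columns {sorted(required)}"
            )
        return cls(
            sample_ids=df["sample_id"].astype(str).tolist(),
            coords=df[["mni_x", "mni_y", "mni_z"]].to_numpy(float),
        )


@dataclass
class SampleValues:
    """Per-sample mean map values; ``included`` is False for empty spheres."""

    sample_ids: list[str]
    values: np.ndarray  # NaN where excluded
    included: np.ndarray  # boolean
    stage_label: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.included = np.asarray(self.included, dtype=bool)
        n = len(self.sample_ids)
        if self.values.shape != (n,) or self.included.shape != (n,):
            raise InvalidInputError("values/included length mismatch with sample ids")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "value": self.values,
                "included": self.included,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, stage_label: str | None = None) -> "SampleValues":
        df = pd.read_csv(path, sep="\t")
        return cls(
            sample_ids=df["sample_id"].astype(str).tolist(),
            values=df["value"].to_numpy(float),
            included=df["included"].to_numpy(bool),
            stage_label=stage_label,
        )


def write_stat_map(stat_map: StatMap, path: str | Path) -> None:
    """Write a map as NIfTI-1 (float32); out-of-mask voxels are NaN."""
    img = nib.Nifti1Image(stat_map.data.astype(np.float32), stat_map.grid.affine)
    nib.save(img, str(path))


def read_stat_map(
    path: str | Path,
    mask: np.ndarray | None = None,
    stage_label: str | None = None,
) -> StatMap:
    """Read a 3D NIfTI volume as a :class:`StatMap`.

    Without an explicit ``mask``, finite voxels define the mask (the
    convention :func:`write_stat_map` uses). A mask whose shape does not
    match the volume is a format error.
    """
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=float)
    except (OSError, nib.filebasedimages.ImageFileError) as exc:
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.squeeze(data) if data.ndim == 4 and data.shape[-1] == 1 else data
    if data.ndim != 3:
        raise FormatError(f"expected a 3D volume, got shape {data.shape}")
    if mask is None:
        mask = np.isfinite(data)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != data.shape:
            raise FormatError(
                f"mask shape {mask.shape} does not match volume shape {data.shape}"
            )
    if not mask.any():
        raise FormatError(f"volume {path} has an empty mask")
    grid = BrainGrid(shape=data.shape, affine=np.asarray(img.affine), mask=mask)
    data = data.copy()
    data[~mask] = np.nan
    return StatMap(grid, data, stage_label=stage_label)


def extract_sample_values(
    stat_map: StatMap,
    samples: SampleTable,
    radius_mm: float = 6.0,
) -> SampleValues:
    """Mean map value in a sphere of ``radius_mm`` around each sample.

    A voxel belongs to a sample's sphere when the Euclidean distance from
    its center to the sample coordinate is <= ``radius_mm`` (boundary
    inclusive) and it is in-mask. Samples whose sphere contains no in-mask
    voxel are flagged excluded; if every sample is excluded the extraction
    is an error.
    """
    if radius_mm <= 0:
        raise InvalidConfigError(f"radius_mm must be > 0, got {radius_mm}")
    centers = stat_map.grid.mask_centers_mm()
    if centers.shape[0] == 0:
        raise InvalidInputError("map has an empty mask")
    in_mask_values = stat_map.values
    tree = cKDTree(centers)
    # small epsilon keeps the boundary inclusive under float round-off
    neighbor_lists = tree.query_ball_point(samples.coords, r=radius_mm * (1 + 1e-12))
    n = len(samples)
    values = np.full(n, np.nan)
    included = np.zeros(n, dtype=bool)
    for i, idx in enumerate(neighbor_lists):
        if idx:
            values[i] = in_mask_values[idx].mean()
            included[i] = True
    if not included.any():
        raise InvalidInputError("no sample has any in-mask voxel within the sphere")
    return SampleValues(
        sample_ids=list(samples.sample_ids),
        values=values,
        included=included,
        stage_label=stat_map.stage_label,
    )


def peak_to_map(
    peaks: Sequence[tuple[Sequence[float], float]],
    grid: BrainGrid,
    kernel_fwhm_mm: float,
) -> StatMap:
    """Build a map as a sum of signed Gaussian kernels at peak coordinates.

    Each peak is ``((x, y, z) mm, weight)``; the kernel is
    ``weight * exp(-d^2 / (2 sigma^2))`` with ``sigma = FWHM / 2.3548``.
    Convenient for constructing toy stage maps from published coordinate
    tables.
    """
    if kernel_fwhm_mm <= 0:
        raise InvalidConfigError("kernel_fwhm_mm must be > 0")
    if len(peaks) == 0:
        raise InvalidInputError("peak list is empty")
    sigma = kernel_fwhm_mm / GAUSSIAN_FWHM_TO_SIGMA
    centers = grid.mask_centers_mm()
    values = np.zeros(centers.shape[0])
    for coord, weight in peaks:
        coord = np.asarray(coord, dtype=float).reshape(3)
        d2 = np.sum((centers - coord) ** 2, axis=1)
        values += float(weight) * np.exp(-d2 / (2.0 * sigma**2))
    data = np.full(grid.shape, np.nan)
    data[grid.mask] = values
    return StatMap(grid, data)


def rank_term_correlations(
    stat_map: StatMap,
    term_maps: Mapping[str, StatMap],
    top_k: int = 5,
) -> list[tuple[str, float]]:
    """Rank term maps by |Pearson r| with the input map over in-mask voxels.

    Mirrors meta-analytic cognitive decoding: each term map (e.g. a
    Neurosynth association map supplied as a file) is correlated voxel-wise
    with the input and the strongest ``top_k`` terms are returned, sorted by
    absolute correlation descending. Positive- and negative-part maps are
    expected to be decoded in separate calls.
    """
    if not term_maps:
        raise InvalidInputError("no term maps supplied")
    base = stat_map.values
    results: list[tuple[str, float]] = []
    for label, tmap in term_maps.items():
        if not stat_map.grid.same_grid(tmap.grid):
            raise InvalidInputError(f"term map '{label}' is not on the input map's grid")
        r = float(np.corrcoef(base, tmap.values)[0, 1])
        results.append((label, r))
    results.sort(key=lambda t: -abs(t[1]))
    return results[:top_k]
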