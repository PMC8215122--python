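"""Likelihood-map construction: Gaussian focus kernels, per-study maps,
condition mean maps, and the joint (summed) dual-condition map.

Each reported peak is modelled as an isotropic 3D Gaussian probability
distribution centered on its coordinate; the per-voxel mass is the density
at the voxel center times the voxel volume, so an interior kernel's mass
sums to ~1 over the grid (midpoint quadrature). Within a study, multiple
foci combine by probabilistic union, L(v) = 1 − Π_f (1 − m_f(v)): the
probability that at least one of the study's reported effects lies at v.
Studies of one condition are averaged voxelwise — null-result studies enter
as all-zero maps and dilute the mean, which is what removes bias toward the
condition with more reported foci. The two condition means are summed into
the joint map, the dual-disorder test statistic (range [0, 2]).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import nibabel as nib
import numpy as np

from .stereotax import SpaceTransform, VoxelGrid, place_foci
from .study_io import Direction, FocusCoordinate, StudyRecord

__all__ = [
    "KernelSpec",
    "LikelihoodMap",
    "focus_probability_map",
    "study_map",
    "condition_mean_map",
    "joint_map",
]

_FWHM_TO_SIGMA = 1.0 / math.sqrt(8.0 * math.log(2.0))


@dataclass(frozen=True)
class KernelSpec:
    """Isotropic Gaussian kernel for focus uncertainty.

    ``fwhm`` is in mm; the kernel is truncated at ``truncation_sigmas``·σ
    (default 3.5σ, which keeps 99.3% of a 3D Gaussian's mass — note the 1D
    two-sided rule of thumb does not transfer to 3D, where 3σ keeps only
    97.1%).
    """

    fwhm: float = 10.0
    truncation_sigmas: float = 3.5

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be > 0")
        if self.truncation_sigmas <= 0:
            raise ValueError("truncation_sigmas must be > 0")

    @property
    def sigma(self) -> float:
        """Gaussian sd in mm: fwhm / sqrt(8 ln 2)."""
        return self.fwhm * _FWHM_TO_SIGMA

    @property
    def truncation_radius(self) -> float:
        """mm beyond which the kernel is exactly zero."""
        return self.truncation_sigmas * self.sigma


@dataclass(frozen=True)
class LikelihoodMap:
    """A per-voxel probability map on a grid, with provenance.

    Values are zero outside the mask. Study and condition-mean maps lie in
    [0, 1]; the joint map in [0, 2]. An all-zero map is valid ("empty map",
    a null-result study).
    """

    grid: VoxelGrid
    values: np.ndarray
    provenance: str
    direction: Direction

    def __post_init__(self) -> None:
        if self.values.shape != tuple(self.grid.shape):
            raise ValueError("map shape does not match grid")

    def masked_values(self) -> np.ndarray:
        """1-D vector of values at in-mask voxels."""
        return self.values[self.grid.mask]

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.values.astype(np.float32), self.grid.affine)


def _same_grid(a: VoxelGrid, b: VoxelGrid) -> bool:
    return (
        a.shape == b.shape
        and np.allclose(a.affine, b.affine)
        and np.array_equal(a.mask, b.mask)
    )


# ---------------------------------------------------------------------------
# Kernel evaluation
# ---------------------------------------------------------------------------

def _gauss_amplitude(sigma: float) -> float:
    return (2.0 * math.pi * sigma * sigma) ** -1.5


def _focus_patch(
    grid: VoxelGrid, focus_mm: np.ndarray, kernel: KernelSpec
) -> tuple[tuple[slice, slice, slice], np.ndarray] | None:
    """Per-voxel kernel mass on the subcube around one focus.

    Returns (slices into the grid, mass values on the window, already
    mask-zeroed), or None when the window misses the grid entirely.
    Evaluation is exact at voxel centers relative to the focus mm position.
    """
    inv = np.linalg.inv(grid.affine)
    ijk_f = focus_mm @ inv[:3, :3].T + inv[:3, 3]
    r_vox = int(math.ceil(kernel.truncation_radius / grid.voxel_size))
    center = np.rint(ijk_f).astype(int)
    lo = np.maximum(center - r_vox, 0)
    hi = np.minimum(center + r_vox + 1, np.array(grid.shape))
    if np.any(lo >= hi):
        return None
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    ax = [np.arange(lo[d], hi[d]) * grid.voxel_size + grid.affine[d, 3] for d in range(3)]
    dx = ax[0][:, None, None] - focus_mm[0]
    dy = ax[1][None, :, None] - focus_mm[1]
    dz = ax[2][None, None, :] - focus_mm[2]
    d2 = dx * dx + dy * dy + dz * dz
    sigma = kernel.sigma
    vals = _gauss_amplitude(sigma) * np.exp(-0.5 * d2 / (sigma * sigma))
    vals *= grid.voxel_volume
    vals[d2 > kernel.truncation_radius ** 2] = 0.0
    vals *= grid.mask[sl]
    return sl, vals


def kernel_cube(grid: VoxelGrid, kernel: KernelSpec) -> np.ndarray:
    """Kernel mass on a (2R+1)³ voxel-offset cube for voxel-centered foci.

    Used by the fast permutation path, where relocated foci always sit at
    voxel centers; identical to :func:`_focus_patch` values in that case
    (before mask zeroing).
    """
    r_vox = int(math.ceil(kernel.truncation_radius / grid.voxel_size))
    off = np.arange(-r_vox, r_vox + 1) * grid.voxel_size
    d2 = (
        off[:, None, None] ** 2
        + off[None, :, None] ** 2
        + off[None, None, :] ** 2
    )
    sigma = kernel.sigma
    cube = _gauss_amplitude(sigma) * np.exp(-0.5 * d2 / (sigma * sigma))
    cube *= grid.voxel_volume
    cube[d2 > kernel.truncation_radius ** 2] = 0.0
    return cube


def focus_probability_map(
    focus: FocusCoordinate, grid: VoxelGrid, kernel: KernelSpec
) -> np.ndarray:
    """Full-grid per-voxel probability mass for a single MNI focus."""
    out = grid.new_map()
    patch = _focus_patch(grid, focus.xyz, kernel)
    if patch is not None:
        sl, vals = patch
        out[sl] = vals
    return out


# ---------------------------------------------------------------------------
# Map construction
# ---------------------------------------------------------------------------

def study_map(
    study: StudyRecord,
    grid: VoxelGrid,
    kernel: KernelSpec,
    direction: Direction,
    transform: SpaceTransform | None = None,
) -> LikelihoodMap:
    """Per-study likelihood map for one effect direction.

    Foci of the other direction are ignored; the study's selected foci are
    converted to MNI, snapped into the mask per the placement policy, and
    combined by probabilistic union. Zero usable foci yield the empty map.
    """
    report = place_foci(grid, study.foci_with_direction(direction), transform)
    comp = np.ones(grid.shape)
    for f in report.placed:
        patch = _focus_patch(grid, f.xyz, kernel)
        if patch is None:
            continue
        sl, vals = patch
        comp[sl] *= 1.0 - vals
    values = 1.0 - comp
    values[~grid.mask] = 0.0
    return LikelihoodMap(grid=grid, values=values, provenance=study.study_id,
                         direction=direction)


def condition_mean_map(
    maps: Sequence[LikelihoodMap], label: str | None = None
) -> LikelihoodMap:
    """Voxelwise unweighted mean of one condition's study maps.

    Empty (all-zero) maps stay in the denominator: a condition with many
    null-result studies is pulled toward zero rather than being represented
    only by its positive studies.
    """
    if not maps:
        raise ValueError("need at least one study map")
    first = maps[0]
    for m in maps[1:]:
        if not _same_grid(m.grid, first.grid):
            raise ValueError("study maps are on different grids")
        if m.direction != first.direction:
            raise ValueError("study maps mix effect directions")
    values = np.mean([m.values for m in maps], axis=0)
    return LikelihoodMap(
        grid=first.grid,
        values=values,
        provenance=label if label is not None else "condition-mean",
        direction=first.direction,
    )


def joint_map(mean_a: LikelihoodMap, mean_b: LikelihoodMap) -> LikelihoodMap:
    """Sum of the two condition mean maps — the dual-disorder statistic."""
    if not _same_grid(mean_a.grid, mean_b.grid):
        raise ValueError("mean maps are on different grids")
    if mean_a.direction != mean_b.direction:
        raise ValueError("mean maps mix effect directions")
    return LikelihoodMap(
        grid=mean_a.grid,
        values=mean_a.values + mean_b.values,
        provenance="joint",
        direction=mean_a.direction,
    )
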