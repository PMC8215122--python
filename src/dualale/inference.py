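"""Permutation inference on the joint likelihood map.

The null hypothesis is spatial randomness: each permutation relocates every
focus independently and uniformly over masked voxel centers, preserving each
study's focus count and condition membership, then rebuilds the
study → condition-mean → joint maps exactly as for the observed data. Joint
values at all masked voxels across all permutations are pooled into one
empirical null (classic ALE pooling), giving a voxel-level p-value
p(v) = (1 + #{null ≥ J(v)}) / (1 + N) — the add-one estimator keeps p > 0
and valid. Voxelwise significance is then controlled by Benjamini–Hochberg
FDR (default q = 0.05), and surviving voxels are grouped into connected
clusters (default 18-connectivity) with a minimum-volume filter
(default 100 mm³).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from statsmodels.stats.multitest import multipletests

from .ale_maps import KernelSpec, LikelihoodMap, kernel_cube
from .stereotax import SpaceTransform, VoxelGrid, place_foci, voxel_to_mm
from .study_io import Direction, StudyRecord

__all__ = [
    "NullDistribution",
    "ClusterResult",
    "permute_null",
    "p_map",
    "fdr_threshold",
    "extract_clusters",
    "uniformity_pit",
]

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class NullDistribution:
    """Pooled empirical null of joint-map values over masked voxels.

    ``values`` is the sorted (ascending) float32 sample of all masked joint
    values across all permutations; its length is
    n_permutations × n_masked_voxels.
    """

    values: np.ndarray
    n_permutations: int
    n_masked: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if len(self.values) != self.n_permutations * self.n_masked:
            raise ValueError("null sample size != n_permutations * n_masked")

    @property
    def n_total(self) -> int:
        return len(self.values)

    def count_ge(self, x: np.ndarray) -> np.ndarray:
        """#{null values ≥ x}, vectorized (x compared in float32)."""
        x32 = np.asarray(x, dtype=np.float32)
        return self.n_total - np.searchsorted(self.values, x32, side="left")


def _stamp_product(
    comp: np.ndarray,
    pos: np.ndarray,
    one_minus_cube: np.ndarray,
    r_vox: int,
    shape: tuple[int, int, int],
) -> None:
    """Multiply (1 − kernel mass) into ``comp`` around voxel ``pos``, clipped."""
    lo = pos - r_vox
    hi = pos + r_vox + 1
    glo = np.maximum(lo, 0)
    ghi = np.minimum(hi, shape)
    klo = glo - lo
    khi = one_minus_cube.shape[0] - (hi - ghi)
    comp[glo[0]:ghi[0], glo[1]:ghi[1], glo[2]:ghi[2]] *= one_minus_cube[
        klo[0]:khi[0], klo[1]:khi[1], klo[2]:khi[2]
    ]


def permute_null(
    studies: Sequence[StudyRecord],
    grid: VoxelGrid,
    kernel: KernelSpec,
    direction: Direction,
    n_permutations: int,
    seed: int,
    transform: SpaceTransform | None = None,
) -> NullDistribution:
    """Sample the spatial-randomness null of the joint map.

    Foci are relocated to uniformly drawn masked voxel centers (matching the
    granularity of map construction and keeping the draw reproducible from
    integer RNG output); per-study focus counts — as actually placed for the
    observed analysis — and per-study condition labels are preserved.
    Deterministic given ``seed``.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    by_cond: dict[str, list[int]] = {}
    counts: list[int] = []
    for s in studies:
        report = place_foci(grid, s.foci_with_direction(direction), transform)
        counts.append(len(report.placed))
        by_cond.setdefault(s.condition, []).append(len(counts) - 1)
    if not by_cond:
        raise ValueError("no studies supplied")

    rng = np.random.default_rng(seed)
    masked_ijk = grid.masked_indices()
    n_masked = len(masked_ijk)
    mask_flat = np.flatnonzero(grid.mask.ravel())

    cube = kernel_cube(grid, kernel)
    one_minus_cube = 1.0 - cube
    r_vox = (cube.shape[0] - 1) // 2
    shape = tuple(grid.shape)

    comp = np.empty(shape)           # per-study complement buffer Π(1 − m)
    sum_comp: dict[str, np.ndarray] = {c: np.empty(shape) for c in by_cond}
    out = np.empty(n_permutations * n_masked, dtype=np.float32)

    for p in range(n_permutations):
        for c in by_cond:
            sum_comp[c].fill(0.0)
        for cond, study_idx in by_cond.items():
            for si in study_idx:
                comp.fill(1.0)
                k = counts[si]
                if k:
                    draws = rng.integers(0, n_masked, size=k)
                    for d in draws:
                        _stamp_product(comp, masked_ijk[d], one_minus_cube,
                                       r_vox, shape)
                sum_comp[cond] += comp
        # joint at masked voxels: Σ_c mean_c = Σ_c (1 − Σ_s comp_s / n_c)
        joint_flat = np.zeros(n_masked)
        for cond, study_idx in by_cond.items():
            joint_flat += 1.0 - sum_comp[cond].ravel()[mask_flat] / len(study_idx)
        out[p * n_masked:(p + 1) * n_masked] = joint_flat
    out.sort()
    return NullDistribution(values=out, n_permutations=n_permutations,
                            n_masked=n_masked, seed=seed)


def p_map(joint: LikelihoodMap, null: NullDistribution) -> np.ndarray:
    """Per-voxel permutation p-values, p(v) = (1 + #{null ≥ J(v)}) / (1 + N).

    Returns a full 3D array; voxels outside the mask are set to 1.
    """
    if null.n_total == 0:
        raise ValueError("empty null distribution")
    if null.n_masked != joint.grid.n_masked:
        raise ValueError("null was built on a different grid")
    p = np.ones(joint.grid.shape)
    j_masked = joint.masked_values()
    p[joint.grid.mask] = (1.0 + null.count_ge(j_masked)) / (1.0 + null.n_total)
    return p


def fdr_threshold(
    p_values: np.ndarray, grid: VoxelGrid, q: float = 0.05
) -> np.ndarray:
    """Benjamini–Hochberg step-up over masked voxels at level ``q``.

    Returns the boolean significance map (False everywhere outside the mask).
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    pm = p_values[grid.mask]
    if pm.size == 0:
        raise ValueError("empty p-map")
    reject, _, _, _ = multipletests(pm, alpha=q, method="fdr_bh")
    sig = np.zeros(grid.shape, dtype=bool)
    sig[grid.mask] = reject
    return sig


@dataclass(frozen=True, eq=False)
class ClusterResult:
    """A suprathreshold connected component of the joint map."""

    cluster_id: int
    voxels: np.ndarray          # (n, 3) int ijk
    volume_mm3: float
    peak_ijk: tuple[int, int, int]
    peak_mni: np.ndarray        # mm
    peak_value: float
    sum_value: float
    mean_value: float
    contributions: Mapping[str, float] | None = None

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)

    def with_contributions(self, pct: Mapping[str, float]) -> "ClusterResult":
        return replace(self, contributions=dict(pct))


def extract_clusters(
    sig: np.ndarray,
    joint: LikelihoodMap,
    min_cluster_mm3: float = 100.0,
    connectivity: int = 18,
) -> list[ClusterResult]:
    """Connected components of the significance map, volume-filtered.

    Components smaller than ``min_cluster_mm3`` are discarded (the filter is
    in mm³, so it is resolution-independent). The peak is the max-joint voxel
    (ties broken toward the smallest flat voxel index); clusters come back
    sorted by descending volume, ids 1..n.
    """
    if min_cluster_mm3 < 0:
        raise ValueError("min_cluster_mm3 must be >= 0")
    try:
        rank = _CONNECTIVITY_RANK[connectivity]
    except KeyError:
        raise ValueError("connectivity must be one of 6, 18, 26") from None
    grid = joint.grid
    structure = ndimage.generate_binary_structure(3, rank)
    labels, n_labels = ndimage.label(sig, structure=structure)
    vox_vol = grid.voxel_volume

    results: list[ClusterResult] = []
    for lab in range(1, n_labels + 1):
        inside = labels == lab
        n_vox = int(inside.sum())
        volume = n_vox * vox_vol
        if volume < min_cluster_mm3:
            continue
        j_vals = np.where(inside, joint.values, -np.inf)
        flat_peak = int(np.argmax(j_vals))  # first occurrence = smallest index
        peak_ijk = np.unravel_index(flat_peak, grid.shape)
        results.append(
            ClusterResult(
                cluster_id=0,
                voxels=np.argwhere(inside),
                volume_mm3=float(volume),
                peak_ijk=tuple(int(v) for v in peak_ijk),
                peak_mni=voxel_to_mm(grid, peak_ijk),
                peak_value=float(joint.values[peak_ijk]),
                sum_value=float(joint.values[inside].sum()),
                mean_value=float(joint.values[inside].mean()),
            )
        )
    results.sort(key=lambda c: -c.volume_mm3)
    return [replace(c, cluster_id=i) for i, c in enumerate(results, start=1)]


def uniformity_pit(
    joint: LikelihoodMap,
    null: NullDistribution,
    kernel: KernelSpec,
    seed: int = 0,
) -> np.ndarray:
    """Randomized probability-integral-transform values for null calibration.

    The production p-values are deliberately conservative (add-one, with an
    atom at p = 1 wherever J = 0), so they cannot be uniform. For checking
    calibration, this diagnostic instead computes, at a spatially thinned
    voxel subsample (spacing > 2× the kernel truncation radius, so the
    subsampled voxels share no kernel support and are effectively
    independent), the randomized PIT
    u(v) = (#{null < J(v)} + U · (#{null = J(v)} + 1)) / (N + 1), U~Unif(0,1),
    which is exactly Uniform(0,1) in aggregate when the observed map is
    exchangeable with the permuted ones. A Kolmogorov–Smirnov statistic on
    the returned values against Uniform(0,1) is the calibration check.
    """
    grid = joint.grid
    step = int(math.ceil(2.0 * kernel.truncation_radius / grid.voxel_size)) + 1
    thin = np.zeros(grid.shape, dtype=bool)
    thin[::step, ::step, ::step] = True
    sel = thin & grid.mask
    x = joint.values[sel].astype(np.float32)
    lo = np.searchsorted(null.values, x, side="left")
    hi = np.searchsorted(null.values, x, side="right")
    rng = np.random.default_rng(seed)
    u = rng.random(len(x))
    return (lo + u * (hi - lo + 1)) / (null.n_total + 1)
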