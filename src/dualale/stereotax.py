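"""Voxel grids and stereotactic coordinate handling.

The sampling lattice for all likelihood maps is a regular isotropic voxel
grid over a bounding box in MNI mm space, restricted by a binary brain mask.
The mask comes either from a NIfTI volume (resampled nearest-neighbour onto
the grid) or from a built-in ellipsoid approximating adult brain extent.

Foci reported in Talairach space are converted to MNI with the Lancaster
"tal2icbm" affine (the pipeline-neutral pooled variant), the standard choice
in coordinate-based meta-analysis; the transform is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .study_io import FocusCoordinate, Space

__all__ = [
    "MNI152_BOUNDS",
    "SpaceTransform",
    "lancaster_transform",
    "VoxelGrid",
    "make_grid",
    "to_mni",
    "mm_to_voxel",
    "voxel_to_mm",
    "place_foci",
]

#: Standard MNI152 bounding box, mm: ((x0, x1), (y0, y1), (z0, z1)).
MNI152_BOUNDS = ((-90.0, 90.0), (-126.0, 90.0), (-72.0, 108.0))

# Lancaster et al. pooled icbm→Talairach affine ("icbm_other2tal"); the
# Talairach→MNI direction used here is its inverse.
_ICBM_OTHER2TAL = np.array(
    [
        [0.9357, 0.0029, -0.0072, -1.0423],
        [-0.0065, 0.9396, -0.0726, -1.3940],
        [0.0103, 0.0752, 0.8967, 3.6475],
        [0.0, 0.0, 0.0, 1.0],
    ]
)


@dataclass(frozen=True)
class SpaceTransform:
    """Affine mapping Talairach mm → MNI mm (with cached inverse)."""

    tal_to_mni: np.ndarray
    name: str = "custom"

    def __post_init__(self) -> None:
        m = np.asarray(self.tal_to_mni, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("transform must be a 4x4 affine")
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("transform affine is singular")
        object.__setattr__(self, "tal_to_mni", m)

    @property
    def mni_to_tal(self) -> np.ndarray:
        return np.linalg.inv(self.tal_to_mni)

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        return (self.tal_to_mni @ np.append(xyz, 1.0))[:3]

    def apply_inverse(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        return (self.mni_to_tal @ np.append(xyz, 1.0))[:3]


def lancaster_transform() -> SpaceTransform:
    """The default Talairach→MNI transform (inverse Lancaster pooled affine)."""
    return SpaceTransform(np.linalg.inv(_ICBM_OTHER2TAL), name="tal2icbm_other")


def to_mni(
    focus: FocusCoordinate, transform: SpaceTransform | None = None
) -> FocusCoordinate:
    """Return the focus in MNI space; MNI input passes through unchanged."""
    if focus.space == Space.MNI:
        return focus
    if focus.space == Space.TALAIRACH:
        if transform is None:
            transform = lancaster_transform()
        x, y, z = transform.apply(focus.xyz)
        return FocusCoordinate(
            x=float(x), y=float(y), z=float(z),
            space=Space.MNI, direction=focus.direction,
        )
    raise ValueError(f"unknown coordinate space: {focus.space!r}")


# ---------------------------------------------------------------------------
# Voxel grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VoxelGrid:
    """Masked isotropic sampling lattice with a voxel-index→mm affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray          # 4x4, voxel ijk -> mm
    voxel_size: float           # mm, isotropic
    mask: np.ndarray = field(repr=False)  # bool, shape == self.shape

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        if self.mask.shape != tuple(self.shape):
            raise ValueError("mask shape does not match grid shape")
        if not self.mask.any():
            raise ValueError("mask is empty")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel, mm³."""
        return float(self.voxel_size) ** 3

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())

    @property
    def origin(self) -> np.ndarray:
        """mm coordinate of voxel (0, 0, 0)."""
        return self.affine[:3, 3].copy()

    def masked_indices(self) -> np.ndarray:
        """(n_masked, 3) integer ijk indices of in-mask voxels."""
        return np.argwhere(self.mask)

    def new_map(self, dtype=np.float64) -> np.ndarray:
        return np.zeros(self.shape, dtype=dtype)


def make_grid(
    voxel_size: float = 2.0,
    bounds: tuple[tuple[float, float], ...] = MNI152_BOUNDS,
    mask_source: str | nib.spatialimages.SpatialImage | None = None,
) -> VoxelGrid:
    """Build the masked voxel grid covering ``bounds`` at ``voxel_size`` mm.

    ``mask_source`` may be a NIfTI path or image (resampled onto the grid by
    nearest neighbour) or ``None`` for a procedural ellipsoid approximating
    adult brain extent.
    """
    if voxel_size <= 0:
        raise ValueError("voxel_size must be > 0")
    bounds = tuple((float(lo), float(hi)) for lo, hi in bounds)
    shape = []
    for lo, hi in bounds:
        span = hi - lo
        if span <= voxel_size:
            raise ValueError(
                f"degenerate bounds ({lo}, {hi}): span must exceed one voxel"
            )
        shape.append(int(np.floor(span / voxel_size)) + 1)
    shape = tuple(shape)

    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = voxel_size
    affine[:3, 3] = [lo for lo, _ in bounds]

    if mask_source is None:
        mask = _ellipsoid_mask(shape, affine)
    else:
        img = (
            mask_source
            if isinstance(mask_source, nib.spatialimages.SpatialImage)
            else nib.load(str(mask_source))
        )
        mask = _resample_mask(img, shape, affine)
    if not mask.any():
        raise ValueError("mask is empty on this grid")
    return VoxelGrid(shape=shape, affine=affine, voxel_size=float(voxel_size), mask=mask)


#: Ellipsoid approximating adult brain extent in MNI mm:
#: center and semi-axes chosen to sit inside the MNI152 box.
_ELLIPSOID_CENTER = np.array([0.0, -18.0, 18.0])
_ELLIPSOID_SEMIAXES = np.array([70.0, 85.0, 65.0])


def _voxel_centers_mm(shape: tuple[int, int, int], affine: np.ndarray) -> np.ndarray:
    ii, jj, kk = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]), indexing="ij"
    )
    ijk = np.stack([ii, jj, kk], axis=-1).astype(float)
    return ijk @ affine[:3, :3].T + affine[:3, 3]


def _ellipsoid_mask(shape: tuple[int, int, int], affine: np.ndarray) -> np.ndarray:
    mm = _voxel_centers_mm(shape, affine)
    r = (mm - _ELLIPSOID_CENTER) / _ELLIPSOID_SEMIAXES
    return (r ** 2).sum(axis=-1) <= 1.0


def in_ellipsoid(xyz) -> bool:
    """True if the mm point lies inside the procedural brain ellipsoid."""
    r = (np.asarray(xyz, dtype=float) - _ELLIPSOID_CENTER) / _ELLIPSOID_SEMIAXES
    return bool((r ** 2).sum() <= 1.0)


def _resample_mask(
    img: nib.spatialimages.SpatialImage,
    shape: tuple[int, int, int],
    affine: np.ndarray,
) -> np.ndarray:
    """Nearest-neighbour sample of a mask volume at our voxel centers."""
    data = np.asarray(img.dataobj) > 0
    src_inv = np.linalg.inv(img.affine)
    mm = _voxel_centers_mm(shape, affine).reshape(-1, 3)
    src_ijk = np.rint(mm @ src_inv[:3, :3].T + src_inv[:3, 3]).astype(int)
    inside = np.all((src_ijk >= 0) & (src_ijk < np.array(data.shape)), axis=1)
    out = np.zeros(len(src_ijk), dtype=bool)
    idx = src_ijk[inside]
    out[inside] = data[idx[:, 0], idx[:, 1], idx[:, 2]]
    return out.reshape(shape)


# ---------------------------------------------------------------------------
# mm <-> voxel conversions
# ---------------------------------------------------------------------------

def mm_to_voxel(grid: VoxelGrid, mm) -> tuple[int, int, int]:
    """Nearest-voxel-center index of a mm coordinate; errors out of bounds."""
    mm = np.asarray(mm, dtype=float)
    inv = np.linalg.inv(grid.affine)
    ijk_f = mm @ inv[:3, :3].T + inv[:3, 3]
    ijk = np.rint(ijk_f).astype(int)
    if np.any(ijk < 0) or np.any(ijk >= np.array(grid.shape)):
        raise ValueError(f"coordinate {mm.tolist()} mm is outside the grid")
    return (int(ijk[0]), int(ijk[1]), int(ijk[2]))


def voxel_to_mm(grid: VoxelGrid, ijk) -> np.ndarray:
    """mm coordinate of a voxel center."""
    ijk = np.asarray(ijk, dtype=float)
    return ijk @ grid.affine[:3, :3].T + grid.affine[:3, 3]


# ---------------------------------------------------------------------------
# Focus placement policy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlacementReport:
    """Outcome of snapping foci into the mask."""

    placed: tuple[FocusCoordinate, ...]
    n_snapped: int
    n_dropped: int


def place_foci(
    grid: VoxelGrid,
    foci,
    transform: SpaceTransform | None = None,
    snap_mm: float = 5.0,
) -> PlacementReport:
    """Convert foci to MNI and enforce the mask placement policy.

    Printed peak coordinates often sit at tissue boundaries; a focus landing
    outside the mask is snapped to the nearest masked voxel center when one
    lies within ``snap_mm``, otherwise dropped (and counted).
    """
    masked_mm = None
    placed: list[FocusCoordinate] = []
    n_snapped = n_dropped = 0
    for f in foci:
        f = to_mni(f, transform)
        try:
            ijk = mm_to_voxel(grid, f.xyz)
            inside = grid.mask[ijk]
        except ValueError:
            inside = False
        if inside:
            placed.append(f)
            continue
        if masked_mm is None:
            masked_mm = voxel_to_mm(grid, grid.masked_indices())
        d2 = ((masked_mm - f.xyz) ** 2).sum(axis=1)
        j = int(np.argmin(d2))
        if d2[j] <= snap_mm ** 2:
            x, y, z = masked_mm[j]
            placed.append(
                FocusCoordinate(
                    x=float(x), y=float(y), z=float(z),
                    space=Space.MNI, direction=f.direction,
                )
            )
            n_snapped += 1
        else:
            n_dropped += 1
    return PlacementReport(tuple(placed), n_snapped, n_dropped)
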