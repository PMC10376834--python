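"""Semi-automatic segmentation of sinus air spaces from voxel volumes.

Mirrors the ITK-SNAP-style workflow: seeds placed inside the air cavity
grow through 6-connected voxels whose intensity lies inside a chosen gray
range, and the resulting binary mask is turned into a triangle surface by
marching cubes at the 0.5 iso-level.  Meshes are always expressed in world
millimetres (``origin + index * spacing``).

No morphological post-processing (closing, smoothing) is applied: the mesh
is exactly the iso-surface of the grown mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy import ndimage
from skimage.measure import marching_cubes

from .errors import (
    EmptySegmentationError,
    InvalidConfigError,
    OpenSurfaceError,
    SeedRejectionError,
)

__all__ = [
    "VoxelVolume",
    "VoxelMask",
    "GrayRange",
    "DEFAULT_AIR_RANGE",
    "region_grow",
    "extract_surface",
    "segment_sinus",
]


@dataclass
class VoxelVolume:
    """Gridded grayscale image with mm spacing (the CT stand-in).

    ``origin`` is the world-mm position of the centre of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __init__(self, values, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
        self.values = np.asarray(values)
        self.spacing = np.asarray(spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(origin, dtype=np.float64).reshape(3)
        if self.values.ndim != 3:
            raise InvalidConfigError("volume must be a 3D grid")
        if not np.all(self.spacing > 0):
            raise InvalidConfigError("voxel spacing must be strictly positive")
        if not np.all(np.isfinite(self.values)):
            raise InvalidConfigError("volume values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class VoxelMask:
    """Boolean grid sharing its source volume's geometry."""

    flags: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __init__(self, flags, spacing, origin):
        self.flags = np.asarray(flags, dtype=bool)
        self.spacing = np.asarray(spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(origin, dtype=np.float64).reshape(3)

    @property
    def voxel_count(self) -> int:
        return int(self.flags.sum())


@dataclass(frozen=True)
class GrayRange:
    """Inclusive intensity window selecting the air space."""

    low: float
    high: float

    def __post_init__(self):
        if self.low > self.high:
            raise InvalidConfigError("gray range requires low <= high")

    def contains(self, values) -> np.ndarray:
        return (np.asarray(values) >= self.low) & (np.asarray(values) <= self.high)


#: Air-like window for the synthetic volumes (HU-like units); the real gray
#: range is operator-chosen per acquisition and always overridable.
DEFAULT_AIR_RANGE = GrayRange(-1100.0, -200.0)

# 6-connectivity: faces only, so diagonal voxel contacts cannot leak
_FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)


def region_grow(volume: VoxelVolume, seeds, gray_range: GrayRange) -> VoxelMask:
    """Grow seeds through 6-connected voxels inside the gray range.

    The result is the union, over all seeds, of the 6-connected components
    of the thresholded set ``{low <= value <= high}`` containing each seed.
    """
    seeds = [tuple(int(c) for c in seed) for seed in np.atleast_2d(np.asarray(seeds))]
    if not seeds:
        raise SeedRejectionError("at least one seed is required")
    for seed in seeds:
        if len(seed) != 3 or any(c < 0 or c >= s for c, s in zip(seed, volume.shape)):
            raise IndexError(f"seed {seed} lies outside the grid {volume.shape}")
        value = volume.values[seed]
        if not gray_range.contains(value):
            raise SeedRejectionError(
                f"seed {seed} has value {value!r} outside gray range "
                f"[{gray_range.low}, {gray_range.high}]")
    inside = gray_range.contains(volume.values)
    labels, _ = ndimage.label(inside, structure=_FACE_STRUCTURE)
    wanted = {labels[seed] for seed in seeds}
    flags = np.isin(labels, sorted(wanted))
    return VoxelMask(flags, volume.spacing, volume.origin)


def extract_surface(mask: VoxelMask) -> trimesh.Trimesh:
    """Marching-cubes iso-surface of a binary mask, in world mm.

    The surface is extracted at level 0.5 of the 0/1 field, so it passes
    midway between mask and background voxel centres.  The mask must not
    touch the grid boundary, otherwise the surface could not close.
    """
    if mask.voxel_count == 0:
        raise EmptySegmentationError("cannot extract a surface from an empty mask")
    flags = mask.flags
    if (flags[0].any() or flags[-1].any() or flags[:, 0].any() or flags[:, -1].any()
            or flags[:, :, 0].any() or flags[:, :, -1].any()):
        raise OpenSurfaceError("mask touches the grid boundary; surface would be open")
    verts, faces, _, _ = marching_cubes(flags.astype(np.float64), level=0.5,
                                        spacing=tuple(mask.spacing))
    mesh = trimesh.Trimesh(vertices=verts + mask.origin, faces=faces, process=False)
    # orient all faces outward (positive enclosed volume)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def segment_sinus(volume: VoxelVolume, seeds,
                  gray_range: GrayRange = DEFAULT_AIR_RANGE,
                  log=None) -> trimesh.Trimesh:
    """Full segmentation stage: region growing then surface extraction."""
    mask = region_grow(volume, seeds, gray_range)
    mesh = extract_surface(mask)
    if log is not None:
        log(f"segmented {mask.voxel_count} voxels -> mesh volume {mesh.volume:.2f} mm^3")
    return mesh
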