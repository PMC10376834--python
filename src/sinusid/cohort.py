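"""Synthetic cohort of paired "AM/PM" maxillary-sinus surface models.

Real sinus shapes are individually distinctive, smooth, closed air
cavities, larger in males than females and roughly mirror-symmetric
between sides.  The generator emulates exactly the statistical structure
the identification analysis relies on:

* per-individual shape = ellipsoid of ~30-40 mm extent deformed by a
  smooth random radial field (a low-order real spherical-harmonic
  mixture), drawn independently per subject and side;
* the left side is the x-mirror of the subject's base geometry with its
  own independent deformation draw;
* repeat "segmentation" of one individual differs only by a small,
  spatially correlated radial jitter (mesh path) or by re-thresholding a
  noisy voxelization (volume path).

Inter-individual shape differences (sd ``shape_amplitude_sd``) dominate
the intra-individual repeat noise (sd ``repeat_noise_sd``), which is the
regime that produces non-overlapping match/mismatch RMS distributions.

Every draw is a pure function of ``(seed, sex, subject index, side,
acquisition)``, so adding subjects never perturbs existing models.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh
from scipy.special import sph_harm_y

from .errors import InvalidConfigError, ResolutionError
from .segmentation import DEFAULT_AIR_RANGE, VoxelVolume, segment_sinus

__all__ = [
    "CohortConfig",
    "SinusModel",
    "Cohort",
    "RadialShape",
    "generate_individual_shape",
    "simulate_repeat_acquisition",
    "generate_cohort",
]

SEXES = ("M", "F")
SIDES = ("right", "left")
ACQUISITIONS = ("AM", "PM")

# sub-stream labels for per-entity SeedSequence keys
_STREAM_SHAPE = 0
_STREAM_JITTER = 1
_STREAM_INTENSITY = 2


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; defaults are the study conditions.

    ``base_semi_axes`` are the half-extents (mm) of the undeformed
    ellipsoid, matching a typical adult maxillary sinus; ``male_scale``
    multiplies the whole male geometry.  ``shape_amplitude_sd`` (mm) is the
    standard deviation over the sphere of the smooth inter-individual
    radial deformation, ``repeat_noise_sd`` (mm) that of the
    intra-individual repeat jitter; both fields are random mixtures of real
    spherical harmonics of degree 1..``harmonic_order``.  Intensity levels
    are HU-like (air -1000, bone 700).
    """

    n_per_sex: int = 50
    base_semi_axes: tuple = (17.0, 12.0, 16.0)
    male_scale: float = 1.05
    shape_amplitude_sd: float = 2.0
    repeat_noise_sd: float = 0.15
    harmonic_order: int = 4
    voxel_spacing: float = 1.0
    air_value: float = -1000.0
    bone_value: float = 700.0
    noise_sd_intensity: float = 30.0
    seed: int = 0
    path: str = "mesh"
    mesh_subdivisions: int = 3

    def __post_init__(self):
        if self.n_per_sex < 1:
            raise InvalidConfigError("n_per_sex must be >= 1")
        if any(a <= 0 for a in self.base_semi_axes) or len(self.base_semi_axes) != 3:
            raise InvalidConfigError("base_semi_axes must be three positive lengths")
        if self.male_scale <= 0:
            raise InvalidConfigError("male_scale must be positive")
        if self.shape_amplitude_sd < 0 or self.repeat_noise_sd < 0:
            raise InvalidConfigError("deformation amplitudes must be >= 0")
        if self.shape_amplitude_sd > 0 and not self.repeat_noise_sd < max(
                self.shape_amplitude_sd, 1e-12):
            raise InvalidConfigError(
                "repeat_noise_sd must be smaller than shape_amplitude_sd "
                "(the separation regime)")
        if self.harmonic_order < 1:
            raise InvalidConfigError("harmonic_order must be >= 1")
        if self.voxel_spacing <= 0:
            raise InvalidConfigError("voxel_spacing must be positive")
        if self.path not in {"mesh", "volume"}:
            raise InvalidConfigError("path must be 'mesh' or 'volume'")
        if self.mesh_subdivisions < 1:
            raise InvalidConfigError("mesh_subdivisions must be >= 1")


class _HarmonicField:
    """Smooth scalar field on the unit sphere: a real spherical-harmonic
    mixture of degrees 1..order, normalized to a target sd over the sphere.

    Orthonormality of the basis gives the mean square over the sphere as
    ``sum(c^2) / (4 pi)``, so the normalization is analytic and independent
    of any particular mesh sampling.
    """

    def __init__(self, order: int, target_sd: float, rng: np.random.Generator):
        self.terms = [(l, m) for l in range(1, order + 1) for m in range(-l, l + 1)]
        coeffs = rng.standard_normal(len(self.terms))
        mean_square = float(np.sum(coeffs ** 2)) / (4.0 * np.pi)
        if target_sd > 0 and mean_square > 0:
            self.coeffs = coeffs * (target_sd / np.sqrt(mean_square))
        else:
            self.coeffs = np.zeros_like(coeffs)

    def __call__(self, directions: np.ndarray) -> np.ndarray:
        """Evaluate at unit vectors (n, 3); returns (n,) values in mm."""
        directions = np.atleast_2d(directions)
        theta = np.arccos(np.clip(directions[:, 2], -1.0, 1.0))
        phi = np.arctan2(directions[:, 1], directions[:, 0])
        out = np.zeros(len(directions))
        for (l, m), c in zip(self.terms, self.coeffs):
            if c == 0.0:
                continue
            y = sph_harm_y(l, abs(m), theta, phi)
            if m > 0:
                basis = np.sqrt(2.0) * (-1.0) ** m * y.real
            elif m < 0:
                basis = np.sqrt(2.0) * (-1.0) ** m * y.imag
            else:
                basis = y.real
            out += c * basis
        return out


@dataclass
class RadialShape:
    """Star-shaped closed surface: deformed ellipsoid with analytic
    inside/outside tests.

    The surface point in direction ``u`` (unit sphere) is
    ``scale * (b(u) + f(u) * b(u)/|b(u)|)`` with ``b(u) = semi_axes * u``
    and ``f`` the radial deformation field; mirroring flips x.
    """

    semi_axes: np.ndarray
    deformation: _HarmonicField
    scale: float = 1.0
    mirror: bool = False

    def radius(self, unit_dirs: np.ndarray) -> np.ndarray:
        """Surface radius (mm) along the *ellipsoid-parameter* directions."""
        base = unit_dirs * np.asarray(self.semi_axes)
        base_norm = np.linalg.norm(base, axis=-1)
        return self.scale * (base_norm + self.deformation(unit_dirs))

    def contains(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        if self.mirror:
            points = points * np.array([-1.0, 1.0, 1.0])
        norms = np.linalg.norm(points, axis=1)
        # ellipsoid parameter u with semi * u parallel to p
        with np.errstate(invalid="ignore"):
            u = points / np.asarray(self.semi_axes)
            u_norm = np.linalg.norm(u, axis=1, keepdims=True)
            u = np.divide(u, u_norm, out=np.zeros_like(u), where=u_norm > 0)
        inside = norms <= self.radius(u)
        inside[norms == 0] = True
        return inside

    def to_mesh(self, subdivisions: int = 3) -> trimesh.Trimesh:
        sphere = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
        u = np.asarray(sphere.vertices)
        base = u * np.asarray(self.semi_axes)
        base_norm = np.linalg.norm(base, axis=1, keepdims=True)
        vertices = self.scale * (base + self.deformation(u) [:, None]
                                 * base / base_norm)
        faces = np.asarray(sphere.faces)
        if self.mirror:
            vertices = vertices * np.array([-1.0, 1.0, 1.0])
            faces = faces[:, [0, 2, 1]]  # restore outward winding
        return trimesh.Trimesh(vertices=vertices, faces=faces, process=False)

    def max_radius(self) -> float:
        bound = float(np.max(np.abs(self.semi_axes)))
        spread = 4.0 * np.sqrt(np.mean(self.deformation.coeffs ** 2) + 1e-30) \
            * np.sqrt(len(self.deformation.coeffs))
        return self.scale * (bound + spread)


@dataclass
class SinusModel:
    """One acquired sinus surface with its cohort bookkeeping."""

    subject_id: str
    sex: str
    side: str
    acquisition: str
    mesh: trimesh.Trimesh
    provenance: dict = field(default_factory=dict)


@dataclass
class Cohort:
    """All models of a synthetic cohort, reproducible from its config."""

    config: CohortConfig
    models: list

    def __iter__(self):
        return iter(self.models)

    def __len__(self):
        return len(self.models)

    def get(self, subject_id: str, side: str, acquisition: str) -> SinusModel:
        for model in self.models:
            if (model.subject_id, model.side, model.acquisition) == (
                    subject_id, side, acquisition):
                return model
        raise KeyError((subject_id, side, acquisition))

    def subjects(self) -> list:
        seen = dict.fromkeys(m.subject_id for m in self.models)
        return list(seen)


def _entity_rng(config: CohortConfig, sex: str, index: int, side: str,
                stream: int, acquisition: str | None = None) -> np.random.Generator:
    key = [int(config.seed), SEXES.index(sex), int(index), SIDES.index(side), stream]
    if acquisition is not None:
        key.append(ACQUISITIONS.index(acquisition))
    return np.random.default_rng(np.random.SeedSequence(key))


def _subject_index(subject_id: str) -> tuple[str, int]:
    sex = subject_id[0]
    if sex not in SEXES:
        raise InvalidConfigError(f"subject id {subject_id!r} must start with M or F")
    return sex, int(subject_id[1:])


def subject_label(sex: str, index: int) -> str:
    return f"{sex}{index:03d}"


def _draw_shape(config: CohortConfig, sex: str, index: int, side: str) -> RadialShape:
    rng = _entity_rng(config, sex, index, side, _STREAM_SHAPE)
    deformation = _HarmonicField(config.harmonic_order,
                                 config.shape_amplitude_sd, rng)
    return RadialShape(
        semi_axes=np.asarray(config.base_semi_axes, dtype=np.float64),
        deformation=deformation,
        scale=config.male_scale if sex == "M" else 1.0,
        mirror=(side == "left"),
    )


def generate_individual_shape(config: CohortConfig, subject_id: str, sex: str,
                              side: str, rng_state=None) -> trimesh.Trimesh:
    """Noise-free shape of one subject/side as a closed triangle mesh.

    The draw is a pure function of ``(config.seed, sex, subject index,
    side)``; ``rng_state`` may override the derived generator (tests only).
    """
    _, index = _subject_index(subject_id)
    shape = _draw_shape(config, sex, index, side)
    if rng_state is not None:
        shape = replace(shape, deformation=_HarmonicField(
            config.harmonic_order, config.shape_amplitude_sd, rng_state))
    return shape.to_mesh(config.mesh_subdivisions)


def _apply_radial_jitter(mesh: trimesh.Trimesh, config: CohortConfig,
                         rng: np.random.Generator) -> trimesh.Trimesh:
    jitter = _HarmonicField(config.harmonic_order, config.repeat_noise_sd, rng)
    vertices = np.asarray(mesh.vertices, dtype=np.float64)
    norms = np.linalg.norm(vertices, axis=1, keepdims=True)
    directions = np.divide(vertices, norms, out=np.zeros_like(vertices),
                           where=norms > 0)
    moved = vertices + jitter(directions)[:, None] * directions
    return trimesh.Trimesh(vertices=moved, faces=np.asarray(mesh.faces).copy(),
                           process=False)


def _voxelize(shape: RadialShape, config: CohortConfig,
              rng: np.random.Generator) -> VoxelVolume:
    spacing = config.voxel_spacing
    if min(shape.semi_axes) * shape.scale / spacing < 8:
        raise ResolutionError(
            "voxel spacing too coarse: need >= 8 voxels across the smallest "
            "semi-axis")
    extent = shape.max_radius() + 3.0 * spacing
    n_half = int(np.ceil(extent / spacing))
    coords = (np.arange(-n_half, n_half + 1)) * spacing
    grid = np.stack(np.meshgrid(coords, coords, coords, indexing="ij"), axis=-1)
    inside = shape.contains(grid.reshape(-1, 3)).reshape(grid.shape[:3])
    values = np.where(inside, config.air_value, config.bone_value)
    values = values + rng.normal(0.0, config.noise_sd_intensity, values.shape)
    origin = np.array([coords[0]] * 3)
    return VoxelVolume(values, spacing=(spacing,) * 3, origin=origin)


def simulate_repeat_acquisition(shape, config: CohortConfig,
                                rng_state: np.random.Generator) -> trimesh.Trimesh:
    """One "acquisition" of a subject's shape, with its repeat noise.

    Mesh path: returns the input surface displaced by a smooth correlated
    radial jitter of sd ``repeat_noise_sd`` (independent per acquisition).
    Volume path (requires a :class:`RadialShape`): voxelizes the shape
    (air inside, bone outside, additive intensity noise), then segments the
    volume back to a mesh, so the repeat differences arise from
    thresholding and surface extraction.
    """
    if config.path == "mesh":
        mesh = shape.to_mesh(config.mesh_subdivisions) \
            if isinstance(shape, RadialShape) else shape
        if config.repeat_noise_sd == 0:
            return mesh.copy()
        return _apply_radial_jitter(mesh, config, rng_state)
    if not isinstance(shape, RadialShape):
        raise InvalidConfigError(
            "the volume path voxelizes the generative shape; pass a RadialShape")
    volume = _voxelize(shape, config, rng_state)
    center = tuple(int(s // 2) for s in volume.shape)
    return segment_sinus(volume, [center], DEFAULT_AIR_RANGE)


def generate_cohort(config: CohortConfig) -> Cohort:
    """All ``n_per_sex*2`` subjects x 2 sides x 2 acquisitions models."""
    models = []
    for sex in SEXES:
        for index in range(config.n_per_sex):
            subject = subject_label(sex, index)
            for side in SIDES:
                shape = _draw_shape(config, sex, index, side)
                for acquisition in ACQUISITIONS:
                    rng = _entity_rng(config, sex, index, side, _STREAM_JITTER
                                      if config.path == "mesh" else _STREAM_INTENSITY,
                                      acquisition)
                    mesh = simulate_repeat_acquisition(shape, config, rng)
                    models.append(SinusModel(
                        subject_id=subject, sex=sex, side=side,
                        acquisition=acquisition, mesh=mesh,
                        provenance={
                            "seed": config.seed, "sex": sex, "index": index,
                            "side": side, "acquisition": acquisition,
                            "path": config.path,
                            "scale": shape.scale,
                            "deformation_coeffs": shape.deformation.coeffs.tolist(),
                        }))
    return Cohort(config=config, models=models)
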