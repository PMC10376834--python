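"""Readers/writers for meshes, volumes, transforms and run manifests.

Meshes travel as PLY (binary little-endian canonical; ASCII accepted on
read), STL or OBJ, always in mm.  Volumes travel as NIfTI (via nibabel)
or NRRD (via SimpleITK) with spacing/origin preserved.  Every CLI stage
writes a JSON run manifest recording the resolved configuration, seeds and
SHA-256 digests of its inputs and outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from datetime import datetime, timezone
from pathlib import Path

import nibabel as nib
import numpy as np
import trimesh

from .errors import FormatError
from .registration import RigidTransform
from .segmentation import VoxelVolume

__all__ = [
    "read_mesh",
    "write_mesh",
    "read_volume",
    "write_volume",
    "read_transform",
    "write_transform",
    "RunManifest",
]

_MESH_SUFFIXES = {".ply", ".stl", ".obj"}


def read_mesh(path) -> trimesh.Trimesh:
    """Load a PLY/STL/OBJ triangle mesh (coordinates assumed mm)."""
    path = Path(path)
    if path.suffix.lower() not in _MESH_SUFFIXES:
        raise FormatError(f"unsupported mesh format {path.suffix!r} for {path}")
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        mesh = trimesh.load_mesh(path, process=False)
    except Exception as exc:  # malformed file
        raise FormatError(f"could not parse mesh file {path}: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise FormatError(f"{path} does not contain a triangle mesh")
    return mesh


def write_mesh(mesh: trimesh.Trimesh, path) -> Path:
    """Write a mesh; PLY is written binary little-endian."""
    path = Path(path)
    if path.suffix.lower() not in _MESH_SUFFIXES:
        raise FormatError(f"unsupported mesh format {path.suffix!r} for {path}")
    path.parent.mkdir(parents=True, exist_ok=True)
    mesh.export(path)
    return path


def read_volume(path) -> VoxelVolume:
    """Load a NIfTI or NRRD volume into grid + spacing + origin."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        img = nib.load(path)
        data = np.asarray(img.dataobj)
        if data.ndim != 3:
            raise FormatError(f"{path}: expected a 3D volume, got {data.ndim}D")
        affine = img.affine
        spacing = np.linalg.norm(affine[:3, :3], axis=0)
        origin = affine[:3, 3]
        return VoxelVolume(data, spacing=spacing, origin=origin)
    if suffixes.endswith(".nrrd"):
        import SimpleITK as sitk
        img = sitk.ReadImage(str(path))
        if img.GetDimension() != 3:
            raise FormatError(f"{path}: expected a 3D volume")
        # SimpleITK arrays come back (z, y, x); transpose to (x, y, z)
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return VoxelVolume(data, spacing=np.asarray(img.GetSpacing()),
                           origin=np.asarray(img.GetOrigin()))
    raise FormatError(f"unsupported volume format for {path}")


def write_volume(volume: VoxelVolume, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        affine = np.diag(list(volume.spacing) + [1.0])
        affine[:3, 3] = volume.origin
        nib.save(nib.Nifti1Image(np.asarray(volume.values), affine), path)
        return path
    if suffixes.endswith(".nrrd"):
        import SimpleITK as sitk
        img = sitk.GetImageFromArray(np.ascontiguousarray(
            np.asarray(volume.values).transpose(2, 1, 0)))
        img.SetSpacing(tuple(float(s) for s in volume.spacing))
        img.SetOrigin(tuple(float(o) for o in volume.origin))
        sitk.WriteImage(img, str(path))
        return path
    raise FormatError(f"unsupported volume format for {path}")


def write_transform(transform: RigidTransform, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps({
        "rotation": transform.rotation.tolist(),
        "translation": transform.translation.tolist(),
    }, indent=2))
    return path


def read_transform(path) -> RigidTransform:
    doc = json.loads(Path(path).read_text())
    return RigidTransform(np.asarray(doc["rotation"]),
                          np.asarray(doc["translation"]))


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


class RunManifest:
    """Provenance record for one pipeline stage."""

    def __init__(self, stage: str, config=None, seed=None):
        from . import __version__
        self.doc = {
            "tool": "sinusid",
            "version": __version__,
            "stage": stage,
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "seed": seed,
            "config": self._jsonable(config),
            "inputs": {},
            "outputs": {},
        }

    @staticmethod
    def _jsonable(config):
        if config is None:
            return None
        if is_dataclass(config):
            return asdict(config)
        return config

    def add_input(self, path):
        path = Path(path)
        self.doc["inputs"][str(path)] = _sha256(path)

    def add_output(self, path):
        path = Path(path)
        self.doc["outputs"][str(path)] = _sha256(path)

    def write(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.doc, indent=2, default=str))
        return path

    @staticmethod
    def verify(path) -> bool:
        """True iff every referenced file still exists with its digest."""
        doc = json.loads(Path(path).read_text())
        for section in ("inputs", "outputs"):
            for file_path, digest in doc.get(section, {}).items():
                if not Path(file_path).exists():
                    return False
                if _sha256(Path(file_path)) != digest:
                    return False
        return True
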