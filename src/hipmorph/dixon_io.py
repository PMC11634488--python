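"""Reading and writing Dixon fat/water image pairs and multi-label muscle masks.

Conventions
-----------
* Voxel indices are 0-based; all anatomical reasoning goes through the 4x4
  voxel-to-world affine (world axes are RAS+: +x right, +y anterior,
  +z superior).
* The *axial* array axis is the one most aligned with the world
  superior-inferior direction; *proximal* means most superior.
* Label masks carry a label dictionary mapping integer ids to
  ``(muscle name, side)`` pairs, externalised on disk as a YAML sidecar.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

__all__ = [
    "DixonVolume",
    "LabelMask",
    "DixonIOError",
    "ShapeMismatchError",
    "AffineMismatchError",
    "UnknownLabelError",
    "read_dixon_pair",
    "read_label_mask",
    "write_dixon_pair",
    "write_label_mask",
    "read_label_map",
    "write_label_map",
]

AFFINE_ATOL = 1e-4


class DixonIOError(ValueError):
    """Base class for image-ingest validation failures."""


class ShapeMismatchError(DixonIOError):
    pass


class AffineMismatchError(DixonIOError):
    pass


class UnknownLabelError(DixonIOError):
    pass


def _voxel_size(affine: np.ndarray) -> tuple[float, float, float]:
    return tuple(float(np.linalg.norm(affine[:3, j])) for j in range(3))


def _world_axis_to_array_axis(affine: np.ndarray, world_axis: int) -> int:
    """Array axis whose direction is most aligned with a given world axis."""
    return int(np.argmax(np.abs(affine[world_axis, :3])))


@dataclass
class DixonVolume:
    """Co-registered fat and water magnitude images on a shared grid."""

    fat: np.ndarray
    water: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.fat = np.asarray(self.fat, dtype=float)
        self.water = np.asarray(self.water, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.fat.shape != self.water.shape:
            raise ShapeMismatchError(
                f"fat shape {self.fat.shape} != water shape {self.water.shape}"
            )
        if self.fat.ndim != 3:
            raise DixonIOError("Dixon images must be 3D")
        if self.affine.shape != (4, 4):
            raise DixonIOError("affine must be 4x4")
        if any(v <= 0 for v in self.voxel_size):
            raise DixonIOError(f"non-positive voxel size {self.voxel_size}")
        if (self.fat < 0).any() or (self.water < 0).any():
            raise DixonIOError("fat/water intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.fat.shape

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        return _voxel_size(self.affine)

    @property
    def axial_axis(self) -> int:
        """Array axis most aligned with world superior-inferior."""
        return _world_axis_to_array_axis(self.affine, 2)

    def slice_superior_coord(self, index: int) -> float:
        """World S coordinate of a slice along the axial axis (up to a
        constant offset from the in-plane position, which is shared by all
        slices and therefore irrelevant for ordering)."""
        ax = self.axial_axis
        return float(self.affine[2, ax] * index + self.affine[2, 3])


@dataclass
class LabelMask:
    """Integer multi-label segmentation sharing a DixonVolume's grid."""

    labels: np.ndarray
    affine: np.ndarray
    label_map: dict[int, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if not np.issubdtype(arr.dtype, np.integer):
            as_int = np.rint(arr).astype(np.int32)
            if not np.allclose(arr, as_int, atol=1e-6):
                raise UnknownLabelError("mask contains non-integer voxel values")
            arr = as_int
        self.labels = arr
        self.affine = np.asarray(self.affine, dtype=float)
        if self.labels.ndim != 3:
            raise DixonIOError("label mask must be 3D")
        self.label_map = {int(k): (str(v[0]), str(v[1])) for k, v in self.label_map.items()}
        present = set(np.unique(self.labels)) - {0}
        unknown = present - set(self.label_map)
        if unknown:
            raise UnknownLabelError(
                f"mask contains labels not in label map: {sorted(unknown)}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        return _voxel_size(self.affine)

    @property
    def axial_axis(self) -> int:
        return _world_axis_to_array_axis(self.affine, 2)

    def slice_superior_coord(self, index: int) -> float:
        ax = self.axial_axis
        return float(self.affine[2, ax] * index + self.affine[2, 3])

    def label_for(self, muscle: str, side: str) -> int:
        for lid, (name, s) in self.label_map.items():
            if name == muscle and s == side:
                return lid
        raise UnknownLabelError(f"no label for muscle {muscle!r} side {side!r}")

    def same_grid(self, other: "LabelMask | DixonVolume") -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=AFFINE_ATOL
        )


def _load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), np.asarray(img.affine)


def read_dixon_pair(fat_path: str | Path, water_path: str | Path) -> DixonVolume:
    """Read co-registered fat and water NIfTI images into a DixonVolume.

    Raises distinct diagnostics for shape mismatch, affine mismatch and
    degenerate voxel geometry.
    """
    fat, fat_aff = _load_nifti(fat_path)
    water, water_aff = _load_nifti(water_path)
    if fat.shape != water.shape:
        raise ShapeMismatchError(
            f"fat {fat.shape} vs water {water.shape}: grids differ"
        )
    if not np.allclose(fat_aff, water_aff, atol=AFFINE_ATOL):
        raise AffineMismatchError("fat and water affines differ beyond tolerance")
    return DixonVolume(fat=fat, water=water, affine=fat_aff)


def read_label_mask(
    path: str | Path, label_map: dict[int, tuple[str, str]] | None = None
) -> LabelMask:
    """Read a multi-label mask; the label map comes from the argument or a
    ``<stem>.labels.yaml`` sidecar next to the file."""
    data, affine = _load_nifti(path)
    if label_map is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise DixonIOError(
                f"no label map given and sidecar {sidecar} not found"
            )
        label_map = read_label_map(sidecar)
    return LabelMask(labels=data, affine=affine, label_map=label_map)


def _sidecar_path(path: str | Path) -> Path:
    p = Path(path)
    stem = p.name
    for suffix in (".nii.gz", ".nii"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    return p.with_name(stem + ".labels.yaml")


def write_dixon_pair(
    volume: DixonVolume, fat_path: str | Path, water_path: str | Path
) -> None:
    nib.save(nib.Nifti1Image(volume.fat.astype(np.float32), volume.affine), str(fat_path))
    nib.save(nib.Nifti1Image(volume.water.astype(np.float32), volume.affine), str(water_path))


def write_label_mask(mask: LabelMask, path: str | Path, sidecar: bool = True) -> None:
    nib.save(nib.Nifti1Image(mask.labels.astype(np.int16), mask.affine), str(path))
    if sidecar:
        write_label_map(mask.label_map, _sidecar_path(path))


def read_label_map(path: str | Path) -> dict[int, tuple[str, str]]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {int(k): (str(v[0]), str(v[1])) for k, v in raw.items()}


def write_label_map(label_map: dict[int, tuple[str, str]], path: str | Path) -> None:
    serialisable = {int(k): [v[0], v[1]] for k, v in label_map.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(serialisable, fh, sort_keys=True)
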