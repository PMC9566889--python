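"""NIfTI-backed I/O for volumes, brain masks, and frozen classifier models.

All images travel as :class:`Volume` / :class:`BrainMask`; a trained
classifier is persisted as a small directory holding the weight map as a
NIfTI volume, the brain mask, and a human-readable JSON sidecar with the
scalar metadata (bias, kernel offset, hyperparameters, training provenance),
so a frozen model is auditable with standard neuroimaging tools.

Voxel indices are 0-based; the affine is carried through untouched and never
used for resampling — inputs are assumed already spatially aligned.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "BrainMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "save_model",
    "load_model",
    "mask_checksum",
]


def _default_affine(voxel_size_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


@dataclass
class Volume:
    """A 3-D scalar field (arbitrary uptake units) with voxel geometry.

    Invariants: finite intensities, strictly positive voxel sizes.
    """

    data: np.ndarray
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3-D volume, got {self.data.ndim}-D")
        n_bad = int(np.sum(~np.isfinite(self.data)))
        if n_bad:
            raise ValueError(f"volume contains {n_bad} non-finite voxel(s)")
        if self.affine is None:
            self.affine = np.eye(4)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if np.any(self.voxel_size_mm <= 0):
            raise ValueError("voxel sizes must be positive")

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt(np.sum(self.affine[:3, :3] ** 2, axis=0))

    @property
    def shape(self):
        return self.data.shape

    @classmethod
    def from_voxel_size(cls, data, voxel_size_mm=(1.0, 1.0, 1.0)) -> "Volume":
        return cls(data=data, affine=_default_affine(voxel_size_mm))


@dataclass
class BrainMask:
    """Boolean 3-D mask delimiting the whole-brain region."""

    data: np.ndarray
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3-D mask, got {self.data.ndim}-D")
        if not self.data.any():
            raise ValueError("mask has no true voxels")
        if self.affine is None:
            self.affine = np.eye(4)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt(np.sum(self.affine[:3, :3] ** 2, axis=0))

    @property
    def shape(self):
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @classmethod
    def from_voxel_size(cls, data, voxel_size_mm=(1.0, 1.0, 1.0)) -> "BrainMask":
        return cls(data=data, affine=_default_affine(voxel_size_mm))


def mask_checksum(mask: BrainMask) -> str:
    """Stable identity of a mask (voxels + grid + geometry), for provenance checks."""
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(mask.data.astype(np.uint8)).tobytes())
    h.update(np.asarray(mask.shape, dtype=np.int64).tobytes())
    h.update(np.round(mask.voxel_size_mm, 6).tobytes())
    return h.hexdigest()


def read_volume(path) -> Volume:
    """Load a NIfTI-1/2 image as a :class:`Volume`.

    Raises on missing files, non-3-D images, and non-finite voxels (the
    error names the number of voxels affected).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected 3-D volume, got {data.ndim}-D image at {path}")
    return Volume(data=data, affine=np.asarray(img.affine))


def write_volume(vol: Volume, path, dtype=np.float32) -> None:
    """Write a volume as NIfTI-1 (float32 payload by default)."""
    img = nib.Nifti1Image(vol.data.astype(dtype), vol.affine)
    nib.save(img, str(path))


def read_mask(path) -> BrainMask:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3-D mask, got {data.ndim}-D image at {path}")
    return BrainMask(data=data > 0, affine=np.asarray(img.affine))


def write_mask(mask: BrainMask, path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    nib.save(img, str(path))


# --- frozen-model persistence -------------------------------------------------

_WEIGHTS_FILE = "weights.nii.gz"
_MASK_FILE = "mask.nii.gz"
_SIDECAR_FILE = "model.json"


def save_model(model, dir_path) -> None:
    """Persist a trained hyperplane model to a directory.

    Layout: ``weights.nii.gz`` (float64 weight map scattered onto the mask
    grid), ``mask.nii.gz`` (uint8), and ``model.json`` holding bias, kernel
    offset, hyperparameters and the preprocessing provenance. Round-trip
    preserves subject scores to better than 1e-10 relative.
    """
    from .svm import HyperplaneModel  # local import to avoid a cycle

    if not isinstance(model, HyperplaneModel):
        raise TypeError("save_model expects a HyperplaneModel")
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)

    grid = np.zeros(model.mask.shape, dtype=np.float64)
    idx = model.voxel_index
    grid[idx[:, 0], idx[:, 1], idx[:, 2]] = model.weights
    write_volume(Volume(data=grid, affine=model.mask.affine), dir_path / _WEIGHTS_FILE,
                 dtype=np.float64)
    write_mask(model.mask, dir_path / _MASK_FILE)

    meta = {
        "bias": float(model.bias),
        "kernel_offset": float(model.params.kernel_offset),
        "score_convention": "weights_dot_image_plus_bias",
        "params": model.params.to_dict(),
        "normalization_record": model.normalization_record,
        "provenance": model.provenance,
        "mask_file": _MASK_FILE,
        "weights_file": _WEIGHTS_FILE,
        "mask_checksum": mask_checksum(model.mask),
    }
    (dir_path / _SIDECAR_FILE).write_text(json.dumps(meta, indent=2, sort_keys=True))


def load_model(dir_path):
    """Load a model saved by :func:`save_model`; inverse up to float64 precision."""
    from .preprocess import mask_voxel_index
    from .svm import HyperplaneModel, SvmParams

    dir_path = Path(dir_path)
    sidecar = dir_path / _SIDECAR_FILE
    if not sidecar.exists():
        raise FileNotFoundError(f"model sidecar missing: {sidecar}")
    meta = json.loads(sidecar.read_text())

    mask = read_mask(dir_path / meta.get("mask_file", _MASK_FILE))
    wvol = read_volume(dir_path / meta.get("weights_file", _WEIGHTS_FILE))
    if wvol.shape != mask.shape:
        raise ValueError(
            f"weight map grid {wvol.shape} does not match mask grid {mask.shape}"
        )
    if meta.get("mask_checksum") and meta["mask_checksum"] != mask_checksum(mask):
        raise ValueError("mask on disk does not match the metadata-declared mask")

    idx = mask_voxel_index(mask)
    weights = wvol.data[idx[:, 0], idx[:, 1], idx[:, 2]]
    return HyperplaneModel(
        weights=weights,
        bias=float(meta["bias"]),
        params=SvmParams.from_dict(meta["params"]),
        voxel_index=idx,
        mask=mask,
        normalization_record=meta.get("normalization_record"),
        provenance=meta.get("provenance", {}),
    )
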