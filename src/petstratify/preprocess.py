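"""Image conditioning: Gaussian smoothing, proportional intensity scaling,
masking, and vectorization into a subjects × voxels feature matrix.

The pipeline order is smooth → proportional-scale → mask-and-flatten. The
"whole-brain mean" used for scaling is the mean over the supplied brain mask
(never the full rectangular grid, whose background would dilute it). The
scaling target defaults to 50, the conventional grand mean in PET
proportional scaling; the choice only rescales subject scores by a constant
and is recorded in the feature matrix for provenance checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_formats import BrainMask, Volume, mask_checksum

__all__ = [
    "FWHM_TO_SIGMA",
    "FeatureMatrix",
    "smooth_gaussian",
    "proportional_scale",
    "mask_voxel_index",
    "vectorize",
    "scatter_to_volume",
]

#: FWHM = 2*sqrt(2*ln 2) * sigma for a Gaussian kernel.
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

# Kernel truncation radius in sigmas. 6 sigma leaves ~2e-9 of the mass in the
# tails, so interior voxels match a dense full-kernel convolution to <1e-8.
_TRUNCATE = 6.0


@dataclass
class FeatureMatrix:
    """Preprocessed cohort as an ``n_subjects x n_voxels`` matrix.

    ``voxel_index`` maps column -> (i, j, k) mask voxel, in ascending
    (k, j, i) lexicographic order. ``normalization_record`` pins the
    smoothing FWHM, scaling target and mask identity so that a frozen model
    can refuse inputs preprocessed differently.
    """

    values: np.ndarray
    voxel_index: np.ndarray
    subject_ids: list
    labels: np.ndarray
    normalization_record: dict

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if len(self.subject_ids) != self.values.shape[0]:
            raise ValueError("subject_ids length must match rows")
        if self.labels.shape[0] != self.values.shape[0]:
            raise ValueError("labels length must match rows")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def subset(self, rows) -> "FeatureMatrix":
        rows = np.asarray(rows)
        return FeatureMatrix(
            values=self.values[rows],
            voxel_index=self.voxel_index,
            subject_ids=[self.subject_ids[r] for r in np.atleast_1d(rows)],
            labels=self.labels[rows],
            normalization_record=self.normalization_record,
        )

    def with_labels(self, labels) -> "FeatureMatrix":
        """Same features with replacement labels (used by permutation nulls)."""
        return FeatureMatrix(
            values=self.values,
            voxel_index=self.voxel_index,
            subject_ids=self.subject_ids,
            labels=np.asarray(labels, dtype=int),
            normalization_record=self.normalization_record,
        )


def smooth_gaussian(vol: Volume, fwhm_mm: float) -> Volume:
    """Separable Gaussian smoothing with per-axis sigma = FWHM/(2√(2 ln 2))/voxel.

    Boundary handling is truncated-kernel convolution renormalized by the
    convolved indicator of the grid, so a constant field maps to itself
    everywhere, including at the edges.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / vol.voxel_size_mm
    num = ndimage.gaussian_filter(vol.data, sigma=sigma_vox, mode="constant",
                                  cval=0.0, truncate=_TRUNCATE)
    den = ndimage.gaussian_filter(np.ones_like(vol.data), sigma=sigma_vox,
                                  mode="constant", cval=0.0, truncate=_TRUNCATE)
    return Volume(data=num / den, affine=vol.affine)


def proportional_scale(vol: Volume, mask: BrainMask, target: float = 50.0) -> Volume:
    """Rescale so the mean over the brain mask equals ``target``.

    Removes per-subject global uptake/dose differences: ``scale(c·X) ==
    scale(X)`` for any c > 0.
    """
    if vol.shape != mask.shape:
        raise ValueError(f"volume grid {vol.shape} != mask grid {mask.shape}")
    if target <= 0:
        raise ValueError("target must be positive")
    m = float(vol.data[mask.data].mean())
    if m <= 0:
        raise ValueError(f"mask mean is non-positive ({m}); pathological scan")
    return Volume(data=vol.data * (target / m), affine=vol.affine)


def mask_voxel_index(mask: BrainMask) -> np.ndarray:
    """Column order of the feature matrix: mask voxels sorted ascending by
    (k, j, i); rows are (i, j, k) triples."""
    kji = np.argwhere(np.transpose(mask.data, (2, 1, 0)))
    return kji[:, ::-1].copy()


def vectorize(cohort, mask: BrainMask | None = None, fwhm_mm: float = 8.0,
              target: float = 50.0) -> FeatureMatrix:
    """Smooth, proportionally scale and flatten every subject of a cohort.

    Row order follows the cohort; each row depends only on its own subject.
    """
    if mask is None:
        mask = cohort.mask
    if len(cohort.subjects) == 0:
        raise ValueError("empty cohort")
    idx = mask_voxel_index(mask)
    rows, ids, labels = [], [], []
    for subject_id, label, vol in cohort.subjects:
        if vol.shape != mask.shape:
            raise ValueError(
                f"subject {subject_id}: grid {vol.shape} != mask grid {mask.shape}"
            )
        v = smooth_gaussian(vol, fwhm_mm) if fwhm_mm else vol
        v = proportional_scale(v, mask, target)
        rows.append(v.data[idx[:, 0], idx[:, 1], idx[:, 2]])
        ids.append(subject_id)
        labels.append(label)
    record = {
        "fwhm_mm": float(fwhm_mm),
        "target": float(target),
        "mask_checksum": mask_checksum(mask),
        "grid_shape": list(mask.shape),
        "voxel_size_mm": [float(s) for s in mask.voxel_size_mm],
        "voxel_order": "kji_ascending",
    }
    return FeatureMatrix(values=np.array(rows), voxel_index=idx, subject_ids=ids,
                         labels=np.array(labels), normalization_record=record)


def scatter_to_volume(values: np.ndarray, voxel_index: np.ndarray,
                      mask: BrainMask) -> Volume:
    """Inverse of the flattening step: place per-voxel values back on the grid."""
    values = np.asarray(values, dtype=np.float64)
    if values.shape[0] != voxel_index.shape[0]:
        raise ValueError("values length does not match voxel_index")
    grid = np.zeros(mask.shape, dtype=np.float64)
    grid[voxel_index[:, 0], voxel_index[:, 1], voxel_index[:, 2]] = values
    return Volume(data=grid, affine=mask.affine)
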