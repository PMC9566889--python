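"""Permutation inference on classifier voxel weights.

The null distribution of each voxel weight is built by retraining the full
SVM on label-permuted data (class sizes preserved) and accumulating, per
voxel, how often the permuted |weight| reaches the true model's |weight|.
The per-voxel p-value is that exceedance proportion; thresholding the true
signed weight map at p < α yields the signed conversion-pattern map
(positive = relative hypermetabolism predictive of conversion, negative =
relative hypometabolism).

Inference is per-voxel and uncorrected — no family-wise or FDR adjustment is
applied; see the methods note. Ties count as exceedances by default, so the
smallest attainable p is 1/n_permutations; the strict-inequality variant and
an add-one (b+1)/(n+1) estimator are available behind flags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import BrainMask, Volume
from .preprocess import FeatureMatrix, scatter_to_volume
from .svm import HyperplaneModel, SvmParams, _train_weights, train_svm

__all__ = [
    "VoxelPValueMap",
    "PermutationNullResult",
    "permutation_null",
    "voxel_pvalues",
    "threshold_pattern",
]


@dataclass
class VoxelPValueMap:
    """Per-voxel permutation p-values plus the signed significance calls."""

    p: np.ndarray
    n_permutations: int
    signed_significant: np.ndarray  # in {-1, 0, +1}
    alpha: float
    seed: int | None = None

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=np.float64)
        if np.any(self.p < 0) or np.any(self.p > 1):
            raise ValueError("p-values must lie in [0, 1]")


@dataclass
class PermutationNullResult:
    """Streamed summary of the permutation null: per-voxel exceedance counts
    against the true model (null weight maps are never stored)."""

    true_model: HyperplaneModel
    exceedance_counts: np.ndarray
    n_effective: int
    n_failed: int
    seed: int


def _statistic(w: np.ndarray, normalize: str | None) -> np.ndarray:
    if normalize is None:
        return np.abs(w)
    if normalize == "l2":
        nrm = float(np.linalg.norm(w))
        return np.abs(w) / (nrm if nrm > 0 else 1.0)
    raise ValueError(f"unknown normalize mode: {normalize!r}")


def permutation_null(features: FeatureMatrix, params: SvmParams | None = None,
                     n_permutations: int = 1000, seed: int = 0,
                     strict: bool = False, normalize: str | None = "l2",
                     permutation_sampler=None) -> PermutationNullResult:
    """Train the true model, then ``n_permutations`` label-shuffled models.

    Labels are uniformly shuffled (class sizes preserved) and the model
    fully retrained with identical hyperparameters; per voxel the count of
    permuted |weight| ≥ true |weight| is accumulated (strictly > with
    ``strict=True``). Reproducible from ``seed``. A permutation whose fit
    fails is excluded and reported via ``n_failed``.

    By default each weight map is L2-normalized before comparison
    (``normalize="l2"``), so the per-voxel statistic is the *relative*
    weight magnitude. The global weight scale of a soft-margin SVM is the
    inverse margin: a strongly separated labeling yields uniformly small
    weights and a label-shuffled, barely separable one uniformly large
    weights, so the raw comparison loses all power exactly when the signal
    is strong. Normalization removes that scale nuisance while leaving the
    null distribution exchangeable (calibration is unaffected); pass
    ``normalize=None`` for the raw-magnitude comparison.

    ``permutation_sampler(rng, labels) -> labels`` may be injected for
    testing (e.g. forcing the identity permutation).
    """
    params = params or SvmParams()
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    true_model = train_svm(features, params)
    abs_true = _statistic(true_model.weights, normalize)

    X, y = features.values, features.labels
    gram = X @ X.T / params.kernel_scale**2 + params.kernel_offset
    rng = np.random.default_rng(seed)
    counts = np.zeros(features.n_voxels, dtype=np.int64)
    n_failed = 0
    for _ in range(n_permutations):
        if permutation_sampler is not None:
            y_perm = np.asarray(permutation_sampler(rng, y), dtype=int)
        else:
            y_perm = rng.permutation(y)
        try:
            w_perm, _ = _train_weights(X, y_perm, params, gram=gram)
        except (RuntimeError, ValueError):
            n_failed += 1
            continue
        stat_perm = _statistic(w_perm, normalize)
        if strict:
            counts += stat_perm > abs_true
        else:
            counts += stat_perm >= abs_true
    n_effective = n_permutations - n_failed
    return PermutationNullResult(true_model=true_model, exceedance_counts=counts,
                                 n_effective=n_effective, n_failed=n_failed,
                                 seed=seed)


def voxel_pvalues(true_model: HyperplaneModel, exceedance_counts: np.ndarray,
                  n_effective: int, alpha: float = 0.05,
                  add_one: bool = False, seed: int | None = None
                  ) -> VoxelPValueMap:
    """p_v = exceedance count / n_effective (``add_one`` switches to the
    (b+1)/(n+1) estimator); signed significance from the true weight sign."""
    counts = np.asarray(exceedance_counts)
    if n_effective < 1:
        raise ValueError("n_effective must be >= 1")
    if np.any(counts > n_effective) or np.any(counts < 0):
        raise ValueError("exceedance counts must lie in [0, n_effective]")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if add_one:
        p = (counts + 1.0) / (n_effective + 1.0)
    else:
        p = counts / float(n_effective)
    signed = np.where(p < alpha, np.sign(true_model.weights), 0.0).astype(np.int8)
    return VoxelPValueMap(p=p, n_permutations=int(n_effective),
                          signed_significant=signed, alpha=alpha, seed=seed)


def threshold_pattern(pmap: VoxelPValueMap, true_model: HyperplaneModel,
                      alpha: float | None = None,
                      mask: BrainMask | None = None) -> Volume:
    """Signed pattern map: the true weight where p < alpha, zero elsewhere.

    Positive voxels mark relative hypermetabolism predictive of conversion,
    negative voxels relative hypometabolism. Returned on the mask grid,
    ready to write as NIfTI.
    """
    alpha = pmap.alpha if alpha is None else alpha
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    mask = mask if mask is not None else true_model.mask
    if mask is None:
        raise ValueError("a brain mask is required to lay out the pattern volume")
    if len(pmap.p) != len(true_model.weights):
        raise ValueError("p-map and model voxel counts differ")
    values = np.where(pmap.p < alpha, true_model.weights, 0.0)
    return scatter_to_volume(values, true_model.voxel_index, mask)
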