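"""Soft-margin linear SVM with a fixed hyperparameter contract.

The classifier is trained in the dual on the kernel

    k(x, y) = (x · y) / kernel_scale² + kernel_offset

with per-class misclassification costs and an optional robust "outlier
fraction": after an initial fit, the configured fraction of training points
with the largest slack is dropped and the model refit once (with
``outlier_fraction = 0`` the plain SVM is recovered). The solved hyperplane
is exported in primal form — one weight per mask voxel plus a bias — and a
subject score is the dot product of a preprocessed image with the weight map
plus the bias; a positive score predicts the converter class.

The contract is the optimization problem, not any particular solver: any
solver whose scores agree with a dense quadratic-programming reference (see
:mod:`petstratify.reference`) is conforming. Note that because the dual
carries the equality constraint Σ αᵢyᵢ = 0, a constant kernel offset cannot
change the optimal dual variables; its contribution to the decision function
is absorbed exactly into the exported bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import SVC

from .io_formats import BrainMask
from .preprocess import FeatureMatrix

__all__ = ["SvmParams", "HyperplaneModel", "train_svm", "subject_score", "classify"]


@dataclass(frozen=True)
class SvmParams:
    """Training hyperparameters.

    Defaults follow the reference protocol: 5% outlier fraction, symmetric
    unit misclassification cost, kernel offset 0.1, kernel scale 1, up to
    10⁶ optimization iterations. ``box_constraint`` is the soft-margin C.
    No feature standardization is applied anywhere; proportional scaling is
    the only normalization.
    """

    outlier_fraction: float = 0.05
    misclassification_cost: tuple = ((0.0, 1.0), (1.0, 0.0))
    kernel_offset: float = 0.1
    kernel_scale: float = 1.0
    max_iterations: int = 1_000_000
    convergence_tolerance: float = 1e-8
    box_constraint: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.outlier_fraction < 1.0:
            raise ValueError("outlier_fraction must be in [0, 1)")
        cost = np.asarray(self.misclassification_cost, dtype=float)
        if cost.shape != (2, 2) or cost[0, 0] != 0 or cost[1, 1] != 0 or np.any(cost < 0):
            raise ValueError("misclassification_cost must be 2x2, nonnegative, zero diagonal")
        if self.kernel_offset < 0:
            raise ValueError("kernel_offset must be >= 0")
        if self.kernel_scale <= 0 or self.box_constraint <= 0:
            raise ValueError("kernel_scale and box_constraint must be > 0")
        if self.max_iterations < 1 or self.convergence_tolerance <= 0:
            raise ValueError("max_iterations >= 1 and convergence_tolerance > 0 required")

    @property
    def class_weights(self) -> dict:
        """Per-class penalty weights: cost of misclassifying a true member."""
        cost = np.asarray(self.misclassification_cost, dtype=float)
        return {0: cost[0, 1], 1: cost[1, 0]}

    def to_dict(self) -> dict:
        return {
            "outlier_fraction": self.outlier_fraction,
            "misclassification_cost": [list(r) for r in np.asarray(self.misclassification_cost, float)],
            "kernel_offset": self.kernel_offset,
            "kernel_scale": self.kernel_scale,
            "max_iterations": self.max_iterations,
            "convergence_tolerance": self.convergence_tolerance,
            "box_constraint": self.box_constraint,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SvmParams":
        d = dict(d)
        d["misclassification_cost"] = tuple(tuple(r) for r in d["misclassification_cost"])
        return cls(**d)


@dataclass
class HyperplaneModel:
    """Trained linear decision boundary: per-voxel weights plus bias.

    ``voxel_index`` ties weight columns to mask voxels; the normalization
    record pins the preprocessing a scored image must have received.
    """

    weights: np.ndarray
    bias: float
    params: SvmParams
    voxel_index: np.ndarray
    mask: BrainMask | None = None
    normalization_record: dict | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if self.voxel_index is not None and len(self.weights) != len(self.voxel_index):
            raise ValueError("weights and voxel_index lengths differ")

    @property
    def kernel_offset(self) -> float:
        return self.params.kernel_offset

    def score(self, x: np.ndarray) -> float:
        return subject_score(self, x)


def _fit_once(X: np.ndarray, y: np.ndarray, params: SvmParams, gram: np.ndarray):
    """Solve the dual on the offset linear kernel; export primal (w, b)."""
    svc = SVC(
        C=params.box_constraint,
        kernel="precomputed",
        class_weight=params.class_weights,
        tol=params.convergence_tolerance,
        max_iter=int(params.max_iterations),
        shrinking=True,
        cache_size=64,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            svc.fit(gram, y)
        except ConvergenceWarning as exc:  # pragma: no cover - rare path
            raise RuntimeError(
                f"SVM did not converge within {params.max_iterations} iterations"
            ) from exc
    dual = svc.dual_coef_.ravel()  # alpha_i * y_i on support vectors
    sv = svc.support_
    w = (X[sv].T @ dual) / params.kernel_scale**2
    # offset contributes offset * sum(alpha_i y_i) to every decision value;
    # sum(alpha_i y_i) = 0 at optimality, but absorb it exactly regardless.
    b = float(svc.intercept_[0] + params.kernel_offset * dual.sum())
    return w, b


def _slack(X, y, w, b) -> np.ndarray:
    y_pm = 2 * y - 1
    return np.maximum(0.0, 1.0 - y_pm * (X @ w + b))


def _train_weights(X: np.ndarray, y: np.ndarray, params: SvmParams,
                   gram: np.ndarray | None = None):
    """Full training path (initial fit + optional outlier trimming).

    ``gram`` may be supplied to reuse a precomputed kernel across repeated
    fits on the same features (cross-validation folds index into it;
    permutation nulls reuse it outright).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    classes = np.unique(y)
    if classes.size != 2 or not np.array_equal(classes, [0, 1]):
        raise ValueError("training requires both classes 0 and 1")
    if len(y) < 4:
        raise ValueError("need at least 4 subjects to train")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features")
    if gram is None:
        gram = X @ X.T / params.kernel_scale**2 + params.kernel_offset
    w, b = _fit_once(X, y, params, gram)
    if params.outlier_fraction > 0:
        xi = _slack(X, y, w, b)
        n_drop = int(np.ceil(params.outlier_fraction * len(y)))
        # only points with positive slack are candidate outliers
        candidates = np.flatnonzero(xi > 0)
        if candidates.size:
            order = candidates[np.argsort(-xi[candidates], kind="stable")]
            drop = order[:n_drop]
            keep = np.setdiff1d(np.arange(len(y)), drop)
            if np.unique(y[keep]).size == 2 and keep.size >= 4:
                w, b = _fit_once(X[keep], y[keep], params,
                                 gram[np.ix_(keep, keep)])
    return w, b


def train_svm(features: FeatureMatrix, params: SvmParams | None = None,
              mask: BrainMask | None = None, provenance: dict | None = None
              ) -> HyperplaneModel:
    """Train the classifier on a preprocessed feature matrix.

    Deterministic for fixed inputs; raises on single-class input, fewer than
    4 subjects, non-finite features, or non-convergence.
    """
    params = params or SvmParams()
    w, b = _train_weights(features.values, features.labels, params)
    prov = {"n_subjects": features.n_subjects,
            "n_per_class": [int((features.labels == 0).sum()),
                            int((features.labels == 1).sum())],
            "seed": params.seed}
    if provenance:
        prov.update(provenance)
    return HyperplaneModel(
        weights=w,
        bias=b,
        params=params,
        voxel_index=features.voxel_index,
        mask=mask,
        normalization_record=features.normalization_record,
        provenance=prov,
    )


def subject_score(model: HyperplaneModel, x: np.ndarray,
                  normalization_record: dict | None = None) -> float:
    """Score = Σ_v w_v x_v + bias for an image vector aligned to the model.

    If the caller supplies a normalization record it must match the model's
    training record exactly — a frozen classifier never silently rescales.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    if x.shape[0] != model.weights.shape[0]:
        raise ValueError(
            f"image vector has {x.shape[0]} voxels, model expects {model.weights.shape[0]}"
        )
    if normalization_record is not None and model.normalization_record is not None:
        if normalization_record != model.normalization_record:
            raise ValueError("normalization record does not match the model's training record")
    return float(model.weights @ x + model.bias)


def classify(score: float) -> int:
    """Positive score ⇒ converter (1); non-positive ⇒ stable (0)."""
    if not np.isfinite(score):
        raise ValueError("score must be finite")
    return int(score > 0)
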