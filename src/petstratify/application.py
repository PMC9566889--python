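"""Apply a frozen classifier to external cohorts.

Every applied subject is preprocessed with the exact pipeline recorded at
training time (smoothing FWHM, scaling target, brain mask); any mismatch is
a hard error — a frozen clinical classifier must never quietly change its
preprocessing. Outputs are per-subject scores/labels, the proportion
classified as converter, the paired ON/OFF-medication score test, and label
agreement counts between paired conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import vectorize
from .svm import HyperplaneModel, classify

__all__ = [
    "CohortClassification",
    "PairedScoreTest",
    "apply_to_cohort",
    "paired_score_test",
    "label_agreement",
]


@dataclass
class CohortClassification:
    per_subject: pd.DataFrame  # subject_id, score, label
    proportion_converter: float
    cohort_name: str = ""


@dataclass(frozen=True)
class PairedScoreTest:
    t: float
    df: int
    p: float
    mean_difference: float


def apply_to_cohort(model: HyperplaneModel, cohort, cohort_name: str = "",
                    fwhm_mm: float | None = None, target: float | None = None
                    ) -> CohortClassification:
    """Preprocess, score and label every subject of a cohort.

    Preprocessing parameters default to the model's training record; if
    passed explicitly they must match it. The cohort's grid/mask must match
    the training mask.
    """
    record = model.normalization_record
    if record is None:
        raise ValueError("model carries no normalization record; cannot apply safely")
    if fwhm_mm is not None and float(fwhm_mm) != record["fwhm_mm"]:
        raise ValueError(
            f"requested fwhm_mm={fwhm_mm} != training record {record['fwhm_mm']}"
        )
    if target is not None and float(target) != record["target"]:
        raise ValueError(
            f"requested target={target} != training record {record['target']}"
        )
    if model.mask is None:
        raise ValueError("model carries no brain mask")
    features = vectorize(cohort, mask=model.mask,
                         fwhm_mm=record["fwhm_mm"], target=record["target"])
    if features.normalization_record != record:
        raise ValueError("normalization record mismatch between model and cohort")
    scores = features.values @ model.weights + model.bias
    labels = np.array([classify(s) for s in scores])
    per_subject = pd.DataFrame({
        "subject_id": features.subject_ids,
        "score": scores,
        "label": labels,
    })
    return CohortClassification(
        per_subject=per_subject,
        proportion_converter=float(labels.mean()),
        cohort_name=cohort_name,
    )


def paired_score_test(scores_off, scores_on) -> PairedScoreTest:
    """Classical paired t test on ON−OFF score differences (two-sided).

    t = mean(d) / (sd(d)/√n) with the sample SD (n−1 divisor), df = n−1.
    Raises on zero variance of the differences (t undefined).
    """
    off = np.asarray(scores_off, dtype=np.float64)
    on = np.asarray(scores_on, dtype=np.float64)
    if off.shape != on.shape or off.ndim != 1:
        raise ValueError("paired score lists must be 1-D and of equal length")
    n = off.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = on - off
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of paired differences; t undefined")
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2 * stats.t.sf(abs(t), df=n - 1))
    return PairedScoreTest(t=t, df=n - 1, p=p, mean_difference=float(d.mean()))


def label_agreement(labels_a, labels_b):
    """(n_agree, n_total) between two equal-length label vectors."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    return int(np.sum(a == b)), int(a.size)
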