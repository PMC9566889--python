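"""Synthetic FDG-PET cohort generator.

Emulates the statistical structure of smoothed, globally-scaled uptake
volumes from two patient groups: a shared brain-like template, class-specific
regional hypo-/hypermetabolism (multiplicative fractions of the template, so
effects scale with local intensity), subject-level multiplicative global
uptake factors (tracer dose / global metabolism nuisance — exactly what
proportional scaling is meant to remove), and additive Gaussian noise inside
the brain mask.

Subject ``i`` of class ``c`` is

    g_i * (template ⊙ (1 + c·E)) + ε_i,   optionally smoothed,

where ``E`` is the signed effect field (±amplitude inside each planted
sphere, 0 elsewhere), ``g_i`` is lognormal with median 1 and log-SD
``global_scale_sd``, and ``ε_i`` is i.i.d. N(0, noise_sd²) inside the mask.
Class 0 ("stable-like") carries no effect; class 1 ("converter-like")
carries the full field, matching the positive-score ⇒ converter convention.

The default grid is coarse (32×40×32 at 4 mm, ≈1.8×10⁴ mask voxels) so that
full permutation suites run at desk scale; it is configurable upward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import BrainMask, Volume, _default_affine
from .preprocess import smooth_gaussian

__all__ = [
    "EffectRegion",
    "SimulationConfig",
    "Cohort",
    "default_effect_regions",
    "make_phantom",
    "simulate_cohort",
    "effect_field",
    "planted_voxels",
]


@dataclass(frozen=True)
class EffectRegion:
    """A planted spherical effect: ±amplitude (fraction of template) inside
    a sphere given in voxel coordinates."""

    center: tuple
    radius_voxels: float
    sign: str  # "hypo" or "hyper"
    amplitude: float

    def __post_init__(self):
        if self.sign not in ("hypo", "hyper"):
            raise ValueError("sign must be 'hypo' or 'hyper'")
        if not 0.0 <= self.amplitude < 1.0:
            raise ValueError("amplitude must be in [0, 1)")

    @property
    def signed_amplitude(self) -> float:
        return -self.amplitude if self.sign == "hypo" else self.amplitude


def default_effect_regions(amplitude: float = 0.3) -> list:
    """Default planted pattern on the 32×40×32 grid.

    Two bilateral posterior "temporo-parietal" hypometabolic spheres plus an
    anterior midline "cingulate" and two deep "putamen-like" hypermetabolic
    spheres — a caricature of the converter pattern (posterior hypo-,
    anterior/deep hypermetabolism), sized so the planted set covers ~10% of
    the brain mask.
    """
    return [
        EffectRegion(center=(10, 12, 20), radius_voxels=5, sign="hypo", amplitude=amplitude),
        EffectRegion(center=(22, 12, 20), radius_voxels=5, sign="hypo", amplitude=amplitude),
        EffectRegion(center=(16, 28, 16), radius_voxels=5, sign="hyper", amplitude=amplitude),
        EffectRegion(center=(12, 24, 11), radius_voxels=4, sign="hyper", amplitude=amplitude),
        EffectRegion(center=(20, 24, 11), radius_voxels=4, sign="hyper", amplitude=amplitude),
    ]


@dataclass
class SimulationConfig:
    """Study conditions for one simulated cohort.

    ``n_per_class`` is (n stable-like, n converter-like); the default 20/23
    mirrors a ~20-subject-per-class training cohort. ``noise_sd`` and
    amplitudes are in units of the template (outer-shell intensity ≈ 1).
    ``smoothing_fwhm_mm`` defaults to 0: the generator emits raw-like
    volumes and the preprocessing stage owns the 8 mm smoothing.
    """

    grid_shape: tuple = (32, 40, 32)
    voxel_size_mm: tuple = (4.0, 4.0, 4.0)
    n_per_class: tuple = (20, 23)
    effect_regions: list = field(default_factory=default_effect_regions)
    noise_sd: float = 0.1
    global_scale_sd: float = 0.05
    smoothing_fwhm_mm: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if any(s < 8 for s in self.grid_shape):
            raise ValueError("degenerate grid: need >= 8 voxels per axis")
        if self.noise_sd < 0 or self.global_scale_sd < 0 or self.smoothing_fwhm_mm < 0:
            raise ValueError("noise_sd, global_scale_sd, smoothing_fwhm_mm must be >= 0")
        if any(n < 0 for n in self.n_per_class):
            raise ValueError("n_per_class must be nonnegative")


@dataclass
class Cohort:
    """Ordered labeled subjects sharing one grid and brain mask."""

    subjects: list  # of (subject_id, label in {0,1}, Volume)
    mask: BrainMask
    provenance: object = None

    def __post_init__(self):
        for sid, label, vol in self.subjects:
            if vol.shape != self.mask.shape:
                raise ValueError(f"subject {sid}: grid mismatch with mask")
            if label not in (0, 1):
                raise ValueError(f"subject {sid}: label must be 0 or 1")

    @property
    def labels(self) -> np.ndarray:
        return np.array([label for _, label, _ in self.subjects], dtype=int)

    @property
    def subject_ids(self) -> list:
        return [sid for sid, _, _ in self.subjects]


def _ellipsoid_radius(shape) -> np.ndarray:
    """Normalized ellipsoid radius field (r=0 center, r=1 at the mask edge)."""
    axes = [np.arange(s, dtype=np.float64) for s in shape]
    centers = [(s - 1) / 2.0 for s in shape]
    semi = [(s - 2) / 2.0 for s in shape]
    ii, jj, kk = np.meshgrid(*axes, indexing="ij")
    return np.sqrt(
        ((ii - centers[0]) / semi[0]) ** 2
        + ((jj - centers[1]) / semi[1]) ** 2
        + ((kk - centers[2]) / semi[2]) ** 2
    )


def make_phantom(config: SimulationConfig):
    """Deterministic brain-like template and ellipsoidal mask.

    Inside the mask the template is a smooth, strictly positive field with
    an outer shell near 1.0 and elevated central "deep gray" intensity
    (≈1.75 at the center); zero outside. No randomness is involved.
    """
    r = _ellipsoid_radius(config.grid_shape)
    mask_data = r <= 1.0
    template = np.zeros(config.grid_shape, dtype=np.float64)
    inside = mask_data
    # outer shell ~1.0 (value at r=1 is 1 + 0.75*exp(-4) ≈ 1.014)
    template[inside] = 1.0 + 0.75 * np.exp(-((r[inside] / 0.5) ** 2))
    affine = _default_affine(config.voxel_size_mm)
    return (
        Volume(data=template, affine=affine),
        BrainMask(data=mask_data, affine=affine),
    )


def effect_field(config: SimulationConfig, mask: BrainMask) -> np.ndarray:
    """Signed effect field E: ±amplitude inside each planted sphere.

    Raises if any region escapes the brain mask (planted truth must be
    fully recoverable in principle).
    """
    shape = mask.shape
    ii, jj, kk = np.meshgrid(*(np.arange(s, dtype=np.float64) for s in shape),
                             indexing="ij")
    E = np.zeros(shape, dtype=np.float64)
    for reg in config.effect_regions:
        ci, cj, ck = reg.center
        inside = ((ii - ci) ** 2 + (jj - cj) ** 2 + (kk - ck) ** 2
                  ) <= reg.radius_voxels ** 2
        if np.any(inside & ~mask.data):
            raise ValueError(
                f"effect region centered at {reg.center} escapes the brain mask"
            )
        E[inside] = reg.signed_amplitude
    return E


def planted_voxels(config: SimulationConfig, mask: BrainMask) -> np.ndarray:
    """Boolean grid of voxels carrying a nonzero planted effect."""
    return effect_field(config, mask) != 0


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Simulate a two-class cohort; bit-reproducible from ``config.seed``.

    Class 0 subjects come first, then class 1. With ``noise_sd=0``,
    ``global_scale_sd=0`` and no effect regions every subject's volume is
    the template, exactly.
    """
    template, mask = make_phantom(config)
    E = effect_field(config, mask)
    rng = np.random.default_rng(config.seed)
    subjects = []
    n0, n1 = config.n_per_class
    for label, n in ((0, n0), (1, n1)):
        signal = template.data * (1.0 + label * E)
        for i in range(n):
            data = signal
            if config.global_scale_sd > 0:
                g = rng.lognormal(mean=0.0, sigma=config.global_scale_sd)
                data = data * g
            if config.noise_sd > 0:
                eps = rng.normal(0.0, config.noise_sd, size=mask.shape)
                data = data + np.where(mask.data, eps, 0.0)
            vol = Volume(data=np.array(data, dtype=np.float64, copy=True),
                         affine=template.affine)
            if config.smoothing_fwhm_mm > 0:
                vol = smooth_gaussian(vol, config.smoothing_fwhm_mm)
            subjects.append((f"sub-{label}{i:03d}", label, vol))
    return Cohort(subjects=subjects, mask=mask, provenance=config)
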