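"""Digital vessel-phantom generator with known ground truth.

Emulates the imaging substrate of a contrast-enhanced coronary CT scan
reconstructed on a 3-kernel x 4-sharpness-level grid: a circular
high-attenuation vessel cross-section (~800 HU lumen) embedded in
low-attenuation pericoronary fat (~-80 HU), blurred by a kernel-dependent
isotropic Gaussian point-spread function and corrupted by kernel-dependent
white Gaussian noise. Sharper kernel levels blur less and carry more noise,
mirroring the resolution/noise trade-off of clinical reconstruction kernels
(Br = body regular, Bv = body vascular, Qr = quantum regular; levels
36/40/44/48).

The module also generates 1D edge profiles directly from the double-sigmoid
pulse model (the forward model of the sharpness fit) and two-reader 5-point
Likert rating tables from a latent-quality ordinal model, so the statistics
layer can be exercised with known ground truth.

Everything is reproducible: a fixed seed yields bit-identical images and
tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .image_io import CircularROI, ImageVolume, ProfileSite
from .sharpness import LineProfile, evaluate_double_sigmoid

FAMILIES = ("Br", "Bv", "Qr")
LEVELS = (36, 40, 44, 48)
CRITERIA = ("overall", "noise", "sharp_coronaries")
SUPERSAMPLE = 8  # anti-aliasing subdivision per pixel edge


@dataclass(frozen=True)
class KernelSpec:
    """One reconstruction configuration of the kernel grid.

    ``psf_sigma`` (mm) is the Gaussian blur of the reconstruction;
    ``noise_sd`` (HU) the white-noise level; ``attenuation_bias`` (HU) an
    additive family-specific lumen offset emulating the spectral attenuation
    differences between kernel families.
    """

    family: str
    level: int
    psf_sigma: float
    noise_sd: float
    attenuation_bias: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.level not in LEVELS:
            raise ValueError(f"unknown sharpness level {self.level}")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be > 0 mm")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0 HU")

    @property
    def name(self) -> str:
        return f"{self.family}{self.level}"


# Default grid calibration.
#
# noise_sd: per-cell image-noise levels (HU) of a clinical photon-counting
# CCTA protocol; strictly increasing with level within each family.
# psf_sigma: chosen so that the noiseless phantom pipeline yields fitted
# sharpness values in the clinically observed 3-7 /mm range, ordered
# Bv > Br ~ Qr at every level and increasing with level within each family
# (sigma strictly decreasing). attenuation_bias orders mean lumen
# attenuation Br > Bv > Qr without modelling spectral physics.
_NOISE_SD = {
    "Br": (37.9, 50.5, 72.4, 79.3),
    "Bv": (38.0, 48.8, 71.3, 78.1),
    "Qr": (37.4, 48.0, 70.6, 90.8),
}
_PSF_SIGMA = {
    "Br": (0.482, 0.397, 0.375, 0.336),
    "Bv": (0.282, 0.241, 0.208, 0.192),
    "Qr": (0.465, 0.410, 0.375, 0.336),
}
_ATTENUATION_BIAS = {"Br": 40.0, "Bv": 15.0, "Qr": 0.0}


def default_kernel_grid() -> list[KernelSpec]:
    """The 12 default reconstruction configurations (3 families x 4 levels)."""
    return [
        KernelSpec(
            family=fam,
            level=lvl,
            psf_sigma=_PSF_SIGMA[fam][i],
            noise_sd=_NOISE_SD[fam][i],
            attenuation_bias=_ATTENUATION_BIAS[fam],
        )
        for fam in FAMILIES
        for i, lvl in enumerate(LEVELS)
    ]


@dataclass(frozen=True)
class PhantomSpec:
    """A single-vessel phantom image: geometry, attenuations and kernel."""

    vessel_diameter: float  # mm, >= 2 (the study measures vessels >= 2 mm)
    kernel: KernelSpec
    seed: int
    vessel_hu: float = 800.0
    fat_hu: float = -80.0
    field_of_view: float = 19.2  # mm
    pixel_spacing: float = 0.3  # mm

    def __post_init__(self) -> None:
        if self.vessel_diameter < 2.0:
            raise ValueError("vessel_diameter must be >= 2 mm")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be > 0")
        if self.vessel_hu <= self.fat_hu:
            raise ValueError("vessel_hu must exceed fat_hu")
        if self.vessel_diameter + 2 * 2.0 > self.field_of_view:
            raise ValueError(
                f"vessel of {self.vessel_diameter} mm does not fit in a "
                f"{self.field_of_view} mm field of view with a 2 mm margin"
            )


def _disk_coverage(
    shape: tuple[int, int],
    spacing: float,
    center: tuple[float, float],
    radius: float,
    supersample: int = SUPERSAMPLE,
) -> np.ndarray:
    """Area-weighted (anti-aliased) coverage of a disk on the pixel grid.

    Each pixel is subdivided ``supersample x supersample`` and the inside
    fraction averaged, which removes the grid artifacts a hard threshold
    would imprint on edge fits. Only the disk's bounding box is rendered.
    """
    cov = np.zeros(shape, dtype=float)
    i0 = max(0, int((center[0] - radius) / spacing) - 1)
    i1 = min(shape[0], int((center[0] + radius) / spacing) + 2)
    j0 = max(0, int((center[1] - radius) / spacing) - 1)
    j1 = min(shape[1], int((center[1] + radius) / spacing) + 2)
    if i0 >= i1 or j0 >= j1:
        return cov
    ss = supersample
    fine = spacing / ss
    u = (np.arange(i0 * ss, i1 * ss) + 0.5) * fine - center[0]
    v = (np.arange(j0 * ss, j1 * ss) + 0.5) * fine - center[1]
    inside = (u[:, None] ** 2 + v[None, :] ** 2) <= radius**2
    block = inside.reshape(i1 - i0, ss, j1 - j0, ss).mean(axis=(1, 3))
    cov[i0:i1, j0:j1] = block
    return cov


def _render_scene(
    shape: tuple[int, int],
    spacing: float,
    disks: Sequence[tuple[tuple[float, float], float, float]],
    fat_hu: float,
    psf_sigma: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render anti-aliased disks, blur with the PSF, add white noise.

    ``disks`` holds ``(center_mm, radius_mm, lumen_hu)`` triples; the
    kernel's attenuation bias is folded into ``lumen_hu`` before blurring.
    """
    img = np.full(shape, fat_hu, dtype=float)
    for center, radius, hu in disks:
        img += (hu - fat_hu) * _disk_coverage(shape, spacing, center, radius)
    img = gaussian_filter(img, sigma=psf_sigma / spacing, mode="nearest")
    if noise_sd > 0:
        img += noise_sd * rng.standard_normal(shape)
    return img


def generate_vessel_image(spec: PhantomSpec) -> ImageVolume:
    """Generate a single centred vessel cross-section image.

    The analytic disk (``vessel_hu`` + kernel attenuation bias inside the
    radius, ``fat_hu`` outside) is rendered with area-weighted anti-aliasing,
    convolved with the kernel's Gaussian PSF, and corrupted with i.i.d.
    Gaussian noise. Deterministic for a fixed ``spec.seed``.
    """
    n = int(round(spec.field_of_view / spec.pixel_spacing))
    center = (n * spec.pixel_spacing / 2.0,) * 2
    rng = np.random.default_rng(spec.seed)
    img = _render_scene(
        (n, n),
        spec.pixel_spacing,
        [(center, spec.vessel_diameter / 2.0,
          spec.vessel_hu + spec.kernel.attenuation_bias)],
        spec.fat_hu,
        spec.kernel.psf_sigma,
        spec.kernel.noise_sd,
        rng,
    )
    return ImageVolume(img, (spec.pixel_spacing, spec.pixel_spacing))


# ---------------------------------------------------------------------------
# Subject scene: seven coronary cross-sections plus a fat reference region,
# mimicking the eight-ROI / six-profile-site measurement layout of a CCTA
# reading (left main, proximal+distal RCA/LAD/LCX, pericoronary fat).

SCENE_FOV = 48.0  # mm
SCENE_SPACING = 0.3  # mm
#: label -> (center_mm, diameter_mm); proximal vessels ~3.5 mm, distal ~2 mm
SCENE_VESSELS: dict[str, tuple[tuple[float, float], float]] = {
    "LM": ((10.0, 10.0), 4.0),
    "RCA_prox": ((24.0, 10.0), 3.5),
    "RCA_dist": ((38.0, 10.0), 2.0),
    "LAD_prox": ((10.0, 24.0), 3.5),
    "LAD_dist": ((24.0, 24.0), 2.0),
    "LCX_prox": ((38.0, 24.0), 3.5),
    "LCX_dist": ((24.0, 38.0), 2.0),
}
SCENE_FAT_ROI = CircularROI("fat", (38.0, 38.0), 3.0)
#: lumen-ROI radius per vessel, kept inside the blurred edge
_SCENE_ROI_RADIUS = {"LM": 1.2, "prox": 0.9, "dist": 0.5}


def default_scene_rois() -> list[CircularROI]:
    """The eight measurement ROIs of the subject scene (7 coronary + fat)."""
    rois = []
    for label, (center, _d) in SCENE_VESSELS.items():
        kind = "dist" if label.endswith("dist") else (
            "prox" if label.endswith("prox") else "LM")
        rois.append(CircularROI(label, center, _SCENE_ROI_RADIUS[kind]))
    rois.append(SCENE_FAT_ROI)
    return rois


def default_scene_sites(half_length: float = 5.0, step: float = 0.1) -> list[ProfileSite]:
    """Six profile sites crossing the prox/dist RCA, LAD and LCX vessels.

    Each segment is centred on the vessel axis and crosses both walls, so
    the sampled profile is a full baseline-edge-plateau-edge-baseline pulse.
    """
    return [
        ProfileSite(label, center, (0.0, 1.0), half_length, step)
        for label, (center, _d) in SCENE_VESSELS.items()
        if label != "LM"
    ]


def generate_subject_scene(
    kernel: KernelSpec,
    seed: int,
    vessel_hu: float = 800.0,
    fat_hu: float = -80.0,
) -> ImageVolume:
    """Generate one subject's scene image for a given reconstruction kernel."""
    n = int(round(SCENE_FOV / SCENE_SPACING))
    rng = np.random.default_rng(seed)
    disks = [
        (center, d / 2.0, vessel_hu + kernel.attenuation_bias)
        for center, d in SCENE_VESSELS.values()
    ]
    img = _render_scene(
        (n, n), SCENE_SPACING, disks, fat_hu,
        kernel.psf_sigma, kernel.noise_sd, rng,
    )
    return ImageVolume(img, (SCENE_SPACING, SCENE_SPACING))


def generate_profile(
    b: float,
    A: float,
    s: float,
    x1: float,
    x2: float,
    grid: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> LineProfile:
    """Sample the double-sigmoid pulse on ``grid`` (mm), plus optional noise.

    Exact model evaluation when ``noise_sd`` is zero; the forward model of
    the sharpness fit.
    """
    if x2 <= x1:
        raise ValueError("x2 must exceed x1")
    grid = np.asarray(grid, dtype=float)
    if not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly ascending")
    values = evaluate_double_sigmoid(grid, b, A, s, x1, x2)
    if noise_sd > 0:
        values = values + noise_sd * np.random.default_rng(seed).standard_normal(
            grid.shape
        )
    return LineProfile(grid, np.asarray(values, dtype=float))


# ---------------------------------------------------------------------------
# Synthetic two-reader Likert ratings from a latent-quality ordinal model.


@dataclass(frozen=True)
class RatingModelSpec:
    """Latent-quality ordinal model for synthetic 5-point Likert ratings.

    For each (subject, reconstruction, rater, criterion) a latent value
    ``latent_quality[criterion][(family, level)] + rater_bias[rater] + eps``
    with ``eps ~ N(0, rater_noise_sd)`` is cut into scores 1-5 by four
    ascending thresholds. The latent scale is in score units: thresholds
    (1.5, 2.5, 3.5, 4.5) make a noise-free latent of 4.2 score as "4".
    """

    n_subjects: int
    latent_quality: Mapping[str, Mapping[tuple[str, int], float]]
    rater_bias: tuple[float, ...] = (0.0, 0.0)
    rater_noise_sd: float = 0.0
    thresholds: tuple[float, float, float, float] = (1.5, 2.5, 3.5, 4.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be > 0")
        if self.rater_noise_sd < 0:
            raise ValueError("rater_noise_sd must be >= 0")
        if not all(
            a < b for a, b in zip(self.thresholds, self.thresholds[1:])
        ):
            raise ValueError("thresholds must be strictly ascending")


#: Default latent quality (score units) per criterion and reconstruction,
#: emulating a reading where the vascular kernel at moderate sharpness rates
#: best overall, perceived noise tracks the sharpness level only, and sharp
#: coronary reproduction favours the vascular family.
_DEFAULT_LATENT: dict[str, dict[tuple[str, int], float]] = {
    "overall": {
        **{("Br", lvl): q for lvl, q in zip(LEVELS, (4.3, 4.2, 3.6, 3.4))},
        **{("Bv", lvl): q for lvl, q in zip(LEVELS, (4.8, 4.9, 4.2, 3.9))},
        **{("Qr", lvl): q for lvl, q in zip(LEVELS, (4.2, 4.1, 3.6, 3.3))},
    },
    "noise": {
        (fam, lvl): q
        for fam in FAMILIES
        for lvl, q in zip(LEVELS, (4.8, 4.3, 3.7, 3.0))
    },
    "sharp_coronaries": {
        **{("Br", lvl): q for lvl, q in zip(LEVELS, (4.1, 4.2, 3.7, 3.5))},
        **{("Bv", lvl): q for lvl, q in zip(LEVELS, (4.7, 4.8, 4.3, 4.0))},
        **{("Qr", lvl): q for lvl, q in zip(LEVELS, (4.0, 4.1, 3.6, 3.4))},
    },
}


def default_rating_model(n_subjects: int = 30, seed: int = 0) -> RatingModelSpec:
    """Default two-reader rating model for a 30-subject cohort."""
    return RatingModelSpec(
        n_subjects=n_subjects,
        latent_quality=_DEFAULT_LATENT,
        rater_bias=(0.0, -0.05),
        rater_noise_sd=0.15,
        seed=seed,
    )


def generate_ratings(
    spec: RatingModelSpec, grid: Sequence[KernelSpec]
) -> pd.DataFrame:
    """Generate a tidy two-rater rating table over the reconstruction grid.

    Returns one row per (subject, family, level, rater, criterion) with an
    integer ``score`` in 1-5. Deterministic for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    thresholds = np.asarray(spec.thresholds)
    latents = spec.latent_quality
    if not all(isinstance(v, Mapping) for v in latents.values()):
        # single shared map (family, level) -> latent, applied to every criterion
        latents = {crit: spec.latent_quality for crit in CRITERIA}
    rows = []
    for subject in range(1, spec.n_subjects + 1):
        for kernel in grid:
            for rater, bias in enumerate(spec.rater_bias, start=1):
                for criterion, lat_map in latents.items():
                    z = (
                        lat_map[(kernel.family, kernel.level)]
                        + bias
                        + (spec.rater_noise_sd * rng.standard_normal()
                           if spec.rater_noise_sd > 0 else 0.0)
                    )
                    score = int(np.searchsorted(thresholds, z) + 1)
                    rows.append(
                        (subject, kernel.family, kernel.level, rater,
                         criterion, score)
                    )
    return pd.DataFrame(
        rows,
        columns=["subject", "family", "level", "rater", "criterion", "score"],
    )
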