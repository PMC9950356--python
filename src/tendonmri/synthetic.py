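"""Synthetic MRI-like phantoms, lesion time courses and trichrome-like
histology with exact ground truth.

Each transverse slice emulates the anatomy a transverse metacarpal MRI
shows: a noisy low-intensity background, a soft-tissue limb disc, a dark
cortical-bone annulus around brighter marrow, a palmar SDFT region of
intermediate intensity and — on lesion-bearing levels — a hyperintense
elliptical lesion inside the SDFT.  The lesion is centre-weighted: its
intensity falls off radially from the core, so that a small central ROI
reads brighter than the whole-lesion mean, as freshly injured tendon core
lesions do.  Ground-truth masks are the exact painted regions, so every
mask-derived quantity (CSA, volume, SI on the true mask) is known without
tolerance.

The lesion mean SI is ``SDFT SI × (1 + k·severity)`` with contrast factor
k = 1.5 by default; per-sequence image quality is reduced to a noise
multiplier (FSE/STIR ≈ 3× the GRE noise), emulating the longer, more
motion-prone acquisitions without modelling motion explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .datamodel import ImageGeometry, ImageSlice, ImageStack, RoiMask
from .errors import ParameterError

#: per-sequence noise multipliers (longer acquisitions are noisier)
DEFAULT_SNR_PROFILE = {
    "T1w_GRE": 1.0,
    "T2*w_GRE": 1.25,
    "T2w_FSE": 3.0,
    "STIR": 3.0,
}

# Phantom anatomy (mm, within the 171 mm field of view) and tissue
# intensities (arbitrary units).  The limb disc leaves background room on
# the lateral, medial and palmar sides for the 50 mm² reference ROIs.
LIMB_CENTRE_MM = (85.5, 85.5)
LIMB_RADIUS_MM = 30.0
BONE_CENTRE_MM = (78.0, 85.5)
BONE_OUTER_RADIUS_MM = 15.0
BONE_INNER_RADIUS_MM = 6.5
SDFT_CENTRE_MM = (103.0, 85.5)
SDFT_SEMI_AXES_MM = (5.5, 9.0)  # (row, col): the tendon is wider than tall

BACKGROUND_SI = 20.0
TISSUE_SI = 80.0
BONE_SI = 10.0
MARROW_SI = 85.0
SDFT_SI = 60.0
LESION_CONTRAST_K = 1.5

#: fraction of the SDFT semi-axes the lesion may occupy before it no longer
#: fits with a safety margin
_LESION_FIT_FRACTION = 0.88


@dataclass(frozen=True)
class LesionPhantomParams:
    """Knobs of the lesion phantom.

    severity scales lesion contrast in [0, 1]; max_csa_mm2 is the peak
    per-slice lesion area, reached at max_level_index; the lesion spans
    n_lesion_levels consecutive levels with a parabolic CSA profile;
    noise_sd is the Gaussian noise SD on the GRE reference sequence,
    multiplied per sequence by sequence_snr_profile.
    """

    severity: float = 0.6
    max_csa_mm2: float = 30.0
    max_level_index: int = 6
    n_lesion_levels: int = 5
    noise_sd: float = 8.0
    sequence_snr_profile: dict = field(default_factory=lambda: dict(DEFAULT_SNR_PROFILE))
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.severity <= 1.0:
            raise ParameterError("severity must lie in [0, 1]")
        if self.max_csa_mm2 <= 0:
            raise ParameterError("max_csa_mm2 must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd cannot be negative")
        if self.n_lesion_levels < 1:
            raise ParameterError("n_lesion_levels must be at least 1")


@dataclass
class GroundTruth:
    """Exact ground truth for one generated stack."""

    lesion_masks: list[RoiMask]
    sdft_masks: list[RoiMask]
    bone_mask: RoiMask
    limb_mask: RoiMask
    bone_roi_centre_mm: tuple[float, float]
    true_csa_per_level: list[float]
    true_volume_mm3: float
    severity: float


def _grids(geometry: ImageGeometry) -> tuple[np.ndarray, np.ndarray]:
    s = geometry.pixel_spacing_mm
    coords = (np.arange(geometry.matrix_size) + 0.5) * s
    return coords[:, None], coords[None, :]


def _disc(rr, cc, centre, radius) -> np.ndarray:
    return (rr - centre[0]) ** 2 + (cc - centre[1]) ** 2 <= radius ** 2


def _ellipse(rr, cc, centre, semi_axes) -> np.ndarray:
    a, b = semi_axes
    return ((rr - centre[0]) / a) ** 2 + ((cc - centre[1]) / b) ** 2 <= 1.0


def _lesion_semi_axes(csa_mm2: float) -> tuple[float, float]:
    """Semi-axes of a lesion ellipse with the SDFT's aspect ratio."""
    aspect = SDFT_SEMI_AXES_MM[1] / SDFT_SEMI_AXES_MM[0]
    a = math.sqrt(csa_mm2 / (math.pi * aspect))
    return a, aspect * a


def _csa_profile(params: LesionPhantomParams) -> dict[int, float]:
    """Unimodal (parabolic) per-level target CSA, peaking at max_level_index."""
    n = params.n_lesion_levels
    lo, hi = -((n - 1) // 2), n // 2
    half_span = (n + 1) / 2.0
    return {
        params.max_level_index + o: params.max_csa_mm2 * (1.0 - (o / half_span) ** 2)
        for o in range(lo, hi + 1)
    }


def generate_stack(
    params: LesionPhantomParams,
    geometry: ImageGeometry = ImageGeometry(),
    *,
    n_levels: int = 12,
    sequence_label: str = "T1w_GRE",
    time_point: int = 1,
    subject_id: str = "phantom",
) -> tuple[ImageStack, GroundTruth]:
    """Generate one examination's slice stack with exact ground truth.

    Levels run 0..n_levels−1 (proximal to distal).  Raises
    :class:`ParameterError` when the requested peak lesion does not fit
    inside the SDFT or the lesion levels fall outside the stack.
    """
    rng = np.random.default_rng(params.seed)
    rr, cc = _grids(geometry)
    pixel_area = geometry.pixel_area_mm2

    limb = _disc(rr, cc, LIMB_CENTRE_MM, LIMB_RADIUS_MM)
    bone_outer = _disc(rr, cc, BONE_CENTRE_MM, BONE_OUTER_RADIUS_MM)
    bone_inner = _disc(rr, cc, BONE_CENTRE_MM, BONE_INNER_RADIUS_MM)
    bone = bone_outer & ~bone_inner
    sdft = _ellipse(rr, cc, SDFT_CENTRE_MM, SDFT_SEMI_AXES_MM)

    base = np.full(limb.shape, BACKGROUND_SI)
    base[limb] = TISSUE_SI
    base[bone] = BONE_SI
    base[bone_inner] = MARROW_SI
    base[sdft] = SDFT_SI

    profile = _csa_profile(params) if params.severity > 0 else {}
    if profile:
        a_max, b_max = _lesion_semi_axes(max(profile.values()))
        if (a_max > _LESION_FIT_FRACTION * SDFT_SEMI_AXES_MM[0]
                or b_max > _LESION_FIT_FRACTION * SDFT_SEMI_AXES_MM[1]):
            raise ParameterError(
                f"peak lesion CSA {params.max_csa_mm2} mm² does not fit inside "
                f"the SDFT region"
            )
        if min(profile) < 0 or max(profile) > n_levels - 1:
            raise ParameterError(
                f"lesion levels {min(profile)}..{max(profile)} fall outside the "
                f"stack (0..{n_levels - 1})"
            )

    noise_scale = params.noise_sd * params.sequence_snr_profile.get(sequence_label, 1.0)

    slices: list[ImageSlice] = []
    lesion_masks: list[RoiMask] = []
    sdft_masks: list[RoiMask] = []
    csa_per_level: list[float] = []
    for level in range(n_levels):
        values = base.copy()
        lesion = np.zeros_like(limb)
        target = profile.get(level, 0.0)
        if target >= pixel_area / 2.0:
            semi = _lesion_semi_axes(target)
            lesion = _ellipse(rr, cc, SDFT_CENTRE_MM, semi) & sdft
            if not lesion.any():
                # sub-pixel ellipse: paint the centre pixel
                s = geometry.pixel_spacing_mm
                lesion[int(SDFT_CENTRE_MM[0] / s), int(SDFT_CENTRE_MM[1] / s)] = True
            # centre-weighted radial falloff, normalised so the lesion mean
            # equals SDFT_SI * (1 + k * severity)
            e2 = (((rr - SDFT_CENTRE_MM[0]) / semi[0]) ** 2
                  + ((cc - SDFT_CENTRE_MM[1]) / semi[1]) ** 2)
            falloff = 1.0 - 0.5 * np.clip(e2, 0.0, 1.0)
            mean_falloff = float(falloff[lesion].mean())
            amplitude = LESION_CONTRAST_K * params.severity * SDFT_SI / mean_falloff
            values[lesion] = SDFT_SI + amplitude * falloff[lesion]
        if noise_scale > 0:
            values = values + rng.normal(0.0, noise_scale, size=values.shape)
        np.clip(values, 0.0, None, out=values)
        slices.append(ImageSlice(values, level_index=level,
                                 sequence_label=sequence_label,
                                 time_point=time_point))
        lesion_masks.append(RoiMask(lesion, role="lesion_whole"))
        sdft_masks.append(RoiMask(sdft.copy(), role="sdft"))
        csa_per_level.append(float(lesion.sum()) * pixel_area)

    # a point on the cortical wall, mid-thickness, dorsal of the bone centre
    bone_roi_centre = (
        BONE_CENTRE_MM[0] - (BONE_OUTER_RADIUS_MM + BONE_INNER_RADIUS_MM) / 2.0,
        BONE_CENTRE_MM[1],
    )
    truth = GroundTruth(
        lesion_masks=lesion_masks,
        sdft_masks=sdft_masks,
        bone_mask=RoiMask(bone, role="cortical_bone"),
        limb_mask=RoiMask(limb, role="sdft"),
        bone_roi_centre_mm=bone_roi_centre,
        true_csa_per_level=csa_per_level,
        true_volume_mm3=float(sum(csa_per_level)) * geometry.slice_spacing_mm,
        severity=params.severity,
    )
    stack = ImageStack(geometry, slices, subject_id=subject_id)
    return stack, truth


def child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-object seeds derived from one base seed (< 2³¹)."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)
    return [int(v & 0x7FFFFFFF) for v in state]


def generate_timecourse(
    base: LesionPhantomParams,
    n_timepoints: int,
    shrink_rate: float,
    level_drift: list[int],
    geometry: ImageGeometry = ImageGeometry(),
    *,
    n_levels: int = 12,
    sequence_label: str = "T1w_GRE",
    subject_id: str = "phantom",
) -> list[tuple[ImageStack, GroundTruth]]:
    """Follow-up series: the peak CSA decays geometrically by shrink_rate per
    examination and the maximum-lesion level is offset by level_drift[t],
    emulating the proximo-distal wander of the worst slice over healing."""
    if n_timepoints < 2:
        raise ParameterError("a time course needs at least 2 time points")
    if n_timepoints > 10:
        raise ParameterError("examination indices are limited to 1..10")
    if len(level_drift) != n_timepoints:
        raise ParameterError("level_drift must list one offset per time point")
    seeds = child_seeds(base.seed, n_timepoints)
    series = []
    for t in range(n_timepoints):
        params_t = replace(
            base,
            max_csa_mm2=base.max_csa_mm2 * shrink_rate ** t,
            max_level_index=base.max_level_index + int(level_drift[t]),
            seed=seeds[t],
        )
        series.append(
            generate_stack(
                params_t, geometry, n_levels=n_levels,
                sequence_label=sequence_label, time_point=t + 1,
                subject_id=subject_id,
            )
        )
    return series


# --- trichrome-like histology -------------------------------------------

_BLUE_RGB = np.array([45, 60, 170], dtype=float)
_RED_RGB = np.array([170, 60, 55], dtype=float)
_WHITE = 250.0
_COLOUR_JITTER = 8.0
_MARGIN_PX = 16


def generate_histology(
    blue_fraction: float,
    size: tuple[int, int] = (256, 256),
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Trichrome-like RGB image with a controlled blue-pixel fraction.

    The tissue is an ellipse inside a white margin; blue-dominant
    (collagen-like) pixels form smooth clusters thresholded out of a
    Gaussian random field, so the realised blue share of tissue pixels hits
    the requested fraction exactly up to integer pixel counts (within half
    a percentage point).  Returns the uint8 H×W×3 image and the realised
    fraction.
    """
    if not 0.0 <= blue_fraction <= 1.0:
        raise ParameterError("blue_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    h, w = size
    rr = np.arange(h)[:, None]
    cc = np.arange(w)[None, :]
    tissue = (((rr - h / 2) / (h / 2 - _MARGIN_PX)) ** 2
              + ((cc - w / 2) / (w / 2 - _MARGIN_PX)) ** 2) <= 1.0
    n_tissue = int(tissue.sum())
    n_blue = int(round(blue_fraction * n_tissue))

    clusters = ndimage.gaussian_filter(rng.normal(size=size), sigma=6.0)
    order = np.argsort(clusters[tissue], kind="stable")[::-1]
    blue_flat = np.zeros(n_tissue, dtype=bool)
    blue_flat[order[:n_blue]] = True
    blue = np.zeros(size, dtype=bool)
    blue[tissue] = blue_flat
    red = tissue & ~blue

    img = np.full((h, w, 3), _WHITE, dtype=float)
    img[blue] = _BLUE_RGB
    img[red] = _RED_RGB
    img += rng.uniform(-_COLOUR_JITTER, _COLOUR_JITTER, size=img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)
    realised = n_blue / n_tissue
    return img, realised
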