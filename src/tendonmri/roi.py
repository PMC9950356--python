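"""ROI construction and standardised signal-intensity quantification.

Implements the ROI strategies used for tendon-lesion SI measurement —
50 mm² circular reference ROIs on cortical bone and in the background,
the largest circle inscribed in the lesion, a 1 mm² circle at the lesion
centre — and the four SI standardisation formulas:

* ``SDNR_background``: (SI_lesion − SI_SDFT) / SD_background
* ``SDNR_cortical``:   (SI_lesion − SI_SDFT) / SD_cortical_bone
* ``REL_background``:  SI_lesion / SI_background
* ``REL_cortical``:    SI_lesion / SI_cortical_bone

All four are dimensionless and invariant to rescaling the whole image,
which is what makes them comparable across examinations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .datamodel import ImageGeometry, ImageSlice, RoiMask, SiMeasurement
from .errors import GeometryError, InputError, UndefinedResultError

FORMULA_IDS = ("SDNR_background", "SDNR_cortical", "REL_background", "REL_cortical")


@dataclass(frozen=True)
class CircleRoi:
    """A circular ROI in physical coordinates (mm)."""

    centre_mm: tuple[float, float]  # (row_mm, col_mm), pixel-centre convention
    radius_mm: float
    target_area_mm2: float

    def __post_init__(self) -> None:
        if self.radius_mm < 0:
            raise InputError("circle radius cannot be negative")


@dataclass(frozen=True)
class StandardisedSi:
    """One standardised SI value and the formula that produced it."""

    value: float
    formula_id: str

    def __post_init__(self) -> None:
        if self.formula_id not in FORMULA_IDS:
            raise InputError(f"unknown formula_id {self.formula_id!r}")
        if not math.isfinite(self.value):
            raise UndefinedResultError(f"{self.formula_id} value is not finite")


def _pixel_centre_grids(geometry: ImageGeometry) -> tuple[np.ndarray, np.ndarray]:
    s = geometry.pixel_spacing_mm
    coords = (np.arange(geometry.matrix_size) + 0.5) * s
    return coords[:, None], coords[None, :]


def rasterise_circle(
    circle: CircleRoi,
    geometry: ImageGeometry,
    *,
    role: str = "lesion_whole",
    clip_to: RoiMask | None = None,
) -> RoiMask:
    """Rasterise a circle: pixels whose centres lie within the radius
    (boundary inclusive).  The pixel containing the centre is always part of
    the mask, so even a vanishing circle yields one pixel.  ``clip_to``
    intersects the result with another mask (used when a small central ROI
    overhangs the lesion boundary)."""
    s = geometry.pixel_spacing_mm
    shape = (clip_to.mask.shape if clip_to is not None
             else (geometry.matrix_size, geometry.matrix_size))
    rr = ((np.arange(shape[0]) + 0.5) * s)[:, None]
    cc = ((np.arange(shape[1]) + 0.5) * s)[None, :]
    cr, ccol = circle.centre_mm
    mask = (rr - cr) ** 2 + (cc - ccol) ** 2 <= circle.radius_mm ** 2
    centre_px = (min(max(int(cr / s), 0), shape[0] - 1),
                 min(max(int(ccol / s), 0), shape[1] - 1))
    mask[centre_px] = True
    if clip_to is not None:
        mask &= clip_to.mask
        if not mask.any():  # keep the centre pixel if it belongs to the clip mask
            raise GeometryError("circle does not intersect the clipping mask")
    return RoiMask(mask, role=role)


def make_circle_roi(
    centre_mm: tuple[float, float],
    area_mm2: float,
    geometry: ImageGeometry,
    *,
    role: str = "lesion_whole",
) -> RoiMask:
    """Circular ROI of a target area placed at a physical point.

    The radius is ``sqrt(area/π)``; the rasterised pixel count approximates
    the target area to within ~10% for areas of at least 1 mm² at typical
    pixel spacings, with the error vanishing as the area grows.
    """
    if area_mm2 <= 0:
        raise InputError("target ROI area must be positive")
    radius = math.sqrt(area_mm2 / math.pi)
    cr, cc = centre_mm
    fov = geometry.field_of_view_mm
    if cr - radius < 0 or cc - radius < 0 or cr + radius > fov or cc + radius > fov:
        raise GeometryError(
            f"circle (centre {centre_mm}, radius {radius:.2f} mm) exceeds the "
            f"{fov}×{fov} mm image bounds"
        )
    circle = CircleRoi(centre_mm, radius, area_mm2)
    return rasterise_circle(circle, geometry, role=role)


def measure_si(image: ImageSlice | np.ndarray, roi: RoiMask) -> SiMeasurement:
    """Mean and population SD of the pixel intensities under an ROI mask."""
    pixels = image.pixels if isinstance(image, ImageSlice) else np.asarray(image, float)
    if pixels.shape != roi.mask.shape:
        raise InputError("image and ROI mask shapes differ")
    if roi.is_empty:
        raise InputError("cannot measure SI in an empty ROI")
    values = pixels[roi.mask]
    return SiMeasurement(
        mean_si=float(values.mean()),
        sd_si=float(values.std(ddof=0)),
        n_pixels=int(values.size),
        role=roi.role,
    )


def _distance_to_complement(mask: np.ndarray) -> np.ndarray:
    """Exact Euclidean distance (pixels) from each mask pixel centre to the
    nearest complement pixel centre; the image border counts as complement."""
    padded = np.pad(mask, 1, mode="constant", constant_values=False)
    dist = ndimage.distance_transform_edt(padded)
    return dist[1:-1, 1:-1]


def largest_inscribed_circle(lesion: RoiMask, geometry: ImageGeometry) -> CircleRoi:
    """Largest circle fitting inside a lesion mask.

    The centre is the lesion-interior pixel centre maximising the exact
    Euclidean distance to the mask complement; the radius is that distance
    minus half a pixel, so the rasterised circle stays strictly inside the
    mask.  Ties between equally deep centres are broken toward the smallest
    (row, col).
    """
    if lesion.is_empty:
        raise InputError("lesion mask is empty")
    dist = _distance_to_complement(lesion.mask)
    centre_px = np.unravel_index(int(np.argmax(dist)), dist.shape)  # first in C order
    s = geometry.pixel_spacing_mm
    radius_px = float(dist[centre_px]) - 0.5
    centre_mm = ((centre_px[0] + 0.5) * s, (centre_px[1] + 0.5) * s)
    radius_mm = radius_px * s
    return CircleRoi(centre_mm, radius_mm, math.pi * radius_mm ** 2)


def central_small_roi(
    lesion: RoiMask,
    geometry: ImageGeometry,
    *,
    area_mm2: float = 1.0,
) -> CircleRoi:
    """Small (default 1 mm²) circle at the lesion's deepest interior point.

    The centre is the distance-transform maximum — guaranteed inside the
    lesion even for crescent shapes whose centroid falls outside.  The
    caller should rasterise with ``clip_to=lesion`` so an overhanging rim is
    trimmed to the lesion.
    """
    if lesion.is_empty:
        raise InputError("lesion mask is empty")
    dist = _distance_to_complement(lesion.mask)
    centre_px = np.unravel_index(int(np.argmax(dist)), dist.shape)
    s = geometry.pixel_spacing_mm
    centre_mm = ((centre_px[0] + 0.5) * s, (centre_px[1] + 0.5) * s)
    return CircleRoi(centre_mm, math.sqrt(area_mm2 / math.pi), area_mm2)


_BACKGROUND_DIRECTIONS = {
    "background_lateral": (0.0, -1.0),
    "background_medial": (0.0, 1.0),
    "background_palmar": (1.0, 0.0),
}


def place_reference_rois(
    slice_: ImageSlice,
    bone_centre_mm: tuple[float, float],
    limb_mask: RoiMask,
    geometry: ImageGeometry,
    *,
    area_mm2: float = 50.0,
    clearance_mm: float = 3.0,
) -> list[RoiMask]:
    """Place the four 50 mm² reference ROIs of the measurement protocol.

    One circle sits on the cortical bone at ``bone_centre_mm``; three sit in
    the background lateral, medial and palmar to the limb, pushed outward
    from the limb contour until they clear it by ``clearance_mm``.  Returns
    the ROIs in order [cortical_bone, lateral, medial, palmar].
    """
    if limb_mask.is_empty:
        raise InputError("limb mask is empty")
    if slice_.shape != limb_mask.mask.shape:
        raise InputError("slice and limb mask shapes differ")
    radius = math.sqrt(area_mm2 / math.pi)
    s = geometry.pixel_spacing_mm
    fov = geometry.field_of_view_mm

    rois = [make_circle_roi(bone_centre_mm, area_mm2, geometry, role="cortical_bone")]

    # distance (mm) from every pixel centre to the nearest limb pixel centre
    dist_to_limb = ndimage.distance_transform_edt(~limb_mask.mask) * s
    rows, cols = np.nonzero(limb_mask.mask)
    centroid = ((rows.mean() + 0.5) * s, (cols.mean() + 0.5) * s)

    for role, (dr, dc) in _BACKGROUND_DIRECTIONS.items():
        placed = False
        step = s
        t = step
        while True:
            cr = centroid[0] + dr * t
            cc = centroid[1] + dc * t
            if (cr - radius < 0 or cc - radius < 0
                    or cr + radius > fov or cc + radius > fov):
                break
            pr = min(int(cr / s), geometry.matrix_size - 1)
            pc = min(int(cc / s), geometry.matrix_size - 1)
            if dist_to_limb[pr, pc] >= radius + clearance_mm:
                rois.append(make_circle_roi((cr, cc), area_mm2, geometry, role=role))
                placed = True
                break
            t += step
        if not placed:
            raise GeometryError(
                f"no {role} position clears the limb by {clearance_mm} mm "
                f"within the image bounds"
            )
    return rois


def pool_background(measurements: list[SiMeasurement]) -> SiMeasurement:
    """Combine the three background ROI measurements into one reference.

    The reference mean is the unweighted mean of the three ROI means; the
    reference SD is the population SD of the pooled pixel set, reconstructed
    exactly from the per-ROI (n, mean, SD) triples.
    """
    if not measurements:
        raise InputError("no background measurements to pool")
    means = np.array([m.mean_si for m in measurements])
    sds = np.array([m.sd_si for m in measurements])
    ns = np.array([m.n_pixels for m in measurements], dtype=float)
    grand = float(np.average(means, weights=ns))
    pooled_var = float(np.sum(ns * (sds ** 2 + (means - grand) ** 2)) / ns.sum())
    return SiMeasurement(
        mean_si=float(means.mean()),
        sd_si=math.sqrt(pooled_var),
        n_pixels=int(ns.sum()),
        role=measurements[0].role,
    )


def standardise_si(
    lesion: SiMeasurement,
    sdft: SiMeasurement | None,
    reference: SiMeasurement,
    formula_id: str,
) -> StandardisedSi:
    """Standardise a lesion SI against a reference region.

    ``sdft`` (the healthy-tendon SI) is required for the SDNR formulas and
    ignored by the relative-SI formulas.  SDNR formulas divide by the
    reference SD; relative formulas divide by the reference mean.
    """
    if formula_id not in FORMULA_IDS:
        raise InputError(f"unknown formula_id {formula_id!r}")
    if formula_id.startswith("SDNR"):
        if sdft is None:
            raise InputError(f"{formula_id} requires an SDFT measurement")
        if reference.sd_si <= 0:
            raise UndefinedResultError(
                f"{formula_id}: reference SD is zero, SDNR undefined"
            )
        value = (lesion.mean_si - sdft.mean_si) / reference.sd_si
    else:
        if reference.mean_si <= 0:
            raise UndefinedResultError(
                f"{formula_id}: reference mean SI is not positive, "
                f"relative SI undefined"
            )
        value = lesion.mean_si / reference.mean_si
    return StandardisedSi(float(value), formula_id)
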