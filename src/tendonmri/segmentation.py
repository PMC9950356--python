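"""Automated lesion segmentation inside a manually drawn SDFT ROI.

A locally adaptive intensity threshold: a pixel is lesion if it exceeds
the mean of its square neighbourhood (default width 30 pixels, restricted
to SDFT pixels so surrounding structures cannot bias the local baseline)
by more than an offset.  Components smaller than ``min_lesion_px`` are
discarded and, mirroring the single-lesion study design, only the largest
surviving component is kept by default.

Offset modes
------------
``relative`` (default)
    offset × robust noise scale of the SDFT ROI (median absolute deviation
    × 1.4826).  Robust, so a hyperintense lesion does not inflate its own
    detection threshold; shift- and scale-covariant with the image.
``sd``
    offset × plain population SD of the SDFT ROI.
``absolute``
    offset in raw intensity units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .datamodel import ImageGeometry, ImageSlice, RoiMask, SiMeasurement
from .errors import InputError, ParameterError
from .lesion_geometry import LesionSliceRecord
from .roi import measure_si

OFFSET_MODES = ("relative", "sd", "absolute")


@dataclass(frozen=True)
class AdaptiveSegParams:
    """Parameters of the locally adaptive lesion segmentation."""

    filter_width_px: int = 30
    offset: float = 3.0
    offset_mode: str = "relative"
    min_lesion_px: int = 5
    connectivity: int = 8
    keep_largest_only: bool = True

    def __post_init__(self) -> None:
        if self.filter_width_px < 3:
            raise ParameterError("filter width must be at least 3 pixels")
        if self.min_lesion_px < 1:
            raise ParameterError("min_lesion_px must be at least 1")
        if self.connectivity not in (4, 8):
            raise ParameterError("connectivity must be 4 or 8")
        if self.offset_mode not in OFFSET_MODES:
            raise ParameterError(f"offset_mode must be one of {OFFSET_MODES}")


def _masked_local_mean(pixels: np.ndarray, mask: np.ndarray, width: int) -> np.ndarray:
    """Mean over the width×width window, counting only mask pixels.

    Windows are clipped at the image border; pixels outside the mask carry
    zero weight, so the local baseline is an SDFT-only average.
    """
    m = mask.astype(float)
    num = ndimage.uniform_filter(pixels * m, size=width, mode="constant", cval=0.0)
    den = ndimage.uniform_filter(m, size=width, mode="constant", cval=0.0)
    out = np.zeros_like(pixels, dtype=float)
    np.divide(num, den, out=out, where=den > 0)
    return out


def _offset_intensity(values: np.ndarray, params: AdaptiveSegParams) -> float:
    if params.offset_mode == "absolute":
        return params.offset
    if params.offset_mode == "sd":
        return params.offset * float(values.std(ddof=0))
    mad = float(np.median(np.abs(values - np.median(values))))
    return params.offset * 1.4826 * mad


_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


def local_adaptive_segment(
    slice_: ImageSlice,
    sdft: RoiMask,
    params: AdaptiveSegParams = AdaptiveSegParams(),
) -> RoiMask:
    """Segment the lesion within the SDFT ROI; the result is ⊆ the SDFT mask."""
    if sdft.is_empty:
        raise InputError("SDFT mask is empty")
    if slice_.shape != sdft.mask.shape:
        raise InputError("slice and SDFT mask shapes differ")
    if params.filter_width_px > max(slice_.shape):
        raise ParameterError("filter width exceeds the image size")

    pixels = slice_.pixels
    local_mean = _masked_local_mean(pixels, sdft.mask, params.filter_width_px)
    offset = _offset_intensity(pixels[sdft.mask], params)
    candidate = sdft.mask & (pixels > local_mean + offset)

    labels, n = ndimage.label(candidate, structure=_STRUCTURES[params.connectivity])
    if n == 0:
        return RoiMask(candidate, role="lesion_whole")
    sizes = ndimage.sum_labels(candidate, labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= params.min_lesion_px) + 1
    if keep.size == 0:
        return RoiMask(np.zeros_like(candidate), role="lesion_whole")
    if params.keep_largest_only:
        keep = keep[np.argmax(sizes[keep - 1]) : np.argmax(sizes[keep - 1]) + 1]
        mask = labels == keep[0]
    else:
        mask = np.isin(labels, keep)
    return RoiMask(mask, role="lesion_whole")


def detect_lesion(mask: RoiMask, params: AdaptiveSegParams = AdaptiveSegParams()) -> bool:
    """Lesion present iff the segmented pixel count reaches ``min_lesion_px``."""
    return mask.n_pixels >= params.min_lesion_px


def automated_measurement(
    slice_: ImageSlice,
    sdft: RoiMask,
    params: AdaptiveSegParams,
    geometry: ImageGeometry,
) -> LesionSliceRecord:
    """Segment, then measure CSA and SI on the automated binary mask.

    When no lesion is detected the record carries zero CSA and no SI.
    """
    mask = local_adaptive_segment(slice_, sdft, params)
    if not detect_lesion(mask, params):
        return LesionSliceRecord(level_index=slice_.level_index, csa_mm2=0.0, si=None)
    si: SiMeasurement = measure_si(slice_, mask)
    return LesionSliceRecord(
        level_index=slice_.level_index,
        csa_mm2=mask.area_mm2(geometry),
        si=si,
    )
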