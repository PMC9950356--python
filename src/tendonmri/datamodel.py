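"""Shared domain types: acquisition geometry, slice stacks, ROI masks and
signal-intensity measurements.

Pixel conventions used throughout the package:

* pixel coordinates are 0-based ``(row, column)`` with row 0 at the image top;
* the physical position of a pixel is its *centre*, at
  ``((row + 0.5) * spacing, (col + 0.5) * spacing)`` in millimetres;
* the physical position of slice ``level_index`` along the tendon is
  ``level_index * slice_spacing_mm`` where the centre-to-centre slice spacing
  is thickness + gap;
* *proximal* means smaller ``level_index``; a shift toward proximal is
  reported as a positive distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError, InputError

#: MRI sequences analysed in the study protocol this package targets.
SEQUENCE_LABELS = ("T1w_GRE", "T2*w_GRE", "T2w_FSE", "STIR")

#: Recognised ROI roles.
ROI_ROLES = (
    "lesion_whole",
    "lesion_circle_max",
    "lesion_circle_1mm2",
    "sdft",
    "cortical_bone",
    "background_lateral",
    "background_medial",
    "background_palmar",
)


@dataclass(frozen=True)
class ImageGeometry:
    """Physical acquisition geometry of a transverse slice stack.

    Defaults match the low-field protocol the package was designed around:
    a square 171 mm field of view on a 256×256 matrix with 5 mm slices
    separated by a 1 mm gap.
    """

    field_of_view_mm: float = 171.0
    matrix_size: int = 256
    slice_thickness_mm: float = 5.0
    slice_gap_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.field_of_view_mm <= 0 or self.matrix_size <= 0:
            raise InputError("field of view and matrix size must be positive")
        if self.slice_thickness_mm <= 0:
            raise InputError("slice thickness must be positive")
        if self.slice_gap_mm < 0:
            raise InputError("slice gap must be non-negative")

    @property
    def pixel_spacing_mm(self) -> float:
        """In-plane pixel edge length (square pixels)."""
        return self.field_of_view_mm / self.matrix_size

    @property
    def slice_spacing_mm(self) -> float:
        """Centre-to-centre distance between consecutive slices."""
        return self.slice_thickness_mm + self.slice_gap_mm

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_spacing_mm ** 2


@dataclass
class ImageSlice:
    """One transverse slice: a 2-D intensity raster plus acquisition context."""

    pixels: np.ndarray
    level_index: int
    sequence_label: str = "T1w_GRE"
    time_point: int = 1

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise FormatError("slice pixels must be a 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise FormatError("slice intensities must be finite")
        if np.any(self.pixels < 0):
            raise FormatError("slice intensities must be non-negative")
        if self.sequence_label not in SEQUENCE_LABELS:
            raise InputError(
                f"unknown sequence label {self.sequence_label!r}; "
                f"expected one of {SEQUENCE_LABELS}"
            )
        if not 1 <= int(self.time_point) <= 10:
            raise InputError("time_point must be an examination index in 1..10")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class ImageStack:
    """Ordered transverse slices (proximal to distal) of one examination."""

    geometry: ImageGeometry
    slices: list[ImageSlice]
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        if not self.slices:
            raise InputError("an ImageStack needs at least one slice")
        n = self.geometry.matrix_size
        for s in self.slices:
            if s.shape != (n, n):
                raise FormatError(
                    f"slice {s.level_index} has shape {s.shape}, "
                    f"geometry expects {(n, n)}"
                )
        levels = [s.level_index for s in self.slices]
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise InputError("slice level_index must be strictly increasing")
        if len({s.sequence_label for s in self.slices}) > 1:
            raise InputError("all slices in a stack must share sequence_label")
        if len({s.time_point for s in self.slices}) > 1:
            raise InputError("all slices in a stack must share time_point")

    def __len__(self) -> int:
        return len(self.slices)

    def __iter__(self):
        return iter(self.slices)

    @property
    def level_indices(self) -> list[int]:
        return [s.level_index for s in self.slices]

    def slice_at(self, level_index: int) -> ImageSlice:
        for s in self.slices:
            if s.level_index == level_index:
                return s
        raise InputError(f"no slice with level_index {level_index}")


@dataclass
class RoiMask:
    """Binary pixel mask on a slice grid, tagged with its ROI role."""

    mask: np.ndarray
    role: str = "lesion_whole"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise FormatError("ROI mask must be a 2-D array")
        if self.role not in ROI_ROLES:
            raise InputError(
                f"unknown ROI role {self.role!r}; expected one of {ROI_ROLES}"
            )

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def is_empty(self) -> bool:
        return not self.mask.any()

    def area_mm2(self, geometry: ImageGeometry) -> float:
        return self.n_pixels * geometry.pixel_area_mm2


@dataclass(frozen=True)
class SiMeasurement:
    """Mean / population-SD / pixel-count of intensities within one ROI."""

    mean_si: float
    sd_si: float
    n_pixels: int
    role: str = "lesion_whole"

    def __post_init__(self) -> None:
        if self.n_pixels < 1:
            raise InputError("an SI measurement needs at least one pixel")
        if self.sd_si < 0:
            raise InputError("SD of intensities cannot be negative")
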