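"""Lesion cross-sectional area, volume and maximum-level tracking.

Two conventions for reading a single representative CSA out of a slice
stack are supported: *CSA fixed* (always read at the level that held the
maximum at the first examination) and *CSA maximum* (read at each
examination's own maximum level).  Lesion volume sums the per-level CSAs
times the centre-to-centre slice spacing (thickness + gap, 6 mm for the
default protocol), so the unsampled gap tissue is represented by the
adjacent slice.  A shift of the maximum level toward proximal (smaller
level index) is reported as a positive distance in mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import ImageGeometry, RoiMask, SiMeasurement
from .errors import InputError


@dataclass
class LesionSliceRecord:
    """Per-slice lesion quantification: level, CSA and (optionally) SI."""

    level_index: int
    csa_mm2: float
    si: SiMeasurement | None = None

    def __post_init__(self) -> None:
        if self.csa_mm2 < 0:
            raise InputError("CSA cannot be negative")


@dataclass
class LesionSeriesSummary:
    """One examination's lesion geometry summary.

    ``level_shift_mm`` is None (undefined) when the lesion is absent at the
    time point; the row is still emitted with zero CSAs so time-series
    tables stay rectangular.
    """

    time_point: int
    csa_fixed_mm2: float
    csa_max_mm2: float
    max_level_index: int | None
    volume_mm3: float
    level_shift_mm: float | None


def records_from_masks(
    lesion_masks: list[RoiMask],
    level_indices: list[int],
    geometry: ImageGeometry,
) -> list[LesionSliceRecord]:
    """Build per-slice records from binary lesion masks (CSA = count × spacing²)."""
    if len(lesion_masks) != len(level_indices):
        raise InputError("masks and level indices differ in length")
    return [
        LesionSliceRecord(level_index=lvl, csa_mm2=m.area_mm2(geometry))
        for m, lvl in zip(lesion_masks, level_indices)
    ]


def max_csa_level(records: list[LesionSliceRecord]) -> tuple[int, float] | None:
    """Level with the largest CSA; proximal (smaller index) wins ties.

    Returns None when every CSA is zero — "no lesion", which is a valid
    observation, not an error.
    """
    if not records:
        raise InputError("no slice records supplied")
    ordered = sorted(records, key=lambda r: r.level_index)
    best = max(ordered, key=lambda r: r.csa_mm2)  # max() keeps the first = proximal
    if best.csa_mm2 == 0:
        return None
    return best.level_index, best.csa_mm2


def csa_at_fixed_level(records: list[LesionSliceRecord], fixed_level: int) -> float:
    """CSA read at a predetermined level; 0 if the lesion no longer reaches it."""
    levels = [r.level_index for r in records]
    if fixed_level < min(levels) or fixed_level > max(levels):
        raise InputError(
            f"fixed level {fixed_level} outside stack range {min(levels)}..{max(levels)}"
        )
    for r in records:
        if r.level_index == fixed_level:
            return r.csa_mm2
    return 0.0


def lesion_volume(
    records: list[LesionSliceRecord],
    geometry: ImageGeometry,
    *,
    spacing_mm: float | None = None,
) -> float:
    """Lesion volume = Σ CSA × inter-slice spacing.

    ``spacing_mm`` overrides the default centre-to-centre spacing
    (thickness + gap) for users who prefer slice thickness alone as the
    multiplier.
    """
    spacing = geometry.slice_spacing_mm if spacing_mm is None else spacing_mm
    return float(sum(r.csa_mm2 for r in records) * spacing)


def level_shift(
    current_max_level: int,
    reference_level: int,
    geometry: ImageGeometry,
) -> float:
    """Signed shift of the maximum-lesion level relative to a reference level.

    Positive = the current maximum lies proximal (smaller index) to the
    reference; in mm of centre-to-centre slice spacing.
    """
    return (reference_level - current_max_level) * geometry.slice_spacing_mm


def summarise_timepoint(
    records: list[LesionSliceRecord],
    fixed_level: int | None,
    geometry: ImageGeometry,
    *,
    time_point: int = 1,
    spacing_mm: float | None = None,
) -> LesionSeriesSummary:
    """Assemble a per-examination summary row.

    ``fixed_level`` is the maximum-CSA level of the first examination; pass
    None for the first examination itself (its own maximum is used).
    """
    peak = max_csa_level(records)
    if peak is None:
        return LesionSeriesSummary(
            time_point=time_point, csa_fixed_mm2=0.0, csa_max_mm2=0.0,
            max_level_index=None, volume_mm3=0.0, level_shift_mm=None,
        )
    max_level, csa_max = peak
    if fixed_level is None:
        fixed_level = max_level
    return LesionSeriesSummary(
        time_point=time_point,
        csa_fixed_mm2=csa_at_fixed_level(records, fixed_level),
        csa_max_mm2=csa_max,
        max_level_index=max_level,
        volume_mm3=lesion_volume(records, geometry, spacing_mm=spacing_mm),
        level_shift_mm=level_shift(max_level, fixed_level, geometry),
    )
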