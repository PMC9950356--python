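"""Readers and writers for slice stacks, ROI masks and result tables.

Grayscale PNG/TIFF directories and (optionally, when pydicom is installed)
DICOM series are read into :class:`~tendonmri.datamodel.ImageStack`; masks
interchange as 0/255 PNG; result tables are CSV with an optional block of
``# column: unit`` comment lines documenting units.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .datamodel import ImageGeometry, ImageSlice, ImageStack, RoiMask
from .errors import FormatError, InputError

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff"}
_DICOM_SUFFIXES = {".dcm", ".ima"}

#: Columns that form the unique row key of a result table.
RESULT_KEY = ["subject_id", "time_point", "sequence_label", "level_index"]


def _level_from_name(path: Path) -> int | None:
    """Parse a slice level index from a filename (last integer group)."""
    groups = re.findall(r"\d+", path.stem)
    return int(groups[-1]) if groups else None


def load_stack(
    path: str | Path,
    geometry: ImageGeometry,
    *,
    sequence_label: str = "T1w_GRE",
    time_point: int = 1,
    subject_id: str | None = None,
) -> ImageStack:
    """Load a directory of grayscale images (or a DICOM series) as a stack.

    Slices are ordered by the level index parsed from each filename (the
    last integer group in the stem) or, for DICOM, by InstanceNumber; when
    no index is parseable, alphabetical order of filenames is used and
    levels are numbered 0, 1, 2, ...
    """
    directory = Path(path)
    if not directory.is_dir():
        raise InputError(f"{directory} is not a directory")
    files = sorted(p for p in directory.iterdir() if p.is_file())
    dicom_files = [p for p in files if p.suffix.lower() in _DICOM_SUFFIXES]
    image_files = [p for p in files if p.suffix.lower() in _IMAGE_SUFFIXES]
    if dicom_files:
        entries = _read_dicom_series(dicom_files)
    elif image_files:
        entries = []
        for p in image_files:
            with Image.open(p) as img:
                if img.mode not in ("L", "I", "I;16", "F"):
                    img = img.convert("I")
                arr = np.asarray(img, dtype=float)
            entries.append((_level_from_name(p), arr))
    else:
        raise InputError(f"no readable images found in {directory}")

    shapes = {arr.shape for _, arr in entries}
    if len(shapes) > 1:
        raise FormatError(f"images have unequal dimensions: {sorted(shapes)}")
    n = geometry.matrix_size
    if shapes.pop() != (n, n):
        raise FormatError(f"image dimensions do not match the {n}×{n} geometry")

    if any(level is None for level, _ in entries):
        entries = [(i, arr) for i, (_, arr) in enumerate(entries)]
    entries.sort(key=lambda e: e[0])
    slices = [
        ImageSlice(arr, level_index=int(level), sequence_label=sequence_label,
                   time_point=time_point)
        for level, arr in entries
    ]
    return ImageStack(geometry, slices, subject_id=subject_id or directory.name)


def _read_dicom_series(files: list[Path]) -> list[tuple[int | None, np.ndarray]]:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise InputError("reading DICOM series requires pydicom") from exc
    entries = []
    for p in files:
        ds = pydicom.dcmread(p)
        level = int(ds.InstanceNumber) if "InstanceNumber" in ds else None
        entries.append((level, ds.pixel_array.astype(float)))
    return entries


def save_mask(roi: RoiMask, path: str | Path) -> None:
    """Write a binary ROI mask as an 8-bit 0/255 PNG."""
    Image.fromarray(np.where(roi.mask, 255, 0).astype(np.uint8)).save(path)


def load_mask(path: str | Path, role: str = "lesion_whole") -> RoiMask:
    """Read a 0/255 PNG as a binary ROI mask (any non-zero pixel is True)."""
    with Image.open(path) as img:
        arr = np.asarray(img.convert("L"))
    return RoiMask(arr > 0, role=role)


def save_results(
    table: pd.DataFrame,
    path: str | Path,
    units: dict[str, str] | None = None,
) -> None:
    """Write a result table as CSV, preserving reals to 12 significant digits.

    ``units`` maps column names to unit strings and is written as
    ``# column: unit`` comment lines ahead of the header.
    """
    if table is None or len(table) == 0:
        raise InputError("refusing to write an empty result table")
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for col, unit in (units or {}).items():
            fh.write(f"# {col}: {unit}\n")
        table.to_csv(fh, index=False, float_format="%.12g")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a CSV written by :func:`save_results` (comments skipped)."""
    return pd.read_csv(path, comment="#")


def validate_result_table(table: pd.DataFrame) -> None:
    """Check the (subject, time point, sequence, level) key is unique."""
    key = [c for c in RESULT_KEY if c in table.columns]
    if key and table.duplicated(subset=key).any():
        raise InputError(f"duplicate rows for key columns {key}")


def average_triplicate(values) -> float:
    """Mean of exactly three repeated measurements of the same quantity."""
    arr = np.asarray(values, dtype=float)
    if arr.shape != (3,):
        raise InputError(f"expected exactly 3 values, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InputError("triplicate values must be finite")
    return float(arr.mean())
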