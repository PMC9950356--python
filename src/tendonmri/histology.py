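"""Trichrome-stain quantification: the percentage of blue-stained pixels.

In Masson's trichrome, collagen-rich repair tissue stains blue while
muscle/cytoplasm stains red, so the blue-pixel share of a tendon section
is a severity readout for the lesion.  The red and blue channels are
extracted, each pixel is classified as blue-stained, red-stained or
background (unstained white / black), and the blue percentage is computed
over stained tissue pixels by default — the slide's arbitrary background
area then cannot dilute the score.  Pass ``denominator="all"`` to divide
by every pixel in the image instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FormatError, InputError, UndefinedResultError


@dataclass(frozen=True)
class HistologyResult:
    """Blue-pixel percentage and the pixel counts behind it."""

    blue_percent: float
    n_tissue_pixels: int
    n_blue_pixels: int
    n_red_pixels: int


def extract_channels(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Red and blue channel maps of an RGB(A) image, as float arrays."""
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise FormatError("expected an RGB image with 3 channels")
    return arr[..., 0].astype(float), arr[..., 2].astype(float)


def _channel_max(red: np.ndarray, blue: np.ndarray, image_dtype=None) -> float:
    if image_dtype is not None and np.issubdtype(image_dtype, np.integer):
        return float(np.iinfo(image_dtype).max)
    peak = max(float(red.max()), float(blue.max()))
    if peak <= 1.0:
        return 1.0
    return 255.0 if peak <= 255.0 else 65535.0


def segment_stain(
    red: np.ndarray,
    blue: np.ndarray,
    *,
    white_threshold: float = 0.9,
    black_threshold: float = 0.05,
    dominance_margin: float = 0.05,
    channel_max: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Classify pixels into (blue mask, red mask, background mask).

    A pixel is background when both channels are at least
    ``white_threshold × channel_max`` (unstained slide) or at most
    ``black_threshold × channel_max``.  Otherwise it is blue-stained when
    blue exceeds red by at least ``dominance_margin × channel_max`` and
    red-stained in the mirror case; ambiguous pixels go to the larger
    channel, with exact ties assigned to red.  The three masks partition
    the image.
    """
    red = np.asarray(red, dtype=float)
    blue = np.asarray(blue, dtype=float)
    if red.shape != blue.shape:
        raise InputError("red and blue maps must have the same shape")
    cmax = channel_max if channel_max is not None else _channel_max(red, blue)
    white = white_threshold * cmax
    black = black_threshold * cmax
    margin = dominance_margin * cmax

    background = ((red >= white) & (blue >= white)) | ((red <= black) & (blue <= black))
    blue_mask = ~background & (blue - red >= margin)
    red_mask = ~background & ~blue_mask & (red - blue >= margin)
    ambiguous = ~background & ~blue_mask & ~red_mask
    blue_mask |= ambiguous & (blue > red)
    red_mask |= ambiguous & (blue <= red)  # exact ties stain red
    return blue_mask, red_mask, background


def blue_pixel_percentage(
    blue_mask: np.ndarray,
    red_mask: np.ndarray,
    *,
    denominator: str = "tissue",
) -> HistologyResult:
    """Percentage of blue pixels.

    ``denominator="tissue"`` (default) divides by the stained pixels
    (blue ∪ red); ``"all"`` divides by every pixel of the image.
    """
    blue_mask = np.asarray(blue_mask, dtype=bool)
    red_mask = np.asarray(red_mask, dtype=bool)
    if blue_mask.shape != red_mask.shape:
        raise InputError("masks must have the same shape")
    if np.any(blue_mask & red_mask):
        raise InputError("blue and red masks must be disjoint")
    if denominator not in ("tissue", "all"):
        raise InputError("denominator must be 'tissue' or 'all'")
    n_blue = int(blue_mask.sum())
    n_red = int(red_mask.sum())
    n_tissue = n_blue + n_red
    denom = n_tissue if denominator == "tissue" else blue_mask.size
    if denom == 0:
        raise UndefinedResultError("no tissue pixels: blue percentage undefined")
    return HistologyResult(
        blue_percent=100.0 * n_blue / denom,
        n_tissue_pixels=n_tissue,
        n_blue_pixels=n_blue,
        n_red_pixels=n_red,
    )


def quantify_histology(image: np.ndarray, **segment_kwargs) -> HistologyResult:
    """End-to-end: extract channels, segment stains, compute blue percent."""
    red, blue = extract_channels(image)
    cmax = segment_kwargs.pop("channel_max", None)
    if cmax is None:
        cmax = _channel_max(red, blue, image_dtype=np.asarray(image).dtype)
    blue_mask, red_mask, _ = segment_stain(red, blue, channel_max=cmax, **segment_kwargs)
    return blue_pixel_percentage(blue_mask, red_mask)
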