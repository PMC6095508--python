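"""Grayscale image reading/writing and flat key-value configuration files.

The scheme targets 8-bit grayscale radiographs; colour inputs are rejected
unless all channels agree, and higher bit depths are rejected rather than
silently truncated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import imageio.v3 as iio


class ImageFormatError(ValueError):
    """Unreadable, multichannel-ambiguous or depth-incompatible image."""


@dataclass
class ImageArray:
    """A 2D intensity array with its bit depth."""

    pixels: np.ndarray
    bit_depth: int = 8

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ImageFormatError("pixels must form a nonempty 2D array")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    @property
    def peak(self) -> float:
        return float(2 ** self.bit_depth - 1)


def read_image(path, bit_depth: int = 8) -> ImageArray:
    """Read a PNG/PGM/TIFF image as grayscale at the requested depth."""
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio raises various types
        raise ImageFormatError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3:
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        elif np.all(arr[:, :, :3].max(axis=2) == arr[:, :, :3].min(axis=2)):
            arr = arr[:, :, 0]
        else:
            raise ImageFormatError(
                f"{path} has distinct colour channels; grayscale input required"
            )
    if arr.ndim != 2:
        raise ImageFormatError(f"{path} is not a 2D image")
    if np.issubdtype(arr.dtype, np.integer):
        if arr.max(initial=0) > 2 ** bit_depth - 1:
            raise ImageFormatError(
                f"{path} holds values beyond {bit_depth}-bit range; "
                "no silent truncation is performed"
            )
    return ImageArray(arr.astype(float), bit_depth)


def write_image(image: ImageArray, path) -> None:
    """Write to PNG/PGM/TIFF chosen by file extension (8-bit)."""
    if image.bit_depth != 8:
        raise ImageFormatError("only 8-bit output is supported")
    data = np.clip(np.rint(image.pixels), 0, 255).astype(np.uint8)
    iio.imwrite(path, data)


def read_config(path) -> dict:
    """Parse a flat key-value text file (``key = value`` or ``key value``
    per line; ``#`` starts a comment)."""
    out = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" in line:
            key, val = line.split("=", 1)
        elif ":" in line:
            key, val = line.split(":", 1)
        else:
            parts = line.split(None, 1)
            if len(parts) != 2:
                raise ValueError(f"cannot parse config line: {line!r}")
            key, val = parts
        out[key.strip()] = val.strip()
    return out
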