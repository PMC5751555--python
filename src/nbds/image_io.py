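"""Image and table I/O helpers (PNG/TIFF/JPEG via imageio)."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import InputValidationError
from .types import FacialImage


def load_image(path: str | Path, space_tag: str = "srgb") -> FacialImage:
    """Read an 8- or 16-bit image file into a [0, 1] float raster."""
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:  # drop alpha
        arr = arr[..., :3]
    if arr.dtype == np.uint8:
        arr = arr.astype(float) / 255.0
    elif arr.dtype == np.uint16:
        arr = arr.astype(float) / 65535.0
    elif np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(float)
    else:
        raise InputValidationError(f"unsupported image dtype {arr.dtype}")
    return FacialImage(np.clip(arr, 0.0, 1.0), space_tag=space_tag)


def save_image(image: FacialImage, path: str | Path) -> None:
    """Write the raster as 8-bit (PNG/JPEG) based on the file extension."""
    arr = np.round(image.pixels * 255.0).astype(np.uint8)
    iio.imwrite(path, arr)
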