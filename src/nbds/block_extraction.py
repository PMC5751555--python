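"""Pupil localization and facial key-block geometry.

Four square key blocks are anchored to the two pupil centers
``P_left = (x_l, y_l)`` and ``P_right = (x_r, y_r)`` of an H-pixel-tall face
image.  In a frame where y increases upward the block centers are

    FHB (forehead)    : ((x_l + x_r)/2, (y_l + y_r)/2 + H/3)
    LCB (left cheek)  : (x_l, y_l - H/4)
    NBB (nose bridge) : ((x_l + x_r)/2, (y_l + y_r)/2 - 2H/9)
    RCB (right cheek) : (x_r, y_r - H/4)

so the forehead block sits above the pupils and the cheek and nose-bridge
blocks below them.  Pupils are found with Canny edges: closed edge contours
in the upper half of the luminance image are filled, connected components are
filtered by area, circularity, and darkness, and the two survivors are the
pupils; their centers are darkness-weighted centroids.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import feature, measure
from skimage.color import rgb2gray

from .errors import BlockBoundsError, DetectionError, InputValidationError
from .types import BLOCK_NAMES, FacialImage, KeyBlock, PupilPair

__all__ = [
    "detect_pupils",
    "compute_block_centers",
    "extract_block",
    "extract_key_blocks",
    "to_array_coords",
    "to_paper_coords",
]


def to_array_coords(x: float, y: float, height: int) -> tuple[float, float]:
    """Paper-frame (x, y-up) -> raster (row, col)."""
    return (height - 1) - y, x


def to_paper_coords(row: float, col: float, height: int) -> tuple[float, float]:
    """Raster (row, col) -> paper-frame (x, y-up)."""
    return col, (height - 1) - row


def _round_half_away(v: float) -> int:
    """Deterministic round-half-away-from-zero (not banker's rounding)."""
    return int(np.sign(v) * np.floor(abs(v) + 0.5))


def compute_block_centers(
    pupils: PupilPair, height: float
) -> dict[str, tuple[float, float]]:
    """Centers of the four key blocks in the paper frame.

    Pure arithmetic on the pupil geometry; bounds are checked only when a
    block is actually extracted.
    """
    (xl, yl), (xr, yr) = pupils.left, pupils.right
    xm = (xl + xr) / 2.0
    ym = (yl + yr) / 2.0
    return {
        "FHB": (xm, ym + height / 3.0),
        "LCB": (xl, yl - height / 4.0),
        "RCB": (xr, yr - height / 4.0),
        "NBB": (xm, ym - 2.0 * height / 9.0),
    }


def extract_block(
    image: FacialImage, center: tuple[float, float], side: int, name: str = "block"
) -> KeyBlock:
    """Cut the side-by-side block centered at a paper-frame coordinate.

    The center is converted to raster coordinates, rounded half-away-from-
    zero, and the window's top-left corner is that integer center minus
    ``side // 2`` in each axis.  The returned pixels are an owned copy.
    """
    if side < 1:
        raise InputValidationError("block side must be positive")
    row_f, col_f = to_array_coords(center[0], center[1], image.height)
    r0 = _round_half_away(row_f) - side // 2
    c0 = _round_half_away(col_f) - side // 2
    if r0 < 0 or c0 < 0 or r0 + side > image.height or c0 + side > image.width:
        raise BlockBoundsError(
            f"block {name!r} window rows {r0}:{r0 + side}, cols {c0}:{c0 + side} "
            f"exceeds image bounds {image.height}x{image.width}"
        )
    pixels = image.pixels[r0 : r0 + side, c0 : c0 + side, :].copy()
    return KeyBlock(name=name, center=tuple(center), side=side, pixels=pixels)


def extract_key_blocks(
    image: FacialImage,
    pupils: PupilPair,
    side: int = 64,
    blocks: tuple[str, ...] = BLOCK_NAMES,
) -> dict[str, KeyBlock]:
    """Convenience: centers from the pupil pair, then one block per name."""
    centers = compute_block_centers(pupils, image.height)
    return {
        name: extract_block(image, centers[name], side, name) for name in blocks
    }


def detect_pupils(
    image: FacialImage,
    expected_radius: float = 10.0,
    canny_sigma: float = 2.0,
    min_circularity: float = 0.6,
) -> PupilPair:
    """Locate the two pupils in the upper half of a corrected face image.

    Procedure: Canny on the luminance channel of the upper half, fill closed
    contours, label connected components, then keep components whose

    * area lies in [0.2 a, 5 a] with a = pi * expected_radius**2,
    * circularity 4*pi*A / P**2 is at least ``min_circularity``, and
    * mean interior luminance is darker than half the image median
      (pupils are far darker than any skin region).

    Exactly two components must survive; otherwise a :class:`DetectionError`
    reporting the candidate count is raised.  Centers are darkness-weighted
    centroids, returned in the paper frame ordered left/right by x.
    """
    if image.space_tag != "srgb":
        raise InputValidationError("pupil detection expects a corrected image")
    gray = rgb2gray(image.pixels)
    h = image.height
    upper = gray[: h // 2, :]

    edges = feature.canny(upper, sigma=canny_sigma)
    filled = ndimage.binary_fill_holes(edges)
    labels = measure.label(filled)
    props = measure.regionprops(labels, intensity_image=upper)

    a = np.pi * expected_radius**2
    dark_cutoff = 0.5 * float(np.median(gray))
    candidates = []
    for p in props:
        if not (0.2 * a <= p.area <= 5.0 * a):
            continue
        perimeter = p.perimeter
        if perimeter <= 0:
            continue
        circularity = 4.0 * np.pi * p.area / perimeter**2
        if circularity < min_circularity:
            continue
        if p.intensity_mean >= dark_cutoff:
            continue
        candidates.append(p)

    if len(candidates) != 2:
        raise DetectionError(len(candidates))

    centers = []
    for p in candidates:
        rows, cols = p.coords[:, 0], p.coords[:, 1]
        w = 1.0 - upper[rows, cols]  # darkness weight
        wsum = float(w.sum())
        row_c = float((w * rows).sum() / wsum)
        col_c = float((w * cols).sum() / wsum)
        centers.append(to_paper_coords(row_c, col_c, h))

    centers.sort(key=lambda c: c[0])
    return PupilPair(left=centers[0], right=centers[1])
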