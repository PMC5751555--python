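"""Core value objects shared across the pipeline stages.

Coordinate conventions
----------------------
Facial geometry is expressed in a *paper frame*: ``x`` is the column index
(increasing rightward) and ``y`` increases **upward**, so the forehead sits at
larger ``y`` than the pupils.  Array (raster) coordinates use the usual
``(row, col)`` with row 0 at the top.  The two are linked by

    row = (height - 1) - y,   col = x.

All block-center formulas are evaluated in the paper frame and converted to
raster indices only when pixels are actually sliced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputValidationError

#: Canonical key-block names: forehead, left cheek, right cheek, nose bridge.
BLOCK_NAMES = ("FHB", "LCB", "RCB", "NBB")

#: Blocks that feed classification by default (the cheeks are symmetric, so
#: only the left one is used alongside forehead and nose bridge).
DEFAULT_FEATURE_BLOCKS = ("FHB", "LCB", "NBB")


@dataclass
class FacialImage:
    """A fixed-size RGB raster with a color-space tag.

    Parameters
    ----------
    pixels : ndarray, shape (H, W, 3)
        Color components as floats in [0, 1].
    space_tag : {"raw", "srgb"}
        ``raw`` marks device output awaiting color correction; ``srgb`` marks
        a corrected (or directly synthesized) image.
    """

    pixels: np.ndarray
    space_tag: str = "srgb"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise InputValidationError(
                f"pixels must be (H, W, 3), got {self.pixels.shape}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise InputValidationError("pixels contain non-finite values")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise InputValidationError("pixel components must lie in [0, 1]")
        if self.space_tag not in ("raw", "srgb"):
            raise InputValidationError(f"unknown space_tag {self.space_tag!r}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class PupilPair:
    """Detected pupil centers in the paper frame, ordered left/right by x."""

    left: tuple[float, float]
    right: tuple[float, float]

    def __post_init__(self):
        if not self.left[0] < self.right[0]:
            raise InputValidationError(
                "left pupil must have strictly smaller x than right pupil"
            )

    def mirrored(self, width: int) -> "PupilPair":
        """The pair seen in a left-right mirrored image of the given width."""
        mx = width - 1
        lx, ly = self.left
        rx, ry = self.right
        return PupilPair(left=(mx - rx, ry), right=(mx - lx, ly))


@dataclass
class KeyBlock:
    """An s-by-s pixel block cut from a named facial region."""

    name: str
    center: tuple[float, float]  # paper frame
    side: int
    pixels: np.ndarray  # (side, side, 3), an owned copy

    def __post_init__(self):
        if self.name not in BLOCK_NAMES and self.name != "block":
            raise InputValidationError(f"unknown block name {self.name!r}")
        if self.pixels.shape != (self.side, self.side, 3):
            raise InputValidationError(
                f"block pixels must be ({self.side}, {self.side}, 3), "
                f"got {self.pixels.shape}"
            )


@dataclass
class LabeledDataset:
    """Feature matrix with samples as columns plus integer-coded labels.

    ``features`` is m-by-n (m = feature dimension, n = samples); ``labels``
    holds one class identifier per column.  This is the natural layout for
    representation-based classifiers, whose training dictionary is exactly
    this matrix.
    """

    features: np.ndarray
    labels: np.ndarray
    feature_blocks: tuple[str, ...] | None = None
    classes: np.ndarray = field(init=False)

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2:
            raise InputValidationError("features must be a 2-D m-by-n matrix")
        if self.labels.shape != (self.features.shape[1],):
            raise InputValidationError(
                "labels must have one entry per feature column"
            )
        if not np.all(np.isfinite(self.features)):
            raise InputValidationError("features contain non-finite values")
        self.classes = np.unique(self.labels)
        if self.feature_blocks is not None:
            if self.features.shape[0] != 6 * len(self.feature_blocks):
                raise InputValidationError(
                    "feature dimension inconsistent with feature_blocks"
                )

    @property
    def n_samples(self) -> int:
        return self.features.shape[1]

    @property
    def n_features(self) -> int:
        return self.features.shape[0]

    def class_index(self, label) -> np.ndarray:
        """Column indices of the samples belonging to ``label``."""
        return np.flatnonzero(self.labels == label)

    def subset(self, columns: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            self.features[:, columns], self.labels[columns], self.feature_blocks
        )

    def select_blocks(self, blocks: tuple[str, ...]) -> "LabeledDataset":
        """Restrict the 6-per-block feature rows to a block combination."""
        if self.feature_blocks is None:
            raise InputValidationError("dataset carries no block annotation")
        rows = []
        for b in blocks:
            if b not in self.feature_blocks:
                raise InputValidationError(f"block {b!r} not in dataset")
            i = self.feature_blocks.index(b)
            rows.extend(range(6 * i, 6 * i + 6))
        return LabeledDataset(self.features[rows, :], self.labels, tuple(blocks))

    def to_sklearn(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, y) with samples as rows, for scikit-learn estimators."""
        return self.features.T.copy(), self.labels.copy()
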