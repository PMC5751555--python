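"""Color-gamut histogram features from facial key blocks.

Block pixels are taken from sRGB through CIEXYZ (D65) and optionally on to
CIELAB; each pixel is then assigned to the nearest of six gamut centroids,
and the block's feature is the 6-vector of assignment proportions.  Features
from several blocks are concatenated in the fixed order FHB, LCB, NBB, so
the three employed blocks yield an 18-dimensional vector.

The six-centroid facial color gamut itself is an input.  The shipped default
(``data/default_gamut.csv``) was obtained by k-means (k=6, fixed seed 42) on
a synthetic skin-tone cloud spanning light-to-dark and red-to-yellow skin
chromaticities; any CSV with columns name, c1, c2, c3, space may replace it.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import color as skcolor
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import GamutError, InputValidationError
from .types import DEFAULT_FEATURE_BLOCKS, KeyBlock

N_CENTROIDS = 6


# ---------------------------------------------------------------------------
# color-space conversions (thin validated wrappers over skimage.color)
# ---------------------------------------------------------------------------

def srgb_to_xyz(pixels: np.ndarray) -> np.ndarray:
    """sRGB in [0,1] -> CIE 1931 XYZ under D65 (inverse companding + matrix)."""
    pixels = np.asarray(pixels, dtype=float)
    if pixels.min() < 0.0 or pixels.max() > 1.0:
        raise InputValidationError("sRGB components must lie in [0, 1]")
    return skcolor.rgb2xyz(pixels)


def xyz_to_srgb(pixels: np.ndarray) -> np.ndarray:
    """CIEXYZ -> sRGB, clipped to [0, 1]."""
    return np.clip(skcolor.xyz2rgb(np.asarray(pixels, dtype=float)), 0.0, 1.0)


def xyz_to_lab(pixels: np.ndarray) -> np.ndarray:
    """CIEXYZ -> CIELAB under the D65 reference white."""
    pixels = np.asarray(pixels, dtype=float)
    if pixels.min() < 0.0:
        raise InputValidationError("XYZ components must be non-negative")
    return skcolor.xyz2lab(pixels)


def lab_to_xyz(pixels: np.ndarray) -> np.ndarray:
    """CIELAB -> CIEXYZ under the D65 reference white."""
    return skcolor.lab2xyz(np.asarray(pixels, dtype=float))


# ---------------------------------------------------------------------------
# gamut and features
# ---------------------------------------------------------------------------

@dataclass
class ColorGamut:
    """Ordered set of six color centroids in a stated CIE space."""

    centroids: np.ndarray  # (6, 3)
    space_tag: str  # "xyz" | "lab"
    names: tuple[str, ...]

    def __post_init__(self):
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.shape != (N_CENTROIDS, 3):
            raise GamutError(
                f"a gamut holds exactly {N_CENTROIDS}x3 centroids, "
                f"got {self.centroids.shape}"
            )
        if self.space_tag not in ("xyz", "lab"):
            raise GamutError(f"unknown gamut space {self.space_tag!r}")
        if len(self.names) != N_CENTROIDS:
            raise GamutError("need one name per centroid")
        d = np.linalg.norm(
            self.centroids[:, None, :] - self.centroids[None, :, :], axis=-1
        )
        d[np.diag_indices(N_CENTROIDS)] = np.inf
        if d.min() <= 1e-6:
            raise GamutError("gamut centroids must be pairwise distinct")


@dataclass
class BlockFeature:
    """Per-block 6-vector of nearest-centroid proportions (sums to 1)."""

    proportions: np.ndarray
    block_name: str

    def __post_init__(self):
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.proportions.shape != (N_CENTROIDS,):
            raise InputValidationError("a block feature has exactly 6 entries")
        if abs(self.proportions.sum() - 1.0) > 1e-9:
            raise InputValidationError("block feature must sum to 1")


@dataclass
class CombinedFeature:
    """Concatenation of block features in the canonical FHB, LCB, NBB order."""

    values: np.ndarray
    blocks: tuple[str, ...]

    @property
    def dim(self) -> int:
        return self.values.shape[0]


def assign_centroids(pixels_srgb: np.ndarray, gamut: ColorGamut) -> np.ndarray:
    """Nearest-centroid index for each pixel, ties to the lowest index."""
    xyz = srgb_to_xyz(pixels_srgb)
    coords = xyz if gamut.space_tag == "xyz" else xyz_to_lab(xyz)
    flat = coords.reshape(-1, 3)
    d2 = ((flat[:, None, :] - gamut.centroids[None, :, :]) ** 2).sum(axis=-1)
    return np.argmin(d2, axis=1)  # argmin takes the first (lowest) index on ties


def extract_block_feature(block: KeyBlock, gamut: ColorGamut) -> BlockFeature:
    """Proportion of block pixels nearest each gamut centroid."""
    idx = assign_centroids(block.pixels, gamut)
    counts = np.bincount(idx, minlength=N_CENTROIDS).astype(float)
    return BlockFeature(counts / idx.size, block.name)


def combine_features(features: list[BlockFeature]) -> CombinedFeature:
    """Concatenate 1-3 block features, preserving the given order."""
    if not 1 <= len(features) <= 3:
        raise InputValidationError("combine 1 to 3 block features")
    names = [f.block_name for f in features]
    if len(set(names)) != len(names):
        raise InputValidationError(f"duplicate block names in {names}")
    values = np.concatenate([f.proportions for f in features])
    return CombinedFeature(values, tuple(names))


class GamutHistogramExtractor(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer turning key blocks into gamut histograms.

    ``transform`` accepts a list of block dictionaries (name -> KeyBlock, as
    produced by :func:`nbds.block_extraction.extract_key_blocks`) and returns
    an (n_samples, 6 * n_blocks) feature matrix in the configured block order.
    """

    def __init__(self, gamut: ColorGamut | None = None,
                 blocks: tuple[str, ...] = DEFAULT_FEATURE_BLOCKS):
        self.gamut = gamut
        self.blocks = blocks

    def fit(self, X=None, y=None):
        self.gamut_ = self.gamut if self.gamut is not None else default_gamut()
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "gamut_"):
            self.fit()
        rows = []
        for sample in X:
            feats = [
                extract_block_feature(sample[name], self.gamut_)
                for name in self.blocks
            ]
            rows.append(combine_features(feats).values)
        return np.asarray(rows)


# ---------------------------------------------------------------------------
# gamut I/O and the shipped default
# ---------------------------------------------------------------------------

def load_gamut(path: str | Path) -> ColorGamut:
    """Read a gamut CSV with columns name, c1, c2, c3, space."""
    df = pd.read_csv(path)
    space = str(df["space"].iloc[0])
    return ColorGamut(
        centroids=df[["c1", "c2", "c3"]].to_numpy(dtype=float),
        space_tag=space,
        names=tuple(df["name"].astype(str)),
    )


def save_gamut(gamut: ColorGamut, path: str | Path) -> None:
    pd.DataFrame(
        {
            "name": list(gamut.names),
            "c1": gamut.centroids[:, 0],
            "c2": gamut.centroids[:, 1],
            "c3": gamut.centroids[:, 2],
            "space": gamut.space_tag,
        }
    ).to_csv(path, index=False)


def default_gamut() -> ColorGamut:
    """The shipped six-centroid facial gamut (CIEXYZ)."""
    with resources.files("nbds").joinpath("data/default_gamut.csv").open() as fh:
        df = pd.read_csv(fh)
    return ColorGamut(
        centroids=df[["c1", "c2", "c3"]].to_numpy(dtype=float),
        space_tag=str(df["space"].iloc[0]),
        names=tuple(df["name"].astype(str)),
    )


def make_default_gamut(seed: int = 42, n_samples: int = 4000) -> ColorGamut:
    """Regenerate the shipped gamut: k-means on a synthetic skin-tone cloud.

    The cloud interpolates between dark and light skin anchors in sRGB with
    red-to-yellow chromatic jitter, is converted to CIEXYZ, and clustered
    with k=6; centroids are ordered by decreasing luminance Y.
    """
    from sklearn.cluster import KMeans

    rng = np.random.default_rng(seed)
    dark = np.array([0.35, 0.22, 0.15])
    light = np.array([0.95, 0.80, 0.72])
    t = rng.uniform(0.0, 1.0, size=(n_samples, 1))
    base = dark + t * (light - dark)
    # red-to-yellow chromatic spread plus mild broadband jitter
    red = rng.uniform(-0.06, 0.10, size=(n_samples, 1)) * np.array([1.0, -0.3, -0.5])
    yellow = rng.uniform(-0.04, 0.08, size=(n_samples, 1)) * np.array([0.4, 0.3, -1.0])
    cloud = np.clip(base + red + yellow + rng.normal(0, 0.01, (n_samples, 3)), 0, 1)
    xyz = srgb_to_xyz(cloud)
    km = KMeans(n_clusters=N_CENTROIDS, n_init=10, random_state=seed).fit(xyz)
    order = np.argsort(-km.cluster_centers_[:, 1])  # by decreasing Y
    centroids = km.cluster_centers_[order]
    names = tuple(f"skin{i + 1}" for i in range(N_CENTROIDS))
    return ColorGamut(centroids, "xyz", names)
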