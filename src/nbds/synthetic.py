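"""Synthetic face images and feature datasets with known ground truth.

The clinical face cohort behind this pipeline is not distributable, so this
module emulates its statistical structure end to end:

* :func:`generate_face` renders a fixed-size skin-colored raster with two
  dark circular pupils at plausible upper-half positions and, around each of
  the four key-block centers implied by the pupil geometry, a patch of
  pixels drawn from a per-region mixture over the six gamut centroids with
  isotropic Gaussian color noise.  The returned ground-truth record makes
  every upstream stage (pupil detection, block geometry, feature
  extraction) checkable against construction.
* :func:`generate_feature_dataset` skips rendering and draws gamut-histogram
  feature vectors directly: healthy samples around a base centroid mixture,
  disease samples around the same mixture with delta probability mass moved
  between two designated centroids — a controllable effect size emulating
  the premise that disease alters the facial color distribution.

Default cohort sizes mirror the reference study: 119 disease (80 cerebral
infarction + 39 other) versus 595 healthy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .block_extraction import compute_block_centers, to_array_coords
from .color_features import ColorGamut, default_gamut, xyz_to_srgb, lab_to_xyz
from .errors import InputValidationError, ProfileError
from .types import BLOCK_NAMES, DEFAULT_FEATURE_BLOCKS, FacialImage, LabeledDataset, PupilPair

#: Default image size (width, height) and block side, matching the capture
#: device contract.
DEFAULT_IMAGE_SIZE = (768, 494)
DEFAULT_BLOCK_SIDE = 64

#: Margin (pixels) by which painted regions exceed the extracted block on
#: each side, absorbing pupil-detection error and center rounding.
REGION_MARGIN = 8

#: Base healthy mixture over the six gamut centroids.
DEFAULT_BASE_MIXTURE = np.array([0.45, 0.20, 0.15, 0.10, 0.06, 0.04])


@dataclass
class ClassProfile:
    """Healthy-vs-disease contrast in gamut-mixture space.

    ``delta`` probability mass is moved from centroid ``shift_from`` to
    ``shift_to`` for the disease class; ``sigma`` is the scale of the
    Gaussian perturbation applied per sample (clipped and renormalized back
    onto the simplex).
    """

    base_mixture: np.ndarray = field(
        default_factory=lambda: DEFAULT_BASE_MIXTURE.copy()
    )
    delta: float = 0.4
    sigma: float = 0.02
    shift_from: int = 0
    shift_to: int = 5

    def __post_init__(self):
        self.base_mixture = np.asarray(self.base_mixture, dtype=float)
        if self.base_mixture.shape != (6,) or self.base_mixture.min() < 0:
            raise ProfileError("base mixture must be 6 non-negative weights")
        if abs(self.base_mixture.sum() - 1.0) > 1e-9:
            raise ProfileError("base mixture must sum to 1")
        if self.delta < 0:
            raise ProfileError("effect size delta must be non-negative")
        if self.base_mixture[self.shift_from] < self.delta - 1e-12:
            raise ProfileError(
                "delta shift would drive the source centroid weight negative"
            )

    def disease_mixture(self) -> np.ndarray:
        mix = self.base_mixture.copy()
        mix[self.shift_from] -= self.delta
        mix[self.shift_to] += self.delta
        return mix


@dataclass
class FaceSpec:
    """Geometry and per-region color mixtures of one synthetic face."""

    width: int = DEFAULT_IMAGE_SIZE[0]
    height: int = DEFAULT_IMAGE_SIZE[1]
    pupils: PupilPair = field(
        default_factory=lambda: PupilPair(left=(300.0, 285.0), right=(468.0, 285.0))
    )
    pupil_radius: float = 10.0
    region_mixtures: dict[str, np.ndarray] = field(default_factory=dict)
    sigma: float = 0.02
    label: str = "H"
    block_side: int = DEFAULT_BLOCK_SIDE

    def __post_init__(self):
        for name, mix in self.region_mixtures.items():
            mix = np.asarray(mix, dtype=float)
            if mix.shape != (6,) or mix.min() < 0 or abs(mix.sum() - 1.0) > 1e-9:
                raise ProfileError(f"region {name!r} mixture is not a simplex point")
            self.region_mixtures[name] = mix
        # pupils must sit in the upper half of the raster
        for x, y in (self.pupils.left, self.pupils.right):
            row, col = to_array_coords(x, y, self.height)
            if not (0 <= row < self.height / 2 and 0 <= col < self.width):
                raise InputValidationError(
                    "pupils must lie in the upper half of the image"
                )


def _simplex_perturb(mixture: np.ndarray, sigma: float, rng) -> np.ndarray:
    """Gaussian perturbation clipped at zero and renormalized to the simplex."""
    if sigma == 0:
        return mixture.copy()
    noisy = np.clip(mixture + rng.normal(0.0, sigma, size=mixture.shape), 0.0, None)
    total = noisy.sum()
    if total <= 0:  # pathological draw; fall back to the mean
        return mixture.copy()
    return noisy / total


def generate_face(
    spec: FaceSpec, seed: int = 0, gamut: ColorGamut | None = None
) -> tuple[FacialImage, dict]:
    """Render one synthetic face and its ground-truth record.

    Each region square (block side plus an 8-pixel margin on each side,
    centered on the true block center) is filled pixel-wise: a centroid is
    drawn from the region's mixture and Gaussian color noise of scale
    ``spec.sigma`` is added in the gamut's space before conversion to sRGB.
    Pupils are dark filled discs.  The same spec and seed reproduce the
    image bit for bit.
    """
    gamut = gamut if gamut is not None else default_gamut()
    rng = np.random.default_rng(seed)
    h, w = spec.height, spec.width
    centers = compute_block_centers(spec.pupils, h)

    region_side = spec.block_side + 2 * REGION_MARGIN
    half = region_side // 2
    for name in BLOCK_NAMES:
        row, col = to_array_coords(*centers[name], h)
        if row - half < 0 or col - half < 0 or row + half > h or col + half > w:
            raise InputValidationError(
                f"pupils too close to the border: region {name!r} does not fit"
            )

    def to_srgb(coords):
        xyz = coords if gamut.space_tag == "xyz" else lab_to_xyz(coords)
        return xyz_to_srgb(xyz)

    # base skin: the mixture-weighted mean centroid of the first region
    base_mix = spec.region_mixtures.get("FHB", np.full(6, 1 / 6))
    base_color = to_srgb((base_mix @ gamut.centroids).reshape(1, 1, 3))[0, 0]
    pixels = np.tile(base_color, (h, w, 1))

    truth_mixtures = {}
    for name in BLOCK_NAMES:
        mix = spec.region_mixtures.get(name, base_mix)
        truth_mixtures[name] = np.asarray(mix, dtype=float)
        row_c, col_c = to_array_coords(*centers[name], h)
        r0, c0 = int(round(row_c)) - half, int(round(col_c)) - half
        idx = rng.choice(6, size=(region_side, region_side), p=mix)
        coords = gamut.centroids[idx]
        if spec.sigma > 0:
            coords = coords + rng.normal(0.0, spec.sigma, size=coords.shape)
        pixels[r0 : r0 + region_side, c0 : c0 + region_side, :] = to_srgb(coords)

    # dark pupil discs
    rows, cols = np.mgrid[0:h, 0:w]
    for x, y in (spec.pupils.left, spec.pupils.right):
        prow, pcol = to_array_coords(x, y, h)
        disc = (rows - prow) ** 2 + (cols - pcol) ** 2 <= spec.pupil_radius**2
        pixels[disc] = 0.03

    truth = {
        "label": spec.label,
        "pupils": {"left": list(spec.pupils.left), "right": list(spec.pupils.right)},
        "pupil_radius": spec.pupil_radius,
        "block_centers": {k: list(v) for k, v in centers.items()},
        "region_mixtures": {k: v.tolist() for k, v in truth_mixtures.items()},
        "sigma": spec.sigma,
        "seed": seed,
    }
    return FacialImage(np.clip(pixels, 0.0, 1.0), space_tag="srgb"), truth


def random_face_spec(
    label: str,
    mixture: np.ndarray,
    rng,
    sigma: float = 0.02,
    width: int = DEFAULT_IMAGE_SIZE[0],
    height: int = DEFAULT_IMAGE_SIZE[1],
    block_side: int = DEFAULT_BLOCK_SIDE,
) -> FaceSpec:
    """A face spec with jittered pupil geometry and one mixture per region."""
    cx = width / 2 + rng.uniform(-8, 8)
    gap = rng.uniform(150, 180)
    # pupil row ~0.42-0.44 of the height: high enough that the forehead
    # region (H/3 above the pupils) clears the top edge, low enough that the
    # cheek regions (H/4 below) clear the bottom and the pupils stay in the
    # upper half
    y = (height - 1) - height * rng.uniform(0.42, 0.44)
    pupils = PupilPair(
        left=(cx - gap / 2, y + rng.uniform(-2, 2)),
        right=(cx + gap / 2, y + rng.uniform(-2, 2)),
    )
    mixtures = {name: np.asarray(mixture, dtype=float) for name in BLOCK_NAMES}
    return FaceSpec(
        width=width,
        height=height,
        pupils=pupils,
        region_mixtures=mixtures,
        sigma=sigma,
        label=label,
        block_side=block_side,
    )


def generate_face_dataset(
    n_disease: int,
    n_healthy: int,
    profile: ClassProfile,
    seed: int = 0,
    gamut: ColorGamut | None = None,
    **spec_kwargs,
) -> list[tuple[FacialImage, dict]]:
    """Render a labeled cohort of faces, disease samples first."""
    rng = np.random.default_rng(seed)
    out = []
    for label, count, mixture in (
        ("BD", n_disease, profile.disease_mixture()),
        ("H", n_healthy, profile.base_mixture),
    ):
        for _ in range(count):
            spec = random_face_spec(
                label, mixture, rng, sigma=profile.sigma, **spec_kwargs
            )
            out.append(
                generate_face(spec, seed=int(rng.integers(2**31 - 1)), gamut=gamut)
            )
    return out


def generate_feature_dataset(
    n_disease: int,
    n_healthy: int,
    profile: ClassProfile,
    seed: int = 0,
    blocks: tuple[str, ...] = DEFAULT_FEATURE_BLOCKS,
) -> LabeledDataset:
    """Draw gamut-histogram features directly (no rendering).

    Each sample concatenates one perturbed mixture per block (6 values per
    block); the disease shift applies to every block, so any block
    combination carries the class signal.  Disease samples occupy the first
    ``n_disease`` columns, matching the split-plan index convention.
    """
    if n_disease < 1 or n_healthy < 1:
        raise InputValidationError("class counts must be at least 1")
    rng = np.random.default_rng(seed)
    columns, labels = [], []
    for label, count, mixture in (
        ("BD", n_disease, profile.disease_mixture()),
        ("H", n_healthy, profile.base_mixture),
    ):
        for _ in range(count):
            parts = [
                _simplex_perturb(mixture, profile.sigma, rng) for _ in blocks
            ]
            columns.append(np.concatenate(parts))
            labels.append(label)
    return LabeledDataset(
        np.column_stack(columns), np.asarray(labels), feature_blocks=tuple(blocks)
    )
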