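import numpy as np
import pytest

from nbds.color_features import (
    BlockFeature,
    ColorGamut,
    GamutHistogramExtractor,
    assign_centroids,
    combine_features,
    extract_block_feature,
    lab_to_xyz,
    load_gamut,
    make_default_gamut,
    save_gamut,
    srgb_to_xyz,
    xyz_to_lab,
    xyz_to_srgb,
)
from nbds.errors import GamutError, InputValidationError
from nbds.types import KeyBlock


def make_block(pixels, name="LCB"):
    s = pixels.shape[0]
    return KeyBlock(name=name, center=(0.0, 0.0), side=s, pixels=pixels)


def test_white_maps_to_d65_whitepoint():
    xyz = srgb_to_xyz(np.ones((1, 1, 3)))[0, 0]
    assert xyz == pytest.approx((0.9505, 1.0000, 1.0888), abs=1e-3)
    assert np.allclose(srgb_to_xyz(np.zeros((1, 1, 3))), 0.0)


def test_d65_white_is_lab_origin():
    white = np.array([[[0.95047, 1.0, 1.08883]]])
    lab = xyz_to_lab(white)[0, 0]
    assert lab[0] == pytest.approx(100.0, abs=1e-6)
    assert lab[1] == pytest.approx(0.0, abs=1e-6)
    assert lab[2] == pytest.approx(0.0, abs=1e-6)
    assert xyz_to_lab(np.zeros((1, 1, 3)))[0, 0, 0] == 0.0


def test_lab_xyz_roundtrip():
    rng = np.random.default_rng(2)
    xyz = rng.uniform(0.05, 0.9, size=(40, 3)) * np.array([0.95, 1.0, 1.08])
    lab = xyz_to_lab(xyz)
    assert np.max(np.abs(xyz_to_lab(lab_to_xyz(lab)) - lab)) < 1e-9


def test_y_channel_monotone_in_each_rgb_channel():
    base = np.array([0.3, 0.4, 0.5])
    for ch in range(3):
        grid = np.tile(base, (20, 1))
        grid[:, ch] = np.linspace(0, 1, 20)
        Y = srgb_to_xyz(grid.reshape(20, 1, 3))[:, 0, 1]
        assert np.all(np.diff(Y) >= 0)


def test_out_of_range_inputs_rejected():
    with pytest.raises(InputValidationError):
        srgb_to_xyz(np.array([[[1.2, 0, 0]]]))
    with pytest.raises(InputValidationError):
        xyz_to_lab(np.array([[[-0.1, 0.5, 0.5]]]))


def test_uniform_block_at_centroid_is_one_hot(gamut):
    srgb = xyz_to_srgb(gamut.centroids[3].reshape(1, 1, 3))[0, 0]
    block = make_block(np.tile(srgb, (16, 16, 1)))
    feat = extract_block_feature(block, gamut)
    assert np.array_equal(feat.proportions, np.eye(6)[3])


def test_half_and_half_block(gamut):
    c0 = xyz_to_srgb(gamut.centroids[0].reshape(1, 1, 3))[0, 0]
    c1 = xyz_to_srgb(gamut.centroids[1].reshape(1, 1, 3))[0, 0]
    pixels = np.tile(c0, (16, 16, 1))
    pixels[:, 8:, :] = c1
    feat = extract_block_feature(make_block(pixels), gamut)
    assert np.allclose(feat.proportions, [0.5, 0.5, 0, 0, 0, 0])


def test_proportions_match_brute_force_scan(gamut):
    """Oracle: exhaustive per-pixel nearest-centroid loop."""
    rng = np.random.default_rng(17)
    pixels = rng.uniform(0.05, 0.95, size=(12, 12, 3))
    feat = extract_block_feature(make_block(pixels), gamut)
    counts = np.zeros(6)
    for i in range(12):
        for j in range(12):
            xyz = srgb_to_xyz(pixels[i, j].reshape(1, 1, 3))[0, 0]
            d = [np.linalg.norm(xyz - c) for c in gamut.centroids]
            counts[int(np.argmin(d))] += 1
    assert np.allclose(feat.proportions, counts / 144)
    assert feat.proportions.sum() == pytest.approx(1.0, abs=1e-9)


def test_pixel_permutation_invariance(gamut):
    rng = np.random.default_rng(4)
    pixels = rng.uniform(size=(10, 10, 3))
    flat = pixels.reshape(-1, 3)
    shuffled = flat[rng.permutation(100)].reshape(10, 10, 3)
    f1 = extract_block_feature(make_block(pixels), gamut)
    f2 = extract_block_feature(make_block(shuffled), gamut)
    assert np.array_equal(f1.proportions, f2.proportions)


def test_extraction_is_deterministic(gamut):
    rng = np.random.default_rng(5)
    pixels = rng.uniform(size=(8, 8, 3))
    a = extract_block_feature(make_block(pixels), gamut).proportions
    b = extract_block_feature(make_block(pixels.copy()), gamut).proportions
    assert np.array_equal(a, b)


def test_tie_resolves_to_lowest_centroid_index():
    # place centroids 0 and 1 exactly symmetric (+-0.125 in X, a power of
    # two, so the offsets are floating-point exact) around the pixel's own
    # XYZ coordinate: both squared distances are bitwise identical
    pixel = np.array([[[0.5, 0.4, 0.3]]])
    xyz = srgb_to_xyz(pixel)[0, 0]
    offset = np.array([0.125, 0.0, 0.0])
    centroids = np.vstack(
        [xyz + offset, xyz - offset,
         [2.0, 2.0, 2.0], [3.0, 3.0, 3.0], [4.0, 4.0, 4.0], [5.0, 5.0, 5.0]]
    )
    gamut = ColorGamut(centroids, "xyz", tuple("abcdef"))
    d = ((xyz - centroids[:2]) ** 2).sum(axis=1)
    assert d[0] == d[1]  # the construction really is an exact tie
    assert assign_centroids(pixel, gamut)[0] == 0


def test_combine_features_order_and_dims():
    f = [
        BlockFeature(np.eye(6)[i], name)
        for i, name in enumerate(("FHB", "LCB", "NBB"))
    ]
    combined = combine_features(f)
    assert combined.dim == 18
    assert combined.values.sum() == pytest.approx(3.0, abs=1e-9)
    two = combine_features([f[0], f[2]])
    assert two.dim == 12
    assert np.array_equal(two.values[:6], f[0].proportions)
    assert np.array_equal(two.values[6:], f[2].proportions)
    one = combine_features([f[1]])
    assert one.dim == 6
    with pytest.raises(InputValidationError):
        combine_features([f[0], f[0]])


def test_degenerate_gamut_rejected():
    centroids = np.tile([0.3, 0.3, 0.3], (6, 1))
    with pytest.raises(GamutError):
        ColorGamut(centroids, "xyz", tuple("abcdef"))


def test_gamut_csv_roundtrip(tmp_path, gamut):
    path = tmp_path / "gamut.csv"
    save_gamut(gamut, path)
    loaded = load_gamut(path)
    assert loaded.space_tag == gamut.space_tag
    assert np.allclose(loaded.centroids, gamut.centroids)


def test_default_gamut_is_reproducible(gamut):
    regenerated = make_default_gamut(seed=42)
    assert np.allclose(regenerated.centroids, gamut.centroids, atol=1e-9)


def test_transformer_matches_function_path(gamut, noisy_face):
    from nbds.block_extraction import detect_pupils, extract_key_blocks

    image, _ = noisy_face
    blocks = extract_key_blocks(image, detect_pupils(image))
    X = GamutHistogramExtractor(gamut=gamut).fit().transform([blocks])
    assert X.shape == (1, 18)
    manual = np.concatenate(
        [
            extract_block_feature(blocks[name], gamut).proportions
            for name in ("FHB", "LCB", "NBB")
        ]
    )
    assert np.array_equal(X[0], manual)
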