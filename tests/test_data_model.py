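"""Dataset I/O, point derivation from masks, and coordinate scaling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from pointseg.data_model import (
    Scene,
    derive_points_from_mask,
    load_manifest,
    read_mask,
    write_mask,
)


# ------------------------------------------------------------ write_mask
def test_mask_round_trip_identity(tmp_path, rng):
    mask = (rng.uniform(size=(16, 16)) > 0.5).astype(np.uint8)
    path = tmp_path / "m.png"
    write_mask(mask, path)
    np.testing.assert_array_equal(read_mask(path), mask)


def test_mask_foreground_count_conserved(tmp_path):
    ones = np.ones((5, 7), dtype=np.uint8)
    write_mask(ones, tmp_path / "ones.png")
    assert read_mask(tmp_path / "ones.png").sum() == 35

    checker = np.indices((4, 4)).sum(axis=0) % 2
    write_mask(checker, tmp_path / "c.png")
    assert read_mask(tmp_path / "c.png").sum() == 8


def test_write_mask_rejects_non_binary(tmp_path):
    with pytest.raises(ValueError):
        write_mask(np.full((4, 4), 3), tmp_path / "bad.png")


# ------------------------------------------- derive_points_from_mask
def brute_force_points(mask):
    """Independent oracle: per-pixel distance to nearest background pixel
    (outside the image counts as background), then per 8-connected component
    the max-distance pixel (row-major ties)."""
    from scipy import ndimage as ndi

    h, w = mask.shape
    padded = np.pad(mask, 1)
    bg = np.argwhere(padded == 0) - 1  # back to unpadded coordinates
    dist = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            if mask[r, c]:
                dist[r, c] = np.sqrt(((bg - (r, c)) ** 2).sum(axis=1)).min()
    labels, n = ndi.label(mask, structure=np.ones((3, 3)))
    pts = []
    for k in range(1, n + 1):
        best, best_d = None, -1.0
        for r in range(h):
            for c in range(w):
                if labels[r, c] == k and dist[r, c] > best_d:
                    best, best_d = (r, c), dist[r, c]
        pts.append(best)
    return pts


def test_empty_mask_gives_no_points():
    assert derive_points_from_mask(np.zeros((8, 8), dtype=np.uint8)) == []


def test_disk_center_is_the_point():
    yy, xx = np.mgrid[0:21, 0:21]
    disk = ((yy - 10) ** 2 + (xx - 10) ** 2 <= 36).astype(np.uint8)
    assert derive_points_from_mask(disk) == [(10, 10)]


def test_rectangle_point_matches_brute_force():
    # 3x7 rectangle at the image corner: with out-of-image treated as
    # background, the deepest pixels sit on the middle row, distance 2
    mask = np.zeros((6, 10), dtype=np.uint8)
    mask[0:3, 0:7] = 1
    (pt,) = derive_points_from_mask(mask)
    (ref,) = brute_force_points(mask)
    assert pt == ref
    assert pt[0] == 1 and 1 <= pt[1] <= 5


def test_points_match_brute_force_on_random_masks(rng):
    for _ in range(15):
        mask = (rng.uniform(size=(12, 12)) > 0.65).astype(np.uint8)
        assert derive_points_from_mask(mask) == brute_force_points(mask)


def test_one_point_per_component_and_deterministic(rng):
    from scipy import ndimage as ndi

    for _ in range(30):
        mask = (rng.uniform(size=(32, 32)) > 0.7).astype(np.uint8)
        pts = derive_points_from_mask(mask)
        _, n = ndi.label(mask, structure=np.ones((3, 3)))
        assert len(pts) == n
        assert pts == derive_points_from_mask(mask)


def test_non_binary_mask_rejected():
    with pytest.raises(ValueError):
        derive_points_from_mask(np.full((4, 4), 2))


@settings(deadline=None, derandomize=True, max_examples=30)
@given(
    arrays(np.uint8, (10, 10), elements=st.integers(min_value=0, max_value=1))
)
def test_one_point_per_component_property(mask):
    """Any binary mask yields exactly one in-component point per component."""
    from scipy import ndimage as ndi

    pts = derive_points_from_mask(mask)
    labels, n = ndi.label(mask, structure=np.ones((3, 3)))
    assert len(pts) == n
    assert len(set(pts)) == n
    seen = {labels[r, c] for r, c in pts}
    assert seen == set(range(1, n + 1))


# ------------------------------------------------------------- manifest
def _write_scene(root, split, scene_id, image, points=None, mask=None):
    import imageio.v3 as iio

    d = root / "images" / split
    d.mkdir(parents=True, exist_ok=True)
    iio.imwrite(d / f"{scene_id}.png", image, extension=".png")
    if points is not None:
        pm = np.zeros(image.shape[:2], dtype=np.uint8)
        for r, c in points:
            pm[r, c] = 1
        write_mask(pm, root / "points" / split / f"{scene_id}.png")
    if mask is not None:
        write_mask(mask, root / "masks" / split / f"{scene_id}.png")
    listing = root / f"{split}.txt"
    prev = listing.read_text() if listing.exists() else ""
    listing.write_text(prev + scene_id + "\n")


def test_empty_root_gives_empty_manifest(tmp_path):
    assert len(load_manifest(tmp_path)) == 0


def test_point_count_preserved(tmp_path, rng):
    img = (rng.uniform(size=(20, 20, 3)) * 255).astype(np.uint8)
    _write_scene(tmp_path, "train", "a", img, points=[(2, 3), (5, 5), (10, 19)])
    man = load_manifest(tmp_path)
    assert len(man.scenes[0].points) == 3


def test_resize_scales_points_half_down(tmp_path):
    img = np.zeros((512, 910, 3), dtype=np.uint8)
    _write_scene(tmp_path, "train", "big", img, points=[(510, 900)])
    man = load_manifest(tmp_path, resize_target=(256, 455))
    scene = man.scenes[0]
    assert scene.image.shape[:2] == (256, 455)
    assert scene.points == [(255, 450)]


def test_missing_image_raises_named_error(tmp_path):
    (tmp_path / "train.txt").write_text("ghost\n")
    with pytest.raises(FileNotFoundError, match="ghost"):
        load_manifest(tmp_path)


def test_point_off_mask_warns_but_is_kept(tmp_path):
    img = np.zeros((10, 10, 3), dtype=np.uint8)
    mask = np.zeros((10, 10), dtype=np.uint8)
    mask[5:8, 5:8] = 1
    _write_scene(tmp_path, "train", "x", img, points=[(1, 1)], mask=mask)
    with pytest.warns(UserWarning, match="off the mask"):
        man = load_manifest(tmp_path)
    assert man.scenes[0].points == [(1, 1)]


def test_scene_rejects_out_of_bounds_and_duplicate_points(rng):
    img = rng.uniform(size=(8, 8, 3))
    with pytest.raises(ValueError, match="outside"):
        Scene("s", img, [(9, 0)])
    with pytest.raises(ValueError, match="duplicate"):
        Scene("s", img, [(1, 1), (1, 1)])
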