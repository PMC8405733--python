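"""The four LCFCN loss terms against straight-line reimplementations."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage.segmentation import watershed

from pointseg.autodiff import Tensor
from pointseg.losses import (
    false_positive_loss,
    find_blobs,
    image_level_loss,
    lcfcn_loss,
    point_level_loss,
    split_level_loss,
)
from pointseg.network import ProbMap

CLAMP = 1e-8
S8 = np.ones((3, 3))


def make_probmap(fg):
    fg = np.asarray(fg, dtype=float)
    return ProbMap(Tensor(np.stack([1.0 - fg, fg])))


# -------------------------------------------------- independent oracle
def oracle_lcfcn(fg_prob, points):
    """Straight-line reimplementation of the four terms."""
    nl = lambda p: -np.log(np.maximum(p, CLAMP))
    bg_prob = 1.0 - fg_prob
    # image level
    if points:
        l_i = nl(fg_prob.max())
    else:
        l_i = nl(1.0 - fg_prob.max())
    # point level
    l_p = sum(nl(fg_prob[r, c]) for r, c in points)
    # blobs
    fg_mask = fg_prob > bg_prob
    labels, n = ndi.label(fg_mask, structure=S8)
    per_blob_pts = {k: [] for k in range(1, n + 1)}
    for r, c in points:
        k = labels[r, c]
        if k:
            per_blob_pts[k].append((r, c))
    # split level: watershed line inside multi-point blobs
    l_s = 0.0
    for k, pts in per_blob_pts.items():
        if len(pts) < 2:
            continue
        markers = np.zeros_like(labels)
        for i, (r, c) in enumerate(pts, 1):
            markers[r, c] = i
        basins = watershed(-fg_prob, markers, mask=labels == k,
                           connectivity=2, watershed_line=True)
        ridge = (labels == k) & (basins == 0)
        l_s += len(pts) * nl(bg_prob[ridge]).sum()
    # false positives
    l_f = 0.0
    for k, pts in per_blob_pts.items():
        if not pts:
            l_f += nl(bg_prob[labels == k]).sum()
    return l_i, l_p, l_s, l_f


# ------------------------------------------------------------ find_blobs
def test_all_background_gives_empty_blobset():
    blobs = find_blobs(make_probmap(np.full((6, 6), 0.2)), [(1, 1)])
    assert len(blobs) == 0


def test_disjoint_squares_each_take_their_point():
    fg = np.zeros((8, 8))
    fg[1:3, 1:3] = 0.9
    fg[5:7, 5:7] = 0.9
    blobs = find_blobs(make_probmap(fg), [(1, 1), (6, 6)])
    assert len(blobs) == 2
    assert sorted(len(b.contained_points) for b in blobs.blobs.values()) == [1, 1]


def test_diagonal_touch_is_one_blob_under_8_connectivity():
    fg = np.zeros((2, 2))
    fg[0, 1] = 0.9
    fg[1, 0] = 0.9
    assert len(find_blobs(make_probmap(fg), [])) == 1
    # sanity: 4-connectivity would split it
    _, n4 = ndi.label(fg > 0.5)
    assert n4 == 2


# ------------------------------------------------------------ term values
def test_image_level_values():
    fg = np.full((4, 4), 0.1)
    fg[2, 2] = 1.0
    assert float(image_level_loss(make_probmap(fg), [(2, 2)]).data) == pytest.approx(0.0)
    zero = np.zeros((4, 4))
    assert float(image_level_loss(make_probmap(zero), []).data) == pytest.approx(0.0)
    half = np.full((4, 4), 0.5)
    assert float(image_level_loss(make_probmap(half), []).data) == pytest.approx(
        np.log(2), abs=1e-9
    )


def test_point_level_values():
    fg = np.full((4, 4), 0.5)
    fg[1, 1] = 0.5
    fg[2, 2] = 0.25
    pm = make_probmap(fg)
    assert float(point_level_loss(pm, []).data) == 0.0
    got = float(point_level_loss(pm, [(1, 1), (2, 2)]).data)
    assert got == pytest.approx(-np.log(0.5) - np.log(0.25), abs=1e-9)


def test_split_loss_strip_boundary_at_middle():
    # 1x5 foreground strip, clicks at both ends, uniform fish prob 0.9:
    # the watershed ridge is the middle column
    fg = np.full((1, 5), 0.9)
    pm = make_probmap(fg)
    blobs = find_blobs(pm, [(0, 0), (0, 4)])
    got = float(split_level_loss(pm, blobs).data)
    assert got == pytest.approx(2 * -np.log(0.1), rel=1e-6)


def test_split_loss_zero_for_single_point_blobs():
    fg = np.zeros((6, 6))
    fg[2:4, 2:4] = 0.9
    pm = make_probmap(fg)
    blobs = find_blobs(pm, [(2, 2)])
    assert float(split_level_loss(pm, blobs).data) == 0.0


def test_false_positive_values():
    fg = np.zeros((4, 4))
    fg[0, 0:3] = [0.5 + 1e-9, 0.5 + 1e-9, 0.75]  # one 3-pixel blob, no point
    pm = make_probmap(fg)
    blobs = find_blobs(pm, [])
    got = float(false_positive_loss(pm, blobs).data)
    assert got == pytest.approx(-np.log(0.5) * 2 - np.log(0.25), rel=1e-6)


def test_false_positive_zero_cases():
    fg = np.zeros((4, 4))
    pm = make_probmap(fg)
    assert float(false_positive_loss(pm, find_blobs(pm, [])).data) == 0.0
    fg[1:3, 1:3] = 0.9
    pm = make_probmap(fg)
    blobs = find_blobs(pm, [(1, 1)])
    assert float(false_positive_loss(pm, blobs).data) == 0.0


# ----------------------------------------------------- full loss vs oracle
def test_total_matches_oracle_on_random_probmaps(rng):
    h = w = 8
    for _ in range(100):
        fg = rng.uniform(size=(h, w))
        n_pts = rng.integers(0, 4)
        pts = []
        while len(pts) < n_pts:
            p = (int(rng.integers(h)), int(rng.integers(w)))
            if p not in pts:
                pts.append(p)
        report = lcfcn_loss(make_probmap(fg), pts)
        l_i, l_p, l_s, l_f = oracle_lcfcn(fg, pts)
        assert report.image_level == pytest.approx(l_i, rel=1e-6, abs=1e-9)
        assert report.point_level == pytest.approx(l_p, rel=1e-6, abs=1e-9)
        assert report.split_level == pytest.approx(l_s, rel=1e-6, abs=1e-9)
        assert report.false_positive == pytest.approx(l_f, rel=1e-6, abs=1e-9)
        total = l_i + l_p + l_s + l_f
        assert float(report.total.data) == pytest.approx(total, rel=1e-6)
        assert min(report.image_level, report.point_level,
                   report.split_level, report.false_positive) >= 0.0


def test_perfect_empty_prediction_has_zero_loss():
    pm = make_probmap(np.zeros((6, 6)))
    report = lcfcn_loss(pm, [])
    assert float(report.total.data) == pytest.approx(0.0, abs=1e-7)


def test_loss_is_differentiable_wrt_probabilities(rng):
    logits = Tensor(rng.standard_normal((2, 6, 6)), requires_grad=True)
    pm = ProbMap(logits.softmax(axis=0))
    report = lcfcn_loss(pm, [(2, 2), (4, 4)])
    report.total.backward()
    assert logits.grad is not None
    assert np.abs(logits.grad).sum() > 0
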