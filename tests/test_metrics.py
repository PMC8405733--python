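"""IoU / MAE / GAME against brute-force pixel and cell counting."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from pointseg.metrics import (
    MetricReport,
    blob_centroids,
    count_predictions,
    evaluate_set,
    game,
    iou_accumulate,
    mae,
)

S8 = np.ones((3, 3))


# ------------------------------------------------------- brute force oracles
def oracle_iou(preds, trues):
    tp = [0, 0]
    fp = [0, 0]
    fn = [0, 0]
    for p, t in zip(preds, trues):
        for c in (0, 1):
            pc, tc = (p == c), (t == c)
            tp[c] += int((pc & tc).sum())
            fp[c] += int((pc & ~tc).sum())
            fn[c] += int((~pc & tc).sum())
    ious = [
        1.0 if tp[c] + fp[c] + fn[c] == 0 else tp[c] / (tp[c] + fp[c] + fn[c])
        for c in (0, 1)
    ]
    return ious[0], ious[1], 0.5 * (ious[0] + ious[1])


def oracle_game(masks, points, L, shape):
    k = 2 ** L
    h, w = shape
    total = 0.0
    for m, pts in zip(masks, points):
        labels, n = ndi.label(m, structure=S8)
        cents = []
        for b in range(1, n + 1):
            rr, cc = np.nonzero(labels == b)
            cents.append((rr.mean(), cc.mean()))
        err = 0
        for i in range(k):
            for j in range(k):
                r0, r1 = (h * i) // k, (h * (i + 1)) // k
                c0, c1 = (w * j) // k, (w * (j + 1)) // k
                pc = sum(1 for r, c in cents if r0 <= r < r1 and c0 <= c < c1)
                tc = sum(1 for r, c in pts if r0 <= r < r1 and c0 <= c < c1)
                err += abs(pc - tc)
        total += err
    return total / len(masks)


def random_mask_set(rng, n=100, h=32, w=32):
    preds, trues, points = [], [], []
    for _ in range(n):
        p = (rng.uniform(size=(h, w)) > 0.8).astype(np.uint8)
        t = (rng.uniform(size=(h, w)) > 0.8).astype(np.uint8)
        npts = int(rng.integers(0, 4))
        pts = [(int(rng.integers(h)), int(rng.integers(w))) for _ in range(npts)]
        preds.append(p)
        trues.append(t)
        points.append(pts)
    return preds, trues, points


# ------------------------------------------------------------------- IoU
def test_identical_masks_are_perfect(rng):
    m = (rng.uniform(size=(10, 10)) > 0.5).astype(np.uint8)
    rep = iou_accumulate([m], [m])
    assert rep.iou_background == 1.0
    assert rep.iou_foreground == 1.0
    assert rep.miou == 1.0


def test_shifted_block_foreground_iou_is_one_third():
    pred = np.zeros((6, 6), dtype=np.uint8)
    true = np.zeros((6, 6), dtype=np.uint8)
    pred[2:4, 1:3] = 1
    true[2:4, 2:4] = 1
    rep = iou_accumulate([pred], [true])
    assert rep.tp[1] == 2 and rep.fp[1] == 2 and rep.fn[1] == 2
    assert rep.iou_foreground == pytest.approx(1 / 3)


def test_absent_class_scores_one():
    z = np.zeros((5, 5), dtype=np.uint8)
    rep = iou_accumulate([z], [z])
    assert rep.iou_background == 1.0
    assert rep.iou_foreground == 1.0  # 0/0 -> vacuously perfect


def test_iou_matches_oracle_on_random_sets(rng):
    preds, trues, _ = random_mask_set(rng)
    rep = iou_accumulate(preds, trues)
    bg, fg, miou = oracle_iou(preds, trues)
    assert rep.iou_background == pytest.approx(bg, abs=1e-12)
    assert rep.iou_foreground == pytest.approx(fg, abs=1e-12)
    assert rep.miou == pytest.approx(miou, abs=1e-12)


def test_micro_average_pools_before_ratio():
    a = np.zeros((4, 4), dtype=np.uint8)
    b = np.ones((4, 4), dtype=np.uint8)
    # image 1 perfect background, image 2 half-wrong foreground
    pred2 = b.copy()
    pred2[:2] = 0
    rep = iou_accumulate([a, pred2], [a, b])
    # pooled: fg tp=8, fn=8, fp=0 -> 0.5 (not the mean of per-image 1.0 and 0.5)
    assert rep.iou_foreground == pytest.approx(8 / 16)


# ------------------------------------------------------------- counting
def test_count_examples():
    assert count_predictions(np.zeros((8, 8))) == 0
    m = np.zeros((12, 12), dtype=np.uint8)
    m[0:2, 0:2] = m[5:7, 5:7] = m[9:11, 0:2] = 1
    assert count_predictions(m) == 3
    corner = np.zeros((6, 6), dtype=np.uint8)
    corner[1:3, 1:3] = 1
    corner[3:5, 3:5] = 1  # touches at one corner -> single 8-connected blob
    assert count_predictions(corner) == 1


def test_mae_examples():
    assert mae([1, 2, 3], [1, 2, 3]) == 0.0
    assert mae([2, 2], [1, 2]) == 0.5
    # pairing is per-image: a permutation changes the value
    assert mae([2, 1], [1, 2]) == 1.0


def test_mae_length_mismatch():
    with pytest.raises(ValueError):
        mae([1], [1, 2])


# ------------------------------------------------------------------ GAME
def test_game_level_zero_equals_mae(rng):
    preds, _, points = random_mask_set(rng, n=30)
    counts_pred = [count_predictions(p) for p in preds]
    counts_true = [len(p) for p in points]
    assert game(preds, points, 0, (32, 32)) == pytest.approx(
        mae(counts_pred, counts_true)
    )


def test_game_perfect_localization_is_zero():
    m = np.zeros((16, 16), dtype=np.uint8)
    m[2:4, 2:4] = 1
    m[10:12, 10:12] = 1
    pts = [(3, 3), (11, 11)]  # each point shares a 4x4 cell with its blob
    assert game([m], [pts], 2, (16, 16)) == 0.0


def test_game_wrong_cell_counts_double():
    m = np.zeros((16, 16), dtype=np.uint8)
    m[1:3, 9:11] = 1  # centroid in right half
    pts = [(2, 2)]  # truth in left half
    assert game([m], [pts], 1, (16, 16)) == 2.0


def test_game_matches_oracle_and_is_monotone(rng):
    preds, _, points = random_mask_set(rng, n=40)
    prev = None
    for L in (0, 1, 2, 4):
        got = game(preds, points, L, (32, 32))
        ref = oracle_game(preds, points, L, (32, 32))
        assert got == pytest.approx(ref, abs=1e-12)
        if prev is not None:
            assert got >= prev - 1e-12
        prev = got


def test_game_four_partitions_into_256_cells():
    # a single prediction: exactly one of the 256 cells takes the count
    m = np.zeros((32, 32), dtype=np.uint8)
    m[0:2, 0:2] = 1
    val = game([m], [[]], 4, (32, 32))
    assert val == 1.0
    assert 2 ** 4 * 2 ** 4 == 256


def test_negative_level_rejected():
    with pytest.raises(ValueError):
        game([], [], -1, (8, 8))


def test_evaluate_set_schema(rng):
    preds, trues, points = random_mask_set(rng, n=10)
    rep = evaluate_set(preds, trues, points)
    d = rep.as_dict()
    for key in ("iou_background", "iou_foreground", "miou", "mae", "game"):
        assert key in d
    assert rep.game[0] == pytest.approx(rep.mae)
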