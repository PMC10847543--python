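"""Hybrid-loss terms: analytic values, invariants and trainability."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from echonac.losses import (
    LossWeights, active_contour_loss, bce_loss, dice_loss,
    hausdorff_distance_loss, hybrid_loss,
)
from echonac.nn import Adam, Tensor


def random_blob(rng, size=12):
    """Small random connected-ish blob mask."""
    m = np.zeros((size, size))
    r, c = rng.integers(2, size - 2, size=2)
    rad = rng.integers(1, 4)
    rows, cols = np.mgrid[0:size, 0:size]
    m[(rows - r) ** 2 + (cols - c) ** 2 <= rad**2] = 1
    return m


# ---------------------------------------------------------------------------
# BCE
# ---------------------------------------------------------------------------

def test_bce_values():
    truth = np.array([[1, 0], [1, 0]], dtype=float)
    prob = np.array([[0.9, 0.1], [0.8, 0.2]])
    expected = -np.mean([np.log(0.9), np.log(0.9), np.log(0.8), np.log(0.8)])
    assert bce_loss(prob, truth) == pytest.approx(expected, abs=1e-12)
    assert expected == pytest.approx(0.1643, abs=5e-5)
    # exact match (after clipping) is near zero
    assert bce_loss(truth, truth) <= 1e-6
    # uninformative p=0.5 gives ln 2 regardless of the truth
    half = np.full((5, 5), 0.5)
    assert bce_loss(half, np.zeros((5, 5))) == pytest.approx(np.log(2), abs=1e-12)
    assert bce_loss(half, np.ones((5, 5))) == pytest.approx(np.log(2), abs=1e-12)


def test_bce_shape_mismatch():
    with pytest.raises(ValueError, match="shape"):
        bce_loss(np.zeros((2, 2)), np.zeros((3, 3)))


# ---------------------------------------------------------------------------
# Dice
# ---------------------------------------------------------------------------

def test_dice_values():
    t = np.zeros((4, 4))
    t[1:3, 1:3] = 1
    assert dice_loss(t, t, smooth=0) == pytest.approx(0.0, abs=1e-12)
    disjoint = np.zeros((4, 4))
    disjoint[0, 0] = 1
    assert dice_loss(disjoint, t - t + np.roll(disjoint, 2, axis=0), smooth=0) == 1.0
    # p = 0.5 * truth: 1 - (2*0.5|T|) / (0.5|T| + |T|) = 1/3
    assert dice_loss(0.5 * t, t, smooth=0) == pytest.approx(1 / 3, abs=1e-12)


def test_dice_range_random(rng):
    for _ in range(20):
        p = rng.random((8, 8))
        t = (rng.random((8, 8)) > 0.5).astype(float)
        assert 0.0 <= dice_loss(p, t) <= 1.0


# ---------------------------------------------------------------------------
# Active contour
# ---------------------------------------------------------------------------

def test_active_contour_analytic_cases():
    zeros = np.zeros((6, 6))
    assert active_contour_loss(zeros, zeros) == pytest.approx(0.0, abs=1e-3)
    # constant 1 vs all-zero truth, lambda 1: region term = 1, length term 0
    assert active_contour_loss(np.ones((6, 6)), zeros, lambda_region=1.0) == \
        pytest.approx(1.0, abs=1e-3)


def test_active_contour_square_matches_forward_difference_oracle():
    square = np.zeros((6, 6))
    square[2:4, 2:4] = 1.0
    # independent oracle: explicit forward differences on the (5,5) crop grid
    dr = square[1:, :] - square[:-1, :]
    dc = square[:, 1:] - square[:, :-1]
    mag = np.sqrt(dr[:, :-1] ** 2 + dc[:-1, :] ** 2 + 1e-8)
    expected_length = mag.mean()
    got = active_contour_loss(square, square, lambda_region=1.0)
    assert got == pytest.approx(expected_length, abs=1e-6)  # region term is 0


# ---------------------------------------------------------------------------
# Hausdorff surrogate
# ---------------------------------------------------------------------------

def exact_hausdorff(a: np.ndarray, b: np.ndarray) -> float:
    """Brute-force symmetric Hausdorff distance between mask foregrounds."""
    pa, pb = np.argwhere(a > 0), np.argwhere(b > 0)
    if len(pa) == 0 or len(pb) == 0:
        return 0.0 if len(pa) == len(pb) else np.inf
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2))
    return max(d.min(axis=1).max(), d.min(axis=0).max())


def test_hausdorff_zero_at_equality_and_convention():
    t = np.zeros((8, 8))
    t[2:5, 2:5] = 1
    assert hausdorff_distance_loss(t, t) == 0.0
    assert hausdorff_distance_loss(np.zeros((8, 8)), np.zeros((8, 8))) == 0.0


def test_hausdorff_monotone_in_separation():
    losses = []
    for sep in (1, 2, 3):
        truth = np.zeros((10, 10))
        truth[0, 0] = 1
        pred = np.zeros((10, 10))
        pred[0, sep] = 1
        losses.append(hausdorff_distance_loss(pred, truth, alpha=2.0))
    assert losses[0] < losses[1] < losses[2]
    assert all(v > 0 for v in losses)


def test_hausdorff_alpha_zero_is_doubled_mse(rng):
    p = rng.random((9, 9))
    t = (rng.random((9, 9)) > 0.6).astype(float)
    expected = 2.0 * np.mean((p - t) ** 2)
    assert hausdorff_distance_loss(p, t, alpha=0.0) == pytest.approx(expected, rel=1e-12)


def shift_mask(mask, dr, dc):
    """Translate a mask without wrap-around; None if the blob would clip."""
    out = np.zeros_like(mask)
    h, w = mask.shape
    rs, cs = np.argwhere(mask > 0).T
    rs2, cs2 = rs + dr, cs + dc
    if ((rs2 < 0) | (rs2 >= h) | (cs2 < 0) | (cs2 >= w)).any():
        return None
    out[rs2, cs2] = 1
    return out


def hd_ordering_violation_rate(rng, n_bases=15, per_base=10):
    """Fraction of within-base pair orderings where the surrogate disagrees
    with the exact symmetric Hausdorff distance (shifted-blob suite)."""
    violations = total = n_pairs = 0
    for _ in range(n_bases):
        base = random_blob(rng)
        entries, tries = [], 0
        while len(entries) < per_base and tries < 100:
            tries += 1
            dr, dc = rng.integers(-5, 6, size=2)
            moved = shift_mask(base, dr, dc)
            if moved is None:
                continue
            hd = exact_hausdorff(moved, base)
            loss = hausdorff_distance_loss(moved.astype(float), base, alpha=2.0)
            entries.append((hd, loss))
            n_pairs += 1
        for i in range(len(entries)):
            for j in range(i + 1, len(entries)):
                (h1, l1), (h2, l2) = entries[i], entries[j]
                if abs(h1 - h2) < 1e-9:
                    continue
                total += 1
                if (h1 - h2) * (l1 - l2) < 0:
                    violations += 1
    assert n_pairs >= 100 and total >= 100
    return violations / total


def test_hausdorff_ordering_tracks_exact_hd(rng):
    """Surrogate ordering agrees with the exact symmetric Hausdorff distance
    (<=5% of comparable within-base pair orderings inverted)."""
    assert hd_ordering_violation_rate(rng) <= 0.05


# ---------------------------------------------------------------------------
# Hybrid
# ---------------------------------------------------------------------------

def test_hybrid_reduces_to_single_terms(rng):
    p = rng.random((6, 6))
    t = (rng.random((6, 6)) > 0.5).astype(float)
    assert hybrid_loss(p, t, LossWeights(1, 0, 0, 0)) == bce_loss(p, t)
    assert hybrid_loss(p, t, LossWeights(0, 1, 0, 0)) == dice_loss(p, t)


def test_hybrid_at_truth_reduces_to_perimeter_penalty():
    """At prob == truth the error terms (BCE, Dice, HD) vanish exactly; only
    the active-contour length term — a perimeter penalty, not an error —
    remains, so the hybrid loss equals w_ac times that term."""
    t = np.zeros((8, 8))
    t[3:6, 2:5] = 1.0
    full = hybrid_loss(t, t, LossWeights(1, 1, 1, 1))
    assert full == pytest.approx(active_contour_loss(t, t), abs=1e-6)
    assert hybrid_loss(t, t, LossWeights(1, 1, 0, 1)) <= 1e-6


def test_hybrid_is_sum_of_terms():
    truth = np.array([[1, 0], [1, 0]], dtype=float)
    prob = np.array([[0.9, 0.1], [0.8, 0.2]])
    expected = (bce_loss(prob, truth) + dice_loss(prob, truth)
                + active_contour_loss(prob, truth)
                + hausdorff_distance_loss(prob, truth))
    assert hybrid_loss(prob, truth, LossWeights(1, 1, 1, 1)) == \
        pytest.approx(expected, rel=1e-12)


def test_hybrid_linear_in_weights(rng):
    p = rng.random((6, 6))
    t = (rng.random((6, 6)) > 0.5).astype(float)
    l1 = hybrid_loss(p, t, LossWeights(1, 2, 3, 4))
    l2 = hybrid_loss(p, t, LossWeights(2, 4, 6, 8))
    assert l2 == pytest.approx(2 * l1, rel=1e-10)


def test_weights_validation():
    with pytest.raises(ValueError):
        LossWeights(0, 0, 0, 0)
    with pytest.raises(ValueError):
        LossWeights(-1, 1, 1, 1)


@pytest.mark.parametrize("term", ["bce", "dice", "ac", "hd"])
def test_each_term_is_individually_trainable(term, rng):
    """Gradient descent on the raw probability map reduces every term."""
    truth = np.zeros((16, 16))
    truth[4:10, 5:12] = 1.0
    logits = Tensor(rng.normal(0, 0.1, (16, 16)), requires_grad=True)
    fns = {
        "bce": lambda p: bce_loss(p, truth),
        "dice": lambda p: dice_loss(p, truth),
        "ac": lambda p: active_contour_loss(p, truth),
        "hd": lambda p: hausdorff_distance_loss(p, truth),
    }
    opt = Adam([logits], lr=0.05)
    history = []
    for _ in range(40):
        loss = fns[term](logits.sigmoid())
        history.append(float(loss.data))
        opt.zero_grad()
        loss.backward()
        opt.step()
    assert history[-1] < history[0]
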