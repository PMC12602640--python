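"""Measure correctness against independent brute-force oracles and invariants."""

import itertools

import numpy as np
import pytest
from scipy.stats import spearmanr

from replicadetect import (
    MeasureSpec,
    SegMask,
    Volume,
    average_surface_distance,
    dice,
    feature_distance,
    mae,
    multiclass_aggregate,
    rmse,
    ssim3d,
    to_distance,
)

from conftest import random_mask, random_volume


# ---------------------------------------------------------------------------
# brute-force oracles, deliberately naive
# ---------------------------------------------------------------------------

def loop_mae(a, b):
    total, count = 0.0, 0
    for i, j, k in itertools.product(*(range(s) for s in a.shape)):
        total += abs(a.data[i, j, k] - b.data[i, j, k])
        count += 1
    return total / count


def loop_rmse(a, b):
    total, count = 0.0, 0
    for i, j, k in itertools.product(*(range(s) for s in a.shape)):
        total += (a.data[i, j, k] - b.data[i, j, k]) ** 2
        count += 1
    return (total / count) ** 0.5


def direct_ssim(a, b, window, k1=0.01, k2=0.03):
    """Mean SSIM over all fully-interior windows, from the defining formula.

    Local statistics use sample (N-1) normalization; data range is the joint
    max-min of the pair.
    """
    x, y = a.data, b.data
    dr = max(x.max(), y.max()) - min(x.min(), y.min())
    c1, c2 = (k1 * dr) ** 2, (k2 * dr) ** 2
    h = window // 2
    vals = []
    for i in range(h, x.shape[0] - h):
        for j in range(h, x.shape[1] - h):
            for k in range(h, x.shape[2] - h):
                wx = x[i - h:i + h + 1, j - h:j + h + 1, k - h:k + h + 1].ravel()
                wy = y[i - h:i + h + 1, j - h:j + h + 1, k - h:k + h + 1].ravel()
                ux, uy = wx.mean(), wy.mean()
                vx = wx.var(ddof=1)
                vy = wy.var(ddof=1)
                cxy = ((wx - ux) * (wy - uy)).sum() / (wx.size - 1)
                vals.append(
                    ((2 * ux * uy + c1) * (2 * cxy + c2))
                    / ((ux**2 + uy**2 + c1) * (vx + vy + c2))
                )
    return float(np.mean(vals))


def surface_voxels(fore):
    """Foreground voxels with a 6-connected background neighbor (border = background)."""
    out = []
    shape = fore.shape
    for i, j, k in zip(*np.nonzero(fore)):
        for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            ni, nj, nk = i + di, j + dj, k + dk
            if not (0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2]):
                out.append((i, j, k))
                break
            if not fore[ni, nj, nk]:
                out.append((i, j, k))
                break
    return out


def allpairs_asd(a, b, label, spacing):
    sa = surface_voxels(a.labels == label)
    sb = surface_voxels(b.labels == label)
    sp = np.asarray(spacing)

    def directed(src, dst):
        dists = []
        for p in src:
            best = min(
                float(np.linalg.norm((np.array(p) - np.array(q)) * sp)) for q in dst
            )
            dists.append(best)
        return float(np.mean(dists))

    return (directed(sa, sb) + directed(sb, sa)) / 2.0


# ---------------------------------------------------------------------------
# oracle agreement (>= 20 seeds per metric)
# ---------------------------------------------------------------------------

SEEDS = range(20)


@pytest.mark.parametrize("seed", SEEDS)
def test_mae_rmse_match_loop_oracle(seed):
    a, b = random_volume(seed), random_volume(seed + 100)
    assert mae(a, b) == pytest.approx(loop_mae(a, b), abs=1e-12)
    assert rmse(a, b) == pytest.approx(loop_rmse(a, b), abs=1e-12)
    assert rmse(a, b) >= mae(a, b)  # Jensen


@pytest.mark.parametrize("seed", SEEDS)
def test_ssim_matches_direct_formula(seed):
    a, b = random_volume(seed), random_volume(seed + 100)
    assert ssim3d(a, b, window=3) == pytest.approx(direct_ssim(a, b, 3), abs=1e-9)


def test_ssim_window7_matches_direct_formula():
    a = random_volume(7, shape=(16, 16, 8))
    b = random_volume(8, shape=(16, 16, 8))
    assert ssim3d(a, b, window=7) == pytest.approx(direct_ssim(a, b, 7), abs=1e-9)


@pytest.mark.parametrize("seed", SEEDS)
def test_dice_matches_counting_oracle(seed):
    a, b = random_mask(seed), random_mask(seed + 100)
    fa, fb = a.labels == 1, b.labels == 1
    inter = sum(
        1 for idx in itertools.product(*(range(s) for s in fa.shape)) if fa[idx] and fb[idx]
    )
    expected = 2 * inter / (fa.sum() + fb.sum())
    assert dice(a, b, 1) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("seed", SEEDS)
def test_asd_matches_allpairs_oracle(seed):
    # small sparse blobs, anisotropic spacing to exercise physical scaling
    spacing = (1.0, 0.7, 2.0)
    a = random_mask(seed, shape=(6, 6, 4), p=0.12, spacing=spacing)
    b = random_mask(seed + 100, shape=(6, 6, 4), p=0.12, spacing=spacing)
    if not (a.labels == 1).any() or not (b.labels == 1).any():
        pytest.skip("degenerate draw: empty mask")
    res = average_surface_distance(a, b, 1)
    assert res.flag is None
    assert res.value == pytest.approx(allpairs_asd(a, b, 1, spacing), abs=1e-9)


@pytest.mark.parametrize("seed", SEEDS)
def test_multiclass_aggregate_recomposes_per_label(seed):
    a = random_mask(seed, n_labels=3, p=0.15)
    b = random_mask(seed + 100, n_labels=3, p=0.15)
    labels = [1, 2, 3]
    expected = np.mean([dice(a, b, l) for l in labels])
    assert multiclass_aggregate(a, b, labels, "dice").value == pytest.approx(expected, abs=1e-12)
    per_label = [float(average_surface_distance(a, b, l)) for l in labels]
    assert multiclass_aggregate(a, b, labels, "asd").value == pytest.approx(
        np.mean(per_label), abs=1e-12
    )


# ---------------------------------------------------------------------------
# analytic examples and degenerate geometry
# ---------------------------------------------------------------------------

def test_image_measure_analytic_values():
    zeros = Volume(np.zeros((4, 4, 4)), id="z")
    ones = Volume(np.ones((4, 4, 4)), id="o")
    twos = Volume(np.full((4, 4, 4), 2.0), id="t")
    assert mae(zeros, ones) == 1.0
    assert rmse(zeros, twos) == 2.0
    assert mae(zeros, zeros) == 0.0


def test_ssim_identity_and_degradation():
    a = random_volume(5)
    assert ssim3d(a, a, window=3) == pytest.approx(1.0)
    inv = Volume(1.0 - a.data, id="inv")
    assert ssim3d(a, inv, window=3) < 1.0


def test_ssim_rejects_oversized_window():
    a = random_volume(0)  # (8, 8, 4): window 7 exceeds the 4-voxel axis
    with pytest.raises(ValueError, match="window"):
        ssim3d(a, a, window=7)


def test_feature_distance_analytic():
    assert feature_distance([1, 2, 3], [1, 2, 3], "feat_cosine") == pytest.approx(1.0)
    assert feature_distance([1, 2, 3], [1, 2, 3], "feat_rmse") == 0.0
    assert feature_distance([1, 0], [0, 1], "feat_cosine") == pytest.approx(0.0)
    assert feature_distance([1, 0], [1, 1], "feat_cosine") == pytest.approx(1 / np.sqrt(2))
    with pytest.raises(ValueError, match="zero"):
        feature_distance([0, 0], [1, 0], "feat_cosine")
    with pytest.raises(ValueError):
        feature_distance([1, 2], [1, 2, 3], "feat_rmse")


def test_dice_conventions():
    shape = (4, 4, 2)
    empty = SegMask(np.zeros(shape, dtype=int), id="e")
    full = SegMask(np.ones(shape, dtype=int), id="f")
    assert dice(empty, empty, 1) == 1.0  # agreement on absence
    assert dice(full, empty, 1) == 0.0
    # |A|=4, |B|=4, |A cap B|=2 -> 0.5
    a = np.zeros(shape, dtype=int)
    b = np.zeros(shape, dtype=int)
    a.ravel()[:4] = 1
    b.ravel()[2:6] = 1
    assert dice(SegMask(a, id="a"), SegMask(b, id="b"), 1) == 0.5


def test_asd_analytic_and_degenerate():
    shape = (8, 4, 4)
    a = np.zeros(shape, dtype=int)
    b = np.zeros(shape, dtype=int)
    a[1, 1, 1] = 1
    b[4, 1, 1] = 1  # 3 voxels apart along axis 0, spacing 1 mm
    assert average_surface_distance(SegMask(a, id="a"), SegMask(b, id="b"), 1).value == pytest.approx(3.0)

    ident = SegMask(a, id="i")
    assert average_surface_distance(ident, ident, 1).value == 0.0

    empty = SegMask(np.zeros(shape, dtype=int), id="e")
    one_sided = average_surface_distance(SegMask(a, id="a"), empty, 1)
    assert one_sided.flag == "undefined-surface"
    assert one_sided.value == pytest.approx(np.linalg.norm(shape))  # physical diagonal
    both = average_surface_distance(empty, empty, 1)
    assert both.flag == "empty-both" and both.value == 0.0


def test_multiclass_aggregate_analytic():
    shape = (4, 4, 2)
    a = np.zeros(shape, dtype=int)
    b = np.zeros(shape, dtype=int)
    # label 1 identical (dice 1), label 2 half-overlapping (dice 0.5)
    a[0, :, :], b[0, :, :] = 1, 1
    a.ravel()[16:20] = 2
    b.ravel()[18:22] = 2
    res = multiclass_aggregate(SegMask(a, id="a"), SegMask(b, id="b"), [1, 2, 3], "dice")
    assert res.value == pytest.approx(0.75)  # label 3 absent from both: skipped
    with pytest.raises(ValueError, match="non-empty"):
        multiclass_aggregate(SegMask(a, id="a"), SegMask(b, id="b"), [], "dice")


# ---------------------------------------------------------------------------
# conversion to the common distance scale
# ---------------------------------------------------------------------------

def test_to_distance_worked_values():
    assert to_distance(0.7, "dice") == pytest.approx(0.3)
    assert to_distance(1.0, "ssim") == 0.0
    assert to_distance(-1.0, "feat_cosine") == 1.0
    assert to_distance(2.5, "rmse") == 2.5  # distances pass through


def test_to_distance_monotone_and_clamped():
    sims = np.linspace(-1, 1, 21)
    dists = [to_distance(s, "ssim") for s in sims]
    assert all(d1 >= d2 for d1, d2 in zip(dists, dists[1:]))
    assert to_distance(1.0 + 5e-10, "dice") == 0.0  # within tolerance: clamped
    with pytest.raises(ValueError, match="range"):
        to_distance(1.1, "dice")
    with pytest.raises(ValueError, match="negative"):
        to_distance(-0.5, "rmse")


def test_measure_spec_levels():
    assert MeasureSpec("rmse").level == "image"
    assert MeasureSpec("feat_cosine").level == "feature"
    assert MeasureSpec("asd").level == "segmentation"
    with pytest.raises(ValueError):
        MeasureSpec("lpips")


# ---------------------------------------------------------------------------
# symmetry / monotone degradation properties
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", range(5))
def test_symmetry_under_argument_swap(seed):
    a, b = random_volume(seed), random_volume(seed + 50)
    assert mae(a, b) == mae(b, a)
    assert rmse(a, b) == rmse(b, a)
    assert ssim3d(a, b, window=3) == pytest.approx(ssim3d(b, a, window=3), abs=1e-12)
    ma, mb = random_mask(seed), random_mask(seed + 50)
    assert dice(ma, mb, 1) == dice(mb, ma, 1)
    assert average_surface_distance(ma, mb, 1).value == pytest.approx(
        average_surface_distance(mb, ma, 1).value, abs=1e-12
    )


def test_monotone_degradation_with_noise():
    """MAE/RMSE grow and SSIM falls as Gaussian noise sigma increases."""
    sigmas = [0.0, 0.05, 0.1, 0.2, 0.4]
    mean_mae, mean_rmse, mean_ssim = [], [], []
    for sigma in sigmas:
        ms, rs, ss = [], [], []
        for seed in range(10):
            a = random_volume(seed)
            rng = np.random.default_rng(1000 + seed)
            b = Volume(a.data + rng.normal(0, sigma, a.shape) if sigma else a.data.copy(), id="b")
            ms.append(mae(a, b))
            rs.append(rmse(a, b))
            ss.append(ssim3d(a, b, window=3))
        mean_mae.append(np.mean(ms))
        mean_rmse.append(np.mean(rs))
        mean_ssim.append(np.mean(ss))
    assert spearmanr(sigmas, mean_mae).statistic == pytest.approx(1.0)
    assert spearmanr(sigmas, mean_rmse).statistic == pytest.approx(1.0)
    assert spearmanr(sigmas, mean_ssim).statistic == pytest.approx(-1.0)
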