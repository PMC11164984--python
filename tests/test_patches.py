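"""Correlation primitives and patch machinery against direct oracles."""

import numpy as np
import pytest

from bayescoloc.background import ValidityMask, image_thresholds, joint_mask
from bayescoloc.patches import (
    UndefinedCorrelationError,
    adaptive_patch_search,
    correlate,
    local_correlation_map,
    patch_correlations,
    patch_grid,
)

from conftest import make_image


# --- independent oracles ---------------------------------------------------

def average_ranks(x: np.ndarray) -> np.ndarray:
    """Ranks with ties receiving their mean rank (1-based)."""
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    sx = x[order]
    while i < len(x):
        j = i
        while j < len(x) and sx[j] == sx[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # mean of positions i+1..j
        i = j
    return ranks


def pearson_oracle(x, y):
    x = x - x.mean()
    y = y - y.mean()
    return float((x @ y) / np.sqrt((x @ x) * (y @ y)))


def spearman_oracle(x, y):
    return pearson_oracle(average_ranks(np.asarray(x)), average_ranks(np.asarray(y)))


def kendall_tau_b_oracle(x, y):
    """Exhaustive pair enumeration with tie correction."""
    n = len(x)
    concordant = discordant = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) / 2
    denom = np.sqrt((n0 - _tie_term(x)) * (n0 - _tie_term(y)))
    return (concordant - discordant) / denom


def _tie_term(v):
    _, counts = np.unique(v, return_counts=True)
    return float((counts * (counts - 1) / 2).sum())


# --- correlate -------------------------------------------------------------

@pytest.mark.parametrize("method", ["pearson", "spearman", "kendall"])
def test_identity_correlation_is_one(method, rng):
    x = rng.uniform(0, 1, 30)
    assert correlate(x, x, method) == pytest.approx(1.0)


@pytest.mark.parametrize("method", ["pearson", "spearman"])
def test_perfect_anticorrelation(method, rng):
    x = rng.uniform(0, 1, 30)
    assert correlate(x, -x + 1.0, method) == pytest.approx(-1.0)


def test_rank_methods_match_bruteforce_oracles_with_ties(rng):
    for _ in range(50):
        n = rng.integers(5, 15)
        # coarse quantization forces many tied ranks
        x = np.round(rng.uniform(0, 1, n), 1)
        y = np.round(rng.uniform(0, 1, n), 1)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        assert correlate(x, y, "spearman") == pytest.approx(spearman_oracle(x, y))
        assert correlate(x, y, "kendall") == pytest.approx(kendall_tau_b_oracle(x, y))
        assert correlate(x, y, "pearson") == pytest.approx(pearson_oracle(x, y))


def test_tied_length6_vectors_match_oracle():
    x = np.array([0.1, 0.1, 0.3, 0.3, 0.7, 0.9])
    y = np.array([0.2, 0.4, 0.4, 0.4, 0.8, 0.8])
    assert correlate(x, y, "spearman") == pytest.approx(spearman_oracle(x, y))
    assert correlate(x, y, "kendall") == pytest.approx(kendall_tau_b_oracle(x, y))


def test_spearman_is_pearson_on_average_ranks(rng):
    x = np.round(rng.uniform(0, 1, 40), 1)
    y = np.round(rng.uniform(0, 1, 40), 1)
    assert correlate(x, y, "spearman") == pytest.approx(
        correlate(average_ranks(x), average_ranks(y), "pearson")
    )


def test_constant_input_is_undefined():
    with pytest.raises(UndefinedCorrelationError):
        correlate(np.ones(10), np.arange(10.0) / 10)


# --- patch grid ------------------------------------------------------------

def test_patch_grid_shapes():
    patches = list(patch_grid((64, 64), 16))
    assert len(patches) == 256
    _, _, rows, cols = patches[0]
    assert rows.stop - rows.start == 4 and cols.stop - cols.start == 4

    assert len(list(patch_grid((10, 10), 1))) == 1
    patches = list(patch_grid((10, 10), 3))  # 3x3 patches, remainder dropped
    assert len(patches) == 9
    last = patches[-1]
    assert last[2].stop == 9 and last[3].stop == 9

    with pytest.raises(ValueError):
        list(patch_grid((10, 10), 11))


# --- patch correlations ----------------------------------------------------

def test_patch_correlations_equal_masked_pixel_oracle(two_channel_image):
    image = two_channel_image
    thresholds = image_thresholds(image, (1, 2))
    mask = joint_mask(image, 1, 2, thresholds)
    for method in ("pearson", "spearman"):
        pc = patch_correlations(image, 1, 2, mask, 8, method)
        a, b = image.channel(1).data, image.channel(2).data
        for i, j, rows, cols in patch_grid(image.shape, 8):
            m = mask.data[rows, cols]
            if m.sum() >= 15:
                expected = correlate(a[rows, cols][m], b[rows, cols][m], method)
                assert pc.values[i, j] == pytest.approx(expected)
                assert pc.valid[i, j]
            else:
                assert np.isnan(pc.values[i, j]) and not pc.valid[i, j]


def test_fifteen_pixel_rule_boundary():
    """A patch with 14 valid pixels is missing; with 15 it is computed."""
    a = np.full((8, 8), 0.5)
    b = np.full((8, 8), 0.5)
    coords = [(r, c) for r in range(4) for c in range(4)]
    rng = np.random.default_rng(1)
    for k, (r, c) in enumerate(coords[:15]):
        a[r, c] = 0.6 + 0.3 * rng.random()
        b[r, c] = 0.6 + 0.3 * rng.random()
    image = make_image([a, b])
    mask14 = np.zeros((8, 8), dtype=bool)
    for r, c in coords[:14]:
        mask14[r, c] = True
    mask15 = mask14.copy()
    mask15[coords[14]] = True
    pc14 = patch_correlations(image, 1, 2, ValidityMask(mask14), 1)
    pc15 = patch_correlations(image, 1, 2, ValidityMask(mask15), 1)
    assert not pc14.valid[0, 0]
    assert pc15.valid[0, 0]


def test_identical_masked_values_give_unit_correlation(rng):
    vals = rng.uniform(0.3, 0.9, (8, 8))
    image = make_image([vals, vals])
    mask = ValidityMask(np.ones((8, 8), dtype=bool))
    pc = patch_correlations(image, 1, 2, mask, 1)
    assert pc.values[0, 0] == pytest.approx(1.0)


def test_validity_monotone_in_min_valid_and_mask(two_channel_image):
    image = two_channel_image
    thresholds = image_thresholds(image, (1, 2))
    mask = joint_mask(image, 1, 2, thresholds)
    counts = [
        patch_correlations(image, 1, 2, mask, 8, min_valid=mv).n_valid_patches
        for mv in (5, 15, 25, 40)
    ]
    assert counts == sorted(counts, reverse=True)

    # shrinking the mask never turns an invalid patch valid
    shrunk = mask.data.copy()
    shrunk[::2, :] = False
    pc_full = patch_correlations(image, 1, 2, mask, 8)
    pc_shrunk = patch_correlations(image, 1, 2, ValidityMask(shrunk), 8)
    assert not np.any(pc_shrunk.valid & ~pc_full.valid)


# --- adaptive patch search -------------------------------------------------

def test_adaptive_search_keeps_dense_configuration(two_channel_image):
    image = two_channel_image
    thresholds = image_thresholds(image, (1, 2))
    mask = joint_mask(image, 1, 2, thresholds)
    pc = adaptive_patch_search(image, 1, 2, mask, 8)
    assert pc is not None and pc.n_patches_side == 8


def test_adaptive_search_halves_until_usable(rng):
    """One small cell: 32 patches/side yields no valid patch, coarser works."""
    a = np.full((64, 64), 0.02)
    b = np.full((64, 64), 0.02)
    sl = slice(24, 40)
    a[sl, sl] = 0.5 + 0.3 * rng.random((16, 16))
    b[sl, sl] = 0.5 + 0.3 * rng.random((16, 16))
    image = make_image([a, b])
    mask = np.zeros((64, 64), dtype=bool)
    mask[sl, sl] = True
    pc = adaptive_patch_search(image, 1, 2, ValidityMask(mask), 32)
    assert pc is not None
    assert pc.n_patches_side < 32
    # verify the returned n is the first usable halving, by direct count
    n = 32
    while n > pc.n_patches_side:
        direct = patch_correlations(image, 1, 2, ValidityMask(mask), n)
        assert direct.n_valid_patches < 2
        n //= 2


def test_adaptive_search_excludes_background_image():
    image = make_image([np.full((32, 32), 0.1), np.full((32, 32), 0.1)])
    mask = ValidityMask(np.zeros((32, 32), dtype=bool))
    assert adaptive_patch_search(image, 1, 2, mask, 16) is None


# --- local correlation map -------------------------------------------------

def test_local_map_equals_window_oracle(two_channel_image):
    image = two_channel_image
    thresholds = image_thresholds(image, (1, 2))
    mask = joint_mask(image, 1, 2, thresholds)
    w = 7
    lm = local_correlation_map(image, 1, 2, mask, w)
    a, b = image.channel(1).data, image.channel(2).data
    off = w // 2
    rng = np.random.default_rng(0)
    h, width = image.shape
    for _ in range(60):
        i = rng.integers(0, h - w + 1)
        j = rng.integers(0, width - w + 1)
        win = mask.data[i : i + w, j : j + w]
        out = lm.values[i + off, j + off]
        if win.sum() >= 15:
            try:
                expected = correlate(a[i:i+w, j:j+w][win], b[i:i+w, j:j+w][win])
                assert out == pytest.approx(expected)
            except UndefinedCorrelationError:
                assert np.isnan(out)
        else:
            assert np.isnan(out)


def test_local_map_identical_channels_is_one(rng):
    vals = np.clip(0.5 + 0.2 * rng.standard_normal((32, 32)), 0, 1)
    image = make_image([vals, vals])
    mask = ValidityMask(np.ones((32, 32), dtype=bool))
    lm = local_correlation_map(image, 1, 2, mask, 5)
    defined = ~np.isnan(lm.values)
    assert defined.any()
    assert np.allclose(lm.values[defined], 1.0)


def test_local_map_background_window_is_missing(rng):
    vals = np.clip(0.5 + 0.2 * rng.standard_normal((32, 32)), 0, 1)
    image = make_image([vals, vals])
    mask = np.ones((32, 32), dtype=bool)
    mask[:16, :16] = False  # a fully background quadrant
    lm = local_correlation_map(image, 1, 2, ValidityMask(mask), 5)
    assert np.isnan(lm.values[8, 8])


def test_local_map_rank_method_matches_loop_oracle(rng):
    vals = np.clip(0.5 + 0.2 * rng.standard_normal((20, 20)), 0, 1)
    other = np.clip(vals + 0.1 * rng.standard_normal((20, 20)), 0, 1)
    image = make_image([vals, other])
    mask = ValidityMask(np.ones((20, 20), dtype=bool))
    lm = local_correlation_map(image, 1, 2, mask, 5, method="spearman")
    i, j = 10, 10
    win_a = vals[8:13, 8:13].ravel()
    win_b = other[8:13, 8:13].ravel()
    assert lm.values[i, j] == pytest.approx(correlate(win_a, win_b, "spearman"))


def test_local_map_window_too_large():
    image = make_image([np.zeros((8, 8)) + 0.5, np.zeros((8, 8)) + 0.5])
    with pytest.raises(ValueError):
        local_correlation_map(image, 1, 2, ValidityMask(np.ones((8, 8), bool)), 9)
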