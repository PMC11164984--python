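"""Patch-wise and sliding-window correlation between two channels.

The image is tiled into an n x n grid of equal-area patches; each patch
contributes one correlation value computed over the pixels that are
above Otsu's threshold in both channels, and only if at least
``min_valid`` (default 15) such pixels exist — otherwise the cell is
missing.  If too few patches qualify at the requested grid size, the
patch number is halved until a usable configuration is found.  A
sliding-window variant produces the local correlation map at a finer
spatial scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy import stats

from .background import ValidityMask
from .images import MultiChannelImage

logger = logging.getLogger("bayescoloc")

#: Supported correlation metrics.
CORRELATION_METHODS = ("pearson", "spearman", "kendall")

CorrelationMethod = str

#: Minimum above-threshold pixels for a patch/window to contribute.
DEFAULT_MIN_VALID = 15

#: Minimum valid patches for a grid size to count as usable.
DEFAULT_MIN_VALID_PATCHES = 2


class UndefinedCorrelationError(ValueError):
    """Correlation undefined (constant input on either side)."""


@dataclass(frozen=True)
class PatchCorrelations:
    """Correlations on an n x n patch grid; missing cells are NaN + invalid."""

    image_name: str
    n_patches_side: int
    values: np.ndarray
    valid: np.ndarray
    method: CorrelationMethod

    @property
    def n_valid_patches(self) -> int:
        return int(self.valid.sum())

    def correlations(self) -> np.ndarray:
        """The valid patch correlations as a flat array."""
        return self.values[self.valid]


@dataclass(frozen=True)
class LocalCorrMap:
    """Sliding-window correlation map; NaN where a window is undefined."""

    image_name: str
    window_side: int
    values: np.ndarray
    method: CorrelationMethod


def _check_method(method: CorrelationMethod) -> str:
    method = method.lower()
    if method not in CORRELATION_METHODS:
        raise ValueError(
            f"unknown correlation method {method!r}; choose from {CORRELATION_METHODS}"
        )
    return method


def correlate(xs, ys, method: CorrelationMethod = "pearson") -> float:
    """Correlation of two intensity sequences.

    Pearson is the product-moment coefficient; Spearman is Pearson on
    average-ranked data (ties receive their mean rank); Kendall is the
    tie-corrected tau-b.  Raises :class:`UndefinedCorrelationError` when
    either side is constant.
    """
    method = _check_method(method)
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.ndim != 1:
        raise ValueError("xs and ys must be 1-D sequences of equal length")
    if xs.size < 2:
        raise UndefinedCorrelationError("need at least 2 points")
    if np.ptp(xs) == 0.0 or np.ptp(ys) == 0.0:
        raise UndefinedCorrelationError("constant input on one side")
    if method == "pearson":
        r = stats.pearsonr(xs, ys).statistic
    elif method == "spearman":
        r = stats.spearmanr(xs, ys).statistic
    else:
        r = stats.kendalltau(xs, ys, variant="b").statistic
    if not np.isfinite(r):
        raise UndefinedCorrelationError("correlation is undefined for this input")
    return float(np.clip(r, -1.0, 1.0))


def patch_grid(
    image_shape: tuple[int, int], n_patches_side: int
) -> Iterator[tuple[int, int, slice, slice]]:
    """Yield ``(row, col, row_slice, col_slice)`` for an n x n patch grid.

    Patches are equal-area, ``floor(h/n) x floor(w/n)``; remainder rows
    and columns at the bottom/right edges are excluded.
    """
    h, w = image_shape
    n = n_patches_side
    if n < 1:
        raise ValueError("n_patches_side must be >= 1")
    if n > min(h, w):
        raise ValueError(f"n_patches_side={n} exceeds image side min({h}, {w})")
    ph, pw = h // n, w // n
    if h % n or w % n:
        logger.debug(
            "patch grid %dx%d on %dx%d px: dropping %d remainder rows, %d columns",
            n, n, h, w, h % n, w % n,
        )
    for i in range(n):
        for j in range(n):
            yield i, j, slice(i * ph, (i + 1) * ph), slice(j * pw, (j + 1) * pw)


def patch_correlations(
    image: MultiChannelImage,
    ch_a: int,
    ch_b: int,
    mask: ValidityMask,
    n_patches_side: int,
    method: CorrelationMethod = "pearson",
    min_valid: int = DEFAULT_MIN_VALID,
) -> PatchCorrelations:
    """Per-patch correlation over masked (above-threshold-in-both) pixels."""
    method = _check_method(method)
    if mask.shape != image.shape:
        raise ValueError("mask shape does not match image shape")
    a = image.channel(ch_a).data
    b = image.channel(ch_b).data
    n = n_patches_side
    values = np.full((n, n), np.nan)
    valid = np.zeros((n, n), dtype=bool)
    for i, j, rows, cols in patch_grid(image.shape, n):
        m = mask.data[rows, cols]
        if int(m.sum()) < min_valid:
            continue
        try:
            values[i, j] = correlate(a[rows, cols][m], b[rows, cols][m], method)
        except UndefinedCorrelationError:
            continue
        valid[i, j] = True
    return PatchCorrelations(image.name, n, values, valid, method)


def adaptive_patch_search(
    image: MultiChannelImage,
    ch_a: int,
    ch_b: int,
    mask: ValidityMask,
    requested_n: int,
    method: CorrelationMethod = "pearson",
    min_valid: int = DEFAULT_MIN_VALID,
    min_valid_patches: int = DEFAULT_MIN_VALID_PATCHES,
) -> PatchCorrelations | None:
    """Patch correlations at ``requested_n``, halving the grid if too sparse.

    Tries requested_n, requested_n//2, ... down to 2 until at least
    ``min_valid_patches`` patches are valid.  Returns ``None`` (image
    excluded, warning logged) when no configuration qualifies; never
    raises for sparse images.
    """
    if requested_n < 2:
        raise ValueError("requested_n must be >= 2")
    n = requested_n
    while n >= 2:
        result = patch_correlations(image, ch_a, ch_b, mask, n, method, min_valid)
        if result.n_valid_patches >= min_valid_patches:
            if n != requested_n:
                logger.warning(
                    "WARN-ADAPTIVE-PATCHES image %s: %d patches per side too sparse, "
                    "using %d", image.name, requested_n, n,
                )
            return result
        n //= 2
    logger.warning(
        "WARN-IMAGE-EXCLUDED image %s: no patch configuration down to 2x2 "
        "yields %d valid patches", image.name, min_valid_patches,
    )
    return None


def _window_sums(arr: np.ndarray, w: int) -> np.ndarray:
    """Sum of every w x w window (valid positions only) via 2-D cumsums."""
    c = np.zeros((arr.shape[0] + 1, arr.shape[1] + 1))
    np.cumsum(np.cumsum(arr, axis=0), axis=1, out=c[1:, 1:])
    return c[w:, w:] - c[:-w, w:] - c[w:, :-w] + c[:-w, :-w]


def local_correlation_map(
    image: MultiChannelImage,
    ch_a: int,
    ch_b: int,
    mask: ValidityMask,
    window_side: int = 7,
    method: CorrelationMethod = "pearson",
    min_valid: int = DEFAULT_MIN_VALID,
) -> LocalCorrMap:
    """Stride-1 sliding-window correlation map over masked pixels.

    The value at a pixel is the correlation of the valid pixels in the
    ``window_side x window_side`` window centred there (NaN when fewer
    than ``min_valid`` valid pixels or the window leaves the image).
    The default 7 px window (49 px^2) sits inside the 10-100 px^2 band
    recommended for local colocalization maps.
    """
    method = _check_method(method)
    w = int(window_side)
    if w < 2:
        raise ValueError("window_side must be >= 2")
    h, width = image.shape
    if w > min(h, width):
        raise ValueError(f"window_side={w} exceeds image dimensions {image.shape}")
    if mask.shape != image.shape:
        raise ValueError("mask shape does not match image shape")
    a = image.channel(ch_a).data
    b = image.channel(ch_b).data
    m = mask.data.astype(float)

    out = np.full((h, width), np.nan)
    off = w // 2
    rows = slice(off, off + h - w + 1)
    cols = slice(off, off + width - w + 1)

    n = _window_sums(m, w)
    if method == "pearson":
        sx = _window_sums(a * m, w)
        sy = _window_sums(b * m, w)
        sxx = _window_sums(a * a * m, w)
        syy = _window_sums(b * b * m, w)
        sxy = _window_sums(a * b * m, w)
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = n * sxy - sx * sy
            var_x = n * sxx - sx * sx
            var_y = n * syy - sy * sy
            r = cov / np.sqrt(var_x * var_y)
        ok = (n >= min_valid) & (var_x > 0) & (var_y > 0) & np.isfinite(r)
        block = np.where(ok, np.clip(r, -1.0, 1.0), np.nan)
        out[rows, cols] = block
    else:
        # rank methods have no sliding-sum decomposition; direct loop
        candidates = np.argwhere(n >= min_valid)
        block = np.full(n.shape, np.nan)
        for i, j in candidates:
            win = mask.data[i : i + w, j : j + w]
            try:
                block[i, j] = correlate(
                    a[i : i + w, j : j + w][win], b[i : i + w, j : j + w][win], method
                )
            except UndefinedCorrelationError:
                continue
        out[rows, cols] = block
    return LocalCorrMap(image.name, w, out, method)
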