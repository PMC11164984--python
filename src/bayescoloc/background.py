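"""Automatic background detection by Otsu's method.

Each channel gets its own threshold: the histogram bin edge maximizing
the between-class variance (equivalently minimizing intra-class
variance).  A pixel enters the colocalization analysis only if it is
strictly above threshold in *both* analyzed channels; the conjunction is
the joint validity mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .images import ChannelRaster, MultiChannelImage


class DegenerateImageError(ValueError):
    """Raised for constant rasters where no threshold separates two classes."""


@dataclass(frozen=True)
class ChannelThreshold:
    channel_id: int
    threshold: float
    histogram_bins: int


@dataclass(frozen=True)
class ValidityMask:
    """Boolean grid marking pixels above Otsu's threshold in both channels."""

    data: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=bool)
        if data.ndim != 2:
            raise ValueError("mask must be 2-D")
        object.__setattr__(self, "data", data)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def n_valid(self) -> int:
        return int(self.data.sum())


def otsu_threshold(raster: ChannelRaster, n_bins: int = 256) -> ChannelThreshold:
    """Otsu threshold of one channel over an ``n_bins`` intensity histogram.

    Candidate thresholds are the interior bin edges; the returned edge
    maximizes the between-class variance  w0*w1*(mu0-mu1)^2.  Ties take
    the lowest maximizing edge (conservative: keeps more pixels as
    signal).  Deterministic for fixed input.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    values = raster.data.ravel()
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        raise DegenerateImageError(
            f"channel {raster.channel_id}: constant intensity {lo:.6g}; "
            "no background/foreground separation exists"
        )
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    total = counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])

    # cumulative class weights/means for every split after bin k
    w0 = np.cumsum(counts)[:-1]
    w1 = total - w0
    mass = counts * centers
    mu0_sum = np.cumsum(mass)[:-1]
    mu_total = mass.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu0_sum / w0
        mu1 = (mu_total - mu0_sum) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between = np.where((w0 == 0) | (w1 == 0), -np.inf, between)
    # ties (e.g. the exact plateau across an empty-bin gap between modes)
    # take the lowest maximizing edge; the relative tolerance absorbs
    # floating-point jitter across the plateau
    peak = between.max()
    best = int(np.argmax(between >= peak - 1e-9 * abs(peak)))
    return ChannelThreshold(
        channel_id=raster.channel_id,
        threshold=float(edges[best + 1]),
        histogram_bins=n_bins,
    )


def joint_mask(
    image: MultiChannelImage,
    ch_a: int,
    ch_b: int,
    thresholds: dict[int, ChannelThreshold],
) -> ValidityMask:
    """Pixels strictly above Otsu's threshold in both analyzed channels."""
    a = image.channel(ch_a)
    b = image.channel(ch_b)
    try:
        ta = thresholds[ch_a].threshold
        tb = thresholds[ch_b].threshold
    except KeyError as exc:
        raise KeyError(f"no threshold for channel {exc.args[0]}") from None
    return ValidityMask((a.data > ta) & (b.data > tb))


def image_thresholds(
    image: MultiChannelImage, channels: tuple[int, int], n_bins: int = 256
) -> dict[int, ChannelThreshold]:
    """Otsu thresholds for the two analyzed channels of one image."""
    return {cid: otsu_threshold(image.channel(cid), n_bins) for cid in channels}
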