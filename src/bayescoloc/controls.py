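"""Null-control construction by pixel-wise or block-wise shuffling.

When no experimental control images exist, a null condition is built
from the sample images themselves: shuffling destroys the cross-channel
spatial association while preserving each channel's intensity
distribution exactly.  Block-wise shuffling (default 3x3 blocks) keeps
short-range autocorrelation intact inside each block, giving a null that
does not understate the variability of correlation estimates on
spatially autocorrelated images.

Each analyzed channel is permuted with an *independent* permutation — a
shared permutation would preserve the cross-channel association the
control must destroy.
"""

from __future__ import annotations

import logging

import numpy as np

from .images import ChannelRaster, MultiChannelImage

logger = logging.getLogger("bayescoloc")


def _resolve_channels(image: MultiChannelImage, channels) -> tuple[int, ...]:
    if channels is None:
        return tuple(c.channel_id for c in image.channels)
    return tuple(channels)


def shuffle_pixels(
    image: MultiChannelImage,
    seed: int,
    channels: tuple[int, ...] | None = None,
) -> MultiChannelImage:
    """Independently permute the pixels of each analyzed channel.

    The per-channel pixel multiset is preserved exactly; channels not in
    *channels* pass through untouched.  Deterministic given *seed*.
    """
    rng = np.random.default_rng(seed)
    targets = _resolve_channels(image, channels)
    new_channels = []
    for ch in image.channels:
        if ch.channel_id in targets:
            flat = ch.data.ravel()
            shuffled = flat[rng.permutation(flat.size)].reshape(ch.data.shape)
            new_channels.append(ChannelRaster(ch.channel_id, shuffled))
        else:
            new_channels.append(ch)
    return MultiChannelImage(f"{image.name}_pixelshuffle", tuple(new_channels))


def shuffle_blocks(
    image: MultiChannelImage,
    seed: int,
    block_side: int = 3,
    channels: tuple[int, ...] | None = None,
) -> MultiChannelImage:
    """Permute block positions of ``block_side x block_side`` tiles.

    Block interiors are untouched, so within-block autocorrelation is
    preserved exactly.  Remainder margins (dimensions not divisible by
    ``block_side``) are left in place and logged, preserving the image
    shape for the downstream mask/patch machinery.
    """
    if block_side < 1:
        raise ValueError("block_side must be >= 1")
    h, w = image.shape
    if h < block_side or w < block_side:
        raise ValueError(
            f"image {image.shape} smaller than one {block_side}x{block_side} block"
        )
    nb_r, nb_c = h // block_side, w // block_side
    if h % block_side or w % block_side:
        logger.debug(
            "block shuffle of %s: %d px bottom / %d px right margin left unshuffled",
            image.name, h % block_side, w % block_side,
        )
    rng = np.random.default_rng(seed)
    targets = _resolve_channels(image, channels)
    core_h, core_w = nb_r * block_side, nb_c * block_side

    new_channels = []
    for ch in image.channels:
        if ch.channel_id not in targets:
            new_channels.append(ch)
            continue
        data = ch.data.copy()
        core = data[:core_h, :core_w]
        # (nb_r, nb_c, bs, bs) view of the block structure
        blocks = core.reshape(nb_r, block_side, nb_c, block_side).swapaxes(1, 2)
        flat = blocks.reshape(nb_r * nb_c, block_side, block_side)
        permuted = flat[rng.permutation(nb_r * nb_c)]
        data[:core_h, :core_w] = (
            permuted.reshape(nb_r, nb_c, block_side, block_side)
            .swapaxes(1, 2)
            .reshape(core_h, core_w)
        )
        new_channels.append(ChannelRaster(ch.channel_id, data))
    return MultiChannelImage(f"{image.name}_blockshuffle", tuple(new_channels))


def make_shuffled_controls(
    images,
    mode: str,
    seed: int,
    block_side: int = 3,
    channels: tuple[int, ...] | None = None,
) -> list[MultiChannelImage]:
    """One shuffled control per sample image (paired design: N vs N)."""
    if mode not in ("pixel", "block"):
        raise ValueError(f"control mode must be 'pixel' or 'block', got {mode!r}")
    seeds = np.random.SeedSequence(seed).spawn(len(images))
    out = []
    for img, ss in zip(images, seeds):
        sub_seed = int(ss.generate_state(1)[0] % (2**31))
        if mode == "pixel":
            out.append(shuffle_pixels(img, sub_seed, channels))
        else:
            out.append(shuffle_blocks(img, sub_seed, block_side, channels))
    return out
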