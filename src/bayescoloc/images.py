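"""Loading, validation and grouping of multi-channel microscopy images.

One image file per channel, named ``[image name]_c[channel ID].[ext]``
(split at the *last* underscore; the sample name may itself contain
underscores).  All files of one biological condition live in one folder.
Supported containers: TIFF/TIF, PNG, JPG/JPEG.  Intensities are rescaled
to [0, 1] by the container's bit-depth maximum so thresholds remain
comparable across images captured with identical settings.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

logger = logging.getLogger("bayescoloc")

SUPPORTED_EXTENSIONS = (".tiff", ".tif", ".jpg", ".jpeg", ".png")

#: BT.601 luma weights used to collapse an RGB plane to one grayscale plane.
_LUMA = np.array([0.299, 0.587, 0.114])

_CHANNEL_SUFFIX = re.compile(r"^c([0-9]+)$")


class NamingConventionError(ValueError):
    """Filename does not follow the ``[name]_c[channel].[ext]`` convention."""


class ImageFormatError(ValueError):
    """Unsupported file extension or undecodable image content."""


class ImageGroupError(ValueError):
    """Inconsistent channel sets or dimensions within a condition folder."""


@dataclass(frozen=True)
class ChannelRaster:
    """A single-channel 2-D intensity raster normalized to [0, 1]."""

    channel_id: int
    data: np.ndarray

    def __post_init__(self) -> None:
        if self.channel_id < 1:
            raise ValueError(f"channel_id must be >= 1, got {self.channel_id}")
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2 or data.size == 0:
            raise ValueError("channel data must be a non-empty 2-D array")
        if np.nanmin(data) < 0.0 or np.nanmax(data) > 1.0:
            raise ValueError("channel intensities must lie in [0, 1]")
        object.__setattr__(self, "data", data)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass(frozen=True)
class MultiChannelImage:
    """Named set of equally sized channel rasters for one sample."""

    name: str
    channels: tuple[ChannelRaster, ...]

    def __post_init__(self) -> None:
        channels = tuple(self.channels)
        if not channels:
            raise ValueError("an image needs at least one channel")
        shapes = {c.shape for c in channels}
        if len(shapes) > 1:
            raise ImageGroupError(
                f"image {self.name!r}: channel dimensions differ: {sorted(shapes)}"
            )
        ids = [c.channel_id for c in channels]
        if ids != list(range(1, len(channels) + 1)):
            raise ImageGroupError(
                f"image {self.name!r}: channel ids must be contiguous from 1, got {ids}"
            )
        object.__setattr__(self, "channels", channels)

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels[0].shape

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def channel(self, channel_id: int) -> ChannelRaster:
        if not 1 <= channel_id <= self.n_channels:
            raise KeyError(
                f"image {self.name!r} has channels 1..{self.n_channels}, "
                f"requested {channel_id}"
            )
        return self.channels[channel_id - 1]


@dataclass
class ImageGroup:
    """All images of one biological condition."""

    label: str
    images: list[MultiChannelImage] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.images:
            raise ImageGroupError(f"condition {self.label!r} contains no images")
        counts = {img.n_channels for img in self.images}
        if len(counts) > 1:
            raise ImageGroupError(
                f"condition {self.label!r}: images disagree on channel count: "
                f"{sorted(counts)}"
            )

    @property
    def n_channels(self) -> int:
        return self.images[0].n_channels

    def __len__(self) -> int:
        return len(self.images)

    def __iter__(self):
        return iter(self.images)


def parse_image_name(filename: str | Path) -> tuple[str, int]:
    """Split a filename into ``(sample_name, channel_id)``.

    The convention is ``[image name]_c[channel ID].[ext]``: everything
    before the *last* underscore is the sample name (and may itself
    contain underscores), the suffix after it must be ``c`` followed by
    an integer >= 1.

    >>> parse_image_name("20231212_HEK293_HAP40_c1.tiff")
    ('20231212_HEK293_HAP40', 1)
    """
    path = Path(filename)
    ext = path.suffix.lower()
    if ext not in SUPPORTED_EXTENSIONS:
        raise ImageFormatError(
            f"{filename}: unsupported extension {ext!r} "
            f"(supported: {', '.join(SUPPORTED_EXTENSIONS)})"
        )
    stem = path.stem
    base, sep, suffix = stem.rpartition("_")
    match = _CHANNEL_SUFFIX.match(suffix) if sep else None
    if not base or match is None:
        raise NamingConventionError(
            f"{filename}: expected '[image name]_c[channel ID]{ext}' "
            "with the channel suffix after the last underscore"
        )
    channel_id = int(match.group(1))
    if channel_id < 1:
        raise NamingConventionError(f"{filename}: channel ID must be >= 1")
    return base, channel_id


def _read_raster(path: Path) -> np.ndarray:
    """Read one file and rescale to [0, 1] by the dtype maximum."""
    if path.suffix.lower() in (".tiff", ".tif"):
        raw = tifffile.imread(path)
    else:
        raw = iio.imread(path)
    raw = np.asarray(raw)
    if raw.ndim == 3:
        if raw.shape[-1] in (3, 4):
            warnings.warn(
                f"{path.name}: RGB(A) content in a single-channel file; "
                "collapsing to one grayscale plane by luminance",
                stacklevel=2,
            )
            raw = raw[..., :3] @ _LUMA
        else:
            raise ImageFormatError(
                f"{path.name}: expected a single 2-D plane, got shape {raw.shape}"
            )
    elif raw.ndim != 2:
        raise ImageFormatError(
            f"{path.name}: expected a single 2-D plane, got shape {raw.shape}"
        )
    dtype = np.asarray(raw).dtype
    if np.issubdtype(dtype, np.integer):
        scale = float(np.iinfo(dtype).max)
        data = raw.astype(float) / scale
    else:
        # float containers are taken as already normalized; clip guards
        # against tiny excursions from lossy encoders
        data = np.clip(raw.astype(float), 0.0, 1.0)
    return data


def load_image_group(folder: str | Path, label: str | None = None) -> ImageGroup:
    """Load every parsable image file in *folder* into an :class:`ImageGroup`.

    Files are grouped by sample name, each group's channels sorted by
    channel id.  Raises :class:`ImageGroupError` for an empty folder,
    a missing channel (non-contiguous ids), or mismatched dimensions
    within one sample.
    """
    folder = Path(folder)
    if not folder.is_dir():
        raise FileNotFoundError(f"image folder not found: {folder}")
    label = label if label is not None else folder.name

    by_sample: dict[str, dict[int, Path]] = {}
    dtypes_seen: set[str] = set()
    for path in sorted(folder.iterdir()):
        if not path.is_file() or path.suffix.lower() not in SUPPORTED_EXTENSIONS:
            continue
        sample, channel_id = parse_image_name(path.name)
        slot = by_sample.setdefault(sample, {})
        if channel_id in slot:
            raise ImageGroupError(
                f"{folder}: duplicate channel {channel_id} for sample {sample!r}"
            )
        slot[channel_id] = path
    if not by_sample:
        raise ImageGroupError(f"{folder}: no parsable image files found")

    images = []
    for sample in sorted(by_sample):
        paths = by_sample[sample]
        ids = sorted(paths)
        if ids != list(range(1, len(ids) + 1)):
            raise ImageGroupError(
                f"{folder}: sample {sample!r} has channels {ids}; "
                "ids must be contiguous from 1"
            )
        rasters = []
        for cid in ids:
            if paths[cid].suffix.lower() in (".tiff", ".tif"):
                dtypes_seen.add(str(tifffile.imread(paths[cid]).dtype))
            rasters.append(ChannelRaster(cid, _read_raster(paths[cid])))
        shapes = {r.shape for r in rasters}
        if len(shapes) > 1:
            raise ImageGroupError(
                f"{folder}: sample {sample!r} mixes dimensions {sorted(shapes)}"
            )
        images.append(MultiChannelImage(sample, tuple(rasters)))
        logger.info("loaded %s: %d channels, %s px", sample, len(rasters), rasters[0].shape)

    if len(dtypes_seen) > 1:
        logger.warning(
            "WARN-MIXED-DEPTH condition %s mixes bit depths %s; intensities were "
            "normalized per file by each file's dtype maximum",
            label,
            sorted(dtypes_seen),
        )
    return ImageGroup(label=label, images=images)
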