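"""Synthetic data with known ground truth, at two levels.

``generate_correlations`` draws patch-correlation lists directly from
the hierarchical generative model (truncated-normal image means,
Student-t patch values) — the natural fixture for testing inference.

``generate_image_pair`` builds a two-channel image with cell-like disk
foreground and dark noisy background; foreground intensities of the two
channels share a controlled latent correlation (via a 2x2 Cholesky
factor on bivariate Gaussians), so the whole pixel-level pipeline can
be exercised against a known truth.  ``generate_condition_pair`` writes
such images to disk as 16-bit TIFFs under the channel naming
convention, exercising the end-to-end file path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import tifffile

from ._math import trunc_normal_rvs
from .images import ChannelRaster, ImageGroup, MultiChannelImage, load_image_group


@dataclass(frozen=True)
class CorrSynthSpec:
    """Ground truth for correlation-level draws from the hierarchy."""

    rho_bar: float = 0.6
    sigma: float = 0.1
    nu: float = 10.0
    n_images: int = 6
    patches_per_image: int = 50
    sigma_patch: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1 < self.rho_bar < 1:
            raise ValueError("rho_bar must lie in (-1, 1)")
        if not 0 < self.sigma < 1:
            raise ValueError("sigma must lie in (0, 1)")
        if self.nu <= 0:
            raise ValueError("nu must be > 0")


@dataclass(frozen=True)
class ImageSynthSpec:
    """Ground truth for a synthetic two-channel fluorescence image."""

    height: int = 256
    width: int = 256
    n_cells: int = 12
    cell_radius_range: tuple[int, int] = (12, 28)
    rho_true: float = 0.7
    background_level: float = 0.06
    noise_sd: float = 0.02
    cell_gradient: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 32 or self.width < 32:
            raise ValueError("image dimensions must be >= 32")
        if not -1 < self.rho_true < 1:
            raise ValueError("rho_true must lie in (-1, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_correlations(spec: CorrSynthSpec) -> list[np.ndarray]:
    """Per-image patch-correlation lists from the generative hierarchy.

    For each image, rho_I ~ Normal(rho_bar, sigma) truncated to (-1, 1);
    patch values are StudentT(nu, rho_I, sigma_patch) clipped to
    [-1, 1].  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    out = []
    for _ in range(spec.n_images):
        rho_i = float(trunc_normal_rvs(spec.rho_bar, spec.sigma, -1.0, 1.0, None, rng))
        vals = rho_i + spec.sigma_patch * rng.standard_t(spec.nu, spec.patches_per_image)
        out.append(np.clip(vals, -1.0, 1.0))
    return out


def _disk_mask(h: int, w: int, cy: float, cx: float, radius: float) -> np.ndarray:
    yy, xx = np.ogrid[:h, :w]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def generate_image_pair(spec: ImageSynthSpec) -> MultiChannelImage:
    """Two-channel image with correlated foreground disks.

    Inside cells, both channels' intensities are monotone maps of
    latent bivariate Gaussians with correlation ``rho_true`` into the
    bright range; outside, low background with Gaussian noise.  The
    construction keeps foreground and background bimodally separated so
    Otsu gating recovers the true foreground.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    r_lo, r_hi = spec.cell_radius_range
    if r_hi >= min(h, w) // 2:
        raise ValueError("cell radii too large for the image dimensions")

    foreground = np.zeros((h, w), dtype=bool)
    gradient = np.zeros((h, w))
    for _ in range(spec.n_cells):
        radius = rng.uniform(r_lo, r_hi)
        cy = rng.uniform(radius, h - radius)
        cx = rng.uniform(radius, w - radius)
        disk = _disk_mask(h, w, cy, cx, radius)
        foreground |= disk
        if spec.cell_gradient:
            yy, xx = np.ogrid[:h, :w]
            dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2) / radius
            gradient[disk] = np.maximum(gradient[disk], 1.0 - 0.5 * dist[disk])

    n_fg = int(foreground.sum())
    # correlated latent Gaussians via the 2x2 Cholesky factor
    rho = spec.rho_true
    z1 = rng.standard_normal(n_fg)
    z2 = rho * z1 + np.sqrt(1.0 - rho**2) * rng.standard_normal(n_fg)

    def _to_intensity(z: np.ndarray) -> np.ndarray:
        # monotone squash of the latent into the bright band (0.45, 1.0);
        # monotonicity approximately preserves the latent correlation
        lo = 0.45
        vals = lo + (1.0 - lo) / (1.0 + np.exp(-z))
        return vals

    channels = []
    for z in (z1, z2):
        data = spec.background_level + spec.noise_sd * rng.standard_normal((h, w))
        fg_vals = _to_intensity(z)
        if spec.cell_gradient:
            fg_vals = fg_vals * (0.6 + 0.4 * gradient[foreground])
        data[foreground] = fg_vals
        channels.append(np.clip(data, 0.0, 1.0))
    return MultiChannelImage(
        f"synthetic_seed{spec.seed}",
        (ChannelRaster(1, channels[0]), ChannelRaster(2, channels[1])),
    )


def write_image(image: MultiChannelImage, folder: Path, name: str | None = None) -> list[Path]:
    """Write each channel as a 16-bit TIFF under the naming convention."""
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    name = name or image.name
    paths = []
    for ch in image.channels:
        path = folder / f"{name}_c{ch.channel_id}.tiff"
        tifffile.imwrite(path, np.round(ch.data * 65535).astype(np.uint16))
        paths.append(path)
    return paths


def generate_condition_pair(
    sample_spec: ImageSynthSpec,
    control_spec: ImageSynthSpec,
    n_images: int,
    out_dir: str | Path,
) -> tuple[ImageGroup, ImageGroup]:
    """Write matched sample/control folders of synthetic images.

    Image k of each condition uses ``spec.seed + k`` so images differ
    but the whole fixture is reproducible; a ground-truth JSON sits next
    to the folders.
    """
    out_dir = Path(out_dir)
    dirs = {"sample": out_dir / "sample", "control": out_dir / "control"}
    for label, spec in (("sample", sample_spec), ("control", control_spec)):
        for k in range(n_images):
            img_spec = _with_seed(spec, spec.seed + k)
            image = generate_image_pair(img_spec)
            write_image(image, dirs[label], f"{label}_{k:02d}")
    truth = {
        "n_images": n_images,
        "sample": asdict(sample_spec),
        "control": asdict(control_spec),
    }
    (out_dir / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return (
        load_image_group(dirs["sample"], "sample"),
        load_image_group(dirs["control"], "control"),
    )


def _with_seed(spec: ImageSynthSpec, seed: int) -> ImageSynthSpec:
    kwargs = asdict(spec)
    kwargs["seed"] = seed
    kwargs["cell_radius_range"] = tuple(kwargs["cell_radius_range"])
    return ImageSynthSpec(**kwargs)
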