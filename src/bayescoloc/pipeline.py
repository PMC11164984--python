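"""End-to-end pipeline: load -> threshold -> patch-correlate -> (controls)
-> fit -> Bayes factor -> report.

``run_pipeline`` wires all stages for a two-condition analysis.  The
control condition is either a folder of real control images or a
shuffled copy of the sample images (pixel- or block-wise).  One master
seed drives named substreams (shuffles, prior draws, inference,
posterior sampling), so a run is reproducible end to end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .background import image_thresholds, joint_mask
from .controls import make_shuffled_controls
from .images import ImageGroup, MultiChannelImage, load_image_group
from .model import (
    FitConfig,
    PriorSpec,
    fit_model,
    make_bayes_result,
)
from .patches import (
    DEFAULT_MIN_VALID,
    adaptive_patch_search,
    local_correlation_map,
)
from .report import ImageArtifacts, RunReport, render_outputs

logger = logging.getLogger("bayescoloc")


@dataclass
class RunConfig:
    """Settings of one colocalization run.

    Exactly one of ``control_dir`` / generated-control ``control_mode``
    (``"pixel"`` or ``"block"``) must be active; ``control_mode="images"``
    means real control images from ``control_dir``.
    """

    sample_dir: str | Path = ""
    control_dir: str | Path | None = None
    control_mode: str = "images"
    channels: tuple[int, int] = (1, 2)
    n_patches_side: int = 16
    method: str = "pearson"
    min_valid: int = DEFAULT_MIN_VALID
    delta_rho0: float = 0.1
    vi_iterations: int = 10_000
    posterior_samples: int = 100_000
    block_side: int = 3
    window_side: int = 7
    n_bins: int = 256
    seed: int = 42
    engine: str = "vi"
    out_dir: str | Path = "out"
    prior: PriorSpec = field(default_factory=PriorSpec)

    def validate(self) -> None:
        if self.channels[0] == self.channels[1]:
            raise ValueError("the two analyzed channels must be distinct")
        if min(self.channels) < 1:
            raise ValueError("channel ids must be >= 1")
        if self.control_mode not in ("images", "pixel", "block"):
            raise ValueError("control_mode must be 'images', 'pixel' or 'block'")
        if self.control_mode == "images" and self.control_dir is None:
            raise ValueError("control_mode='images' requires control_dir")
        if self.control_mode != "images" and self.control_dir is not None:
            raise ValueError(
                "pass either control_dir or a shuffled control_mode, not both"
            )
        if not Path(self.sample_dir).is_dir():
            raise FileNotFoundError(f"sample folder not found: {self.sample_dir}")

    def echo(self) -> dict:
        d = asdict(self)
        d["sample_dir"] = str(self.sample_dir)
        d["control_dir"] = None if self.control_dir is None else str(self.control_dir)
        d["out_dir"] = str(self.out_dir)
        d["channels"] = list(self.channels)
        return d


def analyze_group(
    images: list[MultiChannelImage],
    config: RunConfig,
    label: str,
) -> tuple[list[ImageArtifacts], list[np.ndarray], list[str]]:
    """Threshold, mask and patch-correlate every image of one condition.

    Returns per-image artifacts, the per-image patch-correlation lists
    for the model, and the names of excluded images.
    """
    ch_a, ch_b = config.channels
    artifacts: list[ImageArtifacts] = []
    corr_lists: list[np.ndarray] = []
    excluded: list[str] = []
    for image in images:
        thresholds = image_thresholds(image, config.channels, config.n_bins)
        for cid, t in thresholds.items():
            logger.info("%s/%s channel %d: Otsu threshold %.4f",
                        label, image.name, cid, t.threshold)
        mask = joint_mask(image, ch_a, ch_b, thresholds)
        patches = adaptive_patch_search(
            image, ch_a, ch_b, mask, config.n_patches_side,
            config.method, config.min_valid,
        )
        if patches is None:
            excluded.append(image.name)
            continue
        local = local_correlation_map(
            image, ch_a, ch_b, mask, config.window_side,
            config.method, config.min_valid,
        )
        artifacts.append(ImageArtifacts(image.name, patches, local, mask, thresholds))
        corr_lists.append(patches.correlations())
    return artifacts, corr_lists, excluded


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full colocalization analysis described by *config*."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    seed_shuffle, seed_fit, seed_prior = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    )

    sample_group = load_image_group(config.sample_dir, "sample")
    n_ch = sample_group.n_channels
    if max(config.channels) > n_ch:
        raise ValueError(
            f"requested channels {config.channels} but images have {n_ch} channels"
        )

    if config.control_mode == "images":
        control_images = list(load_image_group(config.control_dir, "control"))
    else:
        control_images = make_shuffled_controls(
            list(sample_group), config.control_mode, seed_shuffle,
            config.block_side, config.channels,
        )
        logger.info("generated %d %s-shuffled control images",
                    len(control_images), config.control_mode)

    sample_arts, sample_corrs, excl_s = analyze_group(
        list(sample_group), config, "sample"
    )
    control_arts, control_corrs, excl_c = analyze_group(
        control_images, config, "control"
    )
    if excl_s or excl_c:
        logger.warning("WARN-IMAGE-EXCLUDED excluded images: sample=%s control=%s",
                       excl_s, excl_c)

    fit_config = FitConfig(
        vi_iterations=config.vi_iterations,
        posterior_samples=config.posterior_samples,
        seed=seed_fit,
        engine=config.engine,
    )
    draws = fit_model(sample_corrs, control_corrs, config.prior, fit_config)
    bayes = make_bayes_result(
        draws, config.prior, config.delta_rho0,
        n_prior_draws=max(config.posterior_samples, 100_000), seed=seed_prior,
    )
    logger.info("BF[H1: delta_rho > %g] = %.4g (%s)",
                config.delta_rho0, bayes.bf, bayes.evidence)

    settings = config.echo()
    settings["prior"] = asdict(config.prior)
    settings["excluded_images"] = {"sample": excl_s, "control": excl_c}
    report = render_outputs(
        sample_arts, control_arts, draws, bayes, settings, config.out_dir
    )
    return report
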