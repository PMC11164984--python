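"""Run outputs: plots, numeric sidecars and the machine-readable summary.

For a dataset of n sample images the run emits 3n + 3 plot artifacts:
per image a patched-correlation map, a local-correlation map and a mask
overlay, plus three global plots (posterior distributions, prior vs
posterior of delta_rho with the Bayes factor, and the Bayes-factor
range curve).  Control-condition per-image plots are mirrored into the
same tree and counted separately.  Every number shown in a plot is also
written to a CSV/JSON sidecar, so no plot carries unique data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .background import ChannelThreshold, ValidityMask
from .model import GLOBAL_PARAMS, BayesResult, HierarchicalDraws
from .patches import LocalCorrMap, PatchCorrelations

logger = logging.getLogger("bayescoloc")


@dataclass
class ImageArtifacts:
    """Per-image analysis products feeding the report."""

    name: str
    patches: PatchCorrelations
    local_map: LocalCorrMap
    mask: ValidityMask
    thresholds: dict[int, ChannelThreshold]


@dataclass
class RunReport:
    """Paths and summary of one pipeline run."""

    out_dir: Path
    summary: dict
    plot_files: list[Path] = field(default_factory=list)
    control_plot_files: list[Path] = field(default_factory=list)
    sidecar_files: list[Path] = field(default_factory=list)

    @property
    def n_plot_artifacts(self) -> int:
        """Sample-condition plot count; equals 3 * n_images + 3."""
        return len(self.plot_files)


def _save_grid_csv(values: np.ndarray, path: Path) -> None:
    pd.DataFrame(values).to_csv(path, index_label="row", na_rep="")


def _plot_map(values, title, path, cmap="RdBu_r", vmin=-1, vmax=1):
    fig, ax = plt.subplots(figsize=(5, 4.2))
    im = ax.imshow(values, cmap=cmap, vmin=vmin, vmax=vmax, interpolation="nearest")
    fig.colorbar(im, ax=ax, shrink=0.85)
    ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _render_image_artifacts(art: ImageArtifacts, img_dir: Path, report: RunReport,
                            target: list[Path]) -> None:
    base = img_dir / art.name
    # patched correlation map
    _plot_map(art.patches.values, f"{art.name}: patch correlations "
              f"({art.patches.n_patches_side}x{art.patches.n_patches_side}, "
              f"{art.patches.method})", base.with_name(base.name + "_patches.png"))
    target.append(base.with_name(base.name + "_patches.png"))
    _save_grid_csv(art.patches.values, base.with_name(base.name + "_patches.csv"))
    report.sidecar_files.append(base.with_name(base.name + "_patches.csv"))
    # local correlation map
    _plot_map(art.local_map.values, f"{art.name}: local correlation "
              f"({art.local_map.window_side}px window)",
              base.with_name(base.name + "_localcorr.png"))
    target.append(base.with_name(base.name + "_localcorr.png"))
    _save_grid_csv(art.local_map.values, base.with_name(base.name + "_localcorr.csv"))
    report.sidecar_files.append(base.with_name(base.name + "_localcorr.csv"))
    # joint validity mask
    _plot_map(art.mask.data.astype(int), f"{art.name}: above-threshold mask",
              base.with_name(base.name + "_mask.png"), cmap="gray", vmin=0, vmax=1)
    target.append(base.with_name(base.name + "_mask.png"))
    _save_grid_csv(art.mask.data.astype(int), base.with_name(base.name + "_mask.csv"))
    report.sidecar_files.append(base.with_name(base.name + "_mask.csv"))


def _render_posterior_plot(draws: HierarchicalDraws, bayes: BayesResult, path: Path):
    names = list(GLOBAL_PARAMS) + ["delta_rho"]
    fig, axes = plt.subplots(3, 3, figsize=(10, 8))
    for ax, name in zip(axes.ravel(), names):
        vals = bayes.delta_rho_posterior if name == "delta_rho" else draws.params[name]
        ax.hist(vals, bins=80, density=True, color="steelblue")
        ax.set_title(name, fontsize=9)
    fig.suptitle("posterior distributions of global parameters", fontsize=11)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _render_bf_plot(bayes: BayesResult, path: Path):
    fig, ax = plt.subplots(figsize=(6, 4.2))
    bins = np.linspace(-1.5, 1.5, 121)
    ax.hist(bayes.delta_rho_prior, bins=bins, density=True, alpha=0.5,
            label="prior", color="gray")
    ax.hist(bayes.delta_rho_posterior, bins=bins, density=True, alpha=0.6,
            label="posterior", color="darkorange")
    ax.axvline(bayes.delta_rho0, color="k", ls="--", lw=1,
               label=f"delta_rho0 = {bayes.delta_rho0:g}")
    ax.set_xlabel("delta_rho")
    ax.set_title(f"BF[H1 : delta_rho > {bayes.delta_rho0:g}] = {bayes.bf:.4g} "
                 f"({bayes.evidence})", fontsize=10)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _render_bf_curve_plot(bayes: BayesResult, path: Path):
    fig, ax = plt.subplots(figsize=(6, 4.2))
    ax.plot(bayes.bf_thresholds, bayes.bf_log10, color="steelblue")
    ax.axvline(bayes.delta_rho0, color="k", ls="--", lw=1)
    ax.axhline(0.0, color="gray", lw=0.8)
    ax.set_xlabel("delta_rho0 threshold")
    ax.set_ylabel("log10 BF")
    ax.set_title("Bayes factor vs. threshold", fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def render_outputs(
    sample_artifacts: list[ImageArtifacts],
    control_artifacts: list[ImageArtifacts],
    draws: HierarchicalDraws,
    bayes: BayesResult,
    settings: dict,
    out_dir: str | Path,
) -> RunReport:
    """Write all plots, sidecars and the JSON summary for one run."""
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)

    report = RunReport(out_dir=out_dir, summary={})
    for art in sample_artifacts:
        _render_image_artifacts(art, img_dir, report, report.plot_files)
    for art in control_artifacts:
        _render_image_artifacts(art, img_dir, report, report.control_plot_files)

    posterior_png = out_dir / "posterior.png"
    _render_posterior_plot(draws, bayes, posterior_png)
    bf_png = out_dir / "bayes_factor.png"
    _render_bf_plot(bayes, bf_png)
    curve_png = out_dir / "bf_range.png"
    _render_bf_curve_plot(bayes, curve_png)
    report.plot_files += [posterior_png, bf_png, curve_png]

    draws_csv = out_dir / "posterior_draws.csv"
    draws.to_frame().to_csv(draws_csv, index=False)
    curve_csv = out_dir / "bf_curve.csv"
    pd.DataFrame({"delta_rho0": bayes.bf_thresholds,
                  "log10_bf": bayes.bf_log10}).to_csv(curve_csv, index=False)
    report.sidecar_files += [draws_csv, curve_csv]

    summary = {
        "settings": settings,
        "n_sample_images": len(sample_artifacts),
        "n_control_images": len(control_artifacts),
        "thresholds": {
            label: {
                art.name: {str(cid): t.threshold for cid, t in art.thresholds.items()}
                for art in arts
            }
            for label, arts in (("sample", sample_artifacts),
                                ("control", control_artifacts))
        },
        "patch_counts": {
            label: {art.name: {"n_patches_side": art.patches.n_patches_side,
                               "n_valid_patches": art.patches.n_valid_patches}
                    for art in arts}
            for label, arts in (("sample", sample_artifacts),
                                ("control", control_artifacts))
        },
        "posterior": bayes.summaries,
        "bf": bayes.bf,
        "bf_bound": bayes.bf_bound,
        "evidence": bayes.evidence,
        "delta_rho0": bayes.delta_rho0,
        "engine": draws.engine,
        "diagnostics": {k: v for k, v in draws.diagnostics.items() if k != "elbo_trace"},
        "plot_files": [str(p.relative_to(out_dir)) for p in report.plot_files],
        "control_plot_files": [str(p.relative_to(out_dir))
                               for p in report.control_plot_files],
    }
    report.summary = summary
    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2))
    report.sidecar_files.append(summary_path)
    logger.info("wrote %d sample-condition plot artifacts (+%d control) to %s",
                report.n_plot_artifacts, len(report.control_plot_files), out_dir)
    return report
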