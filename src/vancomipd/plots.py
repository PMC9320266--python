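"""Report figures, generated from the result tables only."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["gof_plot", "forest_plot", "dose_difference_boxplot", "write_figures"]


def gof_plot(predictions: pd.DataFrame, path: str | Path) -> None:
    """Predicted vs observed second concentration, one panel per approach."""
    approaches = list(predictions["approach"].unique())
    fig, axes = plt.subplots(1, len(approaches), figsize=(3.2 * len(approaches), 3.4),
                             squeeze=False, sharex=True, sharey=True)
    lim = max(predictions["predicted"].max(), predictions["observed"].max()) * 1.05
    for ax, name in zip(axes[0], approaches):
        g = predictions[predictions["approach"] == name]
        ax.plot([0, lim], [0, lim], color="grey", lw=0.8)
        ax.scatter(g["observed"], g["predicted"], s=8, alpha=0.5)
        ax.set_title(name, fontsize=9)
        ax.set_xlabel("observed (mg/L)")
    axes[0][0].set_ylabel("predicted (mg/L)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def forest_plot(performance: pd.DataFrame, path: str | Path) -> None:
    """Overall rBias (with 95% CI) and rRMSE per approach."""
    overall = performance[performance["subgroup"] == "overall"]
    y = np.arange(len(overall))
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(7, 0.6 * len(overall) + 1.5),
                                   sharey=True)
    ax1.errorbar(overall["rbias"], y,
                 xerr=[overall["rbias"] - overall["rbias_lo"],
                       overall["rbias_hi"] - overall["rbias"]],
                 fmt="o", capsize=3)
    ax1.axvline(0, color="grey", lw=0.8)
    ax1.set_yticks(y, overall["approach"])
    ax1.set_xlabel("rBias (%)")
    ax2.barh(y, overall["rrmse"], height=0.5)
    ax2.set_xlabel("rRMSE (%)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def dose_difference_boxplot(doses: pd.DataFrame, approach: str, path: str | Path) -> None:
    """First- and second-dose q12h differences vs prescribed, by exposure
    category at the second concentration."""
    sel = doses[doses["approach"] == approach]
    cats = ["subtherapeutic", "therapeutic", "supratherapeutic"]
    fig, ax = plt.subplots(figsize=(6.5, 4))
    data, positions, colors = [], [], []
    for i, cat in enumerate(cats):
        g = sel[sel["category"] == cat]
        data += [g["difference_first"].to_numpy(), g["difference"].to_numpy()]
        positions += [3 * i, 3 * i + 1]
        colors += ["tab:red", "tab:blue"]
    boxes = ax.boxplot([d if len(d) else [0.0] for d in data], positions=positions,
                       widths=0.8, patch_artist=True)
    for patch, c in zip(boxes["boxes"], colors):
        patch.set_facecolor(c)
        patch.set_alpha(0.5)
    ax.axhline(0, color="grey", lw=0.8)
    ax.set_xticks([3 * i + 0.5 for i in range(len(cats))], cats)
    ax.set_ylabel("predicted - prescribed dose (mg q12h)")
    ax.set_title(f"{approach}: first (red) and second (blue) predicted dose")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def write_figures(result, outdir: str | Path, fmt: str = "svg") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gof_plot(result.predictions, outdir / f"gof.{fmt}")
    forest_plot(result.performance, outdir / f"performance_forest.{fmt}")
    dose_difference_boxplot(result.doses, result.best_approach,
                            outdir / f"dose_differences.{fmt}")
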