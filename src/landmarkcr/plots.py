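"""Plotting helpers for performance reports."""

from __future__ import annotations

import numpy as np

METRIC_LABELS = {
    "auroc": "AUROC",
    "calibration_slope": "Calibration slope",
    "oe_ratio": "O/E ratio",
    "eci": "ECI",
    "scaled_brier": "Scaled Brier score",
}


def plot_landmark_metrics(report, models=None, metrics=None, ax_grid=None):
    """Per-landmark mean metric curves for the dynamic models, one panel per
    metric (discrimination, calibration and overall-performance trajectories
    over the landmark grid).

    Returns the matplotlib figure.
    """
    import matplotlib.pyplot as plt

    summary = report.summary()
    dyn = summary[summary["landmark"] != "static"].copy()
    dyn["landmark"] = dyn["landmark"].astype(int)
    if models is None:
        models = sorted(dyn["model"].unique())
    if metrics is None:
        metrics = [m for m in METRIC_LABELS if m in set(dyn["metric"])]
    fig, axes = plt.subplots(1, len(metrics),
                             figsize=(4 * len(metrics), 3.2), squeeze=False)
    for ax, metric in zip(axes[0], metrics):
        for model in models:
            sub = dyn[(dyn["model"] == model) & (dyn["metric"] == metric)] \
                .sort_values("landmark")
            ax.plot(sub["landmark"], sub["mean"], marker=".", label=model)
        if metric in ("calibration_slope", "oe_ratio"):
            ax.axhline(1.0, color="grey", lw=0.8, ls="--")
        ax.set_xlabel("landmark day $s$")
        ax.set_ylabel(METRIC_LABELS.get(metric, metric))
    axes[0][0].legend(fontsize=8)
    fig.tight_layout()
    return fig
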