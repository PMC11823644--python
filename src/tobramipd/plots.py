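"""Figure replicas: metric sweeps over prior weight and over sample time."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_weight_sweep", "plot_time_sweep"]

_METRICS = ("accuracy", "mpe", "nrmse")
_YLABEL = {"accuracy": "accuracy (%)", "mpe": "MPE (%)", "nrmse": "nRMSE (%)"}


def _metric_panels(title: str):
    fig, axes = plt.subplots(1, 3, figsize=(11, 3.2), constrained_layout=True)
    fig.suptitle(title)
    for ax, m in zip(axes, _METRICS):
        ax.set_ylabel(_YLABEL[m])
    return fig, axes


def plot_weight_sweep(reports: pd.DataFrame, path, design: str | None = None):
    """Accuracy/MPE/nRMSE of AUC estimation vs prior weight, one line per
    estimation model, with bootstrap percentile ribbons; LLR as a dashed
    reference line where present."""
    df = reports.copy()
    if design is not None:
        df = df[df["design"] == design]
    map_df = df[df["method"] == "map"]
    llr_df = df[df["method"] == "llr"]
    fig, axes = _metric_panels("AUC estimation vs prior weight")
    for ax, m in zip(axes, _METRICS):
        for model, sub in map_df.groupby("model"):
            sub = sub.sort_values("weight")
            ax.plot(sub["weight"], sub[m], marker="o", label=model)
            ax.fill_between(sub["weight"], sub[f"{m}_lo"], sub[f"{m}_hi"], alpha=0.2)
        if len(llr_df):
            ax.axhline(float(llr_df.iloc[0][m]), ls="--", color="k", label="LLR 1&10 h")
        ax.set_xlabel("prior weight w")
    axes[0].legend(fontsize=7)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_time_sweep(reports: pd.DataFrame, path, weight: float | None = None):
    """Metrics vs single-sample time (designs named ``single-<t>h``)."""
    df = reports[reports["design"].str.startswith("single-")].copy()
    if weight is not None:
        df = df[(df["method"] == "llr") | (df["weight"] == weight)]
    df["t"] = (
        df["design"].str.removeprefix("single-").str.removesuffix("h").astype(float)
    )
    llr_df = reports[reports["method"] == "llr"]
    fig, axes = _metric_panels("AUC estimation vs single-sample time")
    for ax, m in zip(axes, _METRICS):
        for model, sub in df[df["method"] == "map"].groupby("model"):
            sub = sub.sort_values("t")
            ax.plot(sub["t"], sub[m], marker="o", label=model)
            ax.fill_between(sub["t"], sub[f"{m}_lo"], sub[f"{m}_hi"], alpha=0.2)
        if len(llr_df):
            ax.axhline(float(llr_df.iloc[0][m]), ls="--", color="k", label="LLR 1&10 h")
        ax.set_xlabel("sample time (h after dose)")
    axes[0].legend(fontsize=7)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
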