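"""Figure builders for the four ensemble experiments.

Each function takes an :class:`~manduca.protocols.ExperimentResult` and
returns a matplotlib figure; :func:`plot_experiment` dispatches on the
experiment name and writes one or more PNG files.  Curves show ensemble
means with sample-standard-deviation error bars.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .protocols import ExperimentResult, equal_loss_ratios, summarize

__all__ = ["plot_experiment", "plot_timecourse"]


def _curves(result: ExperimentResult, metric: str, stage: str, group_key: str):
    """(group value -> (levels, means, stds)) for one metric/stage."""
    frame = summarize(result)
    sel = frame[(frame["metric"] == metric) & (frame["stage"] == stage)]
    out: Dict = {}
    for gval, sub in sel.groupby(group_key):
        sub = sub.sort_values("level")
        out[gval] = (
            sub["level"].to_numpy(),
            sub["mean"].to_numpy(),
            sub["std"].to_numpy(),
        )
    return out


def _plot_stage_panel(ax, result, metric, stage, group_key, title):
    for gval, (lv, mean, std) in sorted(_curves(result, metric, stage, group_key).items()):
        ax.errorbar(lv, mean, yerr=std, marker="o", capsize=2, label=f"{group_key}={gval}")
    ax.axhline(1.0, color="k", lw=0.8)
    ax.set_xlabel("injury level")
    ax.set_title(title, fontsize=9)
    ax.legend(fontsize=7)


def plot_recovery(result: ExperimentResult):
    """Normalized post-injury / post-training response and recovery ratio
    vs FAS level, per injury site."""
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    _plot_stage_panel(axes[0], result, "normalized_mean", "post_injury", "site",
                      "post-injury EN response (normalized)")
    _plot_stage_panel(axes[1], result, "normalized_mean", "post_training", "site",
                      "post-training EN response (normalized)")
    # recovery ratio: post-training / post-injury per instance
    for site in sorted({c["site"] for c in result.conditions}):
        lv, ratio = [], []
        for cond, recs in zip(result.conditions, result.records):
            if cond["site"] != site:
                continue
            vals = [
                r.normalized_mean("post_training") / r.normalized_mean("post_injury")
                for r in recs
                if "post_training" in r.responses
            ]
            if vals:
                lv.append(cond["level"])
                ratio.append(np.mean(vals))
        order = np.argsort(lv)
        axes[2].plot(np.asarray(lv)[order], np.asarray(ratio)[order], marker="o", label=site)
    axes[2].set_title("training recovery ratio", fontsize=9)
    axes[2].set_xlabel("injury level")
    axes[2].legend(fontsize=7)
    fig.tight_layout()
    return fig


def plot_qn(result: ExperimentResult):
    """Inhibitory-channel panels: injury response curves per QN count plus
    naive SSNR/SNR distributions."""
    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    _plot_stage_panel(axes[0, 0], result, "normalized_mean", "post_injury",
                      "qn_per_glom", "post-injury response by QN count")
    _plot_stage_panel(axes[0, 1], result, "normalized_mean", "post_training",
                      "qn_per_glom", "post-training response by QN count")
    frame = result.to_frame()
    naive = frame[(frame["stage"] == "naive") & (frame["level"] == 0.0)]
    for ax, metric, title in (
        (axes[1, 0], "ssnr", "naive SSNR"),
        (axes[1, 1], "snr", "naive SNR"),
    ):
        data, labels = [], []
        for qn, sub in naive[naive["metric"] == metric].groupby("qn_per_glom"):
            vals = sub["value"].replace([np.inf], np.nan).dropna()
            data.append(vals)
            labels.append(str(qn))
        if data:
            ax.boxplot(data, tick_labels=labels)
        ax.set_xlabel("QNs per glomerulus")
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    return fig


def plot_noise(result: ExperimentResult):
    """Noise-protection panels: top-tranche and average preservation per AL
    noise factor."""
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    _plot_stage_panel(axes[0], result, "tranche_preservation", "post_injury",
                      "al_noise_factor", "top-tranche preservation (post-injury)")
    _plot_stage_panel(axes[1], result, "tranche_preservation", "post_training",
                      "al_noise_factor", "top-tranche preservation (post-training)")
    _plot_stage_panel(axes[2], result, "normalized_mean", "post_injury",
                      "al_noise_factor", "average-response preservation")
    fig.tight_layout()
    return fig


def plot_ablation(result: ExperimentResult):
    """EN loss vs level for FAS and ablation per site, with the analytic
    ablation curve implied by the FAS fit."""
    sites = sorted({c["site"] for c in result.conditions})
    fig, axes = plt.subplots(1, len(sites), figsize=(5 * len(sites), 4))
    axes = np.atleast_1d(axes)
    from .protocols import _mean_loss_curve

    for ax, site in zip(axes, sites):
        info = equal_loss_ratios(result, site)
        for kind, style in (("fas", "o-"), ("ablation", "x--")):
            lv, loss = _mean_loss_curve(result, site, kind)
            ax.plot(lv, loss, style, label=kind)
        lv_f, loss_f = _mean_loss_curve(result, site, "fas")
        ax.plot(lv_f / info["analytic_factor"], loss_f, ":",
                label=f"theoretical ablation (/{info['analytic_factor']:.2f})")
        ratio = info["mean_ratio"]
        ax.set_title(f"{site}: empirical ratio {ratio:.2f}", fontsize=9)
        ax.set_xlabel("injury level")
        ax.set_ylabel("EN loss (1 - normalized response)")
        ax.legend(fontsize=7)
    fig.tight_layout()
    return fig


_PLOTTERS = {
    "learning_recovery": plot_recovery,
    "qn_ratio": plot_qn,
    "al_noise": plot_noise,
    "ablation_vs_fas": plot_ablation,
}


def plot_experiment(result: ExperimentResult, out_dir) -> List[str]:
    """Render the figure(s) for an experiment; returns written file paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fig = _PLOTTERS[result.name](result)
    path = out / f"fig_{result.name}.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return [str(path)]


def plot_timecourse(timecourse, schedule, out_path) -> str:
    """EN firing-rate trace with puff and octopamine windows marked."""
    fig, ax = plt.subplots(figsize=(10, 3))
    ax.plot(timecourse.t, timecourse.en1, lw=0.8)
    for on, off in schedule.puff_windows:
        ax.axvspan(on, off, color="tab:orange", alpha=0.2, lw=0)
    for on, off in schedule.octopamine_windows:
        ax.axvspan(on, off, color="tab:green", alpha=0.15, lw=0)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("EN rate (normalized units)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return str(out_path)
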