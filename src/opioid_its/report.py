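"""Figure generation: fitted/counterfactual rate plots, excess-rate plots
and cumulative-excess plots with bootstrap bands.

Figures are best-effort reporting artifacts; all quantitative output lives
in the CSV tables written by the pipeline.
"""

from __future__ import annotations

import os

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd


def plot_region_fit(ax, sub: pd.DataFrame, pred: pd.DataFrame, timeline) -> None:
    for g in sub["gender"].unique():
        rows = sub["gender"] == g
        ax.plot(sub.loc[rows, "t"], sub.loc[rows, "rate"], ".", ms=2, alpha=0.5)
        ax.plot(sub.loc[rows, "t"], pred.loc[rows.to_numpy(), "fit"], "-", lw=1)
        ax.fill_between(sub.loc[rows, "t"], pred.loc[rows.to_numpy(), "ci_lower"],
                        pred.loc[rows.to_numpy(), "ci_upper"], alpha=0.3)
        ax.fill_between(sub.loc[rows, "t"], pred.loc[rows.to_numpy(), "pi_lower"],
                        pred.loc[rows.to_numpy(), "pi_upper"], alpha=0.15)
    for e in timeline:
        ax.axvline(e.index, color="grey", ls="--", lw=0.7)
    ax.set_xlabel("months since Jan 1999")
    ax.set_ylabel("deaths per 100,000")


def make_figures(config, timeline, rates: pd.DataFrame, results: dict) -> None:
    out = config.out_dir
    # observed + fitted per region
    fig, axes = plt.subplots(2, 2, figsize=(11, 7), sharex=True)
    for ax, region in zip(axes.ravel(), config.regions):
        pred = pd.read_csv(os.path.join(out, f"predictions_{region}.csv"))
        sub = rates[rates["region"] == region].reset_index(drop=True)
        sub = sub.sort_values(["gender", "t"] if config.model == "gender" else "t",
                              ignore_index=True)
        plot_region_fit(ax, sub, pred, timeline)
        ax.set_title(region)
    fig.tight_layout()
    fig.savefig(os.path.join(out, "fit_by_region.png"), dpi=120)
    plt.close(fig)

    # excess rate per region
    fig, axes = plt.subplots(2, 2, figsize=(11, 7), sharex=True)
    for ax, region in zip(axes.ravel(), config.regions):
        ex = results["excess"][region]
        for g in ex["gender"].unique():
            rows = ex["gender"] == g
            ax.plot(ex.loc[rows, "t"], ex.loc[rows, "excess_rate"], "k-", lw=1)
            ax.fill_between(ex.loc[rows, "t"], ex.loc[rows, "excess_rate_pi_lower"],
                            ex.loc[rows, "excess_rate_pi_upper"], alpha=0.3)
        ax.axhline(0, color="grey", lw=0.7)
        ax.set_title(region)
        ax.set_ylabel("excess deaths per 100,000")
    fig.tight_layout()
    fig.savefig(os.path.join(out, "excess_rate_by_region.png"), dpi=120)
    plt.close(fig)

    # cumulative excess, regional + national
    fig, ax = plt.subplots(figsize=(8, 5))
    for region in config.regions:
        ci = results["bootstrap"][region].ci()
        ax.plot(ci.index, ci["point"], label=region)
        ax.fill_between(ci.index, ci["lower"], ci["upper"], alpha=0.25)
    nat = results["national"].ci()
    ax.plot(nat.index, nat["point"], "k-", lw=2, label="National")
    ax.fill_between(nat.index, nat["lower"], nat["upper"], color="k", alpha=0.15)
    ax.set_xlabel("months since Jan 1999")
    ax.set_ylabel("cumulative excess deaths")
    ax.legend()
    fig.tight_layout()
    fig.savefig(os.path.join(out, "cumulative_excess.png"), dpi=120)
    plt.close(fig)
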