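"""Render MR diagnostic figures from the plot-ready tables.

Every number drawn here comes from :func:`mrkit.sensitivity.diagnostic_datasets`
or the leave-one-out table; the figures add no computation, which keeps plot
and table content consistent by construction.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

# Stable SVG ids so repeated runs produce identical files.
matplotlib.rcParams["svg.hashsalt"] = "mrkit"


def forest_plot(forest: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(forest) + 1.5))
    y = range(len(forest))[::-1]
    for yi, (_, row) in zip(y, forest.iterrows()):
        color = "crimson" if row["kind"] == "combined" else "black"
        ax.plot(
            [row["ci_lower_log"], row["ci_upper_log"]], [yi, yi], color=color, lw=1.2
        )
        ax.plot(row["beta"], yi, "o", color=color, ms=4)
    ax.axvline(0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(list(y))
    ax.set_yticklabels(forest["label"])
    ax.set_xlabel("causal estimate (log OR per unit exposure)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def scatter_plot(scatter: pd.DataFrame, lines: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    ax.errorbar(
        scatter["beta_exposure"],
        scatter["beta_outcome"],
        xerr=[
            scatter["beta_exposure"] - scatter["x_lo"],
            scatter["x_hi"] - scatter["beta_exposure"],
        ],
        yerr=[
            scatter["beta_outcome"] - scatter["y_lo"],
            scatter["y_hi"] - scatter["beta_outcome"],
        ],
        fmt="o",
        color="black",
        ecolor="grey",
        ms=4,
        lw=0.8,
    )
    xs = pd.Series(
        [scatter["beta_exposure"].min(), scatter["beta_exposure"].max()]
    )
    for _, row in lines.iterrows():
        ax.plot(xs, row["intercept"] + row["slope"] * xs, label=row["method"], lw=1.2)
    ax.set_xlabel("SNP effect on exposure")
    ax.set_ylabel("SNP effect on outcome (log OR)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def funnel_plot(funnel: pd.DataFrame, lines: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4.5))
    ax.plot(funnel["ratio"], funnel["precision"], "o", color="black", ms=4)
    for _, row in lines.iterrows():
        ax.axvline(row["beta"], lw=1.2, label=row["method"])
    ax.set_xlabel("per-SNP causal estimate (Wald ratio)")
    ax.set_ylabel("precision 1/SE")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def loo_plot(loo_table: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(loo_table) + 1.5))
    y = range(len(loo_table))[::-1]
    for yi, (_, row) in zip(y, loo_table.iterrows()):
        color = "crimson" if row["SNP"] == "all" else "black"
        ax.plot(
            [row["ci_lower_log"], row["ci_upper_log"]], [yi, yi], color=color, lw=1.2
        )
        ax.plot(row["beta"], yi, "o", color=color, ms=4)
    ax.axvline(0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(list(y))
    ax.set_yticklabels(loo_table["SNP"])
    ax.set_xlabel("IVW estimate excluding the named SNP (log OR)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
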