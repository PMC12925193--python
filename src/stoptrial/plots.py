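"""Basic publication-style figures for the emulation reports."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd


def trajectory_plot(changes: pd.DataFrame, path) -> None:
    """Predicted mean change from baseline in MMSE, by arm."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(changes["t_months"], changes["change_continue"], label="continue")
    ax.plot(
        changes["t_months"],
        changes["change_discontinue"],
        label="discontinue",
        linestyle="--",
    )
    ax.set_xlabel("months since baseline")
    ax.set_ylabel("mean change in MMSE")
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def incidence_plot(incidence: pd.DataFrame, path) -> None:
    """Cumulative incidence of death, by arm."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.step(incidence["m"], incidence["risk_continue"], label="continue")
    ax.step(
        incidence["m"],
        incidence["risk_discontinue"],
        label="discontinue",
        linestyle="--",
    )
    ax.set_xlabel("months since baseline")
    ax.set_ylabel("cumulative incidence of death")
    ax.set_ylim(bottom=0)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def love_plot(balance_table: pd.DataFrame, path, threshold: float = 0.1) -> None:
    """Standardized mean differences before/after weighting, per covariate."""
    tab = balance_table.iloc[::-1]
    fig, ax = plt.subplots(figsize=(6, 0.35 * len(tab) + 1.5))
    y = range(len(tab))
    ax.scatter(tab["smd_unweighted"].abs(), y, label="unweighted", marker="o")
    ax.scatter(tab["smd_weighted"].abs(), y, label="weighted", marker="x")
    ax.set_yticks(list(y), tab["covariate"])
    ax.axvline(threshold, color="red", lw=0.8, linestyle=":")
    ax.set_xlabel("|standardized mean difference|")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def tipping_plot(scan_table: pd.DataFrame, path, alpha: float = 0.05) -> None:
    """Delta-scan estimates with pointwise CIs and the significance cutoff."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.errorbar(
        scan_table["delta"],
        scan_table["estimate"],
        yerr=[
            scan_table["estimate"] - scan_table["ci_low"],
            scan_table["ci_high"] - scan_table["estimate"],
        ],
        fmt="o-",
        capsize=3,
    )
    ax.axhline(0.0, color="grey", lw=0.5)
    crossed = scan_table[scan_table["p_value"] >= alpha]
    if not crossed.empty:
        ax.axvline(crossed["delta"].iloc[0], color="red", linestyle=":")
    ax.set_xlabel("delta (MMSE points subtracted from continuer imputations)")
    ax.set_ylabel("1-year between-group difference")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
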