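"""Optional plot rendering: the four GOF panels and the VPC bands."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .evaluation import VpcResult

__all__ = ["plot_gof", "plot_vpc"]


def plot_gof(gof: pd.DataFrame, path) -> None:
    """Four-panel goodness-of-fit figure: DV vs PRED, DV vs IPRED,
    CWRES vs PRED, CWRES vs time after dose."""
    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    lim = (0, max(gof["DV"].max(), gof["PRED"].max(), gof["IPRED"].max()) * 1.05)
    for ax, xcol in zip(axes[0], ("PRED", "IPRED")):
        ax.plot(gof[xcol], gof["DV"], "o", ms=4, alpha=0.6)
        ax.plot(lim, lim, "k--", lw=1)
        ax.set_xlabel(f"{xcol} (mg/L)")
        ax.set_ylabel("DV (mg/L)")
        ax.set_xlim(lim)
        ax.set_ylim(lim)
    for ax, xcol, xlab in zip(
        axes[1], ("PRED", "TAD"), ("PRED (mg/L)", "Time after dose (h)")
    ):
        ax.plot(gof[xcol], gof["CWRES"], "o", ms=4, alpha=0.6)
        ax.axhline(0, color="k", lw=1)
        for y in (-2, 2):
            ax.axhline(y, color="k", ls=":", lw=1)
        ax.set_xlabel(xlab)
        ax.set_ylabel("CWRES")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_vpc(vpc: VpcResult, obs: pd.DataFrame, path) -> None:
    """VPC figure: observed points and percentiles over the 90% prediction
    interval of the simulated percentiles."""
    fig, ax = plt.subplots(figsize=(8, 5))
    b = vpc.bins
    for p, color in ((5, "tab:blue"), (50, "tab:red"), (95, "tab:blue")):
        ax.fill_between(
            b["t_mid"], b[f"sim_p{p}_lo"], b[f"sim_p{p}_hi"], color=color, alpha=0.25
        )
        ax.plot(b["t_mid"], b[f"obs_p{p}"], "-o", color=color, ms=4, label=f"observed P{p}")
    ax.plot(obs["TIME"], obs["DV"], "k.", ms=3, alpha=0.4)
    ax.set_xlabel("Time after first dose (h)")
    ax.set_ylabel("Concentration (mg/L)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
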