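"""Static diagnostic figures for the synthetic-trial pipeline."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_concentration_profiles(pk: pd.DataFrame, path) -> None:
    """Semi-log concentration-time overlay, one line per subject,
    coloured by cohort."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    obs = pk[(pk["EVID"] == 0) & pk["DV"].notna()]
    cohorts = sorted(obs["COHORT"].dropna().unique())
    cmap = plt.get_cmap("tab10")
    for ci, cohort in enumerate(cohorts):
        sub = obs[obs["COHORT"] == cohort]
        for i, (sid, grp) in enumerate(sub.groupby("ID")):
            ax.semilogy(
                grp["TIME"] / 24.0,
                grp["DV"],
                color=cmap(ci % 10),
                alpha=0.6,
                lw=1,
                label=cohort if i == 0 else None,
            )
    ax.set_xlabel("Time (days)")
    ax.set_ylabel("Serum concentration (ug/mL)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_ro_vs_concentration(ro: pd.DataFrame, path, threshold: float | None = None) -> None:
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, assay in zip(axes, sorted(ro["ASSAY"].unique())):
        sub = ro[(ro["ASSAY"] == assay) & (ro["ANOMALOUS"] == 0) & (ro["CONC"] > 0)]
        ax.semilogx(sub["CONC"], sub["VALUE"], "o", ms=3, alpha=0.5)
        if threshold is not None:
            ax.axvline(threshold, color="r", ls="--", lw=1)
        ax.axhline(0.9, color="grey", ls=":", lw=1)
        ax.set_title(assay)
        ax.set_xlabel("Serum concentration (ug/mL)")
    axes[0].set_ylabel("RO assay ratio (1 = full occupancy)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_clearance_vs_weight(clearances, weights, path, slope=None, intercept=None) -> None:
    fig, ax = plt.subplots(figsize=(5.5, 4))
    cl = np.asarray(clearances, float) * 24.0  # display in L/day
    w = np.asarray(weights, float)
    ax.loglog(w, cl, "o", ms=5)
    if slope is not None and intercept is not None:
        wg = np.linspace(w.min(), w.max(), 50)
        ax.loglog(wg, 24.0 * np.exp(intercept) * wg**slope, "-", color="r", lw=1)
    ax.set_xlabel("Body weight (kg)")
    ax.set_ylabel("Clearance (L/day)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
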