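"""Basic plots: metagene profile panels and correlation profiles with the
Bonferroni threshold."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy.stats import norm

from .correlation import CorrelationProfile, tau_variance
from .profiles import AverageProfile

_SENS_COLOR = {"resistant": "tab:red", "sensitive": "tab:blue"}


def plot_class_profiles(
    profiles: dict[tuple[str, str], AverageProfile], path: str
) -> None:
    """One panel per chromatin class; red/blue lines for resistant/sensitive."""
    classes = sorted({cc for cc, _ in profiles})
    fig, axes = plt.subplots(1, max(1, len(classes)), figsize=(5 * len(classes), 3.2), squeeze=False)
    for ax, cc in zip(axes[0], classes):
        for (pcc, sens), prof in profiles.items():
            if pcc != cc:
                continue
            ax.plot(prof.offsets, prof.smoothed, color=_SENS_COLOR.get(sens, "k"), label=sens)
        ax.set_title(f"{cc} genes")
        ax.set_xlabel("position relative to TSS (nt)")
        ax.set_ylabel("mean sites (window-3 smoothed)")
        ax.axvline(0, color="grey", lw=0.5)
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_correlation_profiles(profiles: list[CorrelationProfile], path: str) -> None:
    """Grid of smoothed Kendall tau curves with dashed Bonferroni thresholds."""
    keys = sorted({(p.labels.get("chromatin_class", ""), p.labels.get("stratum", "")) for p in profiles})
    ncol = max(1, len({k[1] for k in keys}))
    nrow = max(1, len({k[0] for k in keys}))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.6 * ncol, 2.6 * nrow), squeeze=False, sharex=True)
    rows = sorted({k[0] for k in keys})
    cols = sorted({k[1] for k in keys})
    for p in profiles:
        cc = p.labels.get("chromatin_class", "")
        stratum = p.labels.get("stratum", "")
        ax = axes[rows.index(cc)][cols.index(stratum)]
        sens = p.labels.get("sensitivity", "")
        ax.plot(p.offsets, p.smoothed_tau, color=_SENS_COLOR.get(sens, "k"), lw=0.9, label=sens)
        thr = norm.isf(p.alpha / p.m / 2.0) * np.sqrt(tau_variance(p.n))
        ax.axhline(thr, color="k", ls="--", lw=0.6)
        ax.axhline(-thr, color="k", ls="--", lw=0.6)
        ax.axhline(0, color="grey", lw=0.4)
        ax.set_title(f"{cc} / {stratum}", fontsize=8)
    for ax in axes[-1]:
        ax.set_xlabel("position relative to TSS (nt)")
    for row in axes:
        row[0].set_ylabel("Kendall CC (smoothed)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
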