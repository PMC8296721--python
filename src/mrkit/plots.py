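"""Basic diagnostic plots: SNP-effect scatter with fitted slopes, and a funnel."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .estimators import MREstimate
from .summary_gwas import HarmonizedSet


def scatter_plot(
    h: HarmonizedSet,
    estimates: Sequence[MREstimate],
    path: str | Path,
) -> None:
    """SNP-outcome vs SNP-exposure effects with one fitted line per method."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(h.beta_x, h.beta_y, xerr=h.se_x, yerr=h.se_y,
                fmt="o", ms=3, lw=0.6, alpha=0.6, color="0.4")
    xs = np.linspace(min(0.0, h.beta_x.min()), h.beta_x.max(), 50)
    for est in estimates:
        icpt = est.intercept or 0.0
        ax.plot(xs, icpt + est.beta * xs, label=est.method)
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    ax.set_xlabel(f"SNP effect on {h.exposure_name}")
    ax.set_ylabel(f"SNP effect on {h.outcome_name}")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def funnel_plot(h: HarmonizedSet, path: str | Path) -> None:
    """Per-SNP Wald ratios against their precision (1/SE)."""
    ratios = h.beta_y / np.where(h.beta_x == 0, np.nan, h.beta_x)
    prec = np.abs(h.beta_x) / h.se_y
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ratios, prec, s=10, alpha=0.7, color="0.3")
    ax.set_xlabel("Wald ratio")
    ax.set_ylabel("precision (1/SE of ratio)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
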