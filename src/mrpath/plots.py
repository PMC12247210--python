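"""Plot emitters: forest, per-SNP scatter with fitted lines, leave-one-out.

All emitters write straight to file and return the path; they use the Agg
backend so they run headless.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .estimators import MREstimate
from .sumstats import HarmonizedSet


def forest_plot(estimates: Sequence[MREstimate], path, title: str | None = None,
                or_scale: bool = False):
    """Forest plot of method estimates for one exposure–outcome pair."""
    fig, ax = plt.subplots(figsize=(6, 0.6 * len(estimates) + 1.2))
    ys = range(len(estimates))[::-1]
    for y, est in zip(ys, estimates):
        lo, mid, hi = ((est.or_low, est.or_, est.or_high) if or_scale
                       else (est.ci_low, est.beta, est.ci_high))
        ax.plot([lo, hi], [y, y], color="0.3")
        ax.plot(mid, y, "s", color="C0")
    ax.axvline(1.0 if or_scale else 0.0, color="0.6", linestyle="--", lw=0.8)
    ax.set_yticks(list(ys))
    ax.set_yticklabels([f"{e.method} (n={e.n_snps})" for e in estimates])
    ax.set_xlabel("odds ratio (95% CI)" if or_scale else "log-odds effect (95% CI)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def scatter_plot(hs: HarmonizedSet, estimates: Mapping[str, MREstimate], path,
                 title: str | None = None):
    """Per-SNP effect scatter (exposure vs outcome betas, error bars) with
    one fitted line per estimator."""
    bx, sx, by, sy = hs.arrays()
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.errorbar(bx, by, xerr=1.96 * sx, yerr=1.96 * sy, fmt="o", ms=4,
                color="0.4", ecolor="0.75", elinewidth=0.8, zorder=2)
    xs = [min(0, bx.min() * 1.05), max(0, bx.max() * 1.05)]
    for i, (name, est) in enumerate(estimates.items()):
        intercept = est.extras.get("intercept", 0.0)
        ax.plot(xs, [intercept + est.beta * x for x in xs],
                label=name, color=f"C{i}", lw=1.2, zorder=3)
    ax.axhline(0, color="0.85", lw=0.6)
    ax.axvline(0, color="0.85", lw=0.6)
    ax.set_xlabel(f"SNP effect on {hs.exposure_name}")
    ax.set_ylabel(f"SNP effect on {hs.outcome_name}")
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def loo_plot(loo, full_estimate: MREstimate, path, title: str | None = None):
    """Leave-one-out forest: the IVW estimate with each SNP excluded."""
    fig, ax = plt.subplots(figsize=(6, 0.25 * len(loo) + 1.5))
    ys = range(len(loo))[::-1]
    for y, (_, row) in zip(ys, loo.iterrows()):
        lo = row["ivw_beta"] - 1.96 * row["ivw_se"]
        hi = row["ivw_beta"] + 1.96 * row["ivw_se"]
        color = "C3" if row["flagged"] else "0.3"
        ax.plot([lo, hi], [y, y], color=color)
        ax.plot(row["ivw_beta"], y, "s", ms=3, color=color)
    ax.axvline(full_estimate.beta, color="C0", linestyle="--", lw=0.8,
               label="all SNPs")
    ax.axvline(0, color="0.7", lw=0.6)
    ax.set_yticks(list(ys))
    ax.set_yticklabels(loo["snp_id_excluded"], fontsize=6)
    ax.set_xlabel("IVW log-odds effect (95% CI), one SNP removed")
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
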