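"""Sensitivity battery: heterogeneity, pleiotropy, outliers, influence, FDR.

The robustness verdict used for screening mirrors common two-sample MR
practice: a nominally significant IVW estimate is treated as robust only
when Cochran's Q (heterogeneity), the MR-Egger intercept (directional
pleiotropy) and the MR-PRESSO global test (outlying pleiotropy) all fail
to reject at the 0.05 level — i.e. all three p-values are >= 0.05, the
bound being inclusive.  Leave-one-out influence flags are reported but
advisory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .estimators import ivw, mr_egger
from .exceptions import ConfigurationError, EstimationError, ValidationError
from .sumstats import HarmonizedSet


@dataclass
class SensitivityReport:
    """Collected diagnostics for one exposure–outcome pair."""

    q_stat: float | None = None
    q_df: int | None = None
    q_pvalue: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    presso_global_p: float | None = None
    presso_outliers: list[str] = field(default_factory=list)
    presso_distortion_p: float | None = None
    presso_corrected_beta: float | None = None
    loo: pd.DataFrame | None = None
    verdict: bool | None = None

    def as_dict(self) -> dict:
        d = {
            "q_stat": self.q_stat, "q_df": self.q_df, "q_pvalue": self.q_pvalue,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_se": self.egger_intercept_se,
            "egger_intercept_p": self.egger_intercept_p,
            "presso_global_p": self.presso_global_p,
            "presso_outliers": list(self.presso_outliers),
            "presso_distortion_p": self.presso_distortion_p,
            "presso_corrected_beta": self.presso_corrected_beta,
            "verdict": self.verdict,
        }
        if self.loo is not None:
            d["loo"] = self.loo.to_dict("records")
        return d


def cochran_q(hs: HarmonizedSet, pooled_beta: float) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity test across per-SNP Wald ratios.

    Q = Σ wᵢ (ratioᵢ − pooled_beta)² with wᵢ the inverse ratio variance
    (βx²/se_out² under the first-order se); p from chi-square on k−1 df.
    """
    bx, _, by, sy = hs.arrays()
    k = len(bx)
    if k < 2:
        raise EstimationError("Cochran's Q requires >= 2 SNPs")
    ratios = by / bx
    w = (bx / sy) ** 2
    q = float(np.sum(w * (ratios - pooled_beta) ** 2))
    df = k - 1
    p = float(stats.chi2.sf(q, df))
    return q, df, p


def _loo_betas(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """IVW (fixed, through-origin) slope with each SNP left out, vectorized."""
    sxy = np.sum(w * bx * by)
    sxx = np.sum(w * bx * bx)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def mr_presso(
    hs: HarmonizedSet,
    n_sim: int = 1000,
    seed: int | None = None,
    alpha_outlier: float = 0.05,
) -> tuple[float, list[str], float | None, "object"]:
    """Simulation-based residual-sum-of-squares outlier test (MR-PRESSO style).

    The observed statistic is the weighted RSS of each SNP's outcome beta
    around its leave-one-out IVW prediction.  A null distribution is built
    from ``n_sim`` parametric draws of outcome betas about those
    predictions at their stated standard errors; the global p is the
    (add-one) fraction of simulated RSS at least as large as observed.
    Per-SNP outlier p-values use each SNP's own residual contribution
    against its simulated null, Bonferroni-corrected over SNPs; flagged
    outliers are removed and IVW re-run for the corrected estimate.  The
    distortion test compares the corrected-vs-raw shift against random
    removals of the same number of SNPs.

    Returns (global_p, outlier_snp_ids, distortion_p, corrected_estimate);
    the last two are None when no outliers are flagged.
    """
    if seed is None:
        raise EstimationError("mr_presso requires an explicit seed")
    if n_sim < 100:
        raise ConfigurationError("mr_presso needs n_sim >= 100")
    bx, _, by, sy = hs.arrays()
    k = len(bx)
    if k < 4:
        raise EstimationError("MR-PRESSO requires >= 4 SNPs")
    w = 1.0 / sy**2
    beta_loo = _loo_betas(bx, by, w)
    resid = by - beta_loo * bx
    contrib_obs = w * resid**2
    rss_obs = float(contrib_obs.sum())

    rng = np.random.default_rng(seed)
    by_sim = rng.normal(loc=beta_loo * bx, scale=sy, size=(n_sim, k))
    sxy = np.einsum("j,sj->s", w * bx, by_sim)
    sxx = float(np.sum(w * bx * bx))
    beta_loo_sim = (sxy[:, None] - (w * bx)[None, :] * by_sim) / (sxx - w * bx * bx)
    resid_sim = by_sim - beta_loo_sim * bx[None, :]
    contrib_sim = w[None, :] * resid_sim**2
    rss_sim = contrib_sim.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    p_snp = (1 + np.sum(contrib_sim >= contrib_obs[None, :], axis=0)) / (n_sim + 1)
    outlier_mask = p_snp < alpha_outlier / k
    outliers = [str(s) for s in hs.pairs.loc[outlier_mask, "snp_id"]]

    distortion_p = None
    corrected = None
    if outliers and (k - len(outliers)) >= 2:
        kept = hs.subset(~outlier_mask)
        corrected = ivw(kept, mode="multiplicative_random")
        raw = ivw(hs, mode="multiplicative_random")
        if raw.beta != 0:
            d_obs = (corrected.beta - raw.beta) / abs(raw.beta)
            n_out = len(outliers)
            n_perm = min(n_sim, 2000)
            d_null = np.empty(n_perm)
            for i in range(n_perm):
                drop = rng.choice(k, size=n_out, replace=False)
                mask = np.ones(k, bool)
                mask[drop] = False
                b = float(np.sum(w[mask] * bx[mask] * by[mask])
                          / np.sum(w[mask] * bx[mask] ** 2))
                d_null[i] = (b - raw.beta) / abs(raw.beta)
            distortion_p = float((1 + np.sum(np.abs(d_null) >= abs(d_obs)))
                                 / (n_perm + 1))
    return global_p, outliers, distortion_p, corrected


def leave_one_out(hs: HarmonizedSet, alpha: float = 0.05) -> pd.DataFrame:
    """IVW re-estimated with each SNP excluded in turn.

    Returns one row per excluded SNP (snp_id_excluded, ivw_beta, ivw_se,
    ivw_p, flagged); an exclusion is flagged when it changes the sign of
    the estimate or moves its p-value across ``alpha`` relative to the
    full-set fit.
    """
    k = hs.n_snps
    if k < 3:
        raise EstimationError("leave-one-out requires >= 3 SNPs")
    full = ivw(hs, mode="multiplicative_random")
    rows = []
    for i in range(k):
        mask = np.ones(k, bool)
        mask[i] = False
        est = ivw(hs.subset(mask), mode="multiplicative_random")
        flagged = (np.sign(est.beta) != np.sign(full.beta)) or (
            (est.pvalue < alpha) != (full.pvalue < alpha))
        rows.append({
            "snp_id_excluded": hs.pairs["snp_id"].iloc[i],
            "ivw_beta": est.beta, "ivw_se": est.se, "ivw_p": est.pvalue,
            "flagged": bool(flagged),
        })
    return pd.DataFrame(rows)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values (order-preserving)."""
    p = np.asarray(list(pvalues), float)
    if p.size == 0:
        return np.array([])
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def robustness_verdict(report: SensitivityReport) -> bool:
    """True iff heterogeneity, Egger-intercept and PRESSO global tests all
    have p >= 0.05 (inclusive).  When PRESSO removed outliers, its global
    p after removal is the one consulted (stored back in the report by
    :func:`run_sensitivity`)."""
    for name in ("q_pvalue", "egger_intercept_p", "presso_global_p"):
        if getattr(report, name) is None:
            raise ConfigurationError(f"robustness_verdict: missing {name}")
    return (report.q_pvalue >= 0.05
            and report.egger_intercept_p >= 0.05
            and report.presso_global_p >= 0.05)


def run_sensitivity(hs: HarmonizedSet, seed: int, n_sim: int = 1000,
                    alpha_outlier: float = 0.05) -> SensitivityReport:
    """Assemble the full battery for one harmonized set.

    When PRESSO flags outliers they are removed and the global test is
    re-run on the remaining SNPs; the verdict consults the post-removal p.
    Components whose SNP-count preconditions fail are left None and the
    verdict falls back to the available tests (all-available must pass).
    """
    report = SensitivityReport()
    pooled = ivw(hs, mode="fixed")
    if hs.n_snps >= 2:
        report.q_stat, report.q_df, report.q_pvalue = cochran_q(hs, pooled.beta)
    if hs.n_snps >= 3:
        egger = mr_egger(hs)
        report.egger_intercept = egger.extras["intercept"]
        report.egger_intercept_se = egger.extras["intercept_se"]
        report.egger_intercept_p = egger.extras["intercept_p"]
        report.loo = leave_one_out(hs)
    if hs.n_snps >= 4:
        gp, outliers, dp, corrected = mr_presso(
            hs, n_sim=n_sim, seed=seed, alpha_outlier=alpha_outlier)
        report.presso_outliers = outliers
        report.presso_distortion_p = dp
        if outliers and hs.n_snps - len(outliers) >= 4:
            kept = hs.subset(~hs.pairs["snp_id"].isin(outliers).to_numpy())
            gp_clean, _, _, _ = mr_presso(kept, n_sim=n_sim, seed=seed + 1,
                                          alpha_outlier=alpha_outlier)
            report.presso_global_p = gp_clean
        else:
            report.presso_global_p = gp
        if corrected is not None:
            report.presso_corrected_beta = corrected.beta
    available = [p for p in (report.q_pvalue, report.egger_intercept_p,
                             report.presso_global_p) if p is not None]
    report.verdict = bool(available) and all(p >= 0.05 for p in available)
    return report
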