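"""Causal-effect estimators for two-sample MR on a harmonized SNP set.

All estimators combine per-SNP Wald ratios (outcome effect / exposure
effect).  The ratio standard error is first-order, se_out/|beta_exp|,
ignoring exposure-side sampling error (the NOME approximation); this is
defensible because the F > 10 instrument filter upstream keeps exposure
effects estimated far more precisely than the ratios themselves.

Methods:

* IVW — inverse-variance-weighted combination, equivalently weighted
  least squares of outcome on exposure betas through the origin with
  weights 1/se_out².  The multiplicative-random-effects flavour (default)
  inflates the fixed-effect se by max(1, sqrt(Q/(k−1))).
* MR-Egger — the same regression with a free intercept; a nonzero
  intercept estimates directional pleiotropy.  Inference uses a
  t-distribution with k−2 df and a residual scale bounded below by 1.
* Weighted median — consistent when ≥ 50% of instrument weight is valid;
  se by seeded parametric bootstrap.
* Simple / weighted mode — kernel-density mode of the ratios (normal
  kernel, modified-Silverman bandwidth × phi); consistent when the largest
  homogeneous cluster of instruments is valid; se by seeded bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .exceptions import EstimationError
from .sumstats import HarmonizedSet

Z95 = 1.96  # reported CIs use the conventional two-digit normal quantile

DEFAULT_N_BOOT = 1000
DEFAULT_PHI = 1.0


@dataclass
class MREstimate:
    """One method's causal estimate on the log-odds scale, with the
    exponentiated (odds-ratio) scale derived from it."""

    method: str
    beta: float
    se: float
    pvalue: float
    n_snps: int
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    or_: float = field(init=False)
    or_low: float = field(init=False)
    or_high: float = field(init=False)
    exposure: str = "exposure"
    outcome: str = "outcome"
    ci_multiplier: float = Z95
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise EstimationError(f"{self.method}: nonpositive se {self.se}")
        self.ci_low = self.beta - self.ci_multiplier * self.se
        self.ci_high = self.beta + self.ci_multiplier * self.se
        self.or_, self.or_low, self.or_high = (
            float(np.exp(self.beta)),
            float(np.exp(self.ci_low)),
            float(np.exp(self.ci_high)),
        )

    def as_dict(self) -> dict:
        d = {
            "exposure": self.exposure, "outcome": self.outcome,
            "method": self.method, "nsnp": self.n_snps,
            "beta": self.beta, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "p": self.pvalue,
            "or": self.or_, "or_low": self.or_low, "or_high": self.or_high,
        }
        d.update({f"extra_{k}": v for k, v in self.extras.items()})
        return d


def beta_to_or(beta: float, se: float) -> tuple[float, float, float]:
    """Exponentiate a log-odds effect and its 95% CI: (OR, low, high)."""
    if not se > 0:
        raise EstimationError("se must be positive")
    return (float(np.exp(beta)),
            float(np.exp(beta - Z95 * se)),
            float(np.exp(beta + Z95 * se)))


def _normal_p(beta: float, se: float) -> float:
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float, se_out: float,
               exposure: str = "exposure", outcome: str = "outcome") -> MREstimate:
    """Per-SNP causal estimate beta_out/beta_exp with first-order se."""
    if beta_exp == 0:
        raise EstimationError("Wald ratio undefined for zero exposure effect")
    beta = beta_out / beta_exp
    se = abs(se_out / beta_exp)
    return MREstimate(method="wald", beta=beta, se=se, pvalue=_normal_p(beta, se),
                      n_snps=1, exposure=exposure, outcome=outcome)


def _ratios_and_weights(hs: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    bx, _, by, sy = hs.arrays()
    if np.any(bx == 0):
        raise EstimationError("zero exposure effect among instruments")
    ratios = by / bx
    se_ratio = np.abs(sy / bx)
    return ratios, 1.0 / se_ratio**2


def _canonical_arrays(hs: HarmonizedSet):
    """Arrays sorted by snp_id, so bootstrap draws (and hence bootstrap
    ses) are invariant to the input pair order."""
    order = np.argsort(hs.pairs["snp_id"].to_numpy())
    bx, sx, by, sy = hs.arrays()
    if np.any(bx == 0):
        raise EstimationError("zero exposure effect among instruments")
    return bx[order], sx[order], by[order], sy[order]


def ivw(hs: HarmonizedSet, mode: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance-weighted estimate.

    Weighted least squares of beta_outcome on beta_exposure through the
    origin with weights 1/se_outcome².  ``mode="fixed"`` uses the
    model-based se; ``"multiplicative_random"`` (default) scales it by
    max(1, sqrt(Q/(k−1))), which reduces to the fixed-effect se when the
    ratios are homogeneous.
    """
    if mode not in ("fixed", "multiplicative_random"):
        raise EstimationError(f"unknown IVW mode {mode!r}")
    bx, _, by, sy = hs.arrays()
    k = len(bx)
    if k < 1:
        raise EstimationError("IVW requires at least one SNP")
    if mode == "multiplicative_random" and k < 2:
        mode = "fixed"  # Q undefined at k = 1
    w = 1.0 / sy**2
    sxx = float(np.sum(w * bx * bx))
    beta = float(np.sum(w * bx * by)) / sxx
    se_fixed = sxx**-0.5
    q = float(np.sum(w * (by - beta * bx) ** 2))
    scale = 1.0
    if mode == "multiplicative_random":
        scale = max(1.0, np.sqrt(q / (k - 1)))
    se = se_fixed * scale
    return MREstimate(
        method="ivw_fixed" if mode == "fixed" else "ivw_mre",
        beta=beta, se=se, pvalue=_normal_p(beta, se), n_snps=k,
        exposure=hs.exposure_name, outcome=hs.outcome_name,
        extras={"q_stat": q, "q_df": k - 1, "se_fixed": se_fixed},
    )


def mr_egger(hs: HarmonizedSet) -> MREstimate:
    """MR-Egger regression: weighted fit of beta_outcome on beta_exposure
    with a free intercept (weights 1/se_outcome²), pairs first oriented so
    every exposure beta is positive.  The slope estimates the causal
    effect; the intercept, stored in ``extras``, is the directional-
    pleiotropy test.  Inference is t-based with k−2 df and a residual
    scale bounded below by 1.
    """
    bx, _, by, sy = hs.arrays()
    k = len(bx)
    if k < 3:
        raise EstimationError("insufficient SNPs for Egger (need >= 3)")
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    x = bx * flip
    y = by * flip
    w = 1.0 / sy**2
    sw = w.sum()
    mx = float(np.sum(w * x)) / sw
    my = float(np.sum(w * y)) / sw
    sxx = float(np.sum(w * (x - mx) ** 2))
    if sxx == 0:
        raise EstimationError("Egger regression degenerate: no spread in exposure betas")
    slope = float(np.sum(w * (x - mx) * (y - my))) / sxx
    intercept = my - slope * mx
    resid = y - intercept - slope * x
    df = k - 2
    sigma2 = max(1.0, float(np.sum(w * resid**2)) / df)
    se_slope = np.sqrt(sigma2 / sxx)
    se_int = np.sqrt(sigma2 * (1.0 / sw + mx**2 / sxx))
    tq = float(stats.t.ppf(0.975, df))
    p_slope = float(2.0 * stats.t.sf(abs(slope) / se_slope, df))
    p_int = float(2.0 * stats.t.sf(abs(intercept) / se_int, df))
    return MREstimate(
        method="egger", beta=slope, se=se_slope, pvalue=p_slope, n_snps=k,
        exposure=hs.exposure_name, outcome=hs.outcome_name, ci_multiplier=tq,
        extras={"intercept": intercept, "intercept_se": se_int,
                "intercept_p": p_int, "residual_scale": np.sqrt(sigma2)},
    )


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median: the point where the cumulative
    normalized weight (measured at bin midpoints) crosses 0.5."""
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order]
    csum = (np.cumsum(w) - 0.5 * w) / w.sum()
    if csum[0] >= 0.5:
        return float(r[0])
    if csum[-1] < 0.5:
        return float(r[-1])
    below = int(np.max(np.nonzero(csum < 0.5)[0]))
    frac = (0.5 - csum[below]) / (csum[below + 1] - csum[below])
    return float(r[below] + (r[below + 1] - r[below]) * frac)


def weighted_median(hs: HarmonizedSet, n_boot: int = DEFAULT_N_BOOT,
                    seed: int | None = None) -> MREstimate:
    """Weighted-median estimate with parametric-bootstrap se.

    Ratios are ordered and weighted by inverse ratio variance; the
    estimate interpolates where the cumulative normalized weight crosses
    0.5.  The bootstrap redraws per-SNP exposure and outcome betas from
    their normal sampling distributions (seeded) and recomputes the median.
    """
    if seed is None:
        raise EstimationError("weighted_median requires an explicit seed")
    bx, sx, by, sy = _canonical_arrays(hs)
    k = len(bx)
    if k < 3:
        raise EstimationError("weighted median requires >= 3 SNPs")
    ratios = by / bx
    weights = (bx / sy) ** 2
    beta = _weighted_median(ratios, weights)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxb = rng.normal(bx, sx)
        byb = rng.normal(by, sy)
        bxb[bxb == 0] = np.finfo(float).tiny
        rb = byb / bxb
        wb = (bxb / sy) ** 2
        boots[b] = _weighted_median(rb, wb)
    se = float(np.std(boots, ddof=1))
    if se == 0:
        se = np.finfo(float).eps
    return MREstimate(
        method="weighted_median", beta=beta, se=se,
        pvalue=_normal_p(beta, se), n_snps=k,
        exposure=hs.exposure_name, outcome=hs.outcome_name,
    )


def _mode_bandwidth(ratios: np.ndarray, phi: float) -> float:
    """Modified Silverman rule: 0.9 · min(sd, normalized MAD) · k^(−1/5) · phi."""
    sd = float(np.std(ratios, ddof=1))
    mad = float(stats.median_abs_deviation(ratios, scale="normal"))
    s = min(x for x in (sd, mad) if x > 0) if (sd > 0 or mad > 0) else 0.0
    return 0.9 * s * len(ratios) ** (-0.2) * phi


def _kde_mode(ratios: np.ndarray, weights: np.ndarray, h: float,
              grid_size: int = 512, refine: bool = True) -> float:
    """Mode of the weighted normal-kernel density of the ratios.

    Coarse grid over [min, max] followed (optionally) by bounded
    scalar optimization around the best grid point.
    """
    lo, hi = float(ratios.min()), float(ratios.max())
    if h <= 0 or lo == hi:
        return lo
    wn = weights / weights.sum()

    def density(x):
        x = np.atleast_1d(np.asarray(x, float))
        z = (x[:, None] - ratios[None, :]) / h
        return np.exp(-0.5 * z**2) @ wn

    grid = np.linspace(lo, hi, grid_size)
    dens = density(grid)
    best = int(np.argmax(dens))
    if not refine:
        return float(grid[best])
    a = grid[max(best - 1, 0)]
    b = grid[min(best + 1, grid_size - 1)]
    res = optimize.minimize_scalar(lambda x: -density(x)[0], bounds=(a, b),
                                   method="bounded",
                                   options={"xatol": 1e-10})
    return float(res.x)


def mode_estimate(hs: HarmonizedSet, weighted: bool = True,
                  phi: float = DEFAULT_PHI, n_boot: int = DEFAULT_N_BOOT,
                  seed: int | None = None) -> MREstimate:
    """Mode-based estimate: the kernel-density mode of the Wald ratios.

    ``weighted=True`` weights each SNP's kernel by inverse ratio variance
    (weighted mode); ``False`` weights equally (simple mode).  Bandwidth is
    ``phi`` times a modified Silverman rule on the ratios.  When the
    bandwidth degenerates (all ratios identical) the common ratio is
    returned.  se by seeded parametric bootstrap.
    """
    if seed is None:
        raise EstimationError("mode_estimate requires an explicit seed")
    bx, sx, by, sy = _canonical_arrays(hs)
    k = len(bx)
    if k < 3:
        raise EstimationError("mode estimators require >= 3 SNPs")
    ratios = by / bx
    weights = (bx / sy) ** 2 if weighted else np.ones(k)
    h = _mode_bandwidth(ratios, phi)
    beta = _kde_mode(ratios, weights, h)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxb = rng.normal(bx, sx)
        byb = rng.normal(by, sy)
        bxb[bxb == 0] = np.finfo(float).tiny
        rb = byb / bxb
        wb = (bxb / sy) ** 2 if weighted else np.ones(k)
        hb = _mode_bandwidth(rb, phi)
        boots[b] = _kde_mode(rb, wb, hb, grid_size=256, refine=False)
    se = float(np.std(boots, ddof=1))
    if se == 0:
        se = np.finfo(float).eps
    return MREstimate(
        method="weighted_mode" if weighted else "simple_mode",
        beta=beta, se=se, pvalue=_normal_p(beta, se), n_snps=k,
        exposure=hs.exposure_name, outcome=hs.outcome_name,
    )


ALL_METHODS = ("ivw_mre", "egger", "weighted_median", "simple_mode", "weighted_mode")


def run_all_methods(hs: HarmonizedSet, seed: int, n_boot: int = DEFAULT_N_BOOT,
                    phi: float = DEFAULT_PHI,
                    include_bootstrap: bool = True) -> dict[str, MREstimate]:
    """Run the five-method battery, skipping methods whose SNP-count
    preconditions fail.  ``include_bootstrap=False`` restricts to the
    closed-form estimators (IVW flavours and Egger), which is what bulk
    screening needs."""
    out: dict[str, MREstimate] = {}
    out["ivw_mre"] = ivw(hs, mode="multiplicative_random")
    out["ivw_fixed"] = ivw(hs, mode="fixed")
    if hs.n_snps >= 3:
        out["egger"] = mr_egger(hs)
        if include_bootstrap:
            out["weighted_median"] = weighted_median(hs, n_boot=n_boot, seed=seed)
            out["simple_mode"] = mode_estimate(hs, weighted=False, phi=phi,
                                               n_boot=n_boot, seed=seed + 1)
            out["weighted_mode"] = mode_estimate(hs, weighted=True, phi=phi,
                                                 n_boot=n_boot, seed=seed + 2)
    return out
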