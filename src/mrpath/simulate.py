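"""Synthetic GWAS summary statistics with known mediation structure.

The generator emulates the statistical skeleton of a two-sample MR
mediation study: an exposure GWAS, a mediator (metabolite) GWAS, and a
binary-outcome GWAS on the log-odds scale, estimated in three mutually
independent samples.  The causal model is linear and additive:

    mediator = alpha · exposure
    outcome  = theta · exposure + gamma · mediator   (log-odds scale)

so a SNP with true exposure effect b has marginal effects alpha·b on the
mediator and (theta + alpha·gamma)·b on the outcome; the true total
effect is theta + alpha·gamma and the true mediated proportion is
alpha·gamma / (theta + alpha·gamma).  A second panel of SNPs instruments
the mediator directly (effects m, hence gamma·m on the outcome, none on
the exposure), which is what two-step mediation needs for its second leg.

Summary statistics are generated analytically rather than from
individual-level genotypes: the estimated beta for each SNP is drawn as
Normal(true marginal effect, se), with se the standard single-SNP
regression value 1/sqrt(2·MAF·(1−MAF)·N) for quantitative traits, divided
by sqrt(prevalence·(1−prevalence)) for the binary outcome (the usual
linear-approximation scaling of a log-odds GWAS se).  A configurable
fraction of exposure instruments receives an additional direct
(pleiotropic) outcome effect.  Optional LD blocks give consecutive SNPs a
common squared correlation and correspondingly attenuated marginal
effects, and an explicit LD matrix is emitted for the clumping stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .instruments import LDMatrix
from .mediation import PUBLISHED_PATHWAYS, write_replay_table
from .sumstats import DEFAULT_COLUMN_MAP

_NONPALINDROMIC_PAIRS = (("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"),
                         ("A", "C"), ("C", "A"), ("G", "T"), ("T", "G"))
_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))


@dataclass
class SimulationConfig:
    """Ground-truth parameters for one synthetic study.

    Defaults describe a well-powered idealized study: 50 exposure and 50
    mediator instruments with per-allele effects large enough to clear
    genome-wide significance at the stated sample sizes, 200,000
    participants per study, and a 10% outcome prevalence.
    """

    n_snps: int = 50                      # exposure instruments
    n_snps_mediator: int = 50             # direct mediator instruments
    maf_range: tuple[float, float] = (0.1, 0.5)
    beta_exposure_range: tuple[float, float] = (0.05, 0.15)   # |effect| magnitudes
    beta_mediator_range: tuple[float, float] = (0.05, 0.15)
    n_exposure: int = 200_000
    n_mediator: int = 200_000
    n_outcome: int = 200_000
    theta: float = 0.1                    # direct exposure→outcome (log-odds)
    alpha: float = 0.5                    # exposure→mediator
    gamma: float = 0.4                    # mediator→outcome (log-odds)
    pleiotropy_frac: float = 0.0          # fraction of invalid exposure instruments
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    outcome_prevalence: float = 0.1
    palindromic_frac: float = 0.0         # fraction of strand-ambiguous variants
    ld_blocks: tuple[int, float] | None = None   # (block size, within-block r2)
    seed: int = 0

    def validate(self) -> None:
        def fail(name, why):
            raise ConfigurationError(f"SimulationConfig.{name}: {why}")
        if self.n_snps < 1:
            fail("n_snps", "must be >= 1")
        if self.n_snps_mediator < 0:
            fail("n_snps_mediator", "must be >= 0")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            fail("maf_range", "must satisfy 0 < low <= high <= 0.5")
        for name in ("n_exposure", "n_mediator", "n_outcome"):
            if getattr(self, name) <= 2:
                fail(name, "must exceed 2")
        if not (0 <= self.pleiotropy_frac < 1):
            fail("pleiotropy_frac", "must lie in [0, 1)")
        if not (0 < self.outcome_prevalence < 1):
            fail("outcome_prevalence", "must lie in (0, 1)")
        if not (0 <= self.palindromic_frac <= 1):
            fail("palindromic_frac", "must lie in [0, 1]")
        if self.ld_blocks is not None:
            size, r2 = self.ld_blocks
            if size < 1 or not (0 <= r2 <= 1):
                fail("ld_blocks", "need block size >= 1 and r2 in [0, 1]")
        import warnings
        if self.pleiotropy_frac >= 0.5:
            warnings.warn("pleiotropy_frac >= 0.5 breaks weighted-median validity",
                          stacklevel=2)


@dataclass
class SyntheticTruth:
    """Ground truth for recovery testing."""

    theta: float
    alpha: float
    gamma: float
    total_effect: float
    mediated_proportion_true: float
    beta_exposure_true: list[float]
    beta_mediator_true: list[float]
    beta_outcome_true: list[float]
    pleiotropy: list[float]
    exposure_snps: list[str]
    mediator_snps: list[str]

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticStudy:
    """Generated sumstats for the three studies plus the generating truth."""

    exposure: pd.DataFrame
    mediator: pd.DataFrame
    outcome: pd.DataFrame
    truth: SyntheticTruth
    ld: LDMatrix
    config: SimulationConfig = field(repr=False, default=None)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in (("exposure", self.exposure), ("mediator", self.mediator),
                         ("outcome", self.outcome)):
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        self.ld.to_tsv(out / "ld.tsv")
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth.as_dict(), fh, indent=1, sort_keys=True)


def _sumstats_frame(snp_ids, chrom, pos, ea, oa, beta_hat, se, eaf, n) -> pd.DataFrame:
    p = 2.0 * _norm_sf(np.abs(beta_hat) / se)
    return pd.DataFrame({
        "snp": snp_ids, "chr": chrom, "pos": pos, "ea": ea, "oa": oa,
        "beta": beta_hat, "se": se, "p": p, "eaf": eaf,
        "n": np.full(len(snp_ids), n, dtype=int),
    }, columns=list(DEFAULT_COLUMN_MAP.values()))


def _norm_sf(z):
    from scipy import stats
    # floor at tiny to keep p in (0, 1] for downstream validation
    return np.maximum(stats.norm.sf(z), np.finfo(float).tiny)


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Draw one synthetic three-study dataset under ``config``.

    Deterministic given ``config.seed``; the same seed reproduces the
    output byte for byte.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    m_e, m_m = config.n_snps, config.n_snps_mediator
    m = m_e + m_m

    maf = rng.uniform(*config.maf_range, size=m)
    # effect alleles are coded as the trait-increasing allele (the
    # orientation instrument tables use), so true effects are positive and
    # directional pleiotropy keeps a consistent direction under Egger's
    # positive-exposure orientation
    b_exp = rng.uniform(*config.beta_exposure_range, size=m_e)
    b_med_direct = rng.uniform(*config.beta_mediator_range, size=m_m)

    pleio = np.zeros(m_e)
    n_invalid = int(round(config.pleiotropy_frac * m_e))
    if n_invalid:
        idx = rng.choice(m_e, size=n_invalid, replace=False)
        pleio[idx] = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd,
                                size=n_invalid)

    true_exp = np.concatenate([b_exp, np.zeros(m_m)])
    true_med = np.concatenate([config.alpha * b_exp, b_med_direct])
    true_out = np.concatenate([
        (config.theta + config.alpha * config.gamma) * b_exp + pleio,
        config.gamma * b_med_direct,
    ])

    snp_ids = np.array([f"rs{i + 1:05d}" for i in range(m)])
    ld = LDMatrix.identity(list(snp_ids))
    if config.ld_blocks is not None:
        block, r2 = config.ld_blocks
        r = np.sqrt(r2)
        mat = np.eye(m)
        for start in range(0, m, block):
            stop = min(start + block, m)
            mat[start:stop, start:stop] = r2
            np.fill_diagonal(mat[start:stop, start:stop], 1.0)
            # non-lead SNPs tag the lead: attenuated marginal effects
            for arr in (true_exp, true_med, true_out):
                arr[start + 1:stop] = r * arr[start]
        ld = LDMatrix(list(snp_ids), mat)

    var_g = 2.0 * maf * (1.0 - maf)
    se_exp = 1.0 / np.sqrt(var_g * config.n_exposure)
    se_med = 1.0 / np.sqrt(var_g * config.n_mediator)
    prev = config.outcome_prevalence
    se_out = 1.0 / np.sqrt(var_g * config.n_outcome * prev * (1.0 - prev))

    bhat_exp = true_exp + rng.normal(size=m) * se_exp
    bhat_med = true_med + rng.normal(size=m) * se_med
    bhat_out = true_out + rng.normal(size=m) * se_out

    n_pal = int(round(config.palindromic_frac * m))
    pal_idx = set(rng.choice(m, size=n_pal, replace=False)) if n_pal else set()
    pair_pal = rng.integers(len(_PALINDROMIC_PAIRS), size=m)
    pair_non = rng.integers(len(_NONPALINDROMIC_PAIRS), size=m)
    ea = np.empty(m, dtype=object)
    oa = np.empty(m, dtype=object)
    for i in range(m):
        pool, j = ((_PALINDROMIC_PAIRS, pair_pal[i]) if i in pal_idx
                   else (_NONPALINDROMIC_PAIRS, pair_non[i]))
        ea[i], oa[i] = pool[j]

    chrom = (1 + np.arange(m) // 100).astype(str)
    pos = (np.arange(m) % 100) * 1_000_000 + 1

    exposure = _sumstats_frame(snp_ids, chrom, pos, ea, oa, bhat_exp, se_exp,
                               maf, config.n_exposure)
    mediator = _sumstats_frame(snp_ids, chrom, pos, ea, oa, bhat_med, se_med,
                               maf, config.n_mediator)
    outcome = _sumstats_frame(snp_ids, chrom, pos, ea, oa, bhat_out, se_out,
                              maf, config.n_outcome)

    total = config.theta + config.alpha * config.gamma
    truth = SyntheticTruth(
        theta=config.theta, alpha=config.alpha, gamma=config.gamma,
        total_effect=total,
        mediated_proportion_true=(config.alpha * config.gamma / total
                                  if total != 0 else float("nan")),
        beta_exposure_true=true_exp.tolist(),
        beta_mediator_true=true_med.tolist(),
        beta_outcome_true=true_out.tolist(),
        pleiotropy=pleio.tolist(),
        exposure_snps=snp_ids[:m_e].tolist(),
        mediator_snps=snp_ids[m_e:].tolist(),
    )
    return SyntheticStudy(exposure=exposure, mediator=mediator, outcome=outcome,
                          truth=truth, ld=ld, config=config)


def plant_outlier(outcome: pd.DataFrame, snp_index: int, n_se: float = 10.0,
                  ) -> pd.DataFrame:
    """Displace one SNP's outcome beta by ``n_se`` standard errors (a
    synthetic pleiotropic outlier for PRESSO testing); returns a copy."""
    out = outcome.copy()
    out.loc[snp_index, "beta"] = out.loc[snp_index, "beta"] + n_se * out.loc[
        snp_index, "se"]
    z = abs(out.loc[snp_index, "beta"]) / out.loc[snp_index, "se"]
    from scipy import stats
    out.loc[snp_index, "p"] = max(2 * stats.norm.sf(z), np.finfo(float).tiny)
    return out


#: pinned fixture configurations used across the test suite
FIXTURE_CONFIGS: dict[str, SimulationConfig] = {
    "clean-mediation": SimulationConfig(seed=20240101),
    # wider effect-size spread and more instruments: the Egger intercept
    # test is near-collinear with the slope when exposure betas cluster
    # away from zero, so detectable directional pleiotropy needs both
    "directional-pleiotropy": SimulationConfig(
        n_snps=100, beta_exposure_range=(0.02, 0.25),
        pleiotropy_frac=0.3, pleiotropy_mean=0.08, pleiotropy_sd=0.01,
        seed=20240102),
    "planted-outlier": SimulationConfig(n_snps=20, n_snps_mediator=0,
                                        seed=20240103),
    "null": SimulationConfig(theta=0.0, alpha=0.0, gamma=0.0, seed=20240104),
}


def make_fixture_suite(out_dir) -> dict[str, Path]:
    """Write the canonical named fixtures (clean-mediation,
    directional-pleiotropy, planted-outlier, null, published-replay) under
    ``out_dir`` with pinned seeds; returns name → directory."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {out}: {exc}") from exc
    paths: dict[str, Path] = {}
    for name, config in FIXTURE_CONFIGS.items():
        study = simulate_study(config)
        if name == "planted-outlier":
            study.outcome = plant_outlier(study.outcome, snp_index=0, n_se=10.0)
        study.write(out / name)
        paths[name] = out / name
    replay_dir = out / "published-replay"
    replay_dir.mkdir(parents=True, exist_ok=True)
    write_replay_table(PUBLISHED_PATHWAYS, replay_dir / "pathways.tsv")
    paths["published-replay"] = replay_dir
    return paths
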