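"""Two-step MR mediation: mediated effect, CI, and mediated proportion.

Given three IVW estimates —

* beta1: exposure → mediator,
* beta2: mediator → outcome,
* beta_all: total exposure → outcome effect —

the mediated (indirect) effect is the product beta1·beta2 and the mediated
proportion is beta1·beta2 / beta_all.  A proportion outside [0, 1]
indicates suppression (inconsistent mediation): the indirect pathway works
against the total effect.

Two variance pairings for the product's CI ship side by side:

* ``"delta"`` (default): the standard first-order delta method for a
  product of independent estimates, se² = beta2²·se1² + beta1²·se2².
* ``"paper_compat"``: se² = beta1²·se1² + beta2²·se2², the pairing that
  reproduces the published beverage→metabolite→chronic-renal-failure
  mediation table this package replays.  The two coincide when
  |beta1| ≈ |beta2|.

Proportion bounds divide the mediated-effect bounds by beta_all treated
as fixed (no propagation of its uncertainty, matching the replayed
table); when beta_all < 0 this reverses the bound order, and the raw
(unordered) orientation is preserved alongside an ordered form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import pandas as pd

from .estimators import MREstimate, Z95
from .exceptions import ConfigurationError, EstimationError, ValidationError

PAIRINGS = ("delta", "paper_compat")

#: CI width to se conversion for a 95% normal interval (2 × 1.96)
CI_TO_SE = 3.92


class MediatedEffect(NamedTuple):
    effect: float
    se: float
    ci_low: float
    ci_high: float


class MediatedProportion(NamedTuple):
    proportion: float
    ci_low_raw: float    # bounds in transformed order (may be reversed
    ci_high_raw: float   # when beta_all < 0, as published tables print them)
    ci_low: float        # ordered bounds
    ci_high: float


@dataclass
class MediationResult:
    """One mediation pathway row: the three leg estimates and the derived
    mediated effect and proportion with their CIs."""

    exposure: str
    mediator: str
    outcome: str
    beta1: float
    se1: float
    beta2: float
    se2: float
    beta_all: float
    se_all: float
    ci_pairing: str
    mediated_effect: float = field(init=False)
    me_se: float = field(init=False)
    me_ci_low: float = field(init=False)
    me_ci_high: float = field(init=False)
    mediated_proportion: float = field(init=False)
    mp_ci_low_raw: float = field(init=False)
    mp_ci_high_raw: float = field(init=False)
    mp_ci_low: float = field(init=False)
    mp_ci_high: float = field(init=False)
    suppression: bool = field(init=False)

    def __post_init__(self) -> None:
        me = mediated_effect(self.beta1, self.se1, self.beta2, self.se2,
                             pairing=self.ci_pairing)
        self.mediated_effect = me.effect
        self.me_se = me.se
        self.me_ci_low = me.ci_low
        self.me_ci_high = me.ci_high
        mp = mediated_proportion(me.effect, me.ci_low, me.ci_high, self.beta_all)
        self.mediated_proportion = mp.proportion
        self.mp_ci_low_raw = mp.ci_low_raw
        self.mp_ci_high_raw = mp.ci_high_raw
        self.mp_ci_low = mp.ci_low
        self.mp_ci_high = mp.ci_high
        # mediated effect opposing the total effect = suppression
        self.suppression = self.mediated_proportion < 0

    def as_dict(self) -> dict:
        return {
            "exposure": self.exposure, "mediator": self.mediator,
            "outcome": self.outcome,
            "beta1": self.beta1, "se1": self.se1,
            "beta2": self.beta2, "se2": self.se2,
            "beta_all": self.beta_all, "se_all": self.se_all,
            "mediated_effect": self.mediated_effect,
            "me_ci_low": self.me_ci_low, "me_ci_high": self.me_ci_high,
            "mediated_proportion_pct": 100.0 * self.mediated_proportion,
            "mp_ci_low_pct": 100.0 * self.mp_ci_low_raw,
            "mp_ci_high_pct": 100.0 * self.mp_ci_high_raw,
            "ci_pairing": self.ci_pairing,
            "suppression": self.suppression,
        }


def mediated_effect(beta1: float, se1: float, beta2: float, se2: float,
                    pairing: str = "delta") -> MediatedEffect:
    """Product-of-coefficients mediated effect beta1·beta2 with 95% CI.

    ``pairing`` selects the variance formula (module docstring); the CI is
    effect ± 1.96·se.
    """
    if not (se1 > 0 and se2 > 0):
        raise ValidationError("mediated_effect requires positive standard errors")
    if pairing not in PAIRINGS:
        raise ConfigurationError(f"unknown CI pairing {pairing!r}")
    effect = beta1 * beta2
    if pairing == "delta":
        var = beta2**2 * se1**2 + beta1**2 * se2**2
    else:  # paper_compat
        var = beta1**2 * se1**2 + beta2**2 * se2**2
    se = var**0.5
    return MediatedEffect(effect=effect, se=se,
                          ci_low=effect - Z95 * se, ci_high=effect + Z95 * se)


def mediated_proportion(effect: float, me_ci_low: float, me_ci_high: float,
                        beta_all: float) -> MediatedProportion:
    """Mediated proportion effect/beta_all with bounds scaled by 1/beta_all.

    beta_all is treated as fixed.  The raw bounds keep the transformed
    order (reversed when beta_all < 0, as published tables print them);
    ordered bounds are provided alongside.
    """
    if beta_all == 0:
        raise EstimationError("mediated proportion undefined for beta_all = 0")
    prop = effect / beta_all
    lo_raw = me_ci_low / beta_all
    hi_raw = me_ci_high / beta_all
    return MediatedProportion(
        proportion=prop, ci_low_raw=lo_raw, ci_high_raw=hi_raw,
        ci_low=min(lo_raw, hi_raw), ci_high=max(lo_raw, hi_raw),
    )


def two_step_mediation(step1: MREstimate, step2: MREstimate, total: MREstimate,
                       pairing: str = "delta") -> MediationResult:
    """Assemble a mediation row from three MR estimates.

    ``step1`` is exposure→mediator, ``step2`` mediator→outcome, ``total``
    exposure→outcome; their trait names must chain consistently.
    """
    if step1.outcome != step2.exposure:
        raise ConfigurationError(
            f"pathway mismatch: step1 outcome {step1.outcome!r} != "
            f"step2 exposure {step2.exposure!r}")
    if step1.exposure != total.exposure:
        raise ConfigurationError(
            f"pathway mismatch: step1 exposure {step1.exposure!r} != "
            f"total exposure {total.exposure!r}")
    if step2.outcome != total.outcome:
        raise ConfigurationError(
            f"pathway mismatch: step2 outcome {step2.outcome!r} != "
            f"total outcome {total.outcome!r}")
    return MediationResult(
        exposure=step1.exposure, mediator=step1.outcome, outcome=total.outcome,
        beta1=step1.beta, se1=step1.se,
        beta2=step2.beta, se2=step2.se,
        beta_all=total.beta, se_all=total.se,
        ci_pairing=pairing,
    )


def se_from_ci(ci_low: float, ci_high: float) -> float:
    """Back-derive a normal-theory se from a printed 95% CI: width / 3.92."""
    if ci_high <= ci_low:
        raise ValidationError("ci_high must exceed ci_low")
    return (ci_high - ci_low) / CI_TO_SE


#: Published IVW estimates for the six beverage → metabolite → chronic
#: renal failure pathways this package replays: per leg, the log-odds
#: beta and its printed 95% CI.  "O/P ratio" is the ornithine-to-phosphate
#: ratio; "MCS" is 3-methyl catechol sulfate.
PUBLISHED_PATHWAYS: tuple[dict, ...] = (
    {
        "exposure": "Alcohol consumption", "mediator": "O/P ratio",
        "outcome": "CRF",
        "beta1": -0.1822, "ci1": (-0.3431, -0.0213),
        "beta2": -0.1823, "ci2": (-0.2830, -0.0816),
        "beta_all": 0.2429, "ci_all": (0.0453, 0.4405),
    },
    {
        "exposure": "Alcohol consumption", "mediator": "X-23,655",
        "outcome": "CRF",
        "beta1": -0.1948, "ci1": (-0.3765, -0.0130),
        "beta2": 0.1119, "ci2": (0.0317, 0.1920),
        "beta_all": 0.2429, "ci_all": (0.0453, 0.4405),
    },
    {
        "exposure": "Tea consumption", "mediator": "3-methyl catechol sulfate",
        "outcome": "CRF",
        "beta1": 1.6036, "ci1": (0.4504, 2.7569),
        "beta2": 0.1276, "ci2": (0.0528, 0.2024),
        "beta_all": -0.7951, "ci_all": (-1.5928, 0.0026),
    },
    {
        "exposure": "Tea consumption", "mediator": "Glutarate (C5-DC)",
        "outcome": "CRF",
        "beta1": -1.0900, "ci1": (-1.8395, -0.3405),
        "beta2": -0.1065, "ci2": (-0.1804, -0.0325),
        "beta_all": -0.7951, "ci_all": (-1.5928, 0.0026),
    },
    {
        "exposure": "Tea consumption", "mediator": "Salicylate",
        "outcome": "CRF",
        "beta1": 0.8192, "ci1": (0.0945, 1.5438),
        "beta2": -0.1215, "ci2": (-0.2054, -0.0375),
        "beta_all": -0.7951, "ci_all": (-1.5928, 0.0026),
    },
    {
        "exposure": "Tea consumption", "mediator": "X-23,655",
        "outcome": "CRF",
        "beta1": 1.3316, "ci1": (0.0535, 2.6096),
        "beta2": 0.1119, "ci2": (0.0317, 0.1920),
        "beta_all": -0.7951, "ci_all": (-1.5928, 0.0026),
    },
)


def replay_pathway(row: dict, pairing: str = "paper_compat") -> MediationResult:
    """Build a MediationResult from printed leg betas and 95% CIs
    (standard errors back-derived as CI width / 3.92)."""
    return MediationResult(
        exposure=row["exposure"], mediator=row["mediator"], outcome=row["outcome"],
        beta1=row["beta1"], se1=se_from_ci(*row["ci1"]),
        beta2=row["beta2"], se2=se_from_ci(*row["ci2"]),
        beta_all=row["beta_all"], se_all=se_from_ci(*row["ci_all"]),
        ci_pairing=pairing,
    )


def replay_published_pathways(pairing: str = "paper_compat") -> list[MediationResult]:
    """Recompute all six published mediation rows from their printed leg
    estimates."""
    return [replay_pathway(row, pairing=pairing) for row in PUBLISHED_PATHWAYS]


def read_replay_table(path) -> list[dict]:
    """Read a replay TSV (exposure, mediator, outcome, beta1, ci1_low,
    ci1_high, beta2, ci2_low, ci2_high, beta_all, ci_all_low, ci_all_high)
    into replayable pathway dicts."""
    df = pd.read_csv(path, sep="\t")
    rows = []
    for r in df.to_dict("records"):
        rows.append({
            "exposure": r["exposure"], "mediator": r["mediator"],
            "outcome": r["outcome"],
            "beta1": float(r["beta1"]), "ci1": (float(r["ci1_low"]), float(r["ci1_high"])),
            "beta2": float(r["beta2"]), "ci2": (float(r["ci2_low"]), float(r["ci2_high"])),
            "beta_all": float(r["beta_all"]),
            "ci_all": (float(r["ci_all_low"]), float(r["ci_all_high"])),
        })
    return rows


def write_replay_table(rows: Sequence[dict], path) -> None:
    out = []
    for r in rows:
        out.append({
            "exposure": r["exposure"], "mediator": r["mediator"],
            "outcome": r["outcome"],
            "beta1": r["beta1"], "ci1_low": r["ci1"][0], "ci1_high": r["ci1"][1],
            "beta2": r["beta2"], "ci2_low": r["ci2"][0], "ci2_high": r["ci2"][1],
            "beta_all": r["beta_all"],
            "ci_all_low": r["ci_all"][0], "ci_all_high": r["ci_all"][1],
        })
    pd.DataFrame(out).to_csv(path, sep="\t", index=False)


def write_mediation_table(results: Sequence[MediationResult], path) -> None:
    """Write mediation rows as TSV (one row per pathway, percent-scale
    proportions, raw-orientation proportion bounds)."""
    pd.DataFrame([r.as_dict() for r in results]).to_csv(path, sep="\t", index=False)
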