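"""Study orchestration: bidirectional MR, mediator screening, mediation.

The full analysis mirrors a two-sample MR mediation study design:

1. Bidirectional MR between each exposure (beverage) and the binary
   outcome, with the five-estimator battery and the sensitivity suite in
   each direction; the reverse direction re-selects instruments from the
   outcome study.
2. A screening cascade over candidate mediators (metabolites): stage 1
   keeps mediator→outcome IVW p below a first-pass threshold (0.05),
   stage 2 tightens to a second-pass threshold (0.01), stage 3 requires
   the sensitivity verdict to pass.  BH-FDR q-values are reported for all
   stage-1 survivors but do not gate the cascade by default.
3. Mediation assembly: for each qualified mediator whose
   exposure→mediator IVW is itself significant, the three IVW legs are
   composed into a mediated effect and proportion.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .estimators import MREstimate, ivw, run_all_methods
from .exceptions import AnalysisError, ConfigurationError, ValidationError
from .instruments import (DEFAULT_F_MIN, DEFAULT_P_THRESHOLD, DEFAULT_R2_MAX,
                          DEFAULT_WINDOW_KB, LDMatrix, select_instruments)
from .mediation import MediationResult, two_step_mediation
from .sensitivity import SensitivityReport, bh_fdr, run_sensitivity
from .sumstats import (HarmonizedSet, SumStatRecord, harmonize, read_frame,
                       read_sumstats)


@dataclass
class ScreenConfig:
    """Thresholds for the mediator screening cascade."""

    p_screen_1: float = 0.05
    p_screen_2: float = 0.01
    require_sensitivity_pass: bool = True
    fdr_level: float = 0.05
    strict_fdr: bool = False   # when True, stage 1 additionally requires q < fdr_level

    def __post_init__(self) -> None:
        if not (0 < self.p_screen_2 <= self.p_screen_1 < 1):
            raise ConfigurationError(
                "ScreenConfig requires 0 < p_screen_2 <= p_screen_1 < 1")


@dataclass
class IVParams:
    """Instrument-selection thresholds shared across pipeline stages."""

    p_threshold: float = DEFAULT_P_THRESHOLD
    r2_max: float = DEFAULT_R2_MAX
    window_kb: float = DEFAULT_WINDOW_KB
    f_min: float = DEFAULT_F_MIN


@dataclass
class StudyManifest:
    """Named sumstats inputs plus instrument thresholds and seeds."""

    exposures: dict[str, str]
    outcome: dict[str, str]
    mediators: dict[str, str] = field(default_factory=dict)
    iv_params: IVParams = field(default_factory=IVParams)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "StudyManifest":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            exposures=dict(raw["exposures"]),
            outcome=dict(raw["outcome"]),
            mediators=dict(raw.get("mediators", {})),
            iv_params=IVParams(**raw.get("iv_params", {})),
            screen=ScreenConfig(**raw.get("screen", {})),
            seed=int(raw.get("seed", 0)),
        )

    def config_hash(self) -> str:
        blob = json.dumps({
            "exposures": self.exposures, "outcome": self.outcome,
            "mediators": self.mediators, "iv_params": vars(self.iv_params),
            "screen": vars(self.screen), "seed": self.seed,
        }, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class DirectionResult:
    """One direction of a bidirectional MR run."""

    estimates: dict[str, MREstimate] | None
    sensitivity: SensitivityReport | None
    harmonized: HarmonizedSet | None
    attrition: pd.DataFrame | None
    not_estimable: str | None = None


def _as_records(data) -> list[SumStatRecord]:
    if isinstance(data, pd.DataFrame):
        return read_frame(data).records
    if isinstance(data, (str, Path)):
        return read_sumstats(data).records
    return list(data)


def _mr_one_direction(
    exposure_records: Sequence[SumStatRecord],
    outcome_records: Sequence[SumStatRecord],
    ld: LDMatrix | None,
    iv_params: IVParams,
    seed: int,
    exposure_name: str,
    outcome_name: str,
    n_sim: int = 1000,
    full_battery: bool = True,
) -> DirectionResult:
    try:
        instruments, attrition = select_instruments(
            exposure_records, ld,
            p_threshold=iv_params.p_threshold, r2_max=iv_params.r2_max,
            window_kb=iv_params.window_kb, f_min=iv_params.f_min)
    except AnalysisError as exc:
        return DirectionResult(None, None, None, None, not_estimable=str(exc))
    iv_records = [i.record for i in instruments]
    try:
        hs = harmonize(iv_records, outcome_records,
                       exposure_name=exposure_name, outcome_name=outcome_name)
    except AnalysisError as exc:
        return DirectionResult(None, None, None, attrition,
                               not_estimable=str(exc))
    if hs.n_snps == 0:
        return DirectionResult(None, None, hs, attrition,
                               not_estimable="no instruments survived harmonization")
    estimates = run_all_methods(hs, seed=seed, include_bootstrap=full_battery)
    sens = None
    if hs.n_snps >= 2:
        sens = run_sensitivity(hs, seed=seed + 3, n_sim=n_sim)
    return DirectionResult(estimates=estimates, sensitivity=sens,
                           harmonized=hs, attrition=attrition)


def run_bidirectional_mr(
    exposure,
    outcome,
    exposure_ld: LDMatrix | None = None,
    outcome_ld: LDMatrix | None = None,
    iv_params: IVParams | None = None,
    seed: int = 0,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
    n_sim: int = 1000,
) -> dict[str, DirectionResult]:
    """Forward and reverse MR between two studies.

    Inputs may be record lists, DataFrames, or file paths.  The reverse
    direction re-selects instruments from the outcome study with the same
    thresholds.  A direction without selectable instruments is reported as
    not estimable rather than aborting the run.
    """
    iv_params = iv_params or IVParams()
    exp_records = _as_records(exposure)
    out_records = _as_records(outcome)
    if [r.snp_id for r in exp_records] == [r.snp_id for r in out_records] and [
            r.beta for r in exp_records] == [r.beta for r in out_records]:
        raise ValidationError("exposure and outcome studies are identical")
    forward = _mr_one_direction(exp_records, out_records, exposure_ld, iv_params,
                                seed, exposure_name, outcome_name, n_sim=n_sim)
    reverse = _mr_one_direction(out_records, exp_records, outcome_ld, iv_params,
                                seed + 7, outcome_name, exposure_name, n_sim=n_sim)
    return {"forward": forward, "reverse": reverse}


@dataclass
class ScreenResult:
    """Outcome of the mediator screening cascade."""

    qualified: list[str]
    cascade: pd.DataFrame            # stage, n_in, n_out
    table: pd.DataFrame              # per-mediator IVW stats, q-values, stages
    directions: dict[str, DirectionResult]


def screen_mediators(
    candidates: Mapping[str, object],
    outcome,
    config: ScreenConfig | None = None,
    iv_params: IVParams | None = None,
    ld: Mapping[str, LDMatrix] | None = None,
    seed: int = 0,
    n_sim: int = 500,
) -> ScreenResult:
    """Screen candidate mediators against the outcome.

    For each candidate, instruments are selected from its own GWAS and the
    mediator→outcome IVW estimated.  Stage 1 keeps IVW p < p_screen_1,
    stage 2 keeps p < p_screen_2, stage 3 keeps candidates whose
    sensitivity verdict passes (when ``require_sensitivity_pass``).
    BH-FDR q-values are computed across all candidates with an estimable
    IVW and reported for stage-1 survivors; ``strict_fdr`` additionally
    gates stage 1 on q < fdr_level.
    """
    if not candidates:
        raise ConfigurationError("screen_mediators requires at least one candidate")
    config = config or ScreenConfig()
    iv_params = iv_params or IVParams()
    out_records = _as_records(outcome)
    rows = []
    directions: dict[str, DirectionResult] = {}
    rng = np.random.default_rng(seed)
    for name in candidates:
        sub_seed = int(rng.integers(2**31 - 10))
        med_ld = ld.get(name) if ld else None
        res = _mr_one_direction(_as_records(candidates[name]), out_records,
                                med_ld, iv_params, sub_seed, name, "outcome",
                                n_sim=n_sim, full_battery=False)
        directions[name] = res
        if res.not_estimable:
            rows.append({"mediator": name, "estimable": False, "ivw_beta": np.nan,
                         "ivw_se": np.nan, "ivw_p": np.nan, "verdict": False})
            continue
        est = res.estimates["ivw_mre"]
        verdict = bool(res.sensitivity.verdict) if res.sensitivity else False
        rows.append({"mediator": name, "estimable": True, "ivw_beta": est.beta,
                     "ivw_se": est.se, "ivw_p": est.pvalue, "verdict": verdict})
    table = pd.DataFrame(rows)

    estimable = table["estimable"]
    qvals = np.full(len(table), np.nan)
    if estimable.any():
        qvals[estimable.to_numpy()] = bh_fdr(table.loc[estimable, "ivw_p"])
    table["q_value"] = qvals

    stage1 = estimable & (table["ivw_p"] < config.p_screen_1)
    if config.strict_fdr:
        stage1 &= table["q_value"] < config.fdr_level
    stage2 = stage1 & (table["ivw_p"] < config.p_screen_2)
    stage3 = stage2 & table["verdict"] if config.require_sensitivity_pass else stage2
    table["stage1_pass"] = stage1
    table["stage2_pass"] = stage2
    table["stage3_pass"] = stage3

    cascade = pd.DataFrame([
        ("candidates", len(table), int(estimable.sum())),
        ("p_screen_1", int(estimable.sum()), int(stage1.sum())),
        ("p_screen_2", int(stage1.sum()), int(stage2.sum())),
        ("sensitivity", int(stage2.sum()), int(stage3.sum())),
    ], columns=["stage", "n_in", "n_out"])
    qualified = table.loc[stage3, "mediator"].tolist()
    return ScreenResult(qualified=qualified, cascade=cascade, table=table,
                        directions=directions)


def assemble_mediation(
    exposure,
    mediators: Mapping[str, object],
    outcome,
    iv_params: IVParams | None = None,
    pairing: str = "delta",
    seed: int = 0,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
    mediator_results: Mapping[str, MREstimate] | None = None,
    p_gate: float = 0.05,
) -> tuple[list[MediationResult], pd.DataFrame]:
    """Compose mediation rows for qualified mediators.

    For each mediator: beta1 is the exposure→mediator IVW (instruments
    from the exposure study), beta2 the mediator→outcome IVW (instruments
    from the mediator study, reusable via ``mediator_results``), and
    beta_all the total exposure→outcome IVW.  A mediator enters only when
    its exposure→mediator IVW p is below ``p_gate``; exclusions are noted
    in the returned report.
    """
    iv_params = iv_params or IVParams()
    exp_records = _as_records(exposure)
    out_records = _as_records(outcome)

    total_dir = _mr_one_direction(exp_records, out_records, None, iv_params,
                                  seed, exposure_name, outcome_name,
                                  full_battery=False)
    if total_dir.not_estimable:
        raise AnalysisError(
            f"total effect not estimable: {total_dir.not_estimable}")
    total = total_dir.estimates["ivw_mre"]

    results: list[MediationResult] = []
    notes = []
    for i, (name, med_data) in enumerate(mediators.items()):
        med_records = _as_records(med_data)
        step1_dir = _mr_one_direction(exp_records, med_records, None, iv_params,
                                      seed + 11 + i, exposure_name, name,
                                      full_battery=False)
        if step1_dir.not_estimable:
            notes.append({"mediator": name, "included": False,
                          "reason": f"step1 not estimable: {step1_dir.not_estimable}"})
            continue
        step1 = step1_dir.estimates["ivw_mre"]
        if step1.pvalue >= p_gate:
            notes.append({"mediator": name, "included": False,
                          "reason": f"exposure-mediator IVW p={step1.pvalue:.3g} "
                                    f">= {p_gate}"})
            continue
        if mediator_results and name in mediator_results:
            step2 = mediator_results[name]
        else:
            step2_dir = _mr_one_direction(med_records, out_records, None,
                                          iv_params, seed + 101 + i, name,
                                          outcome_name, full_battery=False)
            if step2_dir.not_estimable:
                notes.append({"mediator": name, "included": False,
                              "reason": "step2 not estimable: "
                                        f"{step2_dir.not_estimable}"})
                continue
            step2 = step2_dir.estimates["ivw_mre"]
        results.append(two_step_mediation(step1, step2, total, pairing=pairing))
        notes.append({"mediator": name, "included": True, "reason": ""})
    report = pd.DataFrame(notes, columns=["mediator", "included", "reason"])
    return results, report


def run_study(manifest: StudyManifest, out_dir=None, n_sim: int = 1000,
              pairing: str = "delta") -> dict:
    """Run the full study from a manifest: bidirectional MR per exposure,
    mediator screening, mediation assembly; optionally write result files
    plus a provenance record (config hash, seeds, attrition)."""
    results: dict = {"bidirectional": {}, "provenance": {
        "config_hash": manifest.config_hash(), "seed": manifest.seed}}
    for name, path in manifest.exposures.items():
        results["bidirectional"][name] = run_bidirectional_mr(
            path, manifest.outcome["path"], iv_params=manifest.iv_params,
            seed=manifest.seed, exposure_name=name,
            outcome_name=manifest.outcome.get("name", "outcome"), n_sim=n_sim)
    if manifest.mediators:
        screen = screen_mediators(
            {n: p for n, p in manifest.mediators.items()},
            manifest.outcome["path"], config=manifest.screen,
            iv_params=manifest.iv_params, seed=manifest.seed + 1, n_sim=n_sim)
        results["screen"] = screen
        mediation_all: dict[str, tuple] = {}
        qualified = {n: manifest.mediators[n] for n in screen.qualified}
        for name, path in manifest.exposures.items():
            step2_map = {
                n: screen.directions[n].estimates["ivw_mre"]
                for n in screen.qualified
            }
            mediation_all[name] = assemble_mediation(
                path, qualified, manifest.outcome["path"],
                iv_params=manifest.iv_params, pairing=pairing,
                seed=manifest.seed + 2, exposure_name=name,
                outcome_name=manifest.outcome.get("name", "outcome"),
                mediator_results=step2_map)
        results["mediation"] = mediation_all
    if out_dir is not None:
        _write_outputs(results, Path(out_dir))
    return results


def _write_outputs(results: dict, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    est_rows = []
    for exp_name, directions in results["bidirectional"].items():
        for direction, res in directions.items():
            if res.estimates:
                for est in res.estimates.values():
                    est_rows.append({"direction": direction, **est.as_dict()})
            if res.sensitivity is not None:
                with open(out / f"sensitivity_{exp_name}_{direction}.json",
                          "w") as fh:
                    json.dump(res.sensitivity.as_dict(), fh, indent=1, default=str)
    pd.DataFrame(est_rows).to_csv(out / "mr_estimates.tsv", sep="\t", index=False)
    if "screen" in results:
        results["screen"].table.to_csv(out / "screen_table.tsv", sep="\t",
                                       index=False)
        results["screen"].cascade.to_csv(out / "screen_cascade.tsv", sep="\t",
                                         index=False)
    if "mediation" in results:
        rows = []
        for exp_name, (med_results, report) in results["mediation"].items():
            rows.extend(r.as_dict() for r in med_results)
            report.to_csv(out / f"mediation_report_{exp_name}.tsv", sep="\t",
                          index=False)
        pd.DataFrame(rows).to_csv(out / "mediation_table.tsv", sep="\t",
                                  index=False)
    with open(out / "provenance.json", "w") as fh:
        json.dump(results["provenance"], fh, indent=1)
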