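"""GWAS summary-statistics records: reading, writing, validation, harmonization.

The unit of input is one SNP's association summary in one study
(:class:`SumStatRecord`).  Two studies are combined into a
:class:`HarmonizedSet` whose per-SNP exposure and outcome effects refer to
the same effect allele, which is the precondition for every two-sample MR
estimator downstream.

Harmonization follows standard two-sample MR practice: the outcome record
is aligned to the exposure study's effect allele, negating the outcome beta
(and reflecting the allele frequency) when the allele labels are swapped,
and complementing alleles to resolve strand flips.  Palindromic variants
(A/T, C/G) cannot be resolved from allele labels alone; the default policy
removes them, and an allele-frequency-based inference policy is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import AnalysisError, ConfigurationError, InputError, ValidationError

NUCLEOTIDES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default header names for each logical column
DEFAULT_COLUMN_MAP = {
    "snp_id": "snp",
    "chrom": "chr",
    "pos": "pos",
    "effect_allele": "ea",
    "other_allele": "oa",
    "beta": "beta",
    "se": "se",
    "pvalue": "p",
    "eaf": "eaf",
    "n": "n",
}

_REQUIRED = ("snp_id", "chrom", "pos", "effect_allele", "other_allele",
             "beta", "se", "pvalue", "n")
_OPTIONAL = ("eaf",)


@dataclass(frozen=True)
class SumStatRecord:
    """One SNP's association summary in one study.

    ``beta`` is the additive effect per copy of ``effect_allele`` (log-odds
    for binary traits); ``eaf`` is the effect-allele frequency and may be
    missing (``None``), which blocks F-statistic computation downstream.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float | None
    n: int

    def __post_init__(self) -> None:
        for allele in (self.effect_allele, self.other_allele):
            if allele not in NUCLEOTIDES:
                raise ValidationError(
                    f"{self.snp_id}: allele {allele!r} is not a single A/C/G/T"
                )
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.snp_id}: effect and other allele identical")
        if not self.se > 0:
            raise ValidationError(f"{self.snp_id}: nonpositive se")
        if not (0 < self.pvalue <= 1):
            raise ValidationError(f"{self.snp_id}: pvalue outside (0, 1]")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise ValidationError(f"{self.snp_id}: eaf outside [0, 1]")
        if self.n <= 0:
            raise ValidationError(f"{self.snp_id}: nonpositive sample size")
        if self.pos <= 0:
            raise ValidationError(f"{self.snp_id}: nonpositive position")

    def check_pvalue_consistency(self, factor: float = 2.0) -> bool:
        """Warn when the stated p-value disagrees with the two-sided normal
        test implied by beta/se by more than ``factor``; returns consistency."""
        implied = 2.0 * stats.norm.sf(abs(self.beta) / self.se)
        lo = max(implied / factor, 0.0)
        hi = min(implied * factor, 1.0)
        # very small p-values underflow; compare on z-scale there
        if implied == 0.0:
            return True
        ok = lo <= self.pvalue <= hi
        if not ok:
            warnings.warn(
                f"{self.snp_id}: pvalue {self.pvalue:.3g} inconsistent with "
                f"beta/se-implied {implied:.3g}",
                stacklevel=2,
            )
        return ok

    @property
    def maf(self) -> float | None:
        """Minor-allele frequency, folded from eaf; ``None`` when eaf missing."""
        if self.eaf is None:
            return None
        return min(self.eaf, 1.0 - self.eaf)


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is strand-ambiguous (A/T or C/G)."""
    for allele in (effect_allele, other_allele):
        if allele not in NUCLEOTIDES:
            raise ValidationError(f"allele {allele!r} is not a single A/C/G/T")
    return COMPLEMENT[effect_allele] == other_allele


@dataclass
class ReadResult:
    """Outcome of reading a sumstats file: valid records plus a rejects
    table (snp_id, row, reason) for rows failing type or invariant checks."""

    records: list[SumStatRecord]
    rejects: pd.DataFrame

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _coerce_row(row: dict, colmap: dict[str, str]) -> SumStatRecord:
    def get(key: str):
        return row[colmap[key]]

    eaf_raw = row.get(colmap["eaf"]) if "eaf" in colmap else None
    eaf = None
    if eaf_raw is not None and not (isinstance(eaf_raw, float) and np.isnan(eaf_raw)):
        eaf = float(eaf_raw)
    return SumStatRecord(
        snp_id=str(get("snp_id")),
        chrom=str(get("chrom")),
        pos=int(get("pos")),
        effect_allele=str(get("effect_allele")).upper(),
        other_allele=str(get("other_allele")).upper(),
        beta=float(get("beta")),
        se=float(get("se")),
        pvalue=float(get("pvalue")),
        eaf=eaf,
        n=int(float(get("n"))),
    )


def read_sumstats(
    path,
    column_map: dict[str, str] | None = None,
    delimiter: str | None = None,
) -> ReadResult:
    """Read delimited GWAS summary statistics into validated records.

    ``column_map`` maps logical field names (``snp_id``, ``chrom``, ...) to
    header names; unspecified fields fall back to :data:`DEFAULT_COLUMN_MAP`.
    The delimiter is sniffed (tab, then comma) unless given; gzip input is
    handled transparently by pandas.  Rows that fail type or invariant
    checks are collected into ``rejects`` with a reason, never silently
    dropped.
    """
    colmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        unknown = set(column_map) - set(DEFAULT_COLUMN_MAP)
        if unknown:
            raise ConfigurationError(f"unknown column-map keys: {sorted(unknown)}")
        colmap.update(column_map)

    if delimiter is None:
        # sniff tab vs comma from the header so the exact (C) float parser
        # can be used; the python engine's parser is not round-trip safe
        header = pd.read_csv(path, sep="\0", nrows=1, header=None,
                             engine="python").iloc[0, 0]
        delimiter = "\t" if "\t" in str(header) else ","
    df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    if df.empty:
        raise InputError(f"{path}: no data rows")

    missing = [colmap[k] for k in _REQUIRED if colmap[k] not in df.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing mandatory columns {missing}")
    if colmap["eaf"] not in df.columns:
        colmap.pop("eaf")

    records: list[SumStatRecord] = []
    rejects: list[tuple] = []
    for idx, row in enumerate(df.to_dict("records")):
        try:
            records.append(_coerce_row(row, colmap))
        except ValidationError as exc:
            # surface the invariant name, e.g. "nonpositive se"
            reason = str(exc).split(": ", 1)[-1]
            rejects.append((row.get(colmap["snp_id"], f"row{idx}"), idx, reason))
        except (ValueError, TypeError, KeyError) as exc:
            rejects.append((row.get(colmap["snp_id"], f"row{idx}"), idx,
                            f"unparseable: {exc}"))
    rej = pd.DataFrame(rejects, columns=["snp_id", "row", "reason"])
    return ReadResult(records=records, rejects=rej)


def write_sumstats(records: Iterable[SumStatRecord], path, delimiter: str = "\t") -> None:
    """Write records in the same dialect read_sumstats reads (full float
    precision via repr, so read(write(x)) round-trips exactly)."""
    df = records_to_frame(records)
    df.to_csv(path, sep=delimiter, index=False,
              float_format=lambda v: repr(float(v)))


def records_to_frame(records: Iterable[SumStatRecord]) -> pd.DataFrame:
    rows = [
        {
            "snp": r.snp_id, "chr": r.chrom, "pos": r.pos,
            "ea": r.effect_allele, "oa": r.other_allele,
            "beta": r.beta, "se": r.se, "p": r.pvalue,
            "eaf": np.nan if r.eaf is None else r.eaf, "n": r.n,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(DEFAULT_COLUMN_MAP.values()))


def frame_to_records(df: pd.DataFrame) -> list[SumStatRecord]:
    return read_frame(df).records


def read_frame(df: pd.DataFrame, column_map: dict[str, str] | None = None) -> ReadResult:
    """Validate an in-memory sumstats DataFrame the same way as a file."""
    colmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        colmap.update(column_map)
    if colmap["eaf"] not in df.columns:
        colmap = {k: v for k, v in colmap.items() if k != "eaf"}
    records, rejects = [], []
    for idx, row in enumerate(df.to_dict("records")):
        try:
            records.append(_coerce_row(row, colmap))
        except ValidationError as exc:
            rejects.append((row.get(colmap["snp_id"], f"row{idx}"), idx,
                            str(exc).split(": ", 1)[-1]))
        except (ValueError, TypeError, KeyError) as exc:
            rejects.append((row.get(colmap["snp_id"], f"row{idx}"), idx,
                            f"unparseable: {exc}"))
    return ReadResult(records=records,
                      rejects=pd.DataFrame(rejects, columns=["snp_id", "row", "reason"]))


_PAIR_COLUMNS = [
    "snp_id", "beta_exposure", "se_exposure", "beta_outcome", "se_outcome",
    "eaf_exposure", "eaf_outcome",
]


@dataclass
class HarmonizedSet:
    """Exposure/outcome per-SNP effects aligned to a common effect allele.

    ``pairs`` is a DataFrame with columns snp_id, beta_exposure,
    se_exposure, beta_outcome, se_outcome, eaf_exposure, eaf_outcome;
    ``dropped`` records every intersection SNP excluded, with a reason.
    """

    pairs: pd.DataFrame
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in _PAIR_COLUMNS if c not in self.pairs.columns]
        if missing:
            raise ValidationError(f"HarmonizedSet pairs missing columns {missing}")
        self.pairs = self.pairs.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def n_snps(self) -> int:
        return len(self.pairs)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_exposure, se_exposure, beta_outcome, se_outcome) as float arrays."""
        p = self.pairs
        return (
            p["beta_exposure"].to_numpy(float),
            p["se_exposure"].to_numpy(float),
            p["beta_outcome"].to_numpy(float),
            p["se_outcome"].to_numpy(float),
        )

    def subset(self, mask) -> "HarmonizedSet":
        return HarmonizedSet(
            pairs=self.pairs[mask].reset_index(drop=True),
            exposure_name=self.exposure_name,
            outcome_name=self.outcome_name,
            dropped=list(self.dropped),
        )

    @classmethod
    def from_arrays(
        cls,
        beta_exposure,
        se_exposure,
        beta_outcome,
        se_outcome,
        snp_ids: Sequence[str] | None = None,
        exposure_name: str = "exposure",
        outcome_name: str = "outcome",
    ) -> "HarmonizedSet":
        """Build a set directly from aligned effect arrays (testing and
        simulation convenience; bypasses allele bookkeeping)."""
        bx = np.asarray(beta_exposure, float)
        if snp_ids is None:
            snp_ids = [f"rs{i}" for i in range(len(bx))]
        pairs = pd.DataFrame({
            "snp_id": list(snp_ids),
            "beta_exposure": bx,
            "se_exposure": np.asarray(se_exposure, float),
            "beta_outcome": np.asarray(beta_outcome, float),
            "se_outcome": np.asarray(se_outcome, float),
            "eaf_exposure": np.nan,
            "eaf_outcome": np.nan,
        })
        return cls(pairs=pairs, exposure_name=exposure_name, outcome_name=outcome_name)


def _complement_pair(ea: str, oa: str) -> tuple[str, str]:
    return COMPLEMENT[ea], COMPLEMENT[oa]


def harmonize(
    exposure: Sequence[SumStatRecord],
    outcome: Sequence[SumStatRecord],
    palindrome_policy: str = "remove",
    eaf_threshold: float = 0.08,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
) -> HarmonizedSet:
    """Align outcome effects to the exposure study's effect alleles.

    For each SNP present in both studies: identical allele labels pass
    through; swapped labels negate the outcome beta and reflect its eaf;
    strand flips are resolved by complementing the outcome alleles before
    matching.  Palindromic variants are dropped under the default
    ``"remove"`` policy, or kept under ``"infer_by_eaf"`` when both studies'
    eafs sit on the same side of 0.5 by more than ``eaf_threshold``.
    Irreconcilable allele pairs are dropped with a reason.  The union of
    retained pairs and drop records covers the full snp_id intersection.
    """
    exposure = list(exposure)
    outcome = list(outcome)
    if not exposure or not outcome:
        raise AnalysisError("harmonize requires non-empty exposure and outcome lists")
    if palindrome_policy not in ("remove", "infer_by_eaf"):
        raise ConfigurationError(f"unknown palindrome policy {palindrome_policy!r}")
    for name, recs in (("exposure", exposure), ("outcome", outcome)):
        ids = [r.snp_id for r in recs]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate snp_id in {name} records")

    out_by_id = {r.snp_id: r for r in outcome}
    rows = []
    dropped: list[tuple[str, str]] = []
    for ex in exposure:
        if ex.snp_id not in out_by_id:
            continue
        ou = out_by_id[ex.snp_id]
        exp_pair = (ex.effect_allele, ex.other_allele)

        if is_palindromic(*exp_pair):
            out_pair = (ou.effect_allele, ou.other_allele)
            if out_pair == exp_pair:
                beta_out, eaf_out = ou.beta, ou.eaf
            elif out_pair == exp_pair[::-1]:
                beta_out = -ou.beta
                eaf_out = None if ou.eaf is None else 1 - ou.eaf
            else:
                dropped.append((ex.snp_id, "incompatible alleles"))
                continue
            if palindrome_policy == "remove":
                dropped.append((ex.snp_id, "palindromic"))
                continue
            # label-aligned; allele frequency must now resolve the strand
            keep, flip = _infer_palindrome_eaf(ex.eaf, eaf_out, eaf_threshold)
            if not keep:
                dropped.append((ex.snp_id, "palindromic_ambiguous"))
                continue
            if flip:
                beta_out = -beta_out
                eaf_out = None if eaf_out is None else 1 - eaf_out
            rows.append(_pair_row(ex, ou, beta_out, eaf_out))
            continue

        out_pair = (ou.effect_allele, ou.other_allele)
        candidates = {out_pair: False, out_pair[::-1]: True}
        comp = _complement_pair(*out_pair)
        # strand flip: complemented labels, association itself unchanged
        candidates.setdefault(comp, False)
        candidates.setdefault(comp[::-1], True)
        if exp_pair not in candidates:
            dropped.append((ex.snp_id, "incompatible alleles"))
            continue
        flip = candidates[exp_pair]
        beta_out = -ou.beta if flip else ou.beta
        eaf_out = None if ou.eaf is None else (1 - ou.eaf if flip else ou.eaf)
        rows.append(_pair_row(ex, ou, beta_out, eaf_out))

    if not rows and not dropped:
        raise AnalysisError(
            f"no overlapping SNPs between {exposure_name} and {outcome_name}"
        )
    pairs = pd.DataFrame(rows, columns=_PAIR_COLUMNS)
    return HarmonizedSet(pairs=pairs, exposure_name=exposure_name,
                         outcome_name=outcome_name, dropped=dropped)


def _pair_row(ex: SumStatRecord, ou: SumStatRecord, beta_out: float,
              eaf_out: float | None) -> dict:
    return {
        "snp_id": ex.snp_id,
        "beta_exposure": ex.beta,
        "se_exposure": ex.se,
        "beta_outcome": beta_out,
        "se_outcome": ou.se,
        "eaf_exposure": np.nan if ex.eaf is None else ex.eaf,
        "eaf_outcome": np.nan if eaf_out is None else eaf_out,
    }


def _infer_palindrome_eaf(eaf_exposure: float | None, eaf_outcome: float | None,
                          eaf_threshold: float) -> tuple[bool, bool]:
    """Decide whether a label-aligned palindromic SNP is strand-resolvable.

    Returns (keep, flip).  Resolvable when both eafs are known and at least
    ``eaf_threshold`` away from 0.5; an additional strand flip is applied
    when the eafs sit on opposite sides of 0.5.
    """
    if eaf_exposure is None or eaf_outcome is None:
        return False, False
    if (abs(eaf_exposure - 0.5) <= eaf_threshold
            or abs(eaf_outcome - 0.5) <= eaf_threshold):
        return False, False
    same_side = (eaf_exposure - 0.5) * (eaf_outcome - 0.5) > 0
    return True, not same_side


def write_rejects(rejects: pd.DataFrame, path) -> None:
    """Write a rejects report as TSV with a reason column."""
    rejects.to_csv(path, sep="\t", index=False)
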