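"""Instrument selection: significance filter, greedy LD clumping, strength.

A valid MR instrument must be robustly associated with the exposure,
independent of other selected variants, and strong enough to avoid
weak-instrument bias.  The selection cascade applies, in order: a
genome-wide-significance filter (p < 5e-8 by default), removal of
strand-ambiguous palindromic variants, greedy p-value-ranked LD clumping
(r² < 0.001 within a 10,000 kb window by default), and a per-SNP strength
filter F > 10, where

    R² = 2 · (1 − MAF) · MAF · β²        (variance explained by the SNP)
    F  = R² · (N − 2) / (1 − R²)          (single-SNP F statistic)

LD is supplied as an explicit matrix (file or fixture) rather than derived
from a reference panel, so the whole cascade runs self-contained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import AnalysisError, ValidationError
from .sumstats import SumStatRecord, is_palindromic

DEFAULT_P_THRESHOLD = 5e-8
DEFAULT_R2_MAX = 0.001
DEFAULT_WINDOW_KB = 10_000
DEFAULT_F_MIN = 10.0


def compute_r2(maf: float, beta: float) -> float:
    """Variance in the exposure explained by one SNP: 2·(1−MAF)·MAF·β².

    ``maf`` must already be folded to the minor allele (use
    ``min(eaf, 1 - eaf)`` for an effect-allele frequency).
    """
    if not (0.0 <= maf <= 0.5):
        raise ValidationError(f"maf {maf} outside [0, 0.5]; fold eaf first")
    return 2.0 * (1.0 - maf) * maf * beta * beta


def compute_f(r2: float, n: int) -> float:
    """Single-SNP instrument-strength F statistic: R²·(N−2)/(1−R²)."""
    if not (0.0 <= r2 < 1.0):
        raise ValidationError(f"r2 {r2} outside [0, 1)")
    if n <= 2:
        raise ValidationError(f"sample size {n} must exceed 2")
    return r2 * (n - 2) / (1.0 - r2)


@dataclass(frozen=True)
class Instrument:
    """A retained instrument with its strength statistics."""

    record: SumStatRecord
    r2_explained: float
    f_stat: float


class LDMatrix:
    """Squared-correlation (r²) matrix over a fixed SNP ordering.

    Symmetric, unit diagonal, entries in [0, 1].
    """

    def __init__(self, snp_ids: Sequence[str], r2: np.ndarray):
        r2 = np.asarray(r2, float)
        snp_ids = list(snp_ids)
        if r2.shape != (len(snp_ids), len(snp_ids)):
            raise ValidationError("LD matrix shape does not match snp_ids")
        if not np.allclose(r2, r2.T, atol=1e-12):
            raise ValidationError("LD matrix is not symmetric")
        if not np.allclose(np.diag(r2), 1.0, atol=1e-12):
            raise ValidationError("LD matrix diagonal must be 1")
        if r2.min() < -1e-12 or r2.max() > 1 + 1e-12:
            raise ValidationError("LD r2 values must lie in [0, 1]")
        self.snp_ids = snp_ids
        self.r2 = np.clip(r2, 0.0, 1.0)
        self._index = {s: i for i, s in enumerate(snp_ids)}

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def get(self, snp_a: str, snp_b: str) -> float:
        try:
            return float(self.r2[self._index[snp_a], self._index[snp_b]])
        except KeyError as exc:
            raise AnalysisError(f"SNP {exc.args[0]!r} absent from LD matrix") from None

    @classmethod
    def identity(cls, snp_ids: Sequence[str]) -> "LDMatrix":
        return cls(snp_ids, np.eye(len(snp_ids)))

    @classmethod
    def from_tsv(cls, path) -> "LDMatrix":
        """Square format: header row of SNP ids, first column of SNP ids."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(df.columns):
            raise ValidationError("LD matrix row and column SNP ids differ")
        return cls(list(df.columns), df.to_numpy(float))

    @classmethod
    def from_long(cls, path) -> "LDMatrix":
        """Long format: columns snp_a, snp_b, r2; unlisted pairs are 0."""
        df = pd.read_csv(path, sep="\t")
        ids = sorted(set(df["snp_a"]) | set(df["snp_b"]))
        idx = {s: i for i, s in enumerate(ids)}
        mat = np.eye(len(ids))
        for a, b, r in zip(df["snp_a"], df["snp_b"], df["r2"]):
            mat[idx[a], idx[b]] = r
            mat[idx[b], idx[a]] = r
        return cls(ids, mat)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.r2, index=self.snp_ids, columns=self.snp_ids).to_csv(
            path, sep="\t")


def clump(
    records: Sequence[SumStatRecord],
    ld: LDMatrix | None,
    r2_max: float = DEFAULT_R2_MAX,
    window_kb: float = DEFAULT_WINDOW_KB,
) -> list[SumStatRecord]:
    """Greedy p-value-ranked clumping to independent index SNPs.

    Candidates are visited in ascending (p, snp_id) order — the tie-break
    makes the output invariant to input permutation — and accepted iff
    their r² with every already-accepted SNP on the same chromosome within
    ``window_kb`` is below ``r2_max``.  ``ld=None`` declares the input
    pre-pruned (all pairwise r² treated as 0).
    """
    ordered = sorted(records, key=lambda r: (r.pvalue, r.snp_id))
    if ld is not None:
        missing = [r.snp_id for r in ordered if r.snp_id not in ld]
        if missing:
            raise AnalysisError(f"SNPs absent from LD matrix: {missing}")
    accepted: list[SumStatRecord] = []
    window_bp = window_kb * 1000.0
    for cand in ordered:
        ok = True
        if ld is not None:
            for kept in accepted:
                if kept.chrom != cand.chrom:
                    continue
                if abs(kept.pos - cand.pos) > window_bp:
                    continue
                if ld.get(cand.snp_id, kept.snp_id) >= r2_max:
                    ok = False
                    break
        if ok:
            accepted.append(cand)
    return accepted


def select_instruments(
    records: Sequence[SumStatRecord],
    ld: LDMatrix | None = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    r2_max: float = DEFAULT_R2_MAX,
    window_kb: float = DEFAULT_WINDOW_KB,
    f_min: float = DEFAULT_F_MIN,
) -> tuple[list[Instrument], pd.DataFrame]:
    """Full instrument-selection cascade with per-stage attrition counts.

    Stages: significance filter → palindrome removal → LD clumping → R²/F
    computation → weak-instrument (F) filter.  Returns the retained
    instruments and an attrition table (stage, n_in, n_out).  Raises
    :class:`AnalysisError` carrying the attrition report when nothing
    survives.  SNPs with missing eaf cannot have R²/F computed and are
    dropped at the strength stage with a warning embedded in the report.
    """
    attrition: list[tuple[str, int, int]] = []
    stage = list(records)

    sig = [r for r in stage if r.pvalue < p_threshold]
    attrition.append(("significance", len(stage), len(sig)))

    non_pal = [r for r in sig if not is_palindromic(r.effect_allele, r.other_allele)]
    attrition.append(("palindrome_removal", len(sig), len(non_pal)))

    clumped = clump(non_pal, ld, r2_max=r2_max, window_kb=window_kb) if non_pal else []
    attrition.append(("clumping", len(non_pal), len(clumped)))

    with_eaf = [r for r in clumped if r.eaf is not None]
    attrition.append(("strength_computable", len(clumped), len(with_eaf)))

    instruments = []
    for r in with_eaf:
        r2 = compute_r2(r.maf, r.beta)
        instruments.append(Instrument(record=r, r2_explained=r2,
                                      f_stat=compute_f(r2, r.n)))
    strong = [i for i in instruments if i.f_stat > f_min]
    attrition.append(("f_filter", len(with_eaf), len(strong)))

    report = pd.DataFrame(attrition, columns=["stage", "n_in", "n_out"])
    if not strong:
        raise AnalysisError(
            "0 instruments survived selection; attrition:\n"
            + report.to_string(index=False)
        )
    return strong, report


def mean_f(instruments: Sequence[Instrument]) -> float:
    """Mean per-SNP F across retained instruments (reported alongside
    per-SNP values; conventions differ between studies)."""
    return float(np.mean([i.f_stat for i in instruments]))
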