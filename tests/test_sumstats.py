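"""I/O, validation and allele-harmonization behaviour."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrpath.exceptions import (AnalysisError, ConfigurationError, InputError,
                               ValidationError)
from mrpath.sumstats import (HarmonizedSet, SumStatRecord, harmonize,
                             is_palindromic, read_sumstats, write_sumstats)


def rec(snp="rs1", chrom="1", pos=1000, ea="A", oa="G", beta=0.1, se=0.01,
        p=1e-10, eaf=0.3, n=10000):
    return SumStatRecord(snp_id=snp, chrom=chrom, pos=pos, effect_allele=ea,
                         other_allele=oa, beta=beta, se=se, pvalue=p, eaf=eaf,
                         n=n)


class TestRecordValidation:
    @pytest.mark.parametrize("kwargs,msg", [
        (dict(se=0.0), "nonpositive se"),
        (dict(se=-1.0), "nonpositive se"),
        (dict(p=0.0), "pvalue"),
        (dict(p=1.5), "pvalue"),
        (dict(eaf=1.2), "eaf"),
        (dict(ea="G", oa="G"), "identical"),
        (dict(ea="N"), "A/C/G/T"),
        (dict(n=0), "sample size"),
    ])
    def test_invariant_violations_rejected(self, kwargs, msg):
        with pytest.raises(ValidationError, match=msg):
            rec(**kwargs)

    def test_missing_eaf_allowed_and_blocks_maf(self):
        r = rec(eaf=None)
        assert r.maf is None

    def test_maf_folds_eaf(self):
        assert rec(eaf=0.8).maf == pytest.approx(0.2)

    def test_pvalue_consistency_warns_outside_factor_two(self):
        # beta/se = 10 implies p ~ 1.5e-23; a stated p of 0.5 is inconsistent
        r = rec(beta=0.1, se=0.01, p=0.5)
        with pytest.warns(UserWarning, match="inconsistent"):
            assert not r.check_pvalue_consistency()
        ok = rec(beta=0.1, se=0.05, p=2 * 0.02275)  # exact two-sided normal p
        assert ok.check_pvalue_consistency()


class TestPalindromes:
    def test_enumeration_over_all_ordered_pairs(self):
        true_pairs = {p for p in itertools.permutations("ACGT", 2)
                      if is_palindromic(*p)}
        assert true_pairs == {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

    def test_invalid_nucleotide_rejected(self):
        with pytest.raises(ValidationError):
            is_palindromic("A", "U")


class TestReadWrite:
    def _frame(self):
        return pd.DataFrame({
            "snp": ["rs1", "rs2", "rs3"], "chr": ["1", "1", "2"],
            "pos": [100, 200, 300], "ea": ["A", "C", "G"],
            "oa": ["G", "T", "A"], "beta": [0.1, -0.2, 0.05],
            "se": [0.01, 0.02, 0.01], "p": [1e-10, 1e-8, 1e-6],
            "eaf": [0.3, 0.4, 0.2], "n": [1000, 1000, 1000],
        })

    def test_well_formed_file(self, tmp_path):
        path = tmp_path / "s.tsv"
        self._frame().to_csv(path, sep="\t", index=False)
        res = read_sumstats(path)
        assert len(res.records) == 3 and res.rejects.empty

    def test_nonpositive_se_row_rejected_with_reason(self, tmp_path):
        df = self._frame()
        df.loc[1, "se"] = 0.0
        path = tmp_path / "s.tsv"
        df.to_csv(path, sep="\t", index=False)
        res = read_sumstats(path)
        assert len(res.records) == 2
        assert list(res.rejects["reason"]) == ["nonpositive se"]

    def test_unparseable_numeric_rejected_not_fatal(self, tmp_path):
        df = self._frame().astype({"beta": object})
        df.loc[2, "beta"] = "xx"
        path = tmp_path / "s.tsv"
        df.to_csv(path, sep="\t", index=False)
        res = read_sumstats(path)
        assert len(res.records) == 2
        assert res.rejects["reason"].str.contains("unparseable").all()

    def test_missing_mandatory_column_is_configuration_error(self, tmp_path):
        df = self._frame().drop(columns=["se"])
        path = tmp_path / "s.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ConfigurationError, match="se"):
            read_sumstats(path)

    def test_empty_file_is_input_error(self, tmp_path):
        path = tmp_path / "s.tsv"
        self._frame().head(0).to_csv(path, sep="\t", index=False)
        with pytest.raises(InputError):
            read_sumstats(path)

    def test_custom_column_map_and_comma_delimiter(self, tmp_path):
        df = self._frame().rename(columns={"snp": "rsid", "p": "pval"})
        path = tmp_path / "s.csv"
        df.to_csv(path, index=False)
        res = read_sumstats(path, column_map={"snp_id": "rsid", "pvalue": "pval"})
        assert len(res.records) == 3

    @settings(max_examples=25, deadline=None)
    @given(st.lists(
        st.tuples(st.floats(-2, 2), st.floats(0.001, 1.0),
                  st.floats(1e-30, 1.0, exclude_min=False),
                  st.floats(0, 1)),
        min_size=1, max_size=8))
    def test_round_trip_preserves_full_float_precision(self, tmp_path_factory, rows):
        recs = [rec(snp=f"rs{i}", beta=b, se=s, p=max(p, 1e-300), eaf=e)
                for i, (b, s, p, e) in enumerate(rows)]
        path = tmp_path_factory.mktemp("rt") / "x.tsv"
        write_sumstats(recs, path)
        back = read_sumstats(path).records
        assert back == recs


class TestHarmonize:
    def test_identical_alleles_pass_through(self):
        ex = [rec(snp="rs1", ea="A", oa="G", beta=0.1)]
        ou = [rec(snp="rs1", ea="A", oa="G", beta=0.2)]
        hs = harmonize(ex, ou)
        assert hs.pairs.loc[0, "beta_outcome"] == 0.2
        assert hs.dropped == []

    def test_swapped_alleles_negate_outcome_beta_and_reflect_eaf(self):
        ex = [rec(snp="rs1", ea="A", oa="G", beta=0.1, eaf=0.3)]
        ou = [rec(snp="rs1", ea="G", oa="A", beta=0.2, eaf=0.7)]
        hs = harmonize(ex, ou)
        assert hs.pairs.loc[0, "beta_outcome"] == pytest.approx(-0.2)
        assert hs.pairs.loc[0, "eaf_outcome"] == pytest.approx(0.3)

    def test_strand_flip_resolved_by_complementing(self):
        ex = [rec(snp="rs1", ea="A", oa="G", beta=0.1)]
        ou = [rec(snp="rs1", ea="T", oa="C", beta=0.2)]  # same SNP, other strand
        hs = harmonize(ex, ou)
        assert hs.pairs.loc[0, "beta_outcome"] == pytest.approx(0.2)

    def test_strand_flip_plus_swap_negates(self):
        ex = [rec(snp="rs1", ea="A", oa="G", beta=0.1)]
        ou = [rec(snp="rs1", ea="C", oa="T", beta=0.2)]
        hs = harmonize(ex, ou)
        assert hs.pairs.loc[0, "beta_outcome"] == pytest.approx(-0.2)

    def test_palindromic_removed_by_default(self):
        ex = [rec(snp="rs1", ea="A", oa="T", beta=0.1)]
        ou = [rec(snp="rs1", ea="A", oa="T", beta=0.2)]
        hs = harmonize(ex, ou)
        assert hs.n_snps == 0
        assert hs.dropped == [("rs1", "palindromic")]

    def test_palindromic_inferred_by_eaf_when_unambiguous(self):
        ex = [rec(snp="rs1", ea="A", oa="T", beta=0.1, eaf=0.1)]
        same = [rec(snp="rs1", ea="A", oa="T", beta=0.2, eaf=0.12)]
        opposite = [rec(snp="rs1", ea="A", oa="T", beta=0.2, eaf=0.9)]
        ambiguous = [rec(snp="rs1", ea="A", oa="T", beta=0.2, eaf=0.49)]
        hs = harmonize(ex, same, palindrome_policy="infer_by_eaf")
        assert hs.pairs.loc[0, "beta_outcome"] == pytest.approx(0.2)
        hs = harmonize(ex, opposite, palindrome_policy="infer_by_eaf")
        assert hs.pairs.loc[0, "beta_outcome"] == pytest.approx(-0.2)
        hs = harmonize(ex, ambiguous, palindrome_policy="infer_by_eaf")
        assert hs.dropped == [("rs1", "palindromic_ambiguous")]

    def test_irreconcilable_alleles_dropped_with_reason(self):
        ex = [rec(snp="rs1", ea="A", oa="G")]
        ou = [rec(snp="rs1", ea="A", oa="C")]
        hs = harmonize(ex, ou)
        assert hs.dropped == [("rs1", "incompatible alleles")]

    def test_pairs_plus_dropped_cover_intersection(self):
        ex = [rec(snp="rs1", ea="A", oa="G"), rec(snp="rs2", ea="A", oa="T"),
              rec(snp="rs3", ea="C", oa="T"), rec(snp="rs9", ea="A", oa="G")]
        ou = [rec(snp="rs1", ea="A", oa="G"), rec(snp="rs2", ea="A", oa="T"),
              rec(snp="rs3", ea="A", oa="G"), rec(snp="rs4", ea="A", oa="G")]
        hs = harmonize(ex, ou)
        covered = set(hs.pairs["snp_id"]) | {s for s, _ in hs.dropped}
        assert covered == {"rs1", "rs2", "rs3"}  # full intersection

    def test_empty_intersection_raises(self):
        with pytest.raises(AnalysisError):
            harmonize([rec(snp="rs1")], [rec(snp="rs2")])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            harmonize([rec(snp="rs1"), rec(snp="rs1")], [rec(snp="rs1")])

    def test_idempotence(self):
        """Re-harmonizing already-aligned records changes nothing."""
        ex = [rec(snp=f"rs{i}", ea="A", oa="G", beta=0.1 * i, p=1e-9)
              for i in range(1, 5)]
        ou = [rec(snp=f"rs{i}", ea="A", oa="G", beta=0.05 * i, p=1e-4)
              for i in range(1, 5)]
        once = harmonize(ex, ou)
        # rebuild outcome records from the harmonized orientation
        ou2 = [rec(snp=s, ea="A", oa="G", beta=b, p=1e-4)
               for s, b in zip(once.pairs["snp_id"], once.pairs["beta_outcome"])]
        twice = harmonize(ex, ou2)
        pd.testing.assert_series_equal(once.pairs["beta_outcome"],
                                       twice.pairs["beta_outcome"])

    def test_wald_ratio_invariant_under_outcome_allele_flip(self):
        """Flipping the outcome study's effect allele (with beta negation)
        leaves every per-SNP ratio beta_out/beta_exp unchanged."""
        ex = [rec(snp="rs1", ea="A", oa="G", beta=0.1)]
        ou = [rec(snp="rs1", ea="A", oa="G", beta=0.2, eaf=0.3)]
        ou_flipped = [rec(snp="rs1", ea="G", oa="A", beta=-0.2, eaf=0.7)]
        r1 = harmonize(ex, ou).pairs
        r2 = harmonize(ex, ou_flipped).pairs
        assert (r1["beta_outcome"] / r1["beta_exposure"]).iloc[0] == pytest.approx(
            (r2["beta_outcome"] / r2["beta_exposure"]).iloc[0])


def test_harmonized_set_requires_pair_columns():
    with pytest.raises(ValidationError, match="missing columns"):
        HarmonizedSet(pairs=pd.DataFrame({"snp_id": ["rs1"]}))
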