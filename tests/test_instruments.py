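"""Instrument selection, clumping and harmonization rules."""

import numpy as np
import pandas as pd
import pytest

from drugmr.instruments import (InstrumentSet, build_ldlc_specific_ivs,
                                clump_certificate, f_statistic, harmonize,
                                harmonized_to_parts, maf_filter,
                                remove_region_overlaps, select_cis_instruments,
                                select_trans_instruments)
from drugmr.sumstats import GeneRegion, LDMatrix, SummaryStats

REGION = GeneRegion("G1", "1", 1_000_000, 1_050_000)


def sumstats_from(rows, trait_id="exp"):
    t = pd.DataFrame(rows)
    defaults = {"chrom": "1", "effect_allele": "A", "other_allele": "G",
                "eaf": 0.3, "se": 0.01, "n": 100000}
    for k, v in defaults.items():
        if k not in t.columns:
            t[k] = v
    if "beta" not in t.columns:
        # strong instruments by default (F >> 10)
        t["beta"] = 0.1
    return SummaryStats(trait_id, "quantitative", t)


def ld_from(ids, r):
    return LDMatrix(list(ids), np.asarray(r, dtype=float))


class TestCisSelection:
    def test_mutually_linked_trio_keeps_only_smallest_p(self):
        s = sumstats_from([
            {"snp_id": "a", "pos": 1_000_100, "pval": 1e-10},
            {"snp_id": "b", "pos": 1_000_200, "pval": 1e-9},
            {"snp_id": "c", "pos": 1_000_300, "pval": 0.9e-8},
        ])
        r = np.full((3, 3), np.sqrt(0.9))
        np.fill_diagonal(r, 1.0)
        ld = ld_from("abc", r)
        res = select_cis_instruments(s, REGION, ld)
        assert list(res.table["snp_id"]) == ["a"]
        # brute force: among all subsets with pairwise r2 <= 0.3 containing
        # the smallest-p representative chain, greedy picks {a}
        assert clump_certificate(res, res_candidates(s), ld, 0.3)

    def test_window_boundary_inclusive_at_both_ends(self):
        s = sumstats_from([
            {"snp_id": "in", "pos": REGION.end + 250_000, "pval": 1e-10},
            {"snp_id": "out", "pos": REGION.end + 250_001, "pval": 1e-10},
            {"snp_id": "in2", "pos": REGION.start - 250_000, "pval": 1e-10},
        ])
        ld = ld_from(["in", "out", "in2"], np.eye(3))
        res = select_cis_instruments(s, REGION, ld)
        assert set(res.table["snp_id"]) == {"in", "in2"}

    def test_identity_ld_retains_all_significant(self):
        s = sumstats_from([{"snp_id": f"s{i}", "pos": 1_000_000 + i,
                            "pval": 1e-9} for i in range(5)])
        res = select_cis_instruments(s, REGION, ld_from([f"s{i}" for i in range(5)], np.eye(5)))
        assert res.n_snp == 5

    def test_zero_survivors_is_status_not_exception(self):
        s = sumstats_from([{"snp_id": "a", "pos": 1_000_000, "pval": 0.5}])
        res = select_cis_instruments(s, REGION, ld_from("a", [[1.0]]))
        assert res.empty and res.status.startswith("empty")

    def test_weak_instruments_excluded_by_f_rule(self):
        s = sumstats_from([
            {"snp_id": "strong", "pos": 1_000_100, "pval": 1e-10, "beta": 0.1},
            {"snp_id": "weak", "pos": 1_000_200, "pval": 1e-10, "beta": 0.02},
        ])
        s.table.loc[1, "se"] = 0.0075  # F = (0.02/0.0075)^2 ~ 7.1 < 10
        res = select_cis_instruments(s, REGION, ld_from(["strong", "weak"], np.eye(2)))
        assert list(res.table["snp_id"]) == ["strong"]

    def test_greedy_matches_exhaustive_certificate_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            n = 8
            pos = 1_000_000 + np.arange(n) * 1000
            rho = rng.uniform(0.3, 0.95)
            r = rho ** np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
            ids = [f"s{i}" for i in range(n)]
            s = sumstats_from([{"snp_id": ids[i], "pos": int(pos[i]),
                                "pval": float(rng.uniform(1e-12, 4e-8))}
                               for i in range(n)])
            ld = ld_from(ids, r)
            res = select_cis_instruments(s, REGION, ld)
            assert clump_certificate(res, res_candidates(s), ld, 0.3)

    def test_output_invariant_to_input_row_order(self):
        rng = np.random.default_rng(1)
        n = 6
        ids = [f"s{i}" for i in range(n)]
        rows = [{"snp_id": ids[i], "pos": 1_000_000 + i * 500,
                 "pval": float(rng.uniform(1e-12, 4e-8))} for i in range(n)]
        r = 0.8 ** np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        ld = ld_from(ids, r)
        a = select_cis_instruments(sumstats_from(rows), REGION, ld)
        b = select_cis_instruments(sumstats_from(rows[::-1]), REGION, ld)
        assert list(a.table["snp_id"]) == list(b.table["snp_id"])


def res_candidates(s):
    t = s.table.rename(columns={"beta": "beta_exp", "se": "se_exp",
                                "pval": "pval"}).copy()
    return t


class TestTransSelection:
    def test_hits_beyond_window_both_retained(self):
        s = sumstats_from([
            {"snp_id": "a", "pos": 1_000_000, "pval": 1e-8},
            {"snp_id": "b", "pos": 21_000_000, "pval": 1e-7},
        ])
        ld = ld_from("ab", [[1, 0.9], [0.9, 1]])  # r2 huge but 20 Mb apart
        res = select_trans_instruments(s, ld)
        assert set(res.table["snp_id"]) == {"a", "b"}

    def test_hits_within_window_clumped_at_strict_r2(self):
        s = sumstats_from([
            {"snp_id": "a", "pos": 1_000_000, "pval": 1e-8},
            {"snp_id": "b", "pos": 2_000_000, "pval": 1e-7},
        ])
        r = np.sqrt(0.002)
        ld = ld_from("ab", [[1, r], [r, 1]])
        res = select_trans_instruments(s, ld)
        assert list(res.table["snp_id"]) == ["a"]

    def test_empty_table_gives_empty_set(self):
        s = sumstats_from([{"snp_id": "a", "pos": 1, "pval": 0.5}])
        res = select_trans_instruments(s, ld_from("a", [[1.0]]))
        assert res.empty


class TestLdlcSpecific:
    TARGETS = [GeneRegion("HMGCR", "5", 74_632_154, 74_657_929)]

    def test_snp_inside_target_window_removed(self):
        s = sumstats_from([
            {"snp_id": "inside", "chrom": "5", "pos": 74_700_000, "pval": 1e-9},
            {"snp_id": "far", "chrom": "5", "pos": 90_000_000, "pval": 1e-9},
        ])
        ld = ld_from(["inside", "far"], np.eye(2))
        res = build_ldlc_specific_ivs(s, self.TARGETS, ld)
        assert list(res.table["snp_id"]) == ["far"]
        assert res.provenance["excluded_regions"] == ["HMGCR"]

    def test_all_snps_inside_targets_gives_empty_with_status(self):
        s = sumstats_from([{"snp_id": "a", "chrom": "5", "pos": 74_650_000,
                            "pval": 1e-9}])
        res = build_ldlc_specific_ivs(s, self.TARGETS, ld_from("a", [[1.0]]))
        assert res.empty and "excluded" in res.status


class TestFilters:
    @pytest.mark.parametrize("beta,se,expected", [
        (0.1, 0.01, 100.0), (0.0, 0.01, 0.0), (-0.2, 0.02, 100.0)])
    def test_f_statistic_formula(self, beta, se, expected):
        assert f_statistic(beta, se) == pytest.approx(expected)

    def test_f_statistic_requires_positive_se(self):
        with pytest.raises(ValueError):
            f_statistic(0.1, 0.0)

    def test_f_exactly_ten_retained(self):
        # F == 10 survives the "< 10 excluded" rule
        s = sumstats_from([{"snp_id": "edge", "pos": 1_000_100, "pval": 1e-10,
                            "beta": 0.1}])
        s.table["se"] = 0.1 / np.sqrt(10)
        res = select_cis_instruments(s, REGION, ld_from(["edge"], [[1.0]]))
        assert res.n_snp == 1

    @pytest.mark.parametrize("eaf,kept", [
        (0.005, False), (0.995, False), (0.01, True), (0.5, True)])
    def test_maf_filter_folds_and_uses_strict_bound(self, eaf, kept):
        iv = InstrumentSet("e", pd.DataFrame({
            "snp_id": ["a"], "chrom": ["1"], "pos": [1], "effect_allele": ["A"],
            "other_allele": ["G"], "eaf": [eaf], "beta_exp": [0.1],
            "se_exp": [0.01], "pval_exp": [1e-9], "f_stat": [100.0]}))
        assert (maf_filter(iv).n_snp == 1) is kept


def iv_single(ea="A", oa="G", beta=0.1):
    return InstrumentSet("e", pd.DataFrame({
        "snp_id": ["rs1"], "chrom": ["1"], "pos": [100], "effect_allele": [ea],
        "other_allele": [oa], "eaf": [0.3], "beta_exp": [beta],
        "se_exp": [0.01], "pval_exp": [1e-9], "f_stat": [100.0]}))


def outcome_single(ea, oa, beta=0.2, eaf=0.3):
    return SummaryStats("out", "binary", pd.DataFrame({
        "snp_id": ["rs1"], "chrom": ["1"], "pos": [100], "effect_allele": [ea],
        "other_allele": [oa], "eaf": [eaf], "beta": [beta], "se": [0.05],
        "pval": [1e-4]}))


class TestHarmonize:
    def test_swapped_alleles_flip_beta_and_eaf(self):
        h = harmonize(iv_single("A", "G"), outcome_single("G", "A", beta=0.2, eaf=0.7))
        assert h.table.loc[0, "beta_out"] == pytest.approx(-0.2)
        assert h.table.loc[0, "eaf_out"] == pytest.approx(0.3)

    def test_strand_flip_reconciled_without_sign_change(self):
        h = harmonize(iv_single("A", "G"), outcome_single("T", "C", beta=0.2))
        assert h.table.loc[0, "beta_out"] == pytest.approx(0.2)

    def test_palindromic_removed_unconditionally(self):
        h = harmonize(iv_single("A", "T"), outcome_single("A", "T"))
        assert h.n_snp == 0 and h.dropped["palindromic"] == 1

    def test_irreconcilable_alleles_audited(self):
        h = harmonize(iv_single("A", "G"), outcome_single("A", "C"))
        assert h.n_snp == 0 and h.dropped["allele_mismatch"] == 1

    def test_missing_snp_audited_not_raised(self):
        out = outcome_single("A", "G")
        out.table["snp_id"] = ["rs_other"]
        h = harmonize(iv_single(), out)
        assert h.status.startswith("empty")
        assert h.dropped["not_in_outcome"] == 1

    def test_harmonize_idempotent_on_own_output(self):
        rng = np.random.default_rng(3)
        n = 8
        pairs = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
        rows_iv, rows_out = [], []
        for i in range(n):
            ea, oa = pairs[rng.integers(4)]
            rows_iv.append({"snp_id": f"s{i}", "chrom": "1", "pos": i + 1,
                            "effect_allele": ea, "other_allele": oa,
                            "eaf": 0.3, "beta_exp": 0.1, "se_exp": 0.01,
                            "pval_exp": 1e-9, "f_stat": 100.0})
            swap = rng.random() < 0.5
            rows_out.append({"snp_id": f"s{i}", "chrom": "1", "pos": i + 1,
                             "effect_allele": oa if swap else ea,
                             "other_allele": ea if swap else oa,
                             "eaf": 0.7 if swap else 0.3,
                             "beta": -0.2 if swap else 0.2, "se": 0.05,
                             "pval": 1e-4})
        iv = InstrumentSet("e", pd.DataFrame(rows_iv))
        out = SummaryStats("o", "binary", pd.DataFrame(rows_out))
        h1 = harmonize(iv, out)
        iv2, out2 = harmonized_to_parts(h1)
        h2 = harmonize(iv2, out2)
        pd.testing.assert_frame_equal(
            h1.table[["snp_id", "beta_exp", "beta_out", "eaf_out"]],
            h2.table[["snp_id", "beta_exp", "beta_out", "eaf_out"]])
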