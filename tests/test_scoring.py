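import numpy as np
import pandas as pd
import pytest
from itertools import combinations

from oncosubtype.io import ExpressionMatrix, GeneSetCollection, MafTable
from oncosubtype import scoring
from oncosubtype.scoring import (APM_GENES, INFG_GENES, TIS_CELL_TYPES,
                                 apm_score, checkpoint_genes, compute_tmb,
                                 cyt_score, estimate_scores, iis_tis,
                                 pearson_strong, signature_mean,
                                 ssgsea_enrichment, wilcoxon_test)


def ssgsea_oracle(values: pd.Series, gene_set, alpha):
    """Independent loop implementation of the single-sample score."""
    order = sorted(values.index, key=lambda g: (-values[g], g))
    n = len(order)
    ranks = {g: n - i for i, g in enumerate(order)}  # top gene -> rank n
    in_set = set(gene_set) & set(order)
    w_sum = sum(ranks[g] ** alpha for g in in_set)
    p_in = p_out = es = 0.0
    for g in order:
        if g in in_set:
            p_in += ranks[g] ** alpha / w_sum
        else:
            p_out += 1.0 / (n - len(in_set))
        es += p_in - p_out
    return es


class TestSsgsea:
    def test_hand_fixture_top_two_genes(self):
        vals = pd.DataFrame({"s": [5.0, 4, 3, 2, 1]},
                            index=["g1", "g2", "g3", "g4", "g5"])
        res = ssgsea_enrichment(vals, GeneSetCollection({"top": ["g1", "g2"]}),
                                alpha=0.25)
        expected = ssgsea_oracle(vals["s"], ["g1", "g2"], 0.25)
        assert res["es"].loc["top", "s"] == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_oracle_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i:02d}" for i in range(30)]
        vals = pd.DataFrame(rng.random((30, 3)) * 100, index=genes,
                            columns=["a", "b", "c"])
        sets = {f"set{k}": list(rng.choice(genes, size=rng.integers(3, 10),
                                           replace=False)) for k in range(4)}
        res = ssgsea_enrichment(vals, GeneSetCollection(sets), alpha=0.25)
        for name, members in sets.items():
            for s in vals.columns:
                assert res["es"].loc[name, s] == pytest.approx(
                    ssgsea_oracle(vals[s], members, 0.25), abs=1e-9)

    def test_identical_profiles_identical_scores(self):
        vals = pd.DataFrame({"a": [3.0, 1, 2], "b": [3.0, 1, 2]},
                            index=["x", "y", "z"])
        res = ssgsea_enrichment(vals, GeneSetCollection({"s": ["x", "y"]}))
        assert res["es"].loc["s", "a"] == res["es"].loc["s", "b"]

    def test_invariant_under_strictly_increasing_transform(self):
        rng = np.random.default_rng(7)
        vals = pd.DataFrame(rng.random((20, 2)) + 0.5,
                            index=[f"g{i}" for i in range(20)],
                            columns=["a", "b"])
        coll = GeneSetCollection({"s": [f"g{i}" for i in range(0, 20, 3)]})
        r1 = ssgsea_enrichment(vals, coll)
        r2 = ssgsea_enrichment(np.exp(vals * 3), coll)
        pd.testing.assert_frame_equal(r1["es"], r2["es"])

    def test_row_order_invariance(self):
        rng = np.random.default_rng(8)
        vals = pd.DataFrame(rng.random((15, 2)), index=[f"g{i}" for i in range(15)],
                            columns=["a", "b"])
        coll = GeneSetCollection({"s": ["g1", "g5", "g9"]})
        r1 = ssgsea_enrichment(vals, coll)
        r2 = ssgsea_enrichment(vals.sample(frac=1, random_state=0), coll)
        pd.testing.assert_frame_equal(r1["es"], r2["es"])

    def test_small_sets_skipped_with_warning(self):
        vals = pd.DataFrame({"a": [1.0, 2, 3]}, index=["x", "y", "z"])
        with pytest.warns(UserWarning, match="skipped"):
            res = ssgsea_enrichment(vals, GeneSetCollection({"s": ["x", "nope"]}))
        assert res["es"].empty


class TestCompositeScores:
    def test_estimate_is_exact_sum(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(40)]
        vals = pd.DataFrame(rng.random((40, 6)), index=genes,
                            columns=[f"s{i}" for i in range(6)])
        out = estimate_scores(vals, genes[:10], genes[10:25])
        assert np.array_equal(out["estimate"].to_numpy(),
                              (out["stromal"] + out["immune"]).to_numpy())

    def test_estimate_missing_overlap_errors(self):
        vals = pd.DataFrame({"a": [1.0, 2]}, index=["x", "y"])
        with pytest.raises(ValueError, match="overlap"):
            estimate_scores(vals, ["nope1", "nope2"], ["x", "y"])

    def test_iis_tis_arithmetic_and_panel(self):
        samples = ["s1", "s2"]
        cells = ["A", "B", "C", "D"]
        nes = pd.DataFrame([[0.1, 0.1], [0.2, 0.2], [0.3, 0.3], [0.4, 0.4]],
                           index=cells, columns=samples)
        out = iis_tis({"nes": nes}, adaptive_cells=["A", "B"],
                      innate_cells=["C", "D"], t_cell_sets=["A", "D"])
        assert out.loc["s1", "IIS"] == pytest.approx(0.25)
        assert out.loc["s1", "TIS"] == pytest.approx(0.25)
        assert len(TIS_CELL_TYPES) == 8
        with pytest.raises(KeyError):
            iis_tis({"nes": nes}, ["A"], ["Z"], ["A", "B"])

    def test_cyt_closed_forms_and_symmetry(self):
        vals = pd.DataFrame({"s1": [4.0, 9.0], "s2": [9.0, 4.0], "s3": [0.0, 0.0]},
                            index=["GZMA", "PRF1"])
        c0 = cyt_score(vals, offset=0.0)
        assert c0["s1"] == pytest.approx(6.0)
        assert c0["s2"] == pytest.approx(6.0)  # swap symmetry
        c = cyt_score(vals, offset=0.01)
        assert c["s3"] == pytest.approx(0.01)
        with pytest.raises(KeyError):
            cyt_score(vals.drop(index="PRF1"))

    def test_apm_minmax_endpoints_and_panel(self):
        rng = np.random.default_rng(1)
        genes = APM_GENES + [f"g{i}" for i in range(30)]
        vals = pd.DataFrame(rng.random((len(genes), 5)), index=genes,
                            columns=[f"s{i}" for i in range(5)])
        apm = apm_score(vals)
        assert apm.min() == pytest.approx(0.0)
        assert apm.max() == pytest.approx(1.0)
        assert ((apm >= 0) & (apm <= 1)).all()

    def test_apm_degenerate_cohorts_error(self):
        vals = pd.DataFrame({"only": np.arange(20.0)},
                            index=APM_GENES + ["x", "y"])
        with pytest.raises(ValueError, match="single-sample"):
            apm_score(vals)
        same = pd.concat([vals["only"]] * 3, axis=1)
        same.columns = ["a", "b", "c"]
        with pytest.raises(ValueError, match="zero range"):
            apm_score(same)

    def test_signature_gene_lists(self):
        assert INFG_GENES == ["CXCL10", "CXCL9", "HLA-DRA", "IDO1", "IFNG", "STAT1"]
        assert checkpoint_genes() == ["CD274", "CTLA4", "HAVCR2", "LAG3",
                                      "PDCD1", "PDCD1LG2"]
        assert "HAVCR" in checkpoint_genes(literal=True)

    def test_signature_mean_single_gene_and_monotonicity(self):
        vals = pd.DataFrame({"s1": [3.0], "s2": [15.0]}, index=["CD8A"])
        sig = signature_mean(vals, ["CD8A"])
        assert sig["s1"] == pytest.approx(np.log2(4.0))
        doubled = signature_mean(vals * 2, ["CD8A"])
        assert ((doubled - sig) < 1).all()
        assert (doubled.rank() == sig.rank()).all()
        with pytest.raises(ValueError):
            signature_mean(vals, ["NOPE"])


def _maf_from(rows):
    return MafTable(pd.DataFrame(
        rows, columns=["Hugo_Symbol", "Chromosome", "Start_Position",
                       "Reference_Allele", "Tumor_Seq_Allele2",
                       "Variant_Classification", "Variant_Type",
                       "Tumor_Sample_Barcode"]))


class TestTmb:
    def test_thirtyfive_missense_over_35mb_is_one(self):
        rows = [("G", "1", i + 1, "C", "T", "Missense_Mutation", "SNP", "S1")
                for i in range(35)]
        tmb = compute_tmb(_maf_from(rows), footprint_mb=35)
        assert tmb["S1"] == pytest.approx(1.0)

    def test_silent_only_gives_zero(self):
        rows = [("G", "1", 5, "C", "T", "Silent", "SNP", "S1")]
        tmb = compute_tmb(_maf_from(rows), cohort_samples=["S1"])
        assert tmb["S1"] == 0

    def test_hand_counted_mixture(self):
        classes = (["Missense_Mutation"] * 5 + ["Silent"] * 3
                   + ["Frame_Shift_Del"] * 2)
        rows = [("G", "1", i + 1, "CAT" if c == "Frame_Shift_Del" else "C",
                 "-" if c == "Frame_Shift_Del" else "T", c,
                 "DEL" if c == "Frame_Shift_Del" else "SNP", "S1")
                for i, c in enumerate(classes)]
        tmb = compute_tmb(_maf_from(rows), footprint_mb=35)
        assert tmb["S1"] == pytest.approx(7 / 35)

    def test_absent_sample_warned_zero(self):
        rows = [("G", "1", 5, "C", "T", "Missense_Mutation", "SNP", "S1")]
        with pytest.warns(UserWarning, match="absent"):
            tmb = compute_tmb(_maf_from(rows), cohort_samples=["S1", "S2"])
        assert tmb["S2"] == 0


class TestGroupStats:
    def test_wilcoxon_exact_enumeration(self):
        res = wilcoxon_test([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        assert res["method"] == "exact"
        assert res["p"] == pytest.approx(0.1)

    def test_wilcoxon_identical_multisets(self):
        res = wilcoxon_test([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert res["p"] == pytest.approx(1.0)

    def test_wilcoxon_normal_approx_close_to_exact(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 40)
        labels = np.array(["a"] * 20 + ["b"] * 20)
        exact = wilcoxon_test(x, labels)
        assert exact["method"] == "exact"
        from scipy import stats as ss
        approx = ss.mannwhitneyu(x[:20], x[20:], alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        assert abs(exact["p"] - approx.pvalue) < 0.02

    def test_wilcoxon_empty_group_error(self):
        with pytest.raises(ValueError):
            wilcoxon_test([1, 2, 3], ["a", "a", "a"])

    def test_pearson_strong_rule(self):
        x = np.arange(20.0)
        table = pd.DataFrame({"a": x, "b": 2 * x, "c": np.cos(x)})
        out = pearson_strong(table)
        row_ab = out[(out.score_a == "a") & (out.score_b == "b")].iloc[0]
        assert row_ab["r"] == pytest.approx(1.0)
        assert bool(row_ab["strong"])

    def test_threshold_rule_excludes_weak_but_significant(self):
        # r ~ 0.45 with n large enough for p < 0.05 is still not "strong"
        rng = np.random.default_rng(12)
        for _ in range(20):
            x = rng.normal(0, 1, 300)
            y = 0.5 * x + rng.normal(0, 1, 300)
            out = pearson_strong(pd.DataFrame({"a": x, "b": y}))
            row = out.iloc[0]
            if row["p"] < 0.05 and row["r"] <= 0.5:
                assert not bool(row["strong"])
                return
        pytest.fail("no draw produced the significant-but-weak case")

    def test_pearson_matches_direct_formula(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 50), rng.normal(0, 1, 50)
        out = pearson_strong(pd.DataFrame({"a": x, "b": y}))
        r_direct = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert out.iloc[0]["r"] == pytest.approx(r_direct, abs=1e-12)

    def test_zero_variance_flagged_na(self):
        out = pearson_strong(pd.DataFrame({"a": [1.0, 1, 1], "b": [1.0, 2, 3]}))
        assert np.isnan(out.iloc[0]["r"])
        assert out.iloc[0]["strong"] is pd.NA


def test_planted_cohort_scores_favor_immune_enriched_subtype(cohort):
    """sub1 exceeds sub2 in immune score, IIS, TIS and CYT (one-sided)."""
    from oncosubtype import io
    from oncosubtype.simulate import default_config, synthetic_gene_sets

    sets = synthetic_gene_sets(default_config(seed=1))
    logv = io.log2cpm(cohort.expression)
    lab = cohort.true_labels.labels
    est = estimate_scores(logv, sets["stromal_immune"]["stromal"],
                          sets["stromal_immune"]["immune"])
    enr = ssgsea_enrichment(logv, sets["cell_types"])
    it = iis_tis(enr, scoring.ADAPTIVE_CELL_TYPES, scoring.INNATE_CELL_TYPES)
    cyt = cyt_score(cohort.expression)
    from scipy import stats as ss

    for score in (est["immune"], it["IIS"], it["TIS"], cyt):
        u = ss.mannwhitneyu(score[lab == "sub1"], score[lab == "sub2"],
                            alternative="greater")
        assert u.pvalue < 0.05
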