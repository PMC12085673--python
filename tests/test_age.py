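"""Age-association screening: correlation labels, DE rules, taxonomy,
rank lists, human presets."""

import numpy as np
import pandas as pd
import pytest

from miratlas.age import (age_contrasts, bin_human_ages, candidate_set,
                          classify_correlation, cross_sex_features,
                          differential_expression, effect_size_filter,
                          intersect_reference, rank_for_enrichment,
                          spearman_age, unique_multiple)


def _meta(regions, ages, sexes=None):
    n = len(regions)
    return pd.DataFrame({
        "region": regions,
        "age_months": ages,
        "sex": sexes or ["male"] * n,
    }, index=[f"s{i}" for i in range(n)])


class TestSpearmanAge:
    def test_perfect_monotone_r_one(self):
        meta = _meta(["r"] * 5, [3, 12, 15, 18, 21])
        expr = pd.DataFrame([[1.0, 2, 3, 4, 5]], index=["f"],
                            columns=meta.index)
        out = spearman_age(expr, meta)
        assert out.loc[0, "R"] == 1.0

    def test_constant_feature_missing(self):
        meta = _meta(["r"] * 5, [3, 12, 15, 18, 21])
        expr = pd.DataFrame([[2.0] * 5], index=["f"], columns=meta.index)
        out = spearman_age(expr, meta)
        assert np.isnan(out.loc[0, "R"])

    def test_small_stratum_skipped(self):
        meta = _meta(["r", "r", "tiny", "tiny"], [3, 12, 3, 12])
        expr = pd.DataFrame(np.ones((1, 4)), index=["f"],
                            columns=meta.index)
        out = spearman_age(expr, meta)
        assert set(out["region"]) == set()  # both strata have < 3 samples

    def test_bh_within_stratum(self):
        rng = np.random.default_rng(0)
        meta = _meta(["a"] * 10 + ["b"] * 10,
                     list(range(1, 11)) * 2)
        expr = pd.DataFrame(rng.normal(size=(8, 20)),
                            index=[f"f{i}" for i in range(8)],
                            columns=meta.index)
        out = spearman_age(expr, meta)
        for _, sub in out.groupby("region"):
            from miratlas.stats import bh_adjust
            np.testing.assert_allclose(
                sub["p_adj"].to_numpy(),
                bh_adjust(sub["p_raw"].to_numpy()), rtol=1e-12)


class TestClassify:
    @pytest.mark.parametrize("R,p_adj,label", [
        (0.6, 0.01, "sig-positive"),
        (0.6, 0.20, "ns"),
        (0.4, 0.01, "sig-only"),
        (-0.6, 0.01, "sig-negative"),
        (0.5, 0.01, "sig-only"),      # strict > by default
    ])
    def test_rule(self, R, p_adj, label):
        res = pd.DataFrame({"R": [R], "p_adj": [p_adj]})
        assert classify_correlation(res)["label"][0] == label

    def test_inclusive_comparator(self):
        res = pd.DataFrame({"R": [0.5], "p_adj": [0.01]})
        out = classify_correlation(res, inclusive=True)
        assert out["label"][0] == "sig-positive"


class TestDE:
    def _fixture(self):
        meta = _meta(["r"] * 8, [3, 3, 3, 3, 15, 15, 15, 15])
        expr = pd.DataFrame(
            [[2.0, 2, 2, 2, 3, 3, 3, 3.0001],     # fc 1.5 boundary
             [1.0, 1, 1, 1, 1, 1, 1, 1],          # fc exactly 1
             [4.0, 5, 6, 7, 4.1, 5.1, 6.1, 7.1]],
            index=["up", "flat", "small"], columns=meta.index)
        return expr, meta

    def test_fc_boundary_meets_threshold(self):
        expr, meta = self._fixture()
        out = differential_expression(expr, meta, "age_months", 15, 3)
        row = out.set_index("feature").loc["up"]
        assert row["fold_change"] >= 1.5

    def test_fc_one_removed_from_testing(self):
        expr, meta = self._fixture()
        out = differential_expression(expr, meta, "age_months", 15, 3)
        row = out.set_index("feature").loc["flat"]
        assert np.isnan(row["p_raw"]) and row["fold_change"] == 1.0

    def test_zero_center_flagged_undefined(self):
        meta = _meta(["r"] * 4, [3, 3, 15, 15])
        expr = pd.DataFrame([[0.0, 0, 5, 6]], index=["f"],
                            columns=meta.index)
        out = differential_expression(expr, meta, "age_months", 15, 3)
        assert bool(out.loc[0, "undefined_fc"])

    def test_significance_flag_definition(self):
        rng = np.random.default_rng(1)
        meta = _meta(["r"] * 12, [3] * 6 + [15] * 6)
        expr = pd.DataFrame(rng.lognormal(size=(30, 12)),
                            index=[f"f{i}" for i in range(30)],
                            columns=meta.index)
        out = differential_expression(expr, meta, "age_months", 15, 3)
        manual = ((out["p_adj"] < 0.05)
                  & ((out["fold_change"] >= 1.5)
                     | (out["fold_change"] <= 1 / 1.5)))
        assert (out["significant"] == manual).all()

    def test_age_contrasts_cover_all_older_ages(self, sim_expr, sim_atlas):
        _, _, meta, _ = sim_atlas
        out = age_contrasts(sim_expr, meta)
        assert set(out["comparison"]) == {"12-vs-3", "15-vs-3", "21-vs-3"}


class TestTaxonomy:
    def test_unique_single_region(self):
        sig = pd.DataFrame({"feature": ["f"], "direction": ["up"],
                            "region": ["pons"]})
        out = unique_multiple(sig, "direction")
        assert out.loc[0, "scope"] == "unique"

    def test_multiple_same_direction(self):
        sig = pd.DataFrame({"feature": ["f"] * 3, "direction": ["up"] * 3,
                            "region": ["a", "b", "c"]})
        out = unique_multiple(sig, "direction")
        assert out.loc[0, "scope"] == "multiple"
        assert out.loc[0, "n_regions"] == 3

    def test_direction_change_two_unique_entries(self):
        sig = pd.DataFrame({"feature": ["f", "f"],
                            "direction": ["up", "down"],
                            "region": ["a", "b"]})
        out = unique_multiple(sig, "direction")
        assert len(out) == 2
        assert set(out["scope"]) == {"unique"}


class TestCandidates:
    def test_correlation_only_candidate(self):
        corr = pd.DataFrame({"feature": ["f"], "region": ["a"],
                             "label": ["sig-positive"]})
        out = candidate_set(corr, pd.DataFrame())
        assert out.loc[0, "evidence"] == "correlation"
        assert out.loc[0, "scope"] == "unique"

    def test_deregulation_multiple(self):
        corr = pd.DataFrame({"feature": [], "region": [], "label": []})
        de = pd.DataFrame({"feature": ["f", "f"], "region": ["a", "b"],
                           "significant": [True, True],
                           "direction": ["up", "up"]})
        out = candidate_set(corr, de)
        assert out.loc[0, "evidence"] == "deregulation"
        assert out.loc[0, "scope"] == "multiple"

    def test_direction_flip_counts_once(self):
        corr = pd.DataFrame({"feature": ["f", "f"], "region": ["a", "b"],
                             "label": ["sig-positive", "sig-negative"]})
        out = candidate_set(corr, pd.DataFrame())
        assert len(out) == 1
        assert out.loc[0, "direction"] == "down|up"

    def test_brute_force_oracle_on_random_labels(self):
        rng = np.random.default_rng(5)
        feats = [f"f{i}" for i in range(12)]
        regions = list("abcd")
        for _ in range(25):
            corr = pd.DataFrame([
                {"feature": f, "region": r,
                 "label": rng.choice(["sig-positive", "sig-negative",
                                      "sig-only", "ns"])}
                for f in feats for r in regions])
            de = pd.DataFrame([
                {"feature": f, "region": r,
                 "significant": bool(rng.random() < 0.15),
                 "direction": rng.choice(["up", "down"])}
                for f in feats for r in regions])
            got = candidate_set(corr, de)
            # oracle: plain set logic per feature
            expected = set()
            for f in feats:
                c = corr[(corr["feature"] == f)
                         & corr["label"].isin(["sig-positive",
                                               "sig-negative"])]
                d = de[(de["feature"] == f) & de["significant"]]
                if len(c) or len(d):
                    expected.add(f)
            assert set(got["feature"]) == expected
            for _, row in got.iterrows():
                c = corr[(corr["feature"] == row["feature"])
                         & corr["label"].isin(["sig-positive",
                                               "sig-negative"])]
                d = de[(de["feature"] == row["feature"])
                       & de["significant"]]
                regions_expected = set(c["region"]) | set(d["region"])
                assert row["n_regions"] == len(regions_expected)
                assert (row["scope"] == "unique") == \
                    (len(regions_expected) == 1)

    def test_cross_sex_same_direction(self):
        male = pd.DataFrame({"feature": ["f", "g"],
                             "direction": ["up", "down"]})
        female = pd.DataFrame({"feature": ["f", "g"],
                               "direction": ["up", "up"]})
        out = cross_sex_features({"male": male, "female": female})
        assert list(out["feature"]) == ["f"]


class TestRankList:
    def test_example_order(self):
        res = pd.DataFrame({
            "feature": ["p1", "p2", "n1"],
            "log2_fc": [1.0, 0.5, -1.0],
            "p_raw": [0.01, 0.20, 0.03],
        })
        assert rank_for_enrichment(res) == ["p1", "p2", "n1"]

    def test_all_positive_ascending_p(self):
        res = pd.DataFrame({
            "feature": ["a", "b", "c"],
            "log2_fc": [0.1, 0.2, 0.3],
            "p_raw": [0.5, 0.01, 0.1],
        })
        assert rank_for_enrichment(res) == ["b", "c", "a"]

    def test_negatives_most_significant_last(self):
        res = pd.DataFrame({
            "feature": ["n1", "n2"],
            "log2_fc": [-1.0, -2.0],
            "p_raw": [0.001, 0.5],
        })
        assert rank_for_enrichment(res) == ["n2", "n1"]

    def test_permutation_no_duplicates(self):
        rng = np.random.default_rng(2)
        res = pd.DataFrame({
            "feature": [f"f{i}" for i in range(40)],
            "log2_fc": rng.normal(size=40),
            "p_raw": rng.uniform(size=40),
        })
        ranked = rank_for_enrichment(res)
        assert sorted(ranked) == sorted(res["feature"])


class TestHumanPreset:
    def test_bin_edges(self):
        meta = pd.DataFrame({"age_years": [71, 80.9, 81, 91.9, 92, 102]})
        bins = bin_human_ages(meta)
        assert list(bins) == ["[71,81)", "[71,81)", "[81,92)", "[81,92)",
                              "[92,103)", "[92,103)"]

    def test_out_of_range_listed(self):
        meta = pd.DataFrame({"age_years": [70, 75]})
        with pytest.raises(ValueError, match="70"):
            bin_human_ages(meta)

    @pytest.mark.parametrize("d,kept", [(0.5, True), (-0.5, True),
                                        (-0.49, False)])
    def test_effect_size_boundary(self, d, kept):
        de = pd.DataFrame({"feature": ["f"], "cohen_d": [d],
                           "significant": [True]})
        out = effect_size_filter(de)
        assert (len(out) == 1) is kept


class TestIntersect:
    def test_empty_reference(self):
        cand = pd.DataFrame({"feature": ["f"], "regions": ["a|b"]})
        assert len(intersect_reference(cand, set())) == 0

    def test_full_overlap(self):
        cand = pd.DataFrame({"feature": ["f", "g"],
                             "regions": ["a", "a|b"]})
        out = intersect_reference(cand, {"f", "g"}).set_index("region")
        assert out.loc["a", "n_overlap"] == 2
        assert out.loc["b", "n_overlap"] == 1


class TestPlantedRecovery:
    def test_aging_features_found_as_candidates(self, sim_expr, sim_atlas):
        _, _, meta, truth = sim_atlas
        corr = classify_correlation(spearman_age(sim_expr, meta))
        de = age_contrasts(sim_expr, meta)
        cand = candidate_set(corr, de)
        planted = {a.feature for a in truth.aging
                   if a.shape != "constant"}
        found = planted & set(cand["feature"])
        assert len(found) / len(planted) >= 0.9
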