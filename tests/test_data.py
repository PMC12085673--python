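"""QC, normalization, and filtering rules of the data layer."""

import numpy as np
import pandas as pd
import pytest

from miratlas.data import (CountTable, SchemaError, composition_summary,
                           drop_sparse_regions, expressed_in_region,
                           filter_features, filter_samples, read_counts,
                           rpmm_normalize, write_counts)
from conftest import random_count_fixture


class TestIO:
    def test_round_trip(self, tiny_table, tiny_meta, tmp_path):
        write_counts(tiny_table, tiny_meta, tmp_path / "c.tsv",
                     tmp_path / "m.tsv")
        table2, meta2 = read_counts(tmp_path / "c.tsv", tmp_path / "m.tsv")
        pd.testing.assert_frame_equal(tiny_table.counts, table2.counts,
                                      check_names=False)
        pd.testing.assert_series_equal(tiny_table.feature_class,
                                       table2.feature_class,
                                       check_names=False)
        assert list(meta2.index) == list(tiny_meta.index)

    def test_random_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        for i in range(5):
            table, meta = random_count_fixture(rng)
            write_counts(table, meta, tmp_path / "c.tsv", tmp_path / "m.tsv")
            table2, _ = read_counts(tmp_path / "c.tsv", tmp_path / "m.tsv")
            assert (table.counts.to_numpy()
                    == table2.counts.to_numpy()).all()

    def test_duplicate_sample_id_rejected(self, tiny_table, tiny_meta,
                                          tmp_path):
        write_counts(tiny_table, tiny_meta, tmp_path / "c.tsv",
                     tmp_path / "m.tsv")
        text = (tmp_path / "m.tsv").read_text().splitlines()
        (tmp_path / "m.tsv").write_text("\n".join(text + [text[1]]))
        with pytest.raises(SchemaError, match="duplicate sample"):
            read_counts(tmp_path / "c.tsv", tmp_path / "m.tsv")

    def test_missing_column_named_in_error(self, tiny_meta, tmp_path):
        (tmp_path / "c.tsv").write_text("feature_id\ts1\nf1\t3\n")
        tiny_meta.to_csv(tmp_path / "m.tsv", sep="\t")
        with pytest.raises(SchemaError, match="feature_class"):
            read_counts(tmp_path / "c.tsv", tmp_path / "m.tsv")

    def test_non_integer_count_located(self, tiny_meta, tmp_path):
        (tmp_path / "c.tsv").write_text(
            "feature_id\tfeature_class\ts1\ts2\ts3\ts4\n"
            "f1\tmiRNA\t1\t2\t3.5\t4\n")
        tiny_meta.to_csv(tmp_path / "m.tsv", sep="\t")
        with pytest.raises(SchemaError, match="f1"):
            read_counts(tmp_path / "c.tsv", tmp_path / "m.tsv")

    def test_negative_counts_rejected(self):
        counts = pd.DataFrame([[1, -2]], index=["f"], columns=["a", "b"])
        with pytest.raises(SchemaError, match="negative"):
            CountTable(counts, pd.Series(["miRNA"], index=["f"]))


class TestRpmm:
    def test_full_library_single_feature(self):
        counts = pd.DataFrame([[10]], index=["f"], columns=["s"])
        t = CountTable(counts, pd.Series(["miRNA"], index=["f"]))
        assert rpmm_normalize(t).iloc[0, 0] == 1e6

    def test_hand_arithmetic(self):
        counts = pd.DataFrame([[5], [15]], index=["a", "b"], columns=["s"])
        t = CountTable(counts, pd.Series(["miRNA", "miRNA"],
                                         index=["a", "b"]))
        expr = rpmm_normalize(t)
        assert expr.loc["a", "s"] == 250_000
        assert expr.loc["b", "s"] == 750_000

    def test_zero_count_zero_rpmm(self, tiny_table):
        expr = rpmm_normalize(tiny_table)
        assert expr.loc["mirA", "s2"] == 0

    def test_column_sums_one_million(self, sim_atlas):
        _, table, _, _ = sim_atlas
        expr = rpmm_normalize(table, denominator_class="all")
        np.testing.assert_allclose(expr.sum(axis=0), 1e6, rtol=1e-9)

    def test_denominator_class_restricts(self, tiny_table):
        expr = rpmm_normalize(tiny_table, denominator_class="miRNA")
        mirna_sums = expr.loc[["mirA", "mirB"]].sum(axis=0)
        np.testing.assert_allclose(mirna_sums, 1e6, rtol=1e-12)

    def test_zero_denominator_names_sample(self):
        counts = pd.DataFrame([[0, 1]], index=["f"], columns=["bad", "ok"])
        t = CountTable(counts, pd.Series(["miRNA"], index=["f"]))
        with pytest.raises(ValueError, match="bad"):
            rpmm_normalize(t)


class TestSampleFilter:
    def test_exactly_two_million_dropped(self, tiny_table, tiny_meta):
        meta = tiny_meta.copy()
        meta.loc["s4", "aligned_reads"] = 2_000_000
        _, kept, rep = filter_samples(tiny_table, meta)
        assert "s4" in rep.dropped_sample_ids
        assert rep.samples_out == 3

    def test_all_above_identity(self, tiny_table, tiny_meta):
        t2, m2, rep = filter_samples(tiny_table, tiny_meta)
        assert rep.dropped_sample_ids == []
        assert list(m2.index) == list(tiny_meta.index)

    def test_mixed_counts(self):
        rng = np.random.default_rng(0)
        table, meta = random_count_fixture(rng, n_samples=10)
        meta["aligned_reads"] = [3e6] * 7 + [1e6] * 3
        _, m2, rep = filter_samples(table, meta)
        assert rep.samples_out == 7 and len(rep.dropped_sample_ids) == 3

    def test_idempotent(self, tiny_table, tiny_meta):
        t1, m1, _ = filter_samples(tiny_table, tiny_meta)
        t2, m2, _ = filter_samples(t1, m1)
        assert list(m1.index) == list(m2.index)


class TestFeatureFilter:
    def test_boundary_inclusive(self):
        # one group of 10 samples; count 5 in exactly 1 sample -> kept
        counts = pd.DataFrame([[5] + [0] * 9, [4] + [0] * 9],
                              index=["kept", "dropped"],
                              columns=[f"s{i}" for i in range(10)])
        t = CountTable(counts, pd.Series("miRNA", index=counts.index))
        meta = pd.DataFrame({
            "region": "r", "age_months": 3, "sex": "male",
        }, index=counts.columns)
        t2, rep = filter_features(t, meta, group_by=["region"])
        assert list(t2.feature_ids) == ["kept"]
        assert rep.dropped_feature_ids == ["dropped"]

    def test_all_zero_dropped(self, tiny_table, tiny_meta):
        t = tiny_table.counts.copy()
        t.loc["mirA"] = 0
        table = CountTable(t, tiny_table.feature_class)
        t2, _ = filter_features(table, tiny_meta, group_by=["region"])
        assert "mirA" not in t2.feature_ids

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            table, meta = random_count_fixture(rng)
            t2, _ = filter_features(table, meta,
                                    group_by=["region", "sex"])
            expected = set()
            groups = meta.groupby(["region", "sex"], observed=True)
            for f in table.feature_ids:
                for _, sub in groups:
                    hits = sum(table.counts.loc[f, s] >= 5
                               for s in sub.index)
                    if hits / len(sub) >= 0.10:
                        expected.add(f)
                        break
            assert set(t2.feature_ids) == expected

    def test_empty_grouping_errors(self, tiny_table, tiny_meta):
        with pytest.raises(ValueError, match="empty"):
            filter_features(tiny_table, tiny_meta, group_by=[])


class TestSparseRegions:
    @pytest.mark.parametrize("n,kept", [(3, False), (4, True)])
    def test_boundary(self, n, kept):
        rng = np.random.default_rng(1)
        table, meta = random_count_fixture(rng, n_samples=n + 4)
        meta["region"] = ["small"] * n + ["big"] * 4
        _, m2, rep = drop_sparse_regions(table, meta)
        assert ("small" in set(m2["region"])) is kept

    def test_region_count(self):
        rng = np.random.default_rng(2)
        table, meta = random_count_fixture(rng, n_samples=22)
        meta["region"] = (["a"] * 5 + ["b"] * 5 + ["c"] * 5 + ["d"] * 5
                          + ["e"] * 2)
        _, m2, rep = drop_sparse_regions(table, meta)
        assert set(m2["region"]) == {"a", "b", "c", "d"}
        assert rep.dropped_regions == ["e"]


class TestExpressedInRegion:
    def test_ten_percent_boundary(self):
        counts = pd.DataFrame([[5, 6] + [0] * 18, [5] + [0] * 19],
                              index=["expressed", "not"],
                              columns=[f"s{i}" for i in range(20)])
        t = CountTable(counts, pd.Series("miRNA", index=counts.index))
        meta = pd.DataFrame({"region": "r"}, index=counts.columns)
        assert expressed_in_region(t, meta, "r") == {"expressed"}

    def test_unknown_region(self, tiny_table, tiny_meta):
        with pytest.raises(ValueError, match="unknown"):
            expressed_in_region(tiny_table, tiny_meta, "nowhere")

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            table, meta = random_count_fixture(rng)
            for region in set(meta["region"]):
                got = expressed_in_region(table, meta, region)
                ids = meta.index[meta["region"] == region]
                expected = {
                    f for f in table.feature_ids
                    if sum(table.counts.loc[f, s] >= 5 for s in ids)
                    / len(ids) >= 0.10
                }
                assert got == expected


class TestComposition:
    def test_single_class_share_one(self, tiny_table, tiny_meta):
        sub = tiny_table.subset(features=["mirA", "mirB"])
        out = composition_summary(sub, tiny_meta)
        assert (out["share"].dropna() == 1.0).all()

    def test_hand_shares(self):
        counts = pd.DataFrame(
            [[150, 150], [50, 50]], index=["m", "t"], columns=["a", "b"])
        t = CountTable(counts, pd.Series(["miRNA", "tRNA"],
                                         index=["m", "t"]))
        meta = pd.DataFrame({"region": "r"}, index=["a", "b"])
        out = composition_summary(t, meta).set_index("feature_class")
        assert out.loc["miRNA", "share"] == 0.75
        assert out.loc["tRNA", "share"] == 0.25

    def test_rows_sum_to_one(self, sim_atlas):
        _, table, meta, _ = sim_atlas
        out = composition_summary(table, meta)
        sums = out.groupby("region")["share"].sum()
        np.testing.assert_allclose(sums, 1.0, rtol=1e-12)
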