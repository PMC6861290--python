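"""Preprocessing operations: filters, taxonomy fill-down, agglomeration,
rarefaction, cross-kingdom merge, taxon profiles."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from rhizonet import (
    CountTable,
    agglomerate,
    fill_taxonomy,
    filter_features,
    merge_kingdoms,
    rarefy,
    split_kingdoms,
    taxon_profiles,
)
from conftest import make_attrs, make_metadata, make_taxonomy


def table_from_totals(totals: dict, n_samples: int = 2) -> CountTable:
    rows = {}
    for fid, total in totals.items():
        base = total // n_samples
        row = [base] * n_samples
        row[0] += total - base * n_samples
        rows[fid] = row
    return CountTable(pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"s{i}" for i in range(n_samples)]))


class TestFilterFeatures:
    def test_min_reads_boundary_keeps_exactly_100(self):
        """The 'fewer than 100 reads' rule removes totals < 100 and keeps
        a total of exactly 100."""
        table = table_from_totals({"a": 99, "b": 100, "c": 250})
        out, report = filter_features(table, min_total_reads=100)
        assert out.feature_ids == ["b", "c"]
        assert report.removed_by_min_reads == 1

    def test_no_filters_is_identity(self):
        table = table_from_totals({"a": 5, "b": 7})
        out, report = filter_features(table)
        pd.testing.assert_frame_equal(out.data, table.data)
        assert report.n_retained == 2

    def test_combined_rules_on_length_fixture(self):
        """10 SVs: 8 at 240 bp (one control-flagged), one 261, one 434;
        window [240, 260] and control removal leave 7."""
        ids = [f"sv{i}" for i in range(10)]
        lengths = {fid: 240 for fid in ids[:8]} | {"sv8": 261, "sv9": 434}
        table = table_from_totals({fid: 10 for fid in ids})
        attrs = make_attrs(lengths, controls={"sv0"})
        out, report = filter_features(
            table, attrs, length_window=(240, 260), drop_control=True, min_total_reads=0
        )
        assert len(out.feature_ids) == 7
        assert report.removed_by_length == 2
        assert report.removed_by_control == 1

    def test_length_window_inclusive(self):
        table = table_from_totals({"lo": 10, "hi": 10})
        attrs = make_attrs({"lo": 240, "hi": 260})
        out, _ = filter_features(table, attrs, length_window=(240, 260))
        assert out.feature_ids == ["lo", "hi"]

    def test_missing_attributes_fails_naming_feature(self):
        table = table_from_totals({"a": 10, "b": 10})
        attrs = make_attrs({"a": 250})
        with pytest.raises(ValueError, match="b"):
            filter_features(table, attrs, length_window=(240, 260))

    def test_idempotent(self):
        table = table_from_totals({"a": 99, "b": 150, "c": 250})
        once, _ = filter_features(table, min_total_reads=100)
        twice, _ = filter_features(once, min_total_reads=100)
        pd.testing.assert_frame_equal(once.data, twice.data)


class TestFillTaxonomy:
    def test_family_marker_propagates_to_genus_and_species(self):
        tax = make_taxonomy({
            "SV3": {"Kingdom": "Bacteria", "Phylum": "Bacteroidetes",
                    "Class": "Bacteroidia", "Order": "Bacteroidales",
                    "Family": "Prevotellaceae"},
        })
        filled = fill_taxonomy(tax)
        assert filled.data.loc["SV3", "Genus"] == "Family_Prevotellaceae"
        assert filled.data.loc["SV3", "Species"] == "Family_Prevotellaceae"

    def test_fully_assigned_row_unchanged_and_idempotent(self):
        tax = make_taxonomy({
            "SV1": {r: f"{r.lower()}x" for r in
                    ("Kingdom", "Phylum", "Class", "Order", "Family", "Genus", "Species")},
            "SV2": {"Kingdom": "Bacteria", "Phylum": "Firmicutes", "Class": "Bacilli"},
        })
        once = fill_taxonomy(tax)
        pd.testing.assert_series_equal(once.data.loc["SV1"], tax.data.loc["SV1"])
        twice = fill_taxonomy(once)
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_class_only_assignment_fills_all_lower_ranks(self):
        tax = make_taxonomy({
            "SV5": {"Kingdom": "Bacteria", "Phylum": "Firmicutes", "Class": "Bacilli"},
        })
        filled = fill_taxonomy(tax)
        for rank in ("Order", "Family", "Genus", "Species"):
            assert filled.data.loc["SV5", rank] == "Class_Bacilli"

    def test_unassigned_feature_fails(self):
        tax = make_taxonomy({"SVx": {}})
        with pytest.raises(ValueError, match="SVx"):
            fill_taxonomy(tax)


class TestAgglomerate:
    def test_sums_member_features(self):
        table = CountTable(pd.DataFrame(
            [[1, 2], [3, 4], [5, 6]], index=["a", "b", "c"], columns=["s1", "s2"]))
        tax = make_taxonomy({
            f: {"Kingdom": "Bacteria", "Phylum": "P", "Class": "C", "Order": "O",
                "Family": "F", "Genus": "G", "Species": f"{f}_sp"}
            for f in ("a", "b", "c")
        })
        out = agglomerate(table, tax, "Genus")
        assert out.data.shape == (1, 2)
        assert list(out.data.loc["G"]) == [9, 12]

    def test_unique_genera_identity_up_to_renaming(self):
        table = CountTable(pd.DataFrame(
            [[1, 2], [3, 4]], index=["a", "b"], columns=["s1", "s2"]))
        tax = make_taxonomy({
            f: {"Kingdom": "K", "Phylum": "P", "Class": "C", "Order": "O",
                "Family": "F", "Genus": f"G_{f}", "Species": f}
            for f in ("a", "b")
        })
        out = agglomerate(table, tax, "Genus")
        np.testing.assert_array_equal(out.values, table.values)

    def test_conserves_sample_totals_and_composes(self):
        rng = np.random.default_rng(0)
        table = CountTable(pd.DataFrame(
            rng.integers(0, 50, size=(20, 4)),
            index=[f"sv{i}" for i in range(20)],
            columns=[f"s{i}" for i in range(4)]))
        tax = make_taxonomy({
            f"sv{i}": {"Kingdom": "K", "Phylum": "P", "Class": "C", "Order": "O",
                       "Family": f"Fam{i % 3}", "Genus": f"Gen{i % 6}", "Species": f"sp{i}"}
            for i in range(20)
        })
        by_genus = agglomerate(table, tax, "Genus")
        pd.testing.assert_series_equal(
            by_genus.sample_totals(), table.sample_totals(), check_names=False)
        # genus -> family equals direct family agglomeration
        genus_tax = make_taxonomy({
            f"Gen{g}": {"Kingdom": "K", "Phylum": "P", "Class": "C", "Order": "O",
                        "Family": f"Fam{g % 3}", "Genus": f"Gen{g}", "Species": "s"}
            for g in range(6)
        })
        via_genus = agglomerate(by_genus, genus_tax, "Family")
        direct = agglomerate(table, tax, "Family")
        pd.testing.assert_frame_equal(
            via_genus.data.sort_index(), direct.data.sort_index())

    def test_unknown_rank_rejected(self):
        table = CountTable(pd.DataFrame([[1]], index=["a"], columns=["s"]))
        tax = make_taxonomy({"a": {"Kingdom": "K"}})
        with pytest.raises(ValueError, match="rank"):
            agglomerate(table, tax, "Tribe")


class TestRarefy:
    def test_column_sums_equal_depth(self):
        table = CountTable(pd.DataFrame(
            {"s1": [3, 2], "s2": [4, 4], "s3": [10, 0]}, index=["a", "b"]))
        out, report = rarefy(table, 5, seed=0)
        assert list(out.sample_ids) == ["s1", "s2", "s3"]
        assert (out.sample_totals() == 5).all()
        assert report.dropped_samples == []

    def test_depth_equal_to_total_returns_sample_exactly(self):
        table = CountTable(pd.DataFrame({"s1": [3, 2]}, index=["a", "b"]))
        out, _ = rarefy(table, 5, seed=0)
        assert list(out.data["s1"]) == [3, 2]

    def test_underdepth_samples_dropped_with_report(self):
        table = CountTable(pd.DataFrame({"s1": [10, 10], "s2": [1, 1]}, index=["a", "b"]))
        out, report = rarefy(table, 10, seed=0)
        assert out.sample_ids == ["s1"]
        assert report.dropped_samples == ["s2"]

    def test_depth_beyond_all_samples_fails(self):
        table = CountTable(pd.DataFrame({"s1": [2]}, index=["a"]))
        with pytest.raises(ValueError, match="depth"):
            rarefy(table, 10)

    def test_singleton_inclusion_matches_hypergeometric(self):
        """Sample (1000, 1) rarefied to depth 10: the singleton survives
        with probability 10/1001 (hypergeometric inclusion)."""
        table = CountTable(pd.DataFrame({"s1": [1000, 1]}, index=["big", "one"]))
        n_trials, hits = 10000, 0
        ss = np.random.SeedSequence(123)
        for child in ss.spawn(n_trials):
            out, _ = rarefy(table, 10, seed=child)
            hits += int(out.data.loc["one", "s1"] > 0)
        expected = 10 / 1001
        se = np.sqrt(expected * (1 - expected) / n_trials)
        assert abs(hits / n_trials - expected) < 4 * se

    def test_zero_rows_retained_by_default_dropped_by_flag(self):
        table = CountTable(pd.DataFrame({"s1": [50, 1]}, index=["a", "b"]))
        out, _ = rarefy(table, 5, seed=1)
        assert set(out.feature_ids) == {"a", "b"}
        out2, rep2 = rarefy(table, 5, seed=1, drop_empty_features=True)
        if rep2.dropped_features:
            assert "b" in rep2.dropped_features

    def test_seeded_reproducibility(self):
        table = CountTable(pd.DataFrame({"s1": [30, 20, 10]}, index=["a", "b", "c"]))
        out1, _ = rarefy(table, 15, seed=9)
        out2, _ = rarefy(table, 15, seed=9)
        pd.testing.assert_frame_equal(out1.data, out2.data)


class TestMergeKingdoms:
    def bac(self):
        return CountTable(pd.DataFrame(
            np.arange(12).reshape(3, 4),
            index=["g1", "g2", "g3"], columns=["s1", "s2", "s3", "s4"]), "genus")

    def fun(self):
        return CountTable(pd.DataFrame(
            np.arange(8).reshape(2, 4),
            index=["h1", "h2"], columns=["s1", "s2", "s3", "s4"]), "genus")

    def test_concatenation_shape_and_kingdom_map(self):
        merged, km = merge_kingdoms(self.bac(), self.fun())
        assert merged.data.shape == (5, 4)
        assert sum(v == "bacteria" for v in km.values()) == 3
        assert sum(v == "fungi" for v in km.values()) == 2

    def test_empty_fungi_returns_bacteria(self):
        empty = CountTable(pd.DataFrame(
            np.empty((0, 4), dtype=int), columns=["s1", "s2", "s3", "s4"]), "genus")
        merged, km = merge_kingdoms(self.bac(), empty)
        np.testing.assert_array_equal(
            merged.data.sort_index(axis=1).values,
            self.bac().data.sort_index(axis=1).values)

    def test_name_collision_kept_distinct(self):
        bac = CountTable(pd.DataFrame([[1, 2, 3, 4]], index=["Shared"],
                                      columns=["s1", "s2", "s3", "s4"]), "genus")
        fun = CountTable(pd.DataFrame([[5, 6, 7, 8]], index=["Shared"],
                                      columns=["s1", "s2", "s3", "s4"]), "genus")
        merged, km = merge_kingdoms(bac, fun)
        assert len(merged.feature_ids) == 2
        assert set(km.values()) == {"bacteria", "fungi"}

    def test_sample_mismatch_lists_difference(self):
        fun = self.fun()
        fun.data.columns = ["s1", "s2", "s3", "s5"]
        with pytest.raises(ValueError, match="s5"):
            merge_kingdoms(self.bac(), fun)

    def test_roundtrip_through_split(self):
        bac, fun = self.bac(), self.fun()
        merged, km = merge_kingdoms(bac, fun)
        back_b, back_f = split_kingdoms(merged, km)
        pd.testing.assert_frame_equal(back_b.data, bac.data)
        pd.testing.assert_frame_equal(back_f.data, fun.data)


class TestTaxonProfiles:
    def tax(self, genera):
        return make_taxonomy({
            g: {"Kingdom": "K", "Phylum": "P", "Class": "C", "Order": "O",
                "Family": f"Fam_{g}", "Genus": g, "Species": "s"}
            for g in genera
        })

    def test_single_taxon_is_unit_everywhere(self):
        table = CountTable(pd.DataFrame(
            [[5, 10, 2, 4]], index=["g1"], columns=["a1", "a2", "w1", "w2"]))
        meta = make_metadata({"a1": "mono_A", "a2": "mono_A", "w1": "mono_W", "w2": "mono_W"})
        prof = taxon_profiles(table, self.tax(["g1"]), meta, "Genus")
        assert np.allclose(prof.to_numpy(), 1.0)

    def test_top_n_ordering(self):
        rng = np.random.default_rng(4)
        genera = [f"g{i:02d}" for i in range(30)]
        table = CountTable(pd.DataFrame(
            rng.integers(1, 100, size=(30, 6)), index=genera,
            columns=[f"s{i}" for i in range(6)]))
        meta = make_metadata({f"s{i}": ("mono_A" if i < 3 else "mono_W") for i in range(6)})
        prof = taxon_profiles(table, self.tax(genera), meta, "Family", top_n=10)
        assert len(prof) == 10
        means = prof.mean(axis=1).to_numpy()
        assert (np.diff(means) <= 1e-12).all()

    def test_combined_abundance_threshold_excludes_minor_genus(self):
        # minor genus: 0.3% of each of 3 groups -> combined 0.9% < 1%
        table = CountTable(pd.DataFrame(
            [[997, 997, 997], [3, 3, 3]], index=["major", "minor"],
            columns=["a", "w", "m"]))
        meta = make_metadata({"a": "mono_A", "w": "mono_W", "m": "mixed_A"})
        prof = taxon_profiles(table, self.tax(["major", "minor"]), meta, "Genus",
                              min_combined_relabund=0.01)
        assert "minor" not in prof.index
        assert "major" in prof.index

    def test_sample_missing_from_metadata_fails(self):
        table = CountTable(pd.DataFrame([[1, 2]], index=["g"], columns=["s1", "sX"]))
        meta = make_metadata({"s1": "mono_A"})
        with pytest.raises(ValueError, match="sX"):
            taxon_profiles(table, self.tax(["g"]), meta, "Genus")
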