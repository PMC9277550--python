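import numpy as np
import pandas as pd
import pytest

from peachferm import (
    AbundanceTable,
    ValidationError,
    aggregate_taxa,
    load_table1_fixture,
    read_abundance_table,
    to_relative,
    top_n_taxa,
    write_edge_list,
)
from peachferm.association import CorrelationEdge
from peachferm.tables import read_edge_list, write_abundance_table


def test_tsv_round_trip_preserves_counts(small_counts_table, tmp_path):
    path = tmp_path / "abund.tsv"
    write_abundance_table(small_counts_table, path)
    back = read_abundance_table(path)
    assert back.mode == "counts"
    pd.testing.assert_frame_equal(back.data, small_counts_table.data.astype(float),
                                  check_names=False)
    assert list(back.stage) == list(small_counts_table.stage)


def test_relative_mode_autodetected(tmp_path):
    path = tmp_path / "rel.tsv"
    path.write_text(
        "sample\tstage\treplicate\tt1\tt2\n"
        "A1\tA\t1\t0.25\t0.75\n"
        "B1\tB\t1\t0.5\t0.5\n"
    )
    assert read_abundance_table(path).mode == "relative"


def test_negative_entry_rejected_with_location(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text(
        "sample\tstage\treplicate\tt1\tt2\n"
        "A1\tA\t1\t3\t-1\n"
        "B1\tB\t1\t5\t5\n"
    )
    with pytest.raises(ValidationError, match="t2"):
        read_abundance_table(path)


def test_duplicate_stage_replicate_rejected():
    data = pd.DataFrame([[1, 2], [3, 4]], index=["s1", "s2"], columns=["a", "b"])
    with pytest.raises(ValidationError, match="duplicate"):
        AbundanceTable(data, pd.Series(["A", "A"], index=data.index),
                       pd.Series([1, 1], index=data.index))


@pytest.mark.parametrize(
    "counts,expected",
    [([2, 2], [0.5, 0.5]), ([1, 0, 3], [0.25, 0.0, 0.75])],
)
def test_to_relative_closed_forms(counts, expected):
    data = pd.DataFrame([counts, counts], index=["A1", "B1"],
                        columns=[f"t{i}" for i in range(len(counts))])
    t = AbundanceTable(data, pd.Series(["A", "B"], index=data.index),
                       pd.Series([1, 1], index=data.index))
    rel = to_relative(t)
    assert rel.mode == "relative"
    np.testing.assert_allclose(rel.data.iloc[0].to_numpy(), expected)


def test_to_relative_zero_row_names_sample():
    data = pd.DataFrame([[0, 0], [1, 1]], index=["A1", "B1"], columns=["a", "b"])
    t = AbundanceTable(data, pd.Series(["A", "B"], index=data.index),
                       pd.Series([1, 1], index=data.index))
    with pytest.raises(ValidationError, match="A1"):
        to_relative(t)


class TestAggregateTaxa:
    def test_members_sum_into_group(self, small_counts_table):
        agg = aggregate_taxa(small_counts_table, {"tax_a": "G", "tax_b": "G", "tax_c": "H"})
        assert agg.data.loc["A1", "G"] == 10
        assert agg.data.loc["B1", "G"] == 10

    def test_identity_mapping_is_noop(self, small_counts_table):
        agg = aggregate_taxa(small_counts_table,
                             {t: t for t in small_counts_table.taxa})
        pd.testing.assert_frame_equal(agg.data, small_counts_table.data, check_dtype=False)

    def test_per_sample_totals_conserved(self, small_counts_table):
        agg = aggregate_taxa(small_counts_table, {"tax_a": "G"})  # rest -> Other
        np.testing.assert_allclose(agg.data.sum(axis=1), small_counts_table.data.sum(axis=1))

    def test_empty_mapping_rejected(self, small_counts_table):
        with pytest.raises(ValidationError):
            aggregate_taxa(small_counts_table, {})


class TestTopN:
    def _rel(self, means):
        data = pd.DataFrame([means, means], index=["A1", "B1"],
                            columns=[f"t{i}" for i in range(len(means))])
        return AbundanceTable(data, pd.Series(["A", "B"], index=data.index),
                              pd.Series([1, 1], index=data.index), mode="relative")

    def test_highest_means_kept(self):
        t = top_n_taxa(self._rel([0.5, 0.3, 0.2]), 2)
        assert t.taxa == ["t0", "t1"]

    def test_n_larger_than_table_keeps_all(self):
        assert len(top_n_taxa(self._rel([0.5, 0.3, 0.2]), 40).taxa) == 3

    def test_ties_broken_lexicographically(self):
        data = pd.DataFrame([[0.25, 0.25, 0.5]] * 2, index=["A1", "B1"],
                            columns=["zeta", "alpha", "mid"])
        t = AbundanceTable(data, pd.Series(["A", "B"], index=data.index),
                           pd.Series([1, 1], index=data.index), mode="relative")
        assert top_n_taxa(t, 2).taxa == ["mid", "alpha"]

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValidationError):
            top_n_taxa(self._rel([0.6, 0.4]), 0)


class TestFixture:
    def test_compound_count(self, fixture_tables):
        vt, _ = fixture_tables
        assert len(vt.compounds) == 53

    def test_class_counts(self, fixture_tables):
        vt, _ = fixture_tables
        counts = vt.compound_class.value_counts().to_dict()
        assert counts == {"ester": 23, "alcohol": 13, "aldehyde": 6,
                          "ketone": 2, "terpene": 3, "phenol": 1, "acid": 5}

    def test_ethyl_hexanoate_final_stage(self, fixture_tables):
        vt, th = fixture_tables
        assert vt.concentrations.at["F", "Ethyl hexanoate"] == pytest.approx(71.25)
        assert th.table.at["Ethyl hexanoate", "threshold_low"] == pytest.approx(5.0)

    def test_hexanal_not_detected_late(self, fixture_tables):
        vt, _ = fixture_tables
        assert vt.concentrations.loc[["C", "D", "E", "F"], "Hexanal"].isna().all()

    def test_threshold_ranges_parsed(self, fixture_tables):
        _, th = fixture_tables
        assert th.table.loc["2-Non-anol"].tolist() == [20.0, 50.0]
        assert np.isnan(th.table.at["Isoamyl lactate", "threshold_low"])

    def test_all_present_thresholds_positive(self, fixture_tables):
        _, th = fixture_tables
        assert (th.table["threshold_low"].dropna() > 0).all()

    def test_detected_zero_distinct_from_nd(self, fixture_tables):
        vt, _ = fixture_tables
        assert vt.concentrations.at["B", "3-Hexenyl isobutyrate"] == 0.0
        assert np.isnan(vt.concentrations.at["C", "3-Hexenyl isobutyrate"])


class TestEdgeList:
    def test_empty_edge_set_gives_header_only(self, tmp_path):
        path = tmp_path / "edges.tsv"
        write_edge_list([], path)
        assert len(read_edge_list(path)) == 0

    def test_round_trip(self, tmp_path):
        edges = [
            CorrelationEdge("A", "B", "taxon-fungal", "volatile-ester", 0.8, 0.001, "+"),
            CorrelationEdge("A", "C", "taxon-fungal", "taxon-bacterial", -0.95, 1e-5, "-"),
        ]
        path = tmp_path / "edges.tsv"
        write_edge_list(edges, path)
        df = read_edge_list(path)
        assert len(df) == 2
        assert df.loc[0, "node_b"] == "B"
        assert df.loc[0, "r"] == pytest.approx(0.8)
        assert df.loc[1, "sign"] == "-"
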