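"""Count-table I/O, filter-fraction merging, rarefaction, normalisation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aquacore import (
    CountTable,
    merge_fraction_tables,
    rarefy,
    read_count_table,
    read_metadata,
    to_relative_abundance,
    write_count_table,
)
from aquacore.exceptions import ValidationError

from conftest import random_count_table


class TestCountTableValidation:
    def test_negative_cell_names_offender(self):
        df = pd.DataFrame({"s1": [1, -4]}, index=["a", "b"])
        with pytest.raises(ValidationError, match=r"'b'.*'s1'|negative"):
            CountTable(df)

    def test_non_integer_cell_rejected(self):
        df = pd.DataFrame({"s1": [1.0, 2.5]}, index=["a", "b"])
        with pytest.raises(ValidationError, match="non-integer"):
            CountTable(df)

    def test_integral_floats_are_cast(self):
        df = pd.DataFrame({"s1": [1.0, 2.0]}, index=["a", "b"])
        t = CountTable(df)
        assert np.issubdtype(t.counts.dtype, np.integer)

    @pytest.mark.parametrize("axis", ["index", "columns"])
    def test_duplicate_ids_rejected(self, axis):
        df = pd.DataFrame(np.ones((2, 2), dtype=int))
        setattr(df, axis, ["x", "x"] if axis == "index" else ["s", "s"])
        with pytest.raises(ValidationError, match="duplicate"):
            CountTable(df)


class TestReadWrite:
    def test_tsv_round_trip_is_identity(self, tmp_path, tiny_table):
        path = tmp_path / "t.tsv"
        write_count_table(tiny_table, path)
        back = read_count_table(path)
        pd.testing.assert_frame_equal(back.data, tiny_table.data)

    def test_read_preserves_input_ordering(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("asv_id\ts2\ts1\nzzz\t1\t2\naaa\t3\t4\n")
        t = read_count_table(path)
        assert t.asv_ids == ["zzz", "aaa"]
        assert t.sample_ids == ["s2", "s1"]

    def test_transpose_accepts_samples_in_rows(self, tmp_path, tiny_table):
        path = tmp_path / "t.tsv"
        tiny_table.data.T.to_csv(path, sep="\t", index_label="sample_id")
        back = read_count_table(path, transpose=True)
        pd.testing.assert_frame_equal(
            back.data, tiny_table.data, check_names=False
        )

    def test_biom_round_trip(self, tmp_path, tiny_table):
        biom = pytest.importorskip("biom")
        table = biom.Table(
            tiny_table.counts, tiny_table.asv_ids, tiny_table.sample_ids
        )
        path = tmp_path / "t.biom"
        path.write_text(table.to_json("aquacore-test"))
        back = read_count_table(path, format="biom")
        assert np.array_equal(back.counts, tiny_table.counts)
        assert back.asv_ids == tiny_table.asv_ids

    def test_metadata_reader_validates_and_parses_dates(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text(
            "sample_id\tsite\tland_use_class\tdate\tNITRATE\n"
            "s1\tS01\tagri_ditch\t2017-05-01\t1.5\n"
            "s2\tS02\tforest\t2017-05-01\t0.2\n"
        )
        meta = read_metadata(path)
        assert meta.loc["s1", "year"] == 2017
        assert meta.loc["s2", "date"] == pd.Timestamp("2017-05-01")

    def test_metadata_unknown_land_use_rejected(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text(
            "sample_id\tsite\tland_use_class\tdate\ns1\tS01\turban\t2017-05-01\n"
        )
        with pytest.raises(ValidationError, match="land_use_class"):
            read_metadata(path)


class TestMergeFractionTables:
    def _t(self, mapping, samples):
        return CountTable(pd.DataFrame(mapping, index=samples).T)

    def test_counts_are_summed_per_sample(self):
        a = self._t({"x": [2, 0]}, ["s1", "s2"])
        b = self._t({"x": [3, 5]}, ["s1", "s2"])
        merged = merge_fraction_tables(a, b)
        assert merged.data.loc["x"].tolist() == [5, 5]

    def test_union_of_asv_sets_with_zero_fill(self):
        a = self._t({"u": [1, 2]}, ["s1", "s2"])
        b = self._t({"v": [3, 4]}, ["s1", "s2"])
        merged = merge_fraction_tables(a, b)
        assert set(merged.asv_ids) == {"u", "v"}
        assert merged.data.loc["v", "s1"] == 3
        assert merged.data.loc["u"].tolist() == [1, 2]

    def test_merge_with_empty_table_is_identity(self, tiny_table):
        empty = CountTable(
            pd.DataFrame(0, index=["asvA"], columns=tiny_table.sample_ids)
        )
        merged = merge_fraction_tables(tiny_table, empty)
        pd.testing.assert_frame_equal(merged.data, tiny_table.data)

    def test_strict_mode_rejects_unmatched_samples(self, tiny_table):
        other = CountTable(pd.DataFrame({"s9": [1]}, index=["asvA"]))
        with pytest.raises(ValidationError, match="sample sets differ"):
            merge_fraction_tables(tiny_table, other)

    def test_lenient_mode_zero_fills_unmatched(self, tiny_table):
        other = CountTable(pd.DataFrame({"s9": [1]}, index=["asvA"]))
        merged = merge_fraction_tables(tiny_table, other, strict=False)
        assert merged.data.loc["asvA", "s9"] == 1
        assert merged.data.loc["asvB", "s9"] == 0

    def test_commutative_and_associative_on_matched_samples(self):
        rng = np.random.default_rng(7)
        tables = [random_count_table(rng, 6, 4) for _ in range(3)]
        ab = merge_fraction_tables(tables[0], tables[1])
        ba = merge_fraction_tables(tables[1], tables[0])
        pd.testing.assert_frame_equal(
            ab.data.sort_index(), ba.data.sort_index()
        )
        left = merge_fraction_tables(ab, tables[2])
        right = merge_fraction_tables(
            tables[0], merge_fraction_tables(tables[1], tables[2])
        )
        pd.testing.assert_frame_equal(
            left.data.sort_index(), right.data.sort_index()
        )


class TestRarefy:
    def test_depth_must_be_positive(self, tiny_table):
        with pytest.raises(ValueError, match="positive"):
            rarefy(tiny_table, 0, seed=1)

    def test_retained_columns_sum_exactly_to_depth(self, tiny_table):
        out = rarefy(tiny_table, 4, seed=1)
        assert (out.sample_sums() == 4).all()

    def test_samples_below_depth_are_dropped(self, tiny_table):
        # s1 has only 4 reads
        out = rarefy(tiny_table, 5, seed=1)
        assert "s1" not in out.sample_ids
        assert set(out.sample_ids) == {"s2", "s3"}

    def test_sample_at_exact_depth_returned_unchanged(self, tiny_table):
        out = rarefy(tiny_table, 4, seed=1)
        assert out.data["s1"].tolist() == tiny_table.data["s1"].tolist()

    def test_single_asv_sample_keeps_only_possible_outcome(self):
        t = CountTable(pd.DataFrame({"s": [100]}, index=["only"]))
        out = rarefy(t, 10, seed=3)
        assert out.data.loc["only", "s"] == 10

    def test_same_seed_is_bit_identical(self, small_sim):
        t = small_sim.table
        a = rarefy(t, 5000, seed=42)
        b = rarefy(t, 5000, seed=42)
        pd.testing.assert_frame_equal(a.data, b.data)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), depth=st.integers(1, 30))
    def test_never_exceeds_input_and_conserves_depth(self, seed, depth):
        rng = np.random.default_rng(seed)
        t = random_count_table(rng, 8, 5)
        out = rarefy(t, depth, seed=seed)
        assert (out.sample_sums() == depth).all()
        assert (out.data <= t.data[out.sample_ids]).all().all()


class TestRelativeAbundance:
    def test_column_normalisation(self):
        t = CountTable(pd.DataFrame({"s": [1, 1, 2]}, index=list("abc")))
        rel = to_relative_abundance(t)
        assert rel.data["s"].tolist() == [0.25, 0.25, 0.5]

    def test_rarefied_columns_become_counts_over_depth(self, tiny_table):
        out = rarefy(tiny_table, 4, seed=0)
        rel = to_relative_abundance(out)
        expected = out.data.astype(float) / 4
        pd.testing.assert_frame_equal(rel.data, expected)

    def test_all_zero_column_flagged_not_divided(self):
        t = CountTable(pd.DataFrame({"s0": [0, 0], "s1": [1, 3]},
                                    index=["a", "b"]))
        rel = to_relative_abundance(t)
        assert rel.zero_samples == ("s0",)
        assert rel.data["s0"].tolist() == [0.0, 0.0]
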