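import json
import warnings

import numpy as np
import pandas as pd
import pytest

from msigkit import (
    SBS96,
    MutationalCatalog,
    SampleLookupError,
    SchemaMismatchError,
    SimulationSpec,
    ValidationError,
    compare_spectra,
    generate_catalog,
    grouped_log_boxplot,
    parse_portal_json,
    read_catalog_csv,
    sample_summary,
    to_spectrum,
    write_catalog_csv,
)

from .conftest import random_catalog
from .oracles import quantile_by_sorting


class TestCatalogValidation:
    def test_duplicate_sample_ids_rejected(self, toy_schema):
        with pytest.raises(ValidationError, match="duplicate"):
            MutationalCatalog(toy_schema, ["a", "a"], np.zeros((2, 6), dtype=int))

    def test_negative_counts_rejected(self, toy_schema):
        counts = np.zeros((1, 6), dtype=int)
        counts[0, 2] = -1
        with pytest.raises(ValidationError, match="negative"):
            MutationalCatalog(toy_schema, ["a"], counts)

    def test_shape_mismatch_rejected(self, toy_schema):
        with pytest.raises(ValidationError, match="shape"):
            MutationalCatalog(toy_schema, ["a"], np.zeros((1, 5), dtype=int))


class TestCsvRoundTrip:
    def test_zero_wide_catalog(self, tmp_path):
        path = tmp_path / "zero.csv"
        header = "sample," + ",".join(SBS96.channels)
        rows = ["sA," + ",".join(["0"] * 96), "sB," + ",".join(["0"] * 96)]
        path.write_text(header + "\n" + "\n".join(rows) + "\n")
        cat = read_catalog_csv(path, SBS96)
        assert cat.sample_ids == ["sA", "sB"]
        assert list(cat.totals()) == [0, 0]

    def test_long_csv_fills_missing_channels_with_zero(self, tmp_path):
        path = tmp_path / "long.csv"
        path.write_text(
            "sample,mutationType,mutations\n"
            "s1,A[C>A]A,2\ns1,A[C>G]A,3\ns1,T[T>G]T,1\n"
        )
        cat = read_catalog_csv(path, SBS96)
        assert cat.counts.sum() == 6
        assert int((cat.counts[0] == 0).sum()) == 93

    def test_write_then_read_is_identity(self, tmp_path):
        rng = np.random.default_rng(7)
        for trial in range(20):
            cat = random_catalog(rng, SBS96, n_samples=int(rng.integers(1, 6)))
            path = tmp_path / f"cat{trial}.csv"
            write_catalog_csv(cat, path)
            back = read_catalog_csv(path, SBS96)
            assert back == cat

    def test_write_read_write_byte_identical(self, tmp_path):
        cat = random_catalog(np.random.default_rng(3), SBS96)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_catalog_csv(cat, p1)
        write_catalog_csv(read_catalog_csv(p1, SBS96), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_wide_header_field_count(self, tmp_path):
        cat = random_catalog(np.random.default_rng(0), SBS96, n_samples=1)
        path = tmp_path / "one.csv"
        write_catalog_csv(cat, path)
        lines = path.read_text().strip().split("\n")
        assert len(lines) == 2
        assert len(lines[0].split(",")) == 97

    def test_columns_reordered_into_schema_order(self, toy_schema, tmp_path):
        # write channels in reversed file order; counts must land per schema
        path = tmp_path / "rev.csv"
        labels = list(reversed(toy_schema.channels))
        path.write_text(
            "sample," + ",".join(labels) + "\n" + "x," + ",".join(map(str, range(6))) + "\n"
        )
        cat = read_catalog_csv(path, toy_schema)
        assert list(cat.counts[0]) == [5, 4, 3, 2, 1, 0]

    def test_unknown_channel_named_in_error(self, toy_schema, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("sample,A[C>A]A,B[C>A]B\nx,1,2\n")
        with pytest.raises(SchemaMismatchError, match="B\\[C>A\\]B"):
            read_catalog_csv(path, toy_schema)

    def test_non_integer_count_reports_row(self, toy_schema, tmp_path):
        path = tmp_path / "frac.csv"
        path.write_text(
            "sample," + ",".join(toy_schema.channels) + "\nx,1,2,0.5,0,0,0\n"
        )
        with pytest.raises(ValidationError, match="row 2"):
            read_catalog_csv(path, toy_schema)

    def test_duplicate_sample_rejected(self, toy_schema, tmp_path):
        path = tmp_path / "dup.csv"
        row = ",".join(["1"] * 6)
        path.write_text(
            "sample," + ",".join(toy_schema.channels) + f"\nx,{row}\nx,{row}\n"
        )
        with pytest.raises(ValidationError, match="duplicate"):
            read_catalog_csv(path, toy_schema)


class TestPortalJson:
    @staticmethod
    def records_for(catalog):
        recs = []
        family = catalog.schema.name.rstrip("0123456789")
        for i, s in enumerate(catalog.sample_ids):
            for j, label in enumerate(catalog.schema.channels):
                if catalog.counts[i, j]:
                    recs.append(
                        {"sample": s, "profile": family,
                         "matrix": len(catalog.schema),
                         "mutationType": label,
                         "mutations": int(catalog.counts[i, j])}
                    )
        return recs

    def test_empty_array_is_an_error(self):
        with pytest.raises(ValidationError, match="no records"):
            parse_portal_json("[]", SBS96)

    def test_malformed_json_is_an_error(self):
        with pytest.raises(ValidationError, match="malformed"):
            parse_portal_json("{not json", SBS96)

    def test_missing_field_reports_record_index(self, toy_schema):
        recs = [{"sample": "a", "profile": "TOY", "matrix": 6,
                 "mutationType": "A[C>A]A", "mutations": 1},
                {"sample": "a", "profile": "TOY", "matrix": 6,
                 "mutationType": "A[C>G]A"}]
        with pytest.raises(ValidationError, match="record 1"):
            parse_portal_json(json.dumps(recs), toy_schema)

    def test_profile_matrix_mismatch_rejected(self, toy_schema):
        recs = [{"sample": "a", "profile": "DBS", "matrix": 6,
                 "mutationType": "A[C>A]A", "mutations": 1}]
        with pytest.raises(SchemaMismatchError):
            parse_portal_json(json.dumps(recs), toy_schema)

    def test_96_unit_records_sum_to_96(self):
        recs = [{"sample": "s", "profile": "SBS", "matrix": 96,
                 "mutationType": c, "mutations": 1} for c in SBS96.channels]
        cat = parse_portal_json(json.dumps(recs), SBS96)
        assert cat.totals().tolist() == [96]

    def test_json_and_long_csv_agree(self, tmp_path):
        rng = np.random.default_rng(11)
        cat = random_catalog(rng, SBS96, n_samples=4)
        # long CSV encoding (nonzero cells only)
        lines = ["sample,mutationType,mutations"]
        for i, s in enumerate(cat.sample_ids):
            for j, label in enumerate(SBS96.channels):
                if cat.counts[i, j]:
                    lines.append(f"{s},{label},{cat.counts[i, j]}")
        path = tmp_path / "long.csv"
        path.write_text("\n".join(lines) + "\n")
        from_csv = read_catalog_csv(path, SBS96)
        from_json = parse_portal_json(json.dumps(self.records_for(cat)), SBS96)
        assert from_csv == from_json == cat


class TestSpectrum:
    def test_uniform_row(self, toy_schema):
        cat = MutationalCatalog(toy_schema, ["u"], np.full((1, 6), 7))
        assert np.allclose(to_spectrum(cat, "u").values, 1 / 6)

    def test_zero_row_gives_all_zero_spectrum(self, toy_schema):
        cat = MutationalCatalog(toy_schema, ["z"], np.zeros((1, 6), dtype=int))
        assert np.all(to_spectrum(cat, "z").values == 0)

    def test_nonzero_rows_sum_to_one(self):
        rng = np.random.default_rng(5)
        cat = random_catalog(rng, SBS96, n_samples=8, max_count=100)
        for s in cat.sample_ids:
            total = cat.row(s).sum()
            if total > 0:
                assert abs(to_spectrum(cat, s).values.sum() - 1.0) < 1e-9

    def test_unknown_sample_lists_available_ids(self, toy_catalog):
        with pytest.raises(SampleLookupError, match="s1"):
            to_spectrum(toy_catalog, "nope")


class TestSampleSummary:
    def test_single_mutation_lands_in_its_class(self, toy_schema):
        counts = np.zeros((1, 6), dtype=int)
        counts[0, toy_schema.index_of("A[C>T]A")] = 1
        cat = MutationalCatalog(toy_schema, ["m"], counts)
        row = sample_summary(cat).iloc[0]
        assert row["total_mutations"] == 1 and row["C>T"] == 1
        assert row[["C>A", "C>G", "T>A", "T>C", "T>G"]].sum() == 0

    def test_class_subtotals_conserve_totals(self, small_sim):
        cat, _, _ = small_sim
        table = sample_summary(cat)
        classes = list(cat.schema.substitution_classes)
        assert (table[classes].sum(axis=1) == table["total_mutations"]).all()
        assert table["sample"].tolist() == cat.sample_ids


class TestCompareSpectra:
    def test_self_comparison(self, toy_catalog):
        cmp = compare_spectra(toy_catalog, "s1", "s1")
        assert cmp.cosine_similarity == pytest.approx(1.0)
        assert cmp.rss == 0.0
        assert np.all(cmp.table["difference"] == 0)

    def test_portal_style_sample_names_accepted(self, toy_schema):
        cat = MutationalCatalog(
            toy_schema, ["SP99181", "SP98955"],
            np.array([[1, 2, 3, 0, 0, 0], [0, 0, 3, 2, 1, 0]]),
        )
        cmp = compare_spectra(cat, "SP99181", "SP98955")
        assert 0 <= cmp.cosine_similarity <= 1
        assert {"SP99181", "SP98955"} <= set(cmp.table.columns)

    def test_swap_negates_differences_keeps_scores(self, small_sim):
        cat, _, _ = small_sim
        a, b = cat.sample_ids[:2]
        ab, ba = compare_spectra(cat, a, b), compare_spectra(cat, b, a)
        assert np.allclose(ab.table["difference"], -ba.table["difference"])
        assert ab.cosine_similarity == pytest.approx(ba.cosine_similarity)
        assert ab.rss == pytest.approx(ba.rss)


class TestGroupedLogBoxplot:
    def test_singleton_group_collapses_to_log10(self, toy_schema):
        cat = MutationalCatalog(
            toy_schema, ["one"], np.array([[1000, 0, 0, 0, 0, 0]]),
            metadata={"one": {"ct": "lung"}},
        )
        (stats,) = grouped_log_boxplot(cat, "ct")
        assert stats.median == stats.q1 == stats.q3 == pytest.approx(3.0)
        assert stats.outliers == ()

    def test_median_of_decade_totals(self, toy_schema):
        counts = np.zeros((3, 6), dtype=int)
        counts[0, 0], counts[1, 0], counts[2, 0] = 10, 100, 1000
        cat = MutationalCatalog(
            toy_schema, ["a", "b", "c"], counts,
            metadata={s: {"ct": "g"} for s in ["a", "b", "c"]},
        )
        (stats,) = grouped_log_boxplot(cat, "ct")
        assert stats.median == pytest.approx(2.0)

    def test_missing_metadata_key_names_samples(self, toy_schema):
        cat = MutationalCatalog(
            toy_schema, ["a"], np.full((1, 6), 1), metadata={"a": {"x": "1"}}
        )
        with pytest.raises(ValidationError, match="'ct'.*\\['a'\\]"):
            grouped_log_boxplot(cat, "ct")

    def test_zero_total_samples_excluded_with_warning(self, toy_schema):
        counts = np.array([[10, 0, 0, 0, 0, 0], [0, 0, 0, 0, 0, 0]])
        cat = MutationalCatalog(
            toy_schema, ["a", "z"], counts,
            metadata={s: {"ct": "g"} for s in ["a", "z"]},
        )
        with pytest.warns(UserWarning, match="zero-total"):
            (stats,) = grouped_log_boxplot(cat, "ct")
        assert stats.n == 1

    def test_matches_sorting_oracle_on_random_groups(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(1, 30))
            totals = rng.integers(1, 10_000, size=n)
            counts = np.zeros((n, 96), dtype=int)
            counts[:, 0] = totals
            ids = [f"s{i}" for i in range(n)]
            cat = MutationalCatalog(
                SBS96, ids, counts, metadata={s: {"g": "all"} for s in ids}
            )
            (stats,) = grouped_log_boxplot(cat, "g")
            logs = np.log10(totals.astype(float))
            q1 = quantile_by_sorting(logs, 0.25)
            q3 = quantile_by_sorting(logs, 0.75)
            assert stats.q1 == pytest.approx(q1, abs=1e-12)
            assert stats.median == pytest.approx(quantile_by_sorting(logs, 0.5), abs=1e-12)
            assert stats.q3 == pytest.approx(q3, abs=1e-12)
            iqr = q3 - q1
            inside = logs[(logs >= q1 - 1.5 * iqr) & (logs <= q3 + 1.5 * iqr)]
            assert stats.whisker_low == pytest.approx(min(inside.min(), q1))
            assert stats.whisker_high == pytest.approx(max(inside.max(), q3))
            for o in stats.outliers:
                assert o < stats.whisker_low or o > stats.whisker_high
            assert stats.q1 <= stats.median <= stats.q3
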