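import logging

import numpy as np
import pandas as pd
import pytest

from famscout.matrix import (
    AnnotationRecord,
    FamilyCountMatrix,
    MatrixFormatError,
    PathwayMap,
    build_matrix_from_annotations,
    cluster_order,
    normalize_counts,
    pathway_ratio,
    presence_absence,
    read_count_matrix,
    read_pathway_map,
    read_annotations,
    subset_families,
    write_count_matrix,
)


def write_tsv(path, text):
    path.write_text(text)
    return path


class TestReadCountMatrix:
    def test_direct_parse(self, tmp_path):
        p = write_tsv(tmp_path / "m.tsv", "species\tF1\tF2\nspA\t1\t0\nspB\t0\t3\n")
        m = read_count_matrix(p)
        assert m.species_ids == ["spA", "spB"]
        assert m.family_ids == ["F1", "F2"]
        assert m.counts.to_numpy().tolist() == [[1, 0], [0, 3]]

    def test_duplicate_family_named(self, tmp_path):
        p = write_tsv(tmp_path / "m.tsv", "species\t37M4G\t37M4G\nspA\t1\t2\n")
        with pytest.raises(MatrixFormatError, match="37M4G"):
            read_count_matrix(p)

    def test_duplicate_species_named(self, tmp_path):
        p = write_tsv(tmp_path / "m.tsv", "species\tF1\nspA\t1\nspA\t2\n")
        with pytest.raises(MatrixFormatError, match="spA"):
            read_count_matrix(p)

    def test_header_only_is_empty_matrix(self, tmp_path):
        p = write_tsv(tmp_path / "m.tsv", "species\tF1\tF2\n")
        m = read_count_matrix(p)
        assert m.n_species == 0
        assert m.family_ids == ["F1", "F2"]

    @pytest.mark.parametrize(
        "cell,msg", [("-1", "negative"), ("1.5", "non-integer"), ("x", "non-integer")]
    )
    def test_bad_cells_report_coordinates(self, tmp_path, cell, msg):
        p = write_tsv(tmp_path / "m.tsv", f"species\tF1\nspA\t{cell}\n")
        with pytest.raises(MatrixFormatError) as exc:
            read_count_matrix(p)
        assert msg in str(exc.value)
        assert "spA" in str(exc.value) and "F1" in str(exc.value)

    def test_round_trip(self, toy_matrix, tmp_path):
        p = tmp_path / "out.tsv"
        write_count_matrix(toy_matrix, p)
        again = read_count_matrix(p)
        pd.testing.assert_frame_equal(again.counts, toy_matrix.counts)


class TestInvariants:
    def test_totals_must_dominate_row_sums(self):
        counts = pd.DataFrame([[5, 5]], index=["spA"], columns=["F1", "F2"])
        with pytest.raises(MatrixFormatError, match="spA"):
            FamilyCountMatrix(counts, pd.Series([9], index=["spA"]))

    def test_totals_must_be_positive(self):
        counts = pd.DataFrame([[0]], index=["spA"], columns=["F1"])
        with pytest.raises(MatrixFormatError, match="spA"):
            FamilyCountMatrix(counts, pd.Series([0], index=["spA"]))


class TestAnnotations:
    def test_counting_at_scope(self):
        recs = {
            "spX": [
                AnnotationRecord(f"g{i}", [("37MT6", "33090")]) for i in range(3)
            ]
        }
        m = build_matrix_from_annotations(recs, "33090")
        assert m.counts.loc["spX", "37MT6"] == 3

    def test_other_scope_contributes_nothing(self):
        recs = {"spX": [AnnotationRecord("g1", [("ROOT1", "1")])]}
        m = build_matrix_from_annotations(recs, "33090")
        assert m.n_families == 0

    def test_disjoint_species_union_columns(self):
        # brute-force expectation: union of columns, zeros off own clusters
        recs = {
            "spA": [AnnotationRecord("a1", [("CL1", "33090")]),
                    AnnotationRecord("a2", [("CL1", "33090")])],
            "spB": [AnnotationRecord("b1", [("CL2", "33090")])],
        }
        m = build_matrix_from_annotations(recs, "33090")
        assert m.family_ids == ["CL1", "CL2"]
        assert m.counts.loc["spA"].tolist() == [2, 0]
        assert m.counts.loc["spB"].tolist() == [0, 1]

    def test_row_sums_match_in_scope_tally(self):
        rng = np.random.default_rng(0)
        recs = {}
        expected = {}
        for sp in ["spA", "spB", "spC"]:
            rows, tally = [], 0
            for g in range(20):
                pairs = []
                for cl in ["C1", "C2", "C3"]:
                    scope = rng.choice(["33090", "2759"])
                    pairs.append((cl + str(rng.integers(3)), str(scope)))
                tally += sum(1 for _, t in pairs if t == "33090")
                rows.append(AnnotationRecord(f"{sp}_g{g}", pairs))
            recs[sp] = rows
            expected[sp] = tally
        m = build_matrix_from_annotations(recs, "33090")
        for sp, tot in expected.items():
            assert m.counts.loc[sp].sum() == tot

    def test_emapper_dialect_reader(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text(
            "gene_id\teggNOG_OGs\n"
            "g1\t37MT6@33090,COG1@1\n"
            "g2\t-\n"
        )
        recs = read_annotations(p)
        assert recs[0].og_assignments == [("37MT6", "33090"), ("COG1", "1")]
        assert recs[1].og_assignments == []


class TestPathway:
    def test_missing_family_becomes_zero_column(self, toy_matrix):
        pmap = PathwayMap({"K13232": ["UNSEEN"]})
        sub = subset_families(toy_matrix, pmap)
        assert sub.family_ids == ["UNSEEN"]
        assert (sub.counts == 0).all().all()

    def test_subset_preserves_pathway_order(self, toy_matrix, toy_pathway):
        sub = subset_families(toy_matrix, toy_pathway)
        assert sub.family_ids == ["37M4G", "37R7W", "37Z74", "37MT6"]
        pd.testing.assert_frame_equal(
            sub.counts, toy_matrix.counts[sub.family_ids]
        )

    def test_shared_family_appears_once_and_logs(self, toy_matrix, caplog):
        pmap = PathwayMap({"K1": ["37M4G", "37R7W"], "K2": ["37M4G"]})
        with caplog.at_level(logging.WARNING):
            sub = subset_families(toy_matrix, pmap)
        assert sub.family_ids == ["37M4G", "37R7W"]
        assert any("37M4G" in r.message for r in caplog.records)

    def test_ratio_simple_division(self, toy_pathway):
        counts = pd.DataFrame(
            [[4, 3, 2, 1]], index=["spA"],
            columns=["37M4G", "37R7W", "37Z74", "37MT6"],
        )
        m = FamilyCountMatrix(counts, pd.Series([20000], index=["spA"]))
        assert pathway_ratio(m, toy_pathway)["spA"] == pytest.approx(10 / 20000)

    def test_ratio_zero_when_pathway_absent(self, toy_matrix):
        pmap = PathwayMap({"K9": ["NOPE"]})
        assert (pathway_ratio(toy_matrix, pmap) == 0).all()

    def test_shared_family_counted_once_in_ratio(self):
        # brute force: families {F1: 4, F2: 6}, F1 listed twice -> sum 10 not 14
        counts = pd.DataFrame([[4, 6]], index=["spA"], columns=["F1", "F2"])
        m = FamilyCountMatrix(counts, pd.Series([100], index=["spA"]))
        pmap = PathwayMap({"K1": ["F1", "F2"], "K2": ["F1"]})
        assert pathway_ratio(m, pmap)["spA"] == pytest.approx(0.10)

    def test_ratio_requires_totals(self, toy_pathway):
        m = FamilyCountMatrix(
            pd.DataFrame([[1]], index=["spA"], columns=["37M4G"])
        )
        with pytest.raises(ValueError):
            pathway_ratio(m, toy_pathway)

    def test_ratio_invariant_to_zero_families_and_order(self, toy_matrix, toy_pathway):
        base = pathway_ratio(toy_matrix, toy_pathway)
        shuffled = PathwayMap(
            {"K13232": ["37MT6"], "K10775": ["37Z74", "37M4G", "37R7W"]}
        )
        extra = PathwayMap(
            {**toy_pathway.entries, "K999": ["ALLZERO"]}
        )
        pd.testing.assert_series_equal(base, pathway_ratio(toy_matrix, shuffled))
        pd.testing.assert_series_equal(base, pathway_ratio(toy_matrix, extra))

    def test_pathway_map_reader(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("ko_id\tfamily_id\nK10775\t37M4G\nK10775\t37R7W\nK13232\t37MT6\n")
        pmap = read_pathway_map(p)
        assert pmap.entries == {"K10775": ["37M4G", "37R7W"], "K13232": ["37MT6"]}


class TestPresenceAndNormalize:
    def test_presence_thresholds_at_one(self):
        counts = pd.DataFrame(
            [[1, 0, 49], [0, 3, 0]], index=["a", "b"], columns=["F1", "F2", "F3"]
        )
        pa = presence_absence(FamilyCountMatrix(counts))
        assert pa.to_numpy().tolist() == [[1, 0, 1], [0, 1, 0]]

    def test_all_zero_matrix(self):
        m = FamilyCountMatrix(
            pd.DataFrame(np.zeros((2, 2), dtype=int), index=["a", "b"], columns=["F1", "F2"])
        )
        assert (presence_absence(m) == 0).all().all()

    def test_per_family_max(self):
        m = FamilyCountMatrix(
            pd.DataFrame([[0], [3], [1]], index=["a", "b", "c"], columns=["F1"])
        )
        normed = normalize_counts(m, "per_family_max")
        assert normed["F1"].tolist() == pytest.approx([0, 1, 1 / 3])

    def test_all_zero_column_no_nan(self):
        m = FamilyCountMatrix(
            pd.DataFrame([[0], [0]], index=["a", "b"], columns=["F1"])
        )
        normed = normalize_counts(m, "per_family_max")
        assert not normed.isna().any().any()
        assert (normed == 0).all().all()

    def test_per_species_total(self, toy_matrix):
        normed = normalize_counts(toy_matrix, "per_species_total")
        assert normed.loc["spA", "37Z74"] == pytest.approx(2 / 20000)

    def test_unknown_method_raises(self, toy_matrix):
        with pytest.raises(ValueError, match="unknown"):
            normalize_counts(toy_matrix, "quantile")

    def test_presence_consistent_with_normalization(self, toy_matrix):
        pa = presence_absence(toy_matrix)
        normed = normalize_counts(toy_matrix, "per_family_max")
        assert ((normed > 0).astype(int) == pa).all().all()


class TestClusterOrder:
    def test_single_row(self):
        assert cluster_order(np.array([[1.0, 2.0]]), "rows") == [0]

    def test_identical_pair_adjacent(self):
        # hand linkage: rows 0 and 2 identical (distance 0) merge first
        arr = np.array([[0.0, 0.0], [10.0, 10.0], [0.0, 0.0]])
        order = cluster_order(arr, "rows")
        assert abs(order.index(0) - order.index(2)) == 1

    def test_two_tight_clusters_contiguous(self):
        arr = np.array([[0.0], [0.1], [9.0], [9.1]])
        order = cluster_order(arr, "rows")
        groups = ["lo" if i < 2 else "hi" for i in order]
        assert groups in (["lo", "lo", "hi", "hi"], ["hi", "hi", "lo", "lo"])

    def test_column_axis(self):
        arr = np.array([[0.0, 9.0, 0.0], [0.0, 9.0, 0.1]])
        order = cluster_order(arr, "columns")
        assert abs(order.index(0) - order.index(2)) == 1

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        arr = rng.random((8, 5))
        assert cluster_order(arr, "rows") == cluster_order(arr.copy(), "rows")
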