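"""Data containers, readers/writers, round trips and validation errors."""

import numpy as np
import pandas as pd
import pytest

import refstab as rs
from refstab.io import result_to_frame, write_result_table

from conftest import random_cq_table


def _long_cq_text(sep="\t", n_conditions=8, n_reps=3, n_genes=11, mangle=None):
    lines = [sep.join(["gene", "condition", "replicate", "cq"])]
    rng = np.random.default_rng(0)
    for g in range(n_genes):
        for c in range(n_conditions):
            for r in range(1, n_reps + 1):
                cq = f"{rng.uniform(18, 30):.3f}"
                lines.append(sep.join([f"G{g}", f"cond{c}", str(r), cq]))
    text = "\n".join(lines) + "\n"
    return mangle(text) if mangle else text


class TestCqTableIO:
    def test_full_design_has_expected_cells(self, tmp_path):
        path = tmp_path / "cq.tsv"
        path.write_text(_long_cq_text())
        table = rs.read_cq_table(path)
        assert table.n_cells == 11 * 24
        assert len(table.conditions) == 8
        assert table.replicate_of("cond0_3") == 3

    def test_csv_delimiter_autodetected(self, tmp_path):
        path = tmp_path / "cq.csv"
        path.write_text(_long_cq_text(sep=","))
        table = rs.read_cq_table(path)
        assert len(table.samples) == 24

    def test_na_cq_becomes_missing(self, tmp_path):
        path = tmp_path / "cq.tsv"
        path.write_text(
            "gene\tcondition\treplicate\tcq\n"
            "A\tc1\t1\t20.1\nA\tc1\t2\tNA\nA\tc2\t1\t20.3\n"
        )
        table = rs.read_cq_table(path)
        assert np.isnan(table.cq("A", "c1_2"))
        assert table.cq("A", "c1_1") == 20.1

    def test_missing_condition_column_is_format_error(self, tmp_path):
        path = tmp_path / "cq.tsv"
        path.write_text("gene\treplicate\tcq\nA\t1\t20\n")
        with pytest.raises(rs.FormatError, match="condition"):
            rs.read_cq_table(path)

    def test_non_numeric_cq_names_row(self, tmp_path):
        path = tmp_path / "cq.tsv"
        path.write_text(
            "gene\tcondition\treplicate\tcq\n"
            "A\tc1\t1\t20\nA\tc1\t2\toops\nA\tc1\t3\t21\n"
        )
        with pytest.raises(rs.ParseError, match="row 3"):
            rs.read_cq_table(path)

    def test_duplicate_measurement_is_integrity_error(self, tmp_path):
        path = tmp_path / "cq.tsv"
        path.write_text(
            "gene\tcondition\treplicate\tcq\nA\tc1\t1\t20\nA\tc1\t1\t21\n"
        )
        with pytest.raises(rs.IntegrityError):
            rs.read_cq_table(path)

    def test_round_trip_preserves_values_and_metadata(self, tmp_path):
        rng = np.random.default_rng(3)
        table = random_cq_table(rng, n_genes=4, n_samples=6, n_conditions=3)
        path = tmp_path / "cq.tsv"
        rs.write_cq_table(table, path)
        back = rs.read_cq_table(path)
        assert back.genes == table.genes
        assert back.samples == table.samples
        # written at 6 significant digits; re-reading is exact at that precision
        np.testing.assert_allclose(
            back.values.to_numpy(), table.values.to_numpy(), rtol=1e-5
        )
        assert list(back.meta["condition"]) == list(table.meta["condition"])

    def test_row_permutation_does_not_change_table(self, tmp_path):
        rng = np.random.default_rng(4)
        table = random_cq_table(rng)
        long = table.to_long()
        shuffled = long.sample(frac=1.0, random_state=7)
        a = rs.CqTable.from_long(long)
        b = rs.CqTable.from_long(shuffled)
        b_aligned = b.values.loc[a.genes, a.samples]
        pd.testing.assert_frame_equal(a.values, b_aligned)
        # and downstream statistics agree exactly
        va = rs.pairwise_sd_matrix(a)
        vb = rs.pairwise_sd_matrix(b)
        pd.testing.assert_frame_equal(va, vb.loc[va.index, va.columns])


class TestCountMatrixIO:
    def _write(self, tmp_path, counts: pd.DataFrame, meta: pd.DataFrame):
        cpath, mpath = tmp_path / "counts.tsv", tmp_path / "meta.tsv"
        counts.to_csv(cpath, sep="\t", index_label="gene")
        meta.to_csv(mpath, sep="\t", index_label="sample")
        return cpath, mpath

    def _toy(self, n_genes=10, n_samples=4):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.integers(0, 500, size=(n_genes, n_samples)),
            index=[f"G{i}" for i in range(n_genes)],
            columns=[f"s{i}" for i in range(n_samples)],
        )
        counts.iloc[0] += 1  # keep library sizes positive
        meta = pd.DataFrame(
            {
                "condition": ["a", "a", "b", "b"],
                "replicate": [1, 2, 1, 2],
            },
            index=[f"s{i}" for i in range(n_samples)],
        )
        return counts, meta

    def test_reads_matrix_with_positive_libraries(self, tmp_path):
        counts, meta = self._toy(n_genes=1000, n_samples=4)
        cpath, mpath = self._write(tmp_path, counts, meta)
        m = rs.read_count_matrix(cpath, mpath)
        assert (m.library_sizes() > 0).all()
        assert m.genes[0] == "G0"

    def test_zero_library_sample_rejected(self, tmp_path):
        counts, meta = self._toy()
        counts["s3"] = 0
        cpath, mpath = self._write(tmp_path, counts, meta)
        with pytest.raises(rs.IntegrityError, match="zero library"):
            rs.read_count_matrix(cpath, mpath)

    def test_sample_missing_from_metadata_rejected(self, tmp_path):
        counts, meta = self._toy()
        cpath, mpath = self._write(tmp_path, counts, meta.drop("s2"))
        with pytest.raises(rs.IntegrityError, match="s2"):
            rs.read_count_matrix(cpath, mpath)

    def test_fractional_count_rejected(self, tmp_path):
        counts, meta = self._toy()
        counts = counts.astype(float)
        counts.iloc[1, 1] = 2.5
        cpath, mpath = self._write(tmp_path, counts, meta)
        with pytest.raises(rs.ParseError):
            rs.read_count_matrix(cpath, mpath)

    def test_round_trip(self, tmp_path):
        counts, meta = self._toy()
        m = rs.CountMatrix(counts, meta)
        cpath, mpath = tmp_path / "c.tsv", tmp_path / "m.tsv"
        rs.write_count_matrix(m, cpath, mpath)
        back = rs.read_count_matrix(cpath, mpath)
        pd.testing.assert_frame_equal(back.counts, m.counts)


class TestResultTables:
    def test_comprehensive_ranking_table_layout(self, tmp_path):
        vectors = {
            "m1": pd.Series([1.0, 2, 3], index=["A", "B", "C"]),
            "m2": pd.Series([2.0, 1, 3], index=["A", "B", "C"]),
        }
        ranking = rs.comprehensive_ranking(vectors)
        path = tmp_path / "out.tsv"
        write_result_table(ranking, path)
        frame = pd.read_csv(path, sep="\t")
        assert list(frame.columns) == ["gene", "m1", "m2", "geomean", "final_rank", "tie"]
        assert len(frame) == 3

    def test_empty_result_writes_header_only(self, tmp_path):
        from refstab.stability import StabilityResult

        empty = StabilityResult(
            "delta_ct",
            pd.DataFrame(columns=["value", "rank"], index=pd.Index([], name="gene")),
        )
        path = tmp_path / "empty.tsv"
        write_result_table(empty, path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("gene")

    def test_tied_rows_sorted_by_rank_then_gene(self):
        from refstab.stability import StabilityResult

        table = pd.DataFrame(
            {"value": [0.2, 0.2, 0.5], "rank": [1.0, 1.0, 3.0]},
            index=pd.Index(["B", "A", "C"], name="gene"),
        )
        frame = result_to_frame(StabilityResult("delta_ct", table))
        assert list(frame["gene"]) == ["A", "B", "C"]


class TestValidation:
    def test_replicates_unique_within_condition(self):
        values = pd.DataFrame({"s1": [20.0], "s2": [21.0]}, index=["A"])
        meta = pd.DataFrame(
            {"condition": ["c", "c"], "replicate": [1, 1]}, index=["s1", "s2"]
        )
        with pytest.raises(rs.IntegrityError, match="duplicate"):
            rs.CqTable(values, meta)

    def test_efficiency_bounds(self):
        with pytest.raises(rs.IntegrityError):
            rs.EfficiencyTable({"A": 2.5})
        table = rs.EfficiencyTable.from_percent({"A": 83.0})
        assert table.efficiency("A") == pytest.approx(1.83)
        assert table.efficiency("unlisted") == 2.0

    def test_runconfig_rejects_overlapping_gene_sets(self):
        with pytest.raises(rs.IntegrityError):
            rs.RunConfig(reference_genes=("A",), target_genes=("A", "B"))
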