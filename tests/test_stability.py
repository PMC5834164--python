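"""The four stability statistics against brute-force oracles and invariants."""

import math
import statistics

import numpy as np
import pandas as pd
import pytest

import refstab as rs

from conftest import random_cq_table


# ---------------------------------------------------------------- oracles
def brute_pairwise_sd(table: rs.CqTable) -> dict[tuple[str, str], float]:
    """Plain-Python SD of per-sample Cq differences for every gene pair."""
    out = {}
    for j, gj in enumerate(table.genes):
        for gk in table.genes[j + 1:]:
            diffs = [
                table.cq(gj, s) - table.cq(gk, s)
                for s in table.samples
                if not (math.isnan(table.cq(gj, s)) or math.isnan(table.cq(gk, s)))
            ]
            out[(gj, gk)] = statistics.stdev(diffs)
    return out


def brute_bestkeeper(table: rs.CqTable):
    sd, cv, r = {}, {}, {}
    index = []
    for s in table.samples:
        logs = [math.log(table.cq(g, s)) for g in table.genes]
        index.append(math.exp(sum(logs) / len(logs)))
    for g in table.genes:
        vals = [table.cq(g, s) for s in table.samples]
        sd[g] = statistics.stdev(vals)
        cv[g] = 100.0 * sd[g] / statistics.mean(vals)
        mx, mi = statistics.mean(vals), statistics.mean(index)
        num = sum((x - mx) * (y - mi) for x, y in zip(vals, index))
        den = math.sqrt(
            sum((x - mx) ** 2 for x in vals) * sum((y - mi) ** 2 for y in index)
        )
        r[g] = num / den
    return sd, cv, r


# ----------------------------------------------------------- pairwise SDs
class TestPairwiseSD:
    def test_matches_brute_force(self, toy_cq):
        v = rs.pairwise_sd_matrix(toy_cq)
        oracle = brute_pairwise_sd(toy_cq)
        for (gj, gk), expected in oracle.items():
            assert v.loc[gj, gk] == pytest.approx(expected, abs=1e-12)
            assert v.loc[gk, gj] == v.loc[gj, gk]
        assert (np.diag(v.to_numpy()) == 0).all()

    def test_constant_offset_gene_pair_has_zero_sd(self, toy_cq):
        values = toy_cq.values.copy()
        values.loc["B"] = values.loc["A"] + 3.7
        v = rs.pairwise_sd_matrix(toy_cq.with_values(values))
        assert v.loc["A", "B"] == pytest.approx(0.0, abs=1e-12)

    def test_per_sample_loading_offset_cancels(self, toy_cq):
        offsets = pd.Series([0.5, -1.2, 0.3, 2.0], index=toy_cq.samples)
        shifted = toy_cq.with_values(toy_cq.values.add(offsets, axis=1))
        v0 = rs.pairwise_sd_matrix(toy_cq)
        v1 = rs.pairwise_sd_matrix(shifted)
        np.testing.assert_allclose(v0.to_numpy(), v1.to_numpy(), atol=1e-12)

    def test_too_few_complete_samples_names_pair(self, toy_cq):
        values = toy_cq.values.copy()
        values.loc["A", ["c1_1", "c1_2"]] = np.nan
        with pytest.raises(rs.IntegrityError, match="'A'.*'B'"):
            rs.pairwise_sd_matrix(toy_cq.with_values(values))

    def test_efficiency_rescales_cq(self, toy_cq):
        eff = rs.EfficiencyTable({"A": 1.9, "B": 1.8, "C": 2.0})
        v = rs.pairwise_sd_matrix(toy_cq, eff)
        wa, wb = np.log2(1.9), np.log2(1.8)
        diffs = wa * toy_cq.values.loc["A"] - wb * toy_cq.values.loc["B"]
        assert v.loc["A", "B"] == pytest.approx(diffs.std(ddof=1))


# ----------------------------------------------------------------- geNorm
class TestGeNorm:
    def test_first_pass_m_equals_mean_pairwise_sd(self):
        rng = np.random.default_rng(11)
        table = random_cq_table(rng, n_genes=5, n_samples=8)
        v = rs.pairwise_sd_matrix(table)
        dct = rs.deltact_stability(table)
        m1 = v.sum(axis=1) / (len(v) - 1)
        # the first gene excluded by geNorm is the worst by first-pass M
        res = rs.genorm(table)
        first_excluded = res.table.index[res.table["excluded_step"] == 1][0]
        assert m1.idxmax() == first_excluded
        assert res.table.loc[first_excluded, "value"] == pytest.approx(
            m1.max(), abs=1e-12
        )
        np.testing.assert_allclose(m1.to_numpy(), dct.table["value"].to_numpy())

    def test_exact_copies_tie_at_rank_one(self):
        rng = np.random.default_rng(5)
        n = 8
        meta = pd.DataFrame(
            {"condition": ["c"] * n, "replicate": range(1, n + 1)},
            index=[f"c_{i}" for i in range(1, n + 1)],
        )
        x = rng.normal(22, 0.5, n)
        values = pd.DataFrame(
            {
                s: [x[i], x[i] + 1.0 + rng.normal(0, 0.01), x[i] + rng.normal(0, 0.6)]
                for i, s in enumerate(meta.index)
            },
            index=["X", "Y", "Z"],
        )
        res = rs.genorm(rs.CqTable(values, meta))
        assert res.rank("X") == 1 and res.rank("Y") == 1
        assert res.rank("Z") == 3
        assert res.table.loc["X", "tied_pair"] and res.table.loc["Y", "tied_pair"]

    def test_identical_pair_reaches_zero_m(self):
        meta = pd.DataFrame(
            {"condition": ["c"] * 4, "replicate": range(1, 5)},
            index=[f"c_{i}" for i in range(1, 5)],
        )
        base = np.array([20.0, 20.5, 21.0, 19.5])
        values = pd.DataFrame(
            {s: [base[i], base[i], base[i] + [0.3, -0.2, 0.5, 0.1][i]]
             for i, s in enumerate(meta.index)},
            index=["A", "B", "C"],
        )
        res = rs.genorm(rs.CqTable(values, meta))
        assert res.table.loc["C", "excluded_step"] == 1
        assert res.value("A") == pytest.approx(0.0, abs=1e-12)
        assert res.value("B") == pytest.approx(0.0, abs=1e-12)

    def test_needs_three_genes(self, toy_cq):
        with pytest.raises(rs.IntegrityError):
            rs.genorm(toy_cq.subset(["A", "B"]))

    def test_ranking_is_reverse_exclusion_order(self):
        rng = np.random.default_rng(19)
        table = random_cq_table(rng, n_genes=6, n_samples=10)
        res = rs.genorm(table)
        steps = res.table["excluded_step"]
        for gene, step in steps.items():
            if step > 0:
                n_excluded = int((steps > 0).sum())
                assert res.rank(gene) == 3 + (n_excluded - step)


# ------------------------------------------------------- comparative dCt
class TestDeltaCt:
    def test_two_gene_table_is_symmetric(self, toy_cq):
        res = rs.deltact_stability(toy_cq.subset(["A", "B"]))
        assert res.value("A") == res.value("B")

    def test_duplicating_a_gene_lowers_its_mean_sd(self, toy_cq):
        base = rs.deltact_stability(toy_cq)
        values = toy_cq.values.copy()
        values.loc["A2"] = values.loc["A"] + 0.001
        dup = rs.deltact_stability(toy_cq.with_values(values))
        assert dup.value("A") < base.value("A")


# -------------------------------------------------------------- BestKeeper
class TestBestKeeper:
    def test_matches_direct_formulas(self):
        rng = np.random.default_rng(23)
        table = random_cq_table(rng, n_genes=4, n_samples=6, n_conditions=2)
        res = rs.bestkeeper(table)
        sd, cv, r = brute_bestkeeper(table)
        for g in table.genes:
            assert res.value(g) == pytest.approx(sd[g], abs=1e-12)
            assert res.table.loc[g, "cv_percent"] == pytest.approx(cv[g], abs=1e-10)
            assert res.table.loc[g, "index_r"] == pytest.approx(r[g], abs=1e-10)

    def test_constant_gene_ranks_first(self, toy_cq):
        values = toy_cq.values.copy()
        values.loc["A"] = 21.0
        res = rs.bestkeeper(toy_cq.with_values(values))
        assert res.value("A") == 0.0
        assert res.table.loc["A", "cv_percent"] == 0.0
        assert res.rank("A") == 1

    def test_single_gene_correlates_perfectly_with_index(self, toy_cq):
        res = rs.bestkeeper(toy_cq.subset(["A"]))
        assert res.table.loc["A", "index_r"] == pytest.approx(1.0)

    def test_nonpositive_cq_rejected(self, toy_cq):
        values = toy_cq.values.copy()
        values.loc["A", "c1_1"] = -1.0
        with pytest.raises(rs.IntegrityError):
            rs.bestkeeper(toy_cq.with_values(values))

    def test_not_invariant_to_loading_offsets(self, toy_cq):
        offsets = pd.Series([2.0, -2.0, 1.0, -1.0], index=toy_cq.samples)
        shifted = toy_cq.with_values(toy_cq.values.add(offsets, axis=1))
        a = rs.bestkeeper(toy_cq).table["value"]
        b = rs.bestkeeper(shifted).table["value"]
        assert not np.allclose(a.to_numpy(), b.to_numpy())


# -------------------------------------------------------------- NormFinder
class TestNormFinder:
    def test_degenerate_minimum_all_zero(self):
        meta = pd.DataFrame(
            {"condition": ["a", "a", "b", "b"], "replicate": [1, 2, 1, 2]},
            index=["a_1", "a_2", "b_1", "b_2"],
        )
        shared = np.array([20.0, 20.7, 21.3, 19.9])
        values = pd.DataFrame(
            {s: shared[i] + np.array([0.0, 1.5, -2.0]) for i, s in enumerate(meta.index)},
            index=["A", "B", "C"],
        )
        res = rs.normfinder(rs.CqTable(values, meta))
        np.testing.assert_allclose(res.table["value"].to_numpy(), 0.0, atol=1e-12)

    def test_single_group_orders_by_residual_sd(self):
        n = 10
        meta = pd.DataFrame(
            {"condition": ["c"] * n, "replicate": range(1, n + 1)},
            index=[f"c_{i}" for i in range(1, n + 1)],
        )
        rng = np.random.default_rng(2)
        base = rng.normal(22, 0.3, n)
        values = pd.DataFrame(
            {
                s: [
                    base[i] + rng.normal(0, 0.1),
                    base[i] + rng.normal(0, 0.4),
                    base[i],
                ]
                for i, s in enumerate(meta.index)
            },
            index=["A", "B", "C"],
        )
        with pytest.warns(UserWarning, match="single group"):
            res = rs.normfinder(rs.CqTable(values, meta))
        assert res.rank("B") == max(res.table["rank"])

    def test_small_group_is_an_error(self, toy_cq):
        meta = toy_cq.meta.copy()
        meta.loc["c2_2", "condition"] = "c3"
        with pytest.raises(rs.IntegrityError, match="c3"):
            rs.normfinder(rs.CqTable(toy_cq.values, meta))

    def test_planted_group_shift_ranks_worst(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            table = random_cq_table(rng, n_genes=5, n_samples=12, n_conditions=3)
            values = table.values * 0 + rng.normal(22, 0.15, size=table.values.shape)
            values.loc["G0", table.samples_in("cond1")] += 1.0
            res = rs.normfinder(table.with_values(values))
            hits += res.rank("G0") == 5
        assert hits >= 19

    def test_bias_sums_to_zero_per_gene(self, hatching_cq):
        _, table, _ = hatching_cq
        res = rs.normfinder(table)
        np.testing.assert_allclose(res.bias.sum(axis=1).to_numpy(), 0.0, atol=1e-10)


# --------------------------------------------------------------- Cq spread
class TestCqSpread:
    def test_constant_gene_five_numbers_collapse(self, toy_cq):
        values = toy_cq.values.copy()
        values.loc["A"] = 20.0
        spread = rs.cq_spread(toy_cq.with_values(values))
        row = spread.loc["A"]
        assert row["min"] == row["q1"] == row["median"] == row["q3"] == row["max"]
        assert row["outliers"] == ""

    def test_linear_interpolation_quartiles(self):
        meta = pd.DataFrame(
            {"condition": [f"c{i}" for i in range(8)], "replicate": [1] * 8},
            index=[f"c{i}_1" for i in range(8)],
        )
        values = pd.DataFrame([np.arange(1.0, 9.0)], index=["A"], columns=meta.index)
        spread = rs.cq_spread(rs.CqTable(values, meta))
        assert spread.loc["A", "median"] == 4.5
        assert spread.loc["A", "q1"] == 2.75
        assert spread.loc["A", "q3"] == 6.25
        assert spread.loc["A", "range"] == 7.0

    def test_widest_gene_ranks_worst_by_range(self, hatching_cq):
        cfg, table, truth = hatching_cq
        candidates = [g for g in table.genes if truth.roles[g] != "pulse"]
        spread = rs.cq_spread(table.subset(candidates))
        widest = spread["range"].sort_values().index[-2:]
        assert set(widest) <= {"Act-1", "EIF-3"}


# ----------------------------------------------------- method-level invariants
class TestInvariants:
    def test_loading_offset_invariance_of_cq_methods(self, hatching_cq):
        _, table, _ = hatching_cq
        rng = np.random.default_rng(9)
        offsets = pd.Series(rng.normal(0, 1.5, len(table.samples)), index=table.samples)
        shifted = table.with_values(table.values.add(offsets, axis=1))
        for fn in (rs.deltact_stability, rs.genorm, rs.normfinder):
            a = fn(table).table["value"]
            b = fn(shifted).table["value"]
            np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-9)

    def test_scaling_deviations_scales_statistics(self, toy_cq):
        c = 2.5
        center = toy_cq.values.mean(axis=1)
        scaled = toy_cq.with_values(
            toy_cq.values.sub(center, axis=0).mul(c).add(center, axis=0)
        )
        for fn in (rs.deltact_stability, rs.genorm, rs.normfinder):
            a = fn(toy_cq).table["value"]
            b = fn(scaled).table["value"]
            np.testing.assert_allclose(b.to_numpy(), c * a.to_numpy(), atol=1e-9)
        a = rs.bestkeeper(toy_cq).table["value"]
        b = rs.bestkeeper(scaled).table["value"]
        np.testing.assert_allclose(b.to_numpy(), c * a.to_numpy(), atol=1e-9)
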