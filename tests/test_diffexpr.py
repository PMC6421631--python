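"""Differential-expression pipeline: normalisation, NB Wald test, BH,
FPKM, clustering summaries, Venn regions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isoformgrid import diffexpr as de
from isoformgrid import io_formats as iof
from isoformgrid import synthetic_data as sd


def make_table(matrix, cell_line="A", treatments=None):
    matrix = np.asarray(matrix)
    n = matrix.shape[1]
    treatments = treatments or ["siNEG"] * (n // 2) + ["siMyb"] * (n - n // 2)
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "cell_line": [cell_line] * n,
            "treatment": treatments,
            "replicate": list(range(1, n + 1)),
        }
    )
    genes = [f"g{i}" for i in range(matrix.shape[0])]
    return iof.CountTable(genes, samples, matrix)


class TestSizeFactors:
    def test_proportional_libraries(self):
        m = np.array([[10, 20], [30, 60], [5, 10]])
        f = de.size_factors(m)
        assert f[1] / f[0] == pytest.approx(2.0)

    def test_identical_samples_give_unit_factors(self):
        m = np.array([[10, 10], [30, 30]])
        np.testing.assert_allclose(de.size_factors(m), [1.0, 1.0])

    def test_three_gene_toy_hand_computed(self):
        # medians of ratios are (1/sqrt 2, sqrt 2) after geometric rescale
        m = np.array([[10, 20], [20, 40], [30, 60]])
        np.testing.assert_allclose(
            de.size_factors(m), [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12
        )

    def test_no_all_positive_gene_is_an_error(self):
        with pytest.raises(ValueError, match="filter"):
            de.size_factors(np.array([[0, 5], [5, 0]]))


class TestNBTest:
    def test_all_zero_gene_untested(self):
        m = np.vstack([np.zeros(6, dtype=int), np.full(6, 50)])
        res = de.nb_test_all(make_table(m), "A")
        row = res.iloc[0]
        assert (row["p"], row["log2fc"], row["tested"]) == (1.0, 0.0, False)

    def test_planted_fourfold_recovered(self):
        # 50 of 300 genes 4-fold up (normalisation needs a null majority)
        rng = np.random.default_rng(0)
        n, n_de = 300, 50
        mu = rng.lognormal(np.log(100), 1.0, n)
        fold = np.ones(n)
        fold[:n_de] = 4.0
        r = 1 / 0.05
        a = rng.negative_binomial(r, r / (r + np.repeat(mu[:, None], 3, 1)))
        b = rng.negative_binomial(
            r, r / (r + np.repeat((fold * mu)[:, None], 3, 1))
        )
        res = de.nb_test_all(make_table(np.hstack([a, b])), "A")
        assert np.median(res["log2fc"][:n_de]) == pytest.approx(2.0, abs=0.3)
        assert (res["q"][:n_de] < 0.05).mean() > 0.9

    def test_requires_two_replicates(self):
        m = np.array([[5, 6], [7, 8]])
        with pytest.raises(ValueError, match="replicates"):
            de.nb_test_all(make_table(m, treatments=["siNEG", "siMyb"]), "A")

    def test_single_gene_wrapper_matches_table(self):
        rng = np.random.default_rng(1)
        m = rng.poisson(50, size=(20, 6))
        table = make_table(m)
        res = de.nb_test_all(table, "A")
        p, lfc = de.nb_test(table, "A", "g3")
        assert p == pytest.approx(res.loc[3, "p"])
        assert lfc == pytest.approx(res.loc[3, "log2fc"])


class TestCallDE:
    @pytest.mark.parametrize(
        "q,lfc,expected",
        [
            (0.01, -2.0, "down"),
            (0.01, 0.5, "ns"),
            (0.2, -2.0, "ns"),
            (0.01, 1.0, "up"),
        ],
    )
    def test_threshold_logic(self, q, lfc, expected):
        res = pd.DataFrame({"gene_id": ["g"], "log2fc": [lfc], "q": [q]})
        down, up = de.call_de(res)
        got = "down" if "g" in down else "up" if "g" in up else "ns"
        assert got == expected

    def test_empty_results(self):
        assert de.call_de(pd.DataFrame()) == (set(), set())

    def test_fixture_down_set_recovers_planted(self, simulation, de_results):
        tables, _ = de_results
        truth = simulation["truth"].genes
        for line in ("FMH9", "KL"):
            down, up = de.call_de(tables[line])
            planted_down = set(truth.loc[truth[f"de_{line}"] == "down", "gene_id"])
            jacc = len(down & planted_down) / len(down | planted_down)
            assert jacc >= 0.7


class TestBH:
    @staticmethod
    def brute_force_bh(p):
        """Literal step-up definition: q_i = min over j>=rank(i) of
        min(1, m * p_(j) / j)."""
        p = np.asarray(p, dtype=float)
        m = len(p)
        order = np.argsort(p, kind="stable")
        q = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, m * p[i] / rank)
            q[i] = running
        return q

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 60))
            np.testing.assert_allclose(
                de.bh_adjust(p), self.brute_force_bh(p), rtol=1e-12
            )

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_monotone_in_p_rank(self, pvals):
        q = de.bh_adjust(np.array(pvals))
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestFPKM:
    def _models(self, lengths):
        return [
            iof.GeneModel(
                f"g{i}", f"g{i}",
                iof.GenomicInterval("chr1", i * 10_000, i * 10_000 + L, "+"),
                "+", L,
            )
            for i, L in enumerate(lengths)
        ]

    def test_definitional_value(self):
        # 10 counts, 1 kb gene, 1e6 library -> FPKM 10
        m = np.array([[10, 10], [999_990, 999_990]])
        models = self._models([1000, 100_000])
        out = de.fpkm(make_table(m), models)
        assert out.iloc[0, 0] == pytest.approx(10.0)

    def test_scale_invariance_and_zero(self):
        m = np.array([[10, 20], [90, 180], [0, 0]])
        models = self._models([500, 700, 900])
        a = de.fpkm(make_table(m), models)
        b = de.fpkm(make_table(m * 7), models)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy())
        assert (a.iloc[2] == 0).all()

    def test_missing_model_lists_genes(self):
        with pytest.raises(ValueError, match="g1"):
            de.fpkm(make_table(np.ones((2, 2), dtype=int)), self._models([100]))


class TestSpearmanCluster:
    def test_duplicate_sample_rho_one_and_reversal_minus_one(self):
        base = np.arange(1.0, 21.0)
        mat = pd.DataFrame(
            {"a": base, "b": base, "c": base[::-1]}
        )
        corr, _ = de.spearman_cluster(mat)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "c"] == pytest.approx(-1.0)

    def test_constant_sample_rejected(self):
        mat = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [0.0, 0.0, 0.0]})
        with pytest.raises(ValueError, match="constant"):
            de.spearman_cluster(mat)

    def test_planted_similar_pair_merges_first(self):
        rng = np.random.default_rng(3)
        shared = rng.lognormal(3, 1, 500)
        mat = pd.DataFrame(
            {
                "a": shared * rng.lognormal(0, 0.1, 500),
                "b": shared * rng.lognormal(0, 0.1, 500),
                "c": rng.lognormal(3, 1, 500),
            }
        )
        _, order = de.spearman_cluster(mat)
        assert order.index("c") in (0, 2)  # a,b adjacent


class TestClusterLog2FC:
    def _matrix(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 200)
        return pd.DataFrame(
            {
                "FMH9": x + rng.normal(0, 0.2, 200),
                "KL": x + rng.normal(0, 0.2, 200),
                "LL": rng.normal(0, 0.2, 200),
            },
            index=[f"g{i}" for i in range(200)],
        )

    def test_concordant_columns_adjacent(self):
        _, col_order = de.cluster_log2fc(self._matrix())
        assert col_order.index("LL") in (0, 2)

    def test_row_permutation_invariance(self):
        m = self._matrix()
        r1, c1 = de.cluster_log2fc(m)
        shuffled = m.sample(frac=1, random_state=9)
        r2, c2 = de.cluster_log2fc(shuffled)
        assert r1 == r2 and c1 == c2

    def test_identical_columns_merge_first(self):
        m = self._matrix()
        m["KL"] = m["FMH9"]
        _, col_order = de.cluster_log2fc(m)
        assert abs(col_order.index("FMH9") - col_order.index("KL")) == 1

    def test_single_column_rejected(self):
        with pytest.raises(ValueError):
            de.cluster_log2fc(self._matrix()[["FMH9"]])


class TestVenn:
    def test_two_set_example(self):
        regions = de.venn_overlaps({"x": {"a", "b"}, "y": {"b", "c"}})
        assert regions[frozenset({"x"})] == 1
        assert regions[frozenset({"y"})] == 1
        assert regions[frozenset({"x", "y"})] == 1

    def test_identical_sets(self):
        regions = de.venn_overlaps({"x": {"a", "b"}, "y": {"a", "b"}})
        assert regions[frozenset({"x", "y"})] == 2
        assert regions[frozenset({"x"})] == regions[frozenset({"y"})] == 0

    def test_region_sums_equal_union(self):
        rng = np.random.default_rng(11)
        universe = [f"g{i}" for i in range(1000)]
        sets = {
            name: set(rng.choice(universe, 100, replace=False))
            for name in "abc"
        }
        regions = de.venn_overlaps(sets)
        assert sum(regions.values()) == len(set().union(*sets.values()))


def test_null_simulation_type_one_control():
    """Rejection rate at alpha = 0.05 stays in [0.5a, 1.5a] on null NB data
    (2,000 genes, 3v3)."""
    rates = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        mu = rng.lognormal(np.log(100), 1.2, 2000)
        r = 1 / 0.05
        counts = rng.negative_binomial(
            r, r / (r + np.repeat(mu[:, None], 6, 1))
        )
        res = de.nb_test_all(make_table(counts), "A")
        rates.append((res.loc[res["tested"], "p"] < 0.05).mean())
    assert 0.025 <= np.mean(rates) <= 0.075
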