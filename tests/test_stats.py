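"""Correlation matrices, metagene scores, group tests, Fisher enrichment."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ighquant.stats import (
    CohortStatsError,
    GeneSetCollection,
    MetageneDefinition,
    age_trend,
    correlation_matrix,
    enrichment_fisher,
    example_metagenes,
    group_compare,
    metagene_score,
    read_gmt,
    read_metagenes_yaml,
    top_correlated_genes,
)
from ighquant.synthetic import simulate_expression_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(17)


def _random_expr(rng, n=20, g=5):
    return pd.DataFrame(
        rng.standard_normal((n, g)),
        index=[f"s{i}" for i in range(n)],
        columns=[f"g{j}" for j in range(g)],
    )


class TestCorrelationMatrix:
    def test_unit_diagonal_and_symmetry(self, rng):
        corr = correlation_matrix(_random_expr(rng))
        assert np.allclose(np.diag(corr), 1.0)
        assert np.allclose(corr, corr.T)
        assert (corr.to_numpy() <= 1 + 1e-12).all() and (corr.to_numpy() >= -1 - 1e-12).all()

    def test_perfect_anticorrelation(self):
        expr = pd.DataFrame({"a": [1, 2, 3], "b": [3, 2, 1]})
        assert correlation_matrix(expr).loc["a", "b"] == pytest.approx(-1.0)

    def test_spearman_matches_rank_pearson_oracle(self, rng):
        """Spearman equals Pearson applied to average ranks (textbook formula)."""
        expr = _random_expr(rng)
        expr.iloc[0, 0] = expr.iloc[1, 0]  # introduce a tie
        got = correlation_matrix(expr, method="spearman")
        ranks = expr.apply(lambda c: sps.rankdata(c))
        for a in expr.columns:
            for b in expr.columns:
                x, y = ranks[a].to_numpy(), ranks[b].to_numpy()
                xc, yc = x - x.mean(), y - y.mean()
                oracle = (xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc))
                assert got.loc[a, b] == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_gene_reported_missing(self, rng):
        expr = _random_expr(rng)
        expr["const"] = 1.0
        corr = correlation_matrix(expr)
        assert corr["const"].drop("const").isna().all()
        assert not (corr["const"].drop("const") == 0).any()

    def test_too_few_samples(self):
        with pytest.raises(CohortStatsError):
            correlation_matrix(pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]}))


class TestMetageneScore:
    def test_single_marker_equals_column(self, rng):
        expr = _random_expr(rng)
        score = metagene_score(expr, MetageneDefinition("m", ("g0",)))
        assert (score == expr["g0"]).all()

    def test_constant_markers(self):
        expr = pd.DataFrame({"a": [2.0, 2.0], "b": [4.0, 4.0]})
        score = metagene_score(expr, MetageneDefinition("m", ("a", "b")))
        assert (score == 3.0).all()

    def test_matches_column_mean_oracle_and_marker_order(self, rng):
        expr = _random_expr(rng, g=12)
        markers = tuple(f"g{j}" for j in range(10))
        score = metagene_score(expr, MetageneDefinition("m", markers))
        oracle = expr[list(markers)].to_numpy().mean(axis=1)
        assert np.allclose(score.to_numpy(), oracle, atol=1e-12)
        rev = metagene_score(expr, MetageneDefinition("m", markers[::-1]))
        assert (score == rev).all()

    def test_commutes_with_sample_permutation(self, rng):
        expr = _random_expr(rng)
        d = MetageneDefinition("m", ("g0", "g1", "g2"))
        perm = rng.permutation(expr.index)
        assert (metagene_score(expr, d).loc[perm]
                == metagene_score(expr.loc[perm], d)).all()

    def test_absent_markers_dropped_all_absent_error(self, rng):
        expr = _random_expr(rng)
        score = metagene_score(expr, MetageneDefinition("m", ("g0", "NOPE")))
        assert (score == expr["g0"]).all()
        with pytest.raises(CohortStatsError):
            metagene_score(expr, MetageneDefinition("m", ("NOPE",)))


class TestGroupCompare:
    def test_identical_groups(self):
        v = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        g = pd.Series(["a", "a", "a", "b", "b", "b"])
        t, p = group_compare(v, g)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_separated_groups_welch_oracle(self, rng):
        a = np.array([0.0, 0.01, -0.01, 0.02])
        b = np.array([1.0, 1.01, 0.99, 1.02])
        v = pd.Series(np.r_[a, b])
        g = pd.Series(["a"] * 4 + ["b"] * 4)
        t, p = group_compare(v, g)
        # closed-form Welch statistic
        se = math.sqrt(a.var(ddof=1) / 4 + b.var(ddof=1) / 4)
        assert t == pytest.approx((a.mean() - b.mean()) / se, abs=1e-10)
        assert p < 0.01

    def test_label_swap_flips_sign(self, rng):
        v = pd.Series(rng.standard_normal(10))
        g = pd.Series(["x"] * 5 + ["y"] * 5)
        g2 = g.map({"x": "y", "y": "x"})
        t1, p1 = group_compare(v, g)
        t2, p2 = group_compare(v, g2)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_small_group_rejected(self):
        with pytest.raises(CohortStatsError):
            group_compare(pd.Series([1.0, 2.0, 3.0]), pd.Series(["a", "b", "b"]))


class TestAgeTrend:
    def test_perfect_linear_fit(self):
        age = pd.Series([40.0, 50, 60, 70, 80])
        slope, p = age_trend(0.1 * age + 2.0, age)
        assert slope == pytest.approx(0.1, abs=1e-12)
        assert p < 1e-8

    def test_constant_age_rejected(self):
        with pytest.raises(CohortStatsError):
            age_trend(pd.Series([1.0, 2.0, 3.0]), pd.Series([50.0, 50.0, 50.0]))

    def test_slope_invariant_to_expression_shift(self, rng):
        age = pd.Series(rng.uniform(40, 80, 30))
        expr = pd.Series(rng.standard_normal(30))
        s1, _ = age_trend(expr, age)
        s2, _ = age_trend(expr + 5.0, age)
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_null_p_values_uniform(self):
        """Expression independent of age: p uniform on (0,1) (KS check)."""
        rng = np.random.default_rng(123)
        ps = []
        for _ in range(200):
            age = pd.Series(rng.uniform(40, 80, 500))
            expr = pd.Series(rng.standard_normal(500))
            ps.append(age_trend(expr, age)[1])
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestTopCorrelatedGenes:
    def test_planted_block_recovered(self, rng):
        expr, _, _ = simulate_expression_matrix(
            n_samples=100, n_genes=60, planted_size=10, noise_sd=0.2, seed=3)
        top = top_correlated_genes(expr, "IGHG1", k=10)
        assert set(top) == {f"PL{i:03d}" for i in range(10)}

    def test_k_zero_empty(self, rng):
        assert top_correlated_genes(_random_expr(rng), "g0", k=0) == []

    def test_target_never_included(self, rng):
        expr = _random_expr(rng, g=6)
        assert "g0" not in top_correlated_genes(expr, "g0", k=4)

    def test_constant_target_rejected(self, rng):
        expr = _random_expr(rng)
        expr["g0"] = 3.0
        with pytest.raises(CohortStatsError):
            top_correlated_genes(expr, "g0", k=2)

    def test_ties_break_lexicographically(self):
        base = pd.Series([1.0, 2.0, 3.0, 4.0])
        expr = pd.DataFrame({"t": base, "zz": base * 2, "aa": base + 1, "neg": -base})
        assert top_correlated_genes(expr, "t", k=2) == ["aa", "zz"]


def hypergeom_tail_oracle(a, hits, set_size, universe):
    """P(overlap >= a) by explicit tail summation with exact rationals."""
    total = Fraction(0)
    for x in range(a, min(hits, set_size) + 1):
        total += Fraction(
            math.comb(set_size, x) * math.comb(universe - set_size, hits - x),
            math.comb(universe, hits),
        )
    return float(total)


class TestEnrichmentFisher:
    def test_matches_hypergeometric_tail_oracle(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(2000)]
        for _ in range(100):
            n_hits = int(rng.integers(5, 150))
            set_size = int(rng.integers(5, 400))
            overlap = int(rng.integers(0, min(n_hits, set_size) + 1))
            hits = genes[:n_hits]
            gene_set = genes[n_hits - overlap: n_hits - overlap + set_size]
            coll = GeneSetCollection(sets={"s": gene_set}, universe=genes)
            p = enrichment_fisher(hits, coll).loc["s", "p"]
            oracle = hypergeom_tail_oracle(overlap, n_hits, set_size, 2000)
            assert p == pytest.approx(oracle, abs=1e-12)

    def test_degenerate_set_equals_universe(self):
        genes = ["a", "b", "c"]
        coll = GeneSetCollection(sets={"s": genes}, universe=genes)
        assert enrichment_fisher(genes, coll).loc["s", "p"] == pytest.approx(1.0)

    def test_zero_overlap_large_set(self):
        genes = [f"g{i}" for i in range(100)]
        coll = GeneSetCollection(sets={"s": genes[50:]}, universe=genes)
        assert enrichment_fisher(genes[:10], coll).loc["s", "p"] == pytest.approx(1.0)

    def test_empty_hits_rejected(self):
        coll = GeneSetCollection(sets={"s": ["a"]}, universe=["a", "b"])
        with pytest.raises(CohortStatsError):
            enrichment_fisher([], coll)

    def test_hits_outside_universe_rejected(self):
        coll = GeneSetCollection(sets={"s": ["a"]}, universe=["a", "b"])
        with pytest.raises(CohortStatsError):
            enrichment_fisher(["zzz"], coll)

    def test_planted_set_ranks_first(self):
        expr, coll, planted = simulate_expression_matrix(
            n_samples=150, n_genes=400, planted_size=20, noise_sd=0.3, seed=9)
        hits = top_correlated_genes(expr, "IGHG1", k=100)
        enr = enrichment_fisher(hits, coll)
        assert enr.index[0] == planted


class TestIO:
    def test_read_gmt(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("SET_A\tdesc\tg1\tg2\tg3\nSET_B\tdesc\tg2\tg4\n")
        coll = read_gmt(p, universe=["g1", "g2", "g3", "g4", "g5"])
        assert coll.sets["SET_A"] == ["g1", "g2", "g3"]
        # restricted to universe
        coll2 = read_gmt(p, universe=["g1", "g2", "g4"])
        assert coll2.sets["SET_A"] == ["g1", "g2"]

    def test_metagene_yaml_roundtrip(self, tmp_path):
        p = tmp_path / "mg.yaml"
        p.write_text("t_cells: [CD3D, CD3E]\n")
        defs = read_metagenes_yaml(p)
        assert defs[0].name == "t_cells" and defs[0].markers == ("CD3D", "CD3E")

    def test_packaged_example_metagenes_load(self):
        defs = example_metagenes()
        names = {d.name for d in defs}
        assert {"t_cells", "b_lineage", "fibroblasts", "treg"} <= names
        assert all(len(set(d.markers)) == len(d.markers) for d in defs)
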