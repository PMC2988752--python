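"""Tests of enrichment, correlation and expression-validation statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from zmeta.synthetic import generate_expression_matrix, generate_truth
from zmeta.validation import (
    GeneSet,
    bonferroni,
    compare_correlations,
    enrichment_ttest,
    pearson_z_correlation,
    per_gene_ttest,
    relative_z,
    set_mean_z,
    spearman_rank_validation,
)

from conftest import make_table, random_table


def pooled_t(x, y):
    """Textbook pooled-variance two-sample t statistic (independent oracle)."""
    nx_, ny = len(x), len(y)
    sp2 = ((nx_ - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (
        nx_ + ny - 2
    )
    return (np.mean(x) - np.mean(y)) / math.sqrt(sp2 * (1 / nx_ + 1 / ny))


class TestRelativeZ:
    def test_whole_table_is_unity(self, rng):
        table = random_table(rng, 40)
        gs = GeneSet.from_iterable("all", table.genes)
        assert relative_z(table, gs).ratio == pytest.approx(1.0)

    def test_small_example(self):
        table = make_table({"A": 3.0, "B": -1.0, "C": 1.0, "D": 1.0})
        out = relative_z(table, GeneSet.from_iterable("s", ["A"]))
        assert out.ratio == pytest.approx(2.0)
        assert out.set_mean_abs_z == pytest.approx(3.0)
        assert out.overall_mean_abs_z == pytest.approx(1.5)
        assert out.n_members == 1

    def test_random_sets_concentrate_near_unity(self, rng):
        table = random_table(rng, 800)
        ratios = []
        for _ in range(200):
            members = rng.choice(table.genes, size=100, replace=False)
            ratios.append(relative_z(table, GeneSet.from_iterable("r", members)).ratio)
        assert abs(np.mean(ratios) - 1.0) < 0.05

    def test_disjoint_set_raises(self):
        table = make_table({"A": 1.0})
        with pytest.raises(ValueError, match="nope"):
            relative_z(table, GeneSet.from_iterable("nope", ["X"]))


class TestEnrichmentTtest:
    def test_identical_groups_give_zero_t(self):
        table = make_table({"A": 1.0, "B": 2.0, "C": -1.0, "D": -2.0})
        t, df, p = enrichment_ttest(table, GeneSet.from_iterable("half", ["A", "B"]))
        assert t == pytest.approx(0.0, abs=1e-12)
        assert df == 2
        assert p == pytest.approx(1.0)

    def test_matches_pooled_formula(self):
        table = make_table({"A": 3.0, "B": 4.0, "C": 1.0, "D": 2.0, "E": 1.0, "F": 2.0})
        t, df, _ = enrichment_ttest(table, GeneSet.from_iterable("s", ["A", "B"]))
        assert t == pytest.approx(pooled_t([3.0, 4.0], [1.0, 2.0, 1.0, 2.0]), abs=1e-12)
        assert df == len(table) - 2

    def test_oracle_equivalence_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 60))
            table = random_table(rng, n)
            k = int(rng.integers(2, n - 2))
            members = rng.choice(table.genes, size=k, replace=False)
            t, df, _ = enrichment_ttest(table, GeneSet.from_iterable("s", members))
            abs_z = table.z.abs()
            x = abs_z.loc[table.genes.intersection(sorted(set(members)))].to_numpy()
            y = abs_z.drop(list(set(members))).to_numpy()
            assert t == pytest.approx(pooled_t(x, y), abs=1e-10)
            assert df == n - 2


class TestCorrelations:
    def test_self_correlation(self, rng):
        t = random_table(rng, 50)
        r, n = pearson_z_correlation(t, t)
        assert r == pytest.approx(1.0)
        assert n == 50

    def test_negated_correlation(self, rng):
        t = random_table(rng, 50)
        neg = make_table((-t.z).to_dict())
        r, _ = pearson_z_correlation(t, neg)
        assert r == pytest.approx(-1.0)

    def test_recovers_population_rho(self, rng):
        n = 10_000
        rho = 0.3
        x = rng.standard_normal(n)
        y = rho * x + math.sqrt(1 - rho**2) * rng.standard_normal(n)
        genes = [f"G{i:05d}" for i in range(n)]
        r, _ = pearson_z_correlation(
            make_table(dict(zip(genes, x))), make_table(dict(zip(genes, y)))
        )
        assert abs(r - rho) < 0.03

    def test_too_few_shared_genes(self):
        a, b = make_table({"A": 1.0, "B": 2.0}), make_table({"A": 1.0, "B": 0.5})
        with pytest.raises(ValueError):
            pearson_z_correlation(a, b)


class TestCompareCorrelations:
    def test_equal_correlations_give_zero(self):
        assert compare_correlations(0.4, 100, 0.4, 5000) == pytest.approx(0.0)

    def test_fisher_formula_example(self):
        # (atanh 0.36 - atanh 0.22) / sqrt(1/10821 + 1/11981), frozen from
        # high-precision evaluation of the closed form
        z = compare_correlations(0.36, 10_824, 0.22, 11_984)
        assert z == pytest.approx(11.5544, abs=1e-3)

    def test_antisymmetry(self):
        z1 = compare_correlations(0.3, 500, 0.1, 700)
        z2 = compare_correlations(0.1, 700, 0.3, 500)
        assert z1 == pytest.approx(-z2)

    def test_monotone_in_r1(self):
        zs = [compare_correlations(r, 200, 0.2, 200) for r in (0.0, 0.2, 0.5, 0.8)]
        assert zs == sorted(zs)

    @pytest.mark.parametrize("bad", [(1.0, 10, 0.2, 10), (0.2, 3, 0.1, 10)])
    def test_rejects_degenerate_inputs(self, bad):
        with pytest.raises(ValueError):
            compare_correlations(*bad)


class TestSpearmanValidation:
    def test_monotone_transform_gives_unity(self, rng):
        t = random_table(rng, 100)
        lr = pd.Series(np.exp(t.z / 2), index=t.genes)  # strictly increasing
        rho, n, _ = spearman_rank_validation(t, lr)
        assert rho == pytest.approx(1.0)
        assert n == 100

    def test_reversal_gives_minus_one(self, rng):
        t = random_table(rng, 100)
        rho, _, _ = spearman_rank_validation(t, pd.Series(-t.z, index=t.genes))
        assert rho == pytest.approx(-1.0)

    def test_independent_orderings_near_zero(self, rng):
        t = random_table(rng, 1000)
        lr = pd.Series(rng.standard_normal(1000), index=t.genes)
        rho, _, _ = spearman_rank_validation(t, lr)
        assert abs(rho) < 0.1


class TestSetMeanZ:
    def test_identical_sets_share_means(self, rng):
        t = random_table(rng, 30)
        all_set = GeneSet.from_iterable("all", t.genes)
        out = set_mean_z(t, all_set, all_set)
        assert out["up"][0] == pytest.approx(out["down"][0])
        assert out["up"][0] == pytest.approx(out["all"][0])

    def test_two_gene_example(self):
        t = make_table({"A": 2.0, "B": -2.0})
        out = set_mean_z(
            t, GeneSet.from_iterable("up", ["A"]), GeneSet.from_iterable("down", ["B"])
        )
        assert out["up"][0] == pytest.approx(2.0)
        assert out["down"][0] == pytest.approx(-2.0)
        assert out["all"][0] == pytest.approx(0.0)

    def test_external_study_ordering(self, small_scenario):
        """Planted up genes score above the overall mean, down genes below."""
        truth, _, result = small_scenario
        eff = truth.effect["localized_vs_metastatic"]
        up = GeneSet.from_iterable("up", eff.index[eff > 0])
        down = GeneSet.from_iterable("down", eff.index[eff < 0])
        out = set_mean_z(result.level3, up, down)
        assert out["up"][0] > out["all"][0] > out["down"][0]


class TestPerGeneTtest:
    def test_null_matrix_statistics(self):
        truth = generate_truth(200, 0, seed=3)
        m = generate_expression_matrix(truth, "normal_vs_tumor", 9, 5, seed=4)
        out = per_gene_ttest(m)
        # p roughly uniform under the null; no tiny-p pileup
        assert out["p_value"].min() > 1e-6
        assert abs(out["log_ratio"].mean()) < 0.2

    def test_clear_shift_called_up(self, rng):
        values = pd.DataFrame(
            [[2.0, 2.01, 1.99, 0.0, 0.01, -0.01]],
            index=["G1"],
            columns=[f"S{i}" for i in range(6)],
        )
        groups = pd.Series(["case"] * 3 + ["control"] * 3, index=values.columns)
        from zmeta.synthetic import ExpressionMatrix

        out = per_gene_ttest(ExpressionMatrix(values, groups))
        assert out.loc["G1", "direction"] == "up"
        assert out.loc["G1", "p_value"] < 1e-4

    def test_matches_textbook_formula(self, rng):
        truth = generate_truth(100, 20, effect_size_mean=0.7, seed=6)
        m = generate_expression_matrix(truth, "normal_vs_tumor", 9, 5, seed=7)
        out = per_gene_ttest(m)
        case = m.values[m.group_columns("case")].to_numpy()
        ctrl = m.values[m.group_columns("control")].to_numpy()
        for i in range(100):
            t_ref = pooled_t(case[i], ctrl[i])
            assert out["t"].iloc[i] == pytest.approx(t_ref, abs=1e-10)
            p_ref = 2 * stats.t.sf(abs(t_ref), 12)
            assert out["p_value"].iloc[i] == pytest.approx(p_ref, abs=1e-10)

    def test_zero_variance_gene_reported_flat(self, caplog):
        from zmeta.synthetic import ExpressionMatrix

        values = pd.DataFrame(
            [[1.0, 1.0, 0.0, 0.0], [1.0, 2.0, 0.5, 0.3]],
            index=["FLAT", "OK"],
            columns=["C1", "C2", "K1", "K2"],
        )
        groups = pd.Series(["case", "case", "control", "control"], index=values.columns)
        with caplog.at_level("WARNING"):
            out = per_gene_ttest(ExpressionMatrix(values, groups))
        assert out.loc["FLAT", "p_value"] == 1.0
        assert out.loc["FLAT", "log_ratio"] == pytest.approx(1.0)
        assert "zero pooled variance" in caplog.text


class TestBonferroni:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.01] + [0.5] * 9, 0.1),
            ([0.5] + [0.2] * 9, 1.0),
            ([0.37], 0.37),
        ],
    )
    def test_adjustment(self, p, expected):
        assert bonferroni(p)[0] == pytest.approx(expected)

    def test_agrees_with_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=50)
        ours = bonferroni(p)
        theirs = multipletests(p, method="bonferroni")[1]
        assert np.allclose(ours, theirs, atol=1e-12)

    def test_rejects_invalid_p(self):
        with pytest.raises(ValueError):
            bonferroni([0.5, 1.5])
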