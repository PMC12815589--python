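import numpy as np
import pandas as pd
import pytest
from scipy.stats import multinomial

from odmc.model_fit import (
    CountTable,
    DataError,
    FitError,
    deviance_stat,
    fit_multinomial,
    fit_multinomial_glm,
    from_frame,
    pearson_stat,
    read_counts,
)


def _write_csv(tmp_path, rows, columns=("group", "cluster", "category", "count")):
    p = tmp_path / "counts.csv"
    pd.DataFrame(rows, columns=list(columns)).to_csv(p, index=False)
    return p


class TestReadCounts:
    def test_direct_parse(self, tmp_path):
        rows = [
            (g, b, c, 5)
            for g in ("g1", "g2")
            for b in ("b1", "b2")
            for c in ("c1", "c2")
        ]
        ct = read_counts(_write_csv(tmp_path, rows))
        assert ct.n_clusters == 4
        assert ct.n_categories == 2
        np.testing.assert_array_equal(ct.counts, 5)

    def test_zero_rows_densified(self, tmp_path):
        rows = [("g1", "b1", "c1", 3), ("g1", "b2", "c1", 1), ("g1", "b2", "c2", 4)]
        ct = read_counts(_write_csv(tmp_path, rows))
        np.testing.assert_array_equal(ct.counts, [[3, 0], [1, 4]])

    def test_negative_count_rejected(self, tmp_path):
        with pytest.raises(DataError):
            read_counts(_write_csv(tmp_path, [("g1", "b1", "c1", -1)]))

    def test_duplicate_cell_rejected(self, tmp_path):
        rows = [("g1", "b1", "c1", 1), ("g1", "b1", "c1", 2)]
        with pytest.raises(DataError):
            read_counts(_write_csv(tmp_path, rows))

    def test_covariate_column_kept(self, tmp_path):
        rows = [
            ("g1", "b1", "c1", 3, "d1"),
            ("g1", "b1", "c2", 2, "d1"),
            ("g1", "b2", "c1", 1, "d2"),
            ("g1", "b2", "c2", 4, "d2"),
        ]
        ct = read_counts(
            _write_csv(tmp_path, rows, columns=("group", "cluster", "category", "count", "donor"))
        )
        assert list(ct.covariates["donor"]) == ["d1", "d2"]


class TestFitMultinomial:
    def test_pooled_symmetric(self, two_cluster_table):
        fit = fit_multinomial(two_cluster_table)
        np.testing.assert_allclose(fit.pi_hat, [[0.5, 0.5]])
        assert (fit.N, fit.n, fit.P) == (4, 2, 1)

    def test_single_cluster_hand_value(self):
        ct = CountTable(
            counts=np.array([[1, 3]]),
            groups=np.array(["g1"]),
            clusters=np.array(["b1"]),
            categories=["c1", "c2"],
        )
        fit = fit_multinomial(ct)
        np.testing.assert_allclose(fit.pi_hat, [[0.25, 0.75]])
        assert fit.beta[0] == pytest.approx(np.log(3.0))

    def test_identical_groups_give_zero_between_beta(self, two_group_table):
        counts = np.array([[4, 6], [6, 4], [4, 6], [6, 4]])
        ct = two_group_table.with_counts(counts)
        fit = fit_multinomial(ct)
        # second block of beta holds the group-2 vs group-1 log odds ratios
        np.testing.assert_allclose(fit.beta[1:], 0, atol=1e-12)

    def test_cluster_split_invariance(self, two_cluster_table):
        merged = CountTable(
            counts=np.array([[10, 10]]),
            groups=np.array(["g1"]),
            clusters=np.array(["b1"]),
            categories=["c1", "c2"],
        )
        np.testing.assert_allclose(
            fit_multinomial(two_cluster_table).pi_hat, fit_multinomial(merged).pi_hat
        )

    def test_loglik_matches_direct_pmf(self, two_group_table):
        fit = fit_multinomial(two_group_table)
        direct = sum(
            multinomial.logpmf(
                two_group_table.counts[i],
                n=two_group_table.counts[i].sum(),
                p=fit.cluster_probs[i],
            )
            for i in range(two_group_table.n_clusters)
        )
        assert fit.loglik == pytest.approx(direct)

    def test_expected_counts_sum_to_cluster_totals(self, two_group_table):
        fit = fit_multinomial(two_group_table)
        np.testing.assert_allclose(
            fit.expected.sum(axis=1), two_group_table.cluster_totals
        )


class TestGlmFit:
    def test_group_only_matches_closed_form(self, two_group_table):
        pooled = fit_multinomial(two_group_table)
        glm = fit_multinomial_glm(two_group_table, ["group"])
        np.testing.assert_allclose(glm.pi_hat, pooled.pi_hat, atol=1e-8)
        np.testing.assert_allclose(glm.loglik, pooled.loglik, atol=1e-6)

    def test_identical_blocks_give_zero_block_coef(self):
        counts = np.array([[4, 6], [4, 6], [2, 8], [2, 8]])
        ct = CountTable(
            counts=counts,
            groups=np.array(["g1", "g1", "g2", "g2"]),
            clusters=np.array(["b1", "b2", "b3", "b4"]),
            categories=["c1", "c2"],
            covariates=pd.DataFrame({"block": ["d1", "d2", "d1", "d2"]}),
        )
        glm = fit_multinomial_glm(ct, ["group", "block"])
        # last coefficient row is the d2-vs-d1 block effect
        np.testing.assert_allclose(glm.coef[-1], 0, atol=1e-6)

    def test_binary_case_matches_logistic_regression_oracle(self):
        """C=2 reduces to binomial logistic regression on group."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(42)
        G, B, m = 3, 6, 40
        probs = [0.3, 0.45, 0.6]
        counts = np.array(
            [[m - k, k] for g in range(G) for k in rng.binomial(m, probs[g], size=B)]
        )
        groups = np.repeat([f"g{g+1}" for g in range(G)], B)
        ct = CountTable(
            counts=counts,
            groups=groups,
            clusters=np.array([f"b{i}" for i in range(G * B)]),
            categories=["c1", "c2"],
        )
        glm = fit_multinomial_glm(ct, ["group"])
        X = pd.get_dummies(pd.Series(groups), drop_first=True).astype(float)
        X.insert(0, "const", 1.0)
        oracle = sm.GLM(
            np.column_stack([counts[:, 1], counts[:, 0]]), X, family=sm.families.Binomial()
        ).fit()
        np.testing.assert_allclose(glm.coef[:, 0], oracle.params.to_numpy(), atol=1e-6)

    def test_zero_group_total_rejected(self):
        ct = CountTable(
            counts=np.array([[3, 2], [0, 0]]),
            groups=np.array(["g1", "g2"]),
            clusters=np.array(["b1", "b2"]),
            categories=["c1", "c2"],
        )
        with pytest.raises(FitError):
            fit_multinomial(ct)


class TestLackOfFit:
    def test_pearson_hand_value(self, two_cluster_table):
        fit = fit_multinomial(two_cluster_table)
        assert pearson_stat(fit, two_cluster_table) == pytest.approx(3.2)

    def test_deviance_hand_value(self, two_cluster_table):
        fit = fit_multinomial(two_cluster_table)
        expected = 2 * 2 * (3 * np.log(3 / 5) + 7 * np.log(7 / 5))
        assert deviance_stat(fit, two_cluster_table) == pytest.approx(expected)
        assert deviance_stat(fit, two_cluster_table) == pytest.approx(3.2913, abs=1e-4)

    def test_perfect_fit_is_zero(self):
        ct = CountTable(
            counts=np.array([[5, 5], [5, 5]]),
            groups=np.array(["g1", "g1"]),
            clusters=np.array(["b1", "b2"]),
            categories=["c1", "c2"],
        )
        fit = fit_multinomial(ct)
        assert pearson_stat(fit, ct) == pytest.approx(0)
        assert deviance_stat(fit, ct) == pytest.approx(0)

    def test_pearson_quadratic_in_deviation(self, two_cluster_table):
        fit = fit_multinomial(two_cluster_table)
        doubled = two_cluster_table.with_counts(np.array([[1, 9], [9, 1]]))
        assert pearson_stat(fit, doubled) == pytest.approx(
            4 * pearson_stat(fit, two_cluster_table)
        )

    def test_chi2_deviance_agree_at_large_m(self):
        """First-order agreement of chi^2 and D on well-fitting large counts."""
        rng = np.random.default_rng(3)
        m = 10_000
        counts = rng.multinomial(m, [0.3, 0.3, 0.4], size=8)
        ct = CountTable(
            counts=counts,
            groups=np.repeat(["g1"], 8),
            clusters=np.array([f"b{i}" for i in range(8)]),
            categories=["c1", "c2", "c3"],
        )
        fit = fit_multinomial(ct)
        chi2, D = pearson_stat(fit, ct), deviance_stat(fit, ct)
        assert abs(chi2 - D) / chi2 < 0.05
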