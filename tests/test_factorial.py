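"""Per-gene ANOVA, the interaction contrast, selection, collapsing, PCA."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, special, stats

from serrsig import factorial
from serrsig.factorial import (
    GroupDesign,
    SelectionThresholds,
    collapse_probesets,
    fit_oneway_anova,
    interaction_test,
    pairwise_group_test,
    principal_components,
    select_interaction_genes,
)
from serrsig.matrix import DesignError, ExpressionMatrix
from serrsig.simulate import SimFactorialConfig, simulate_factorial_expression


def _matrix(data, groups):
    values = pd.DataFrame(data)
    return ExpressionMatrix(values, pd.Series(groups))


class TestAnovaFit:
    def test_exact_means_zero_variance(self):
        X = _matrix(
            {"a1": [1.0], "a2": [1.0], "b1": [3.0], "b2": [3.0]},
            {"a1": "a", "a2": "a", "b1": "b", "b2": "b"},
        )
        fit = fit_oneway_anova(X, GroupDesign(groups=("a", "b"), quartet=None))
        assert fit.group_means.loc[0, "a"] == 1.0
        assert fit.group_means.loc[0, "b"] == 3.0
        assert fit.s2.iloc[0] == 0.0
        assert fit.df == 2

    def test_pooled_variance_matches_brute_force(self, two_group_matrix):
        design = GroupDesign(groups=("a", "b"), quartet=None)
        fit = fit_oneway_anova(two_group_matrix, design)
        # brute force: residual sum of squares around group means per gene
        vals = two_group_matrix.values
        for gene in vals.index:
            rss = 0.0
            for g in ("a", "b"):
                cols = two_group_matrix.samples_in_group(g)
                x = vals.loc[gene, cols]
                rss += ((x - x.mean()) ** 2).sum()
            assert fit.s2[gene] == pytest.approx(rss / fit.df)
        assert fit.df == 2
        assert fit.group_means.loc["g1", "a"] == pytest.approx(1.0)
        assert fit.group_means.loc["g1", "b"] == pytest.approx(2.0)

    def test_single_sample_groups_have_no_test(self):
        X = _matrix({"a1": [1.0], "b1": [2.0]}, {"a1": "a", "b1": "b"})
        with pytest.raises(DesignError, match="degrees of freedom"):
            fit_oneway_anova(X, GroupDesign(groups=("a", "b"), quartet=None))

    def test_missing_group_is_design_error(self, two_group_matrix):
        design = GroupDesign(groups=("a", "b", "c"), quartet=None)
        with pytest.raises(DesignError, match="'c'"):
            fit_oneway_anova(two_group_matrix, design)


class TestInteraction:
    def test_contrast_arithmetic_identity(self, quartet_matrix):
        """c = (m_double - m_braf) - (m_cdx2 - m_ctrl) and rho = 2**c."""
        fit = fit_oneway_anova(quartet_matrix)
        st = interaction_test(fit)
        m = fit.group_means
        c = (m["Cdx2KO_BrafVE"] - m["BrafVE"]) - (m["Cdx2KO"] - m["control"])
        assert np.allclose(st["contrast_log2"], c)
        assert np.allclose(st["ratio_of_ratios"], 2.0 ** c)

    def test_equal_means_give_null_statistic(self):
        rng = np.random.default_rng(0)
        data = {}
        labels = {}
        for g in factorial.DEFAULT_GROUPS:
            for i in (1, 2, 3):
                sid = f"{g}_{i}"
                data[sid] = [float(rng.normal(5, 1))]
                labels[sid] = g
        X = ExpressionMatrix(pd.DataFrame(data, index=["g"]), pd.Series(labels))
        fit = fit_oneway_anova(X)
        # overwrite means to be exactly equal, keep positive s2
        fit.group_means.loc["g"] = 3.0
        st = interaction_test(fit)
        assert st.loc["g", "contrast_log2"] == 0.0
        assert st.loc["g", "ratio_of_ratios"] == 1.0
        assert st.loc["g", "t"] == 0.0
        assert st.loc["g", "p"] == 1.0

    def test_p_matches_numeric_integration_of_t_density(self):
        """Two-sided p equals the numerically integrated t-tail at the same df."""
        cfg = SimFactorialConfig(n_genes=5, n_per_group=3, noise_sd=1.0, seed=11,
                                 frac_interaction=0.4, interaction_effect=2.0)
        X, _ = simulate_factorial_expression(cfg)
        fit = fit_oneway_anova(X)
        st = interaction_test(fit)
        df = fit.df

        def t_pdf(x):
            return (
                special.gamma((df + 1) / 2)
                / (np.sqrt(df * np.pi) * special.gamma(df / 2))
                * (1 + x**2 / df) ** (-(df + 1) / 2)
            )

        for gene in st.index:
            tval = abs(st.loc[gene, "t"])
            tail, _ = integrate.quad(t_pdf, tval, np.inf)
            assert st.loc[gene, "p"] == pytest.approx(2 * tail, rel=1e-6)

    def test_zero_variance_gene_flagged_degenerate(self):
        data = {}
        labels = {}
        for g in factorial.DEFAULT_GROUPS:
            for i in (1, 2):
                sid = f"{g}_{i}"
                data[sid] = [1.0]
                labels[sid] = g
        X = ExpressionMatrix(pd.DataFrame(data, index=["flat"]), pd.Series(labels))
        st = interaction_test(fit_oneway_anova(X))
        assert bool(st.loc["flat", "degenerate"])
        assert np.isnan(st.loc["flat", "p"])
        calls = select_interaction_genes(st, SelectionThresholds(0.5, 1.01))
        assert calls["flat"] == "neither"

    def test_location_invariance(self, quartet_matrix):
        """Adding a constant to one gene leaves c, t, p unchanged."""
        fit = fit_oneway_anova(quartet_matrix)
        st = interaction_test(fit)
        shifted = quartet_matrix.values.copy()
        shifted.loc["gA"] += 13.5
        X2 = ExpressionMatrix(shifted, quartet_matrix.sample_groups)
        st2 = interaction_test(fit_oneway_anova(X2))
        for col in ("contrast_log2", "t", "p"):
            assert st2.loc["gA", col] == pytest.approx(st.loc["gA", col])

    def test_rho_reciprocal_identity(self, quartet_matrix):
        st = interaction_test(fit_oneway_anova(quartet_matrix))
        rho_pos = 2.0 ** st["contrast_log2"]
        rho_neg = 2.0 ** (-st["contrast_log2"])
        assert np.allclose(rho_pos * rho_neg, 1.0)


class TestPairwise:
    def test_antisymmetry_and_closed_form(self, quartet_matrix):
        fit = fit_oneway_anova(quartet_matrix)
        ab = pairwise_group_test(fit, "Cdx2KO", "control")
        ba = pairwise_group_test(fit, "control", "Cdx2KO")
        assert np.allclose(ab["contrast_log2"], -ba["contrast_log2"])
        assert np.allclose(ab["p"], ba["p"])
        # closed form: diff / sqrt(s2 (1/n1 + 1/n2)) on the residual df
        n = fit.n_per_group
        se = np.sqrt(fit.s2 * (1 / n["Cdx2KO"] + 1 / n["control"]))
        t = (fit.group_means["Cdx2KO"] - fit.group_means["control"]) / se
        assert np.allclose(ab["t"], t)
        assert np.allclose(ab["p"], 2 * stats.t.sf(np.abs(t), fit.df))


class TestSelection:
    @pytest.mark.parametrize(
        "p,rho,expected",
        [
            (0.005, 12.0, "up"),
            (0.005, 1 / 12.0, "down"),
            (0.005, 10.0, "up"),        # rho cut inclusive
            (0.005, 0.1, "down"),       # 1/rho cut inclusive
            (0.01, 12.0, "neither"),    # p cut strict
            (0.005, 9.9, "neither"),
        ],
    )
    def test_threshold_rules(self, p, rho, expected):
        st = pd.DataFrame({"p": [p], "ratio_of_ratios": [rho]}, index=["g"])
        calls = select_interaction_genes(st, SelectionThresholds(0.01, 10.0))
        assert calls["g"] == expected

    def test_selection_monotone_in_thresholds(self):
        rng = np.random.default_rng(3)
        st = pd.DataFrame(
            {"p": rng.uniform(0, 0.05, 500), "ratio_of_ratios": 2.0 ** rng.normal(0, 2, 500)}
        )
        loose = select_interaction_genes(st, SelectionThresholds(0.02, 1.2))
        tight = select_interaction_genes(st, SelectionThresholds(0.01, 1.5))
        selected_tight = set(tight.index[tight != "neither"])
        selected_loose = set(loose.index[loose != "neither"])
        assert selected_tight <= selected_loose


class TestCollapse:
    def test_collapse_rules(self):
        calls = pd.Series(
            {"p1": "up", "p2": "neither", "p3": "up", "p4": "down", "p5": "down", "p6": "neither"}
        )
        mapping = pd.Series({"p1": "geneA", "p2": "geneA", "p3": "geneB", "p4": "geneB",
                             "p5": "geneC", "p6": "geneD"})
        out = collapse_probesets(calls, mapping)
        assert out["geneA"] == "up"           # up + neither -> up
        assert out["geneB"] == "neither"      # up + down conflict
        assert out["geneC"] == "down"
        assert out["geneD"] == "neither"

    def test_distinct_gene_count_and_unmapped_drop(self):
        rng = np.random.default_rng(8)
        probes = [f"p{i}" for i in range(200)]
        genes = [f"g{i}" for i in range(37)]
        mapping = pd.Series(rng.choice(genes, size=180), index=probes[:180])
        calls = pd.Series(rng.choice(["up", "down", "neither"], size=200), index=probes)
        out = collapse_probesets(calls, mapping)
        assert set(out.index) == set(mapping.unique())


class TestPCA:
    def test_scores_match_eigendecomposition(self):
        rng = np.random.default_rng(5)
        vals = pd.DataFrame(rng.normal(size=(10, 6)),
                            columns=[f"s{i}" for i in range(6)])
        X = ExpressionMatrix(vals, pd.Series("g", index=vals.columns))
        scores, ev = principal_components(X, n_components=5)
        A = vals.to_numpy() - vals.to_numpy().mean(axis=1, keepdims=True)
        C = A @ A.T / (6 - 1)
        eig = np.sort(np.linalg.eigvalsh(C))[::-1]
        assert np.allclose(np.sort(ev.to_numpy())[::-1], eig[:5], atol=1e-10)
        # scores reproduce the centered matrix geometry: pairwise distances preserved
        full_scores, _ = principal_components(X, n_components=6)
        d_scores = np.linalg.norm(
            full_scores.to_numpy()[:, None, :] - full_scores.to_numpy()[None, :, :], axis=2
        )
        d_data = np.linalg.norm(A.T[:, None, :] - A.T[None, :, :], axis=2)
        assert np.allclose(d_scores, d_data, atol=1e-8)

    def test_variance_conservation(self):
        rng = np.random.default_rng(6)
        vals = pd.DataFrame(rng.normal(size=(30, 5)), columns=[f"s{i}" for i in range(5)])
        X = ExpressionMatrix(vals, pd.Series("g", index=vals.columns))
        _, ev = principal_components(X, n_components=5)
        total = ((vals.to_numpy() - vals.to_numpy().mean(axis=1, keepdims=True)) ** 2).sum() / 4
        assert ev.sum() == pytest.approx(total)

    def test_identical_samples_have_zero_variance(self):
        vals = pd.DataFrame({"s1": [1.0, 2.0, 5.0], "s2": [1.0, 2.0, 5.0]})
        X = ExpressionMatrix(vals, pd.Series("g", index=vals.columns))
        _, ev = principal_components(X, n_components=2)
        assert np.allclose(ev, 0.0)

    def test_too_many_components_is_error(self):
        vals = pd.DataFrame({"s1": [1.0], "s2": [2.0]})
        X = ExpressionMatrix(vals, pd.Series("g", index=vals.columns))
        with pytest.raises(DesignError):
            principal_components(X, n_components=3)
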