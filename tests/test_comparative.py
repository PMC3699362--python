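"""Regressions, multivariate tests, contrasts and the simulation-null ANOVA."""

import numpy as np
import pandas as pd
import pytest

import wingshape as ws
from wingshape.exceptions import ValidationError

import oracles


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(2024)


class TestSpeciesMeans:
    def test_means_match_direct_summation_oracle(self, rng):
        taxa = [f"t{i:02d}" for i in range(37)]
        rows = []
        for t in taxa:
            for wing in ("fore", "hind"):
                for s in range(10):
                    rows.append(
                        {
                            "taxon": t,
                            "wing": wing,
                            "rsm": rng.uniform(0.4, 0.6),
                            "log_centroid_size": rng.normal(4.0, 0.3),
                        }
                    )
        df = pd.DataFrame(rows)
        means = ws.species_means(df)
        assert len(means) == 74
        for _, row in means.sample(5, random_state=1).iterrows():
            sub = df[(df.taxon == row.taxon) & (df.wing == row.wing)]
            assert row.rsm_mean == pytest.approx(sub.rsm.sum() / len(sub))
            assert row.n_specimens == len(sub)

    def test_constant_specimens_give_common_value(self):
        df = pd.DataFrame(
            {
                "taxon": ["a"] * 2,
                "wing": ["fore"] * 2,
                "rsm": [0.5, 0.7],
                "log_centroid_size": [1.0, 1.0],
            }
        )
        means = ws.species_means(df)
        assert means.rsm_mean.iloc[0] == pytest.approx(0.6)


class TestPolynomialRegression:
    def test_exact_quadratic_has_unit_r_squared(self, rng):
        x = rng.normal(size=20)
        y = 1.0 + 2.0 * x - 0.5 * x**2
        fit = ws.polynomial_regression(y, x, 2)
        assert fit.r_squared == pytest.approx(1.0)

    def test_df_for_37_species(self, rng):
        x = rng.normal(size=37)
        y = rng.normal(size=37)
        assert ws.polynomial_regression(y, x, 1).df == (1, 35)
        assert ws.polynomial_regression(y, x, 2).df == (2, 34)

    def test_coefficients_match_normal_equations(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        fit = ws.polynomial_regression(y, x, 2)
        X = np.column_stack([np.ones_like(x), x, x**2])
        np.testing.assert_allclose(
            fit.coefficients, oracles.normal_equation_coefficients(y, X), atol=1e-10
        )


class TestMancova:
    def test_univariate_case_reduces_to_ancova(self, rng):
        y = rng.normal(size=40)
        fac = np.repeat(["a", "b"], 20)
        cov = rng.normal(size=40)
        m = ws.mancova_wilks(y, fac, cov)
        a = ws.ancova(y, fac, cov).table
        assert m.table.loc["factor", "F"] == pytest.approx(
            a.loc["group", "F"], rel=1e-8
        )
        assert m.table.loc["covariate", "F"] == pytest.approx(
            a.loc["covariate", "F"], rel=1e-8
        )

    def test_wilks_matches_determinant_ratio_oracle(self, rng):
        n, p = 30, 4
        Y = rng.normal(size=(n, p))
        fac = np.repeat(["a", "b", "c"], 10)
        cov = rng.normal(size=n)
        m = ws.mancova_wilks(Y, fac, cov)
        dummies = pd.get_dummies(pd.Series(fac), drop_first=True).to_numpy(float)
        X = np.column_stack([np.ones(n), dummies, cov])
        lam_fac = oracles.wilks_det_ratio(Y, X, [1, 2])
        lam_cov = oracles.wilks_det_ratio(Y, X, [3])
        assert m.table.loc["factor", "wilks_lambda"] == pytest.approx(lam_fac, abs=1e-8)
        assert m.table.loc["covariate", "wilks_lambda"] == pytest.approx(
            lam_cov, abs=1e-8
        )

    def test_shape_variable_layout_gives_20_52_df(self, rng):
        # 74 species x wing means, 20 shape variables, wing factor + RSM covariate
        Y = rng.normal(size=(74, 20))
        fac = np.repeat(["fore", "hind"], 37)
        cov = rng.normal(size=74)
        m = ws.mancova_wilks(Y, fac, cov)
        assert m.table.loc["covariate", "df_num"] == 20
        assert m.table.loc["covariate", "df_den"] == 52

    def test_too_many_responses_rejected(self, rng):
        Y = rng.normal(size=(10, 9))
        with pytest.raises(np.linalg.LinAlgError):
            ws.mancova_wilks(Y, np.repeat(["a", "b"], 5), rng.normal(size=10))


class TestAncovaAndGlm:
    def test_odonata_layout_df(self, rng):
        # 27 + 54 + 27 taxa, group + body length covariate
        n = 108
        group = np.repeat(["calo", "dragon", "noncalo"], [27, 54, 27])
        y = rng.normal(size=n)
        cov = rng.normal(size=n)
        fit = ws.ancova(y, group, cov)
        assert fit.table.loc["group", "df"] == 2
        assert fit.table.loc["Residual", "df"] == 104

    def test_group_f_near_one_under_null(self, rng):
        fs = []
        for _ in range(300):
            y = rng.normal(size=30)
            fit = ws.ancova(y, np.repeat(["a", "b", "c"], 10), rng.normal(size=30))
            fs.append(fit.table.loc["group", "F"])
        assert np.mean(fs) == pytest.approx(1.0, abs=0.25)

    def test_glm_error_df_for_37_taxa_six_groups(self, rng):
        groups = np.repeat(np.arange(1, 7), [7, 6, 6, 6, 6, 6])
        y = rng.normal(size=37) * 0.01 + 0.55
        x = rng.normal(size=37)
        fit = ws.glm_coloration(y, groups, x)
        assert fit.table.loc["Error", "df"] == 29
        assert fit.table.loc["coloration_group", "df"] == 5

    def test_ss_decomposition_adds_up_in_balanced_orthogonal_design(self, rng):
        # balanced groups; x symmetric (+-v) and tiled, so 1, x, x^2 and the
        # group contrasts are mutually orthogonal and partial SS must add up
        groups = np.repeat([1, 2, 3], 12)
        v = rng.normal(size=6)
        x = np.tile(np.concatenate([v, -v]), 3)
        y = rng.normal(size=36)
        fit = ws.glm_coloration(y, groups, x)
        t = fit.table
        total = ((y - y.mean()) ** 2).sum()
        assert t.sum_sq.sum() == pytest.approx(total, rel=1e-8)


class TestNonAllometricResiduals:
    def test_exact_quadratic_gives_zero_residuals(self, rng):
        x = rng.normal(size=20)
        y = 0.5 - 0.02 * x + 0.003 * x**2
        r = ws.nonallometric_residuals(y, x)
        assert np.abs(r).max() < 1e-12

    def test_orthogonality_and_lstsq_oracle(self, rng):
        x = rng.normal(size=37)
        y = rng.normal(size=37)
        r = ws.nonallometric_residuals(y, x)
        assert abs(r.sum()) < 1e-10
        assert abs(r @ x) < 1e-9
        assert abs(r @ x**2) < 1e-9
        X = np.column_stack([np.ones_like(x), x, x**2])
        expected = y - X @ oracles.normal_equation_coefficients(y, X)
        np.testing.assert_allclose(r, expected, atol=1e-10)


class TestBranchTransforms:
    def test_none_is_identity(self, tree3):
        t = ws.transform_branch_lengths(tree3, "none")
        assert t.branch_lengths() == tree3.branch_lengths()

    def test_monotone_map_preserves_equality(self):
        t = ws.read_newick("((A:2,B:2):2,(C:2,D:2):2);")
        for method in ("log", "sqrt", "exp"):
            out = ws.transform_branch_lengths(t, method)
            assert len(set(np.round(out.branch_lengths(), 12))) == 1

    def test_log_rejects_zero_length_edge(self):
        t = ws.read_newick("((A:0.0,B:1):1,C:2);")
        with pytest.raises(ValidationError):
            ws.transform_branch_lengths(t, "log")

    def test_transform_reduces_standardization_violation(self):
        """Contrasts of a BM trait computed on squared branch lengths show
        |contrast| rising with sd; sqrt-transforming restores homoscedasticity."""
        rng = np.random.default_rng(5)
        depths = [0.05, 0.2, 0.8, 3.0, 8.0]
        newick = "(((((A:0.05,B:0.05):0.15,C:0.2):0.6,D:0.8):2.2,E:3):5,F:8);"
        true_tree = ws.read_newick(newick)
        wrong = true_tree.copy()
        for node in wrong.tree.preorder_node_iter():
            if node.parent_node is not None:
                node.edge.length = node.edge.length**2
        wrong = ws.Phylogeny(wrong.tree)
        diags_wrong, diags_fixed = [], []
        for _ in range(40):
            sim = ws.brownian_simulate(true_tree, 1.0, seed=rng, n_rep=1)[0]
            trait = dict(zip(true_tree.tip_labels, sim))
            diags_wrong.append(
                abs(ws.standardization_diagnostic(ws.independent_contrasts(wrong, trait)))
            )
            fixed = ws.transform_branch_lengths(wrong, "sqrt")
            diags_fixed.append(
                abs(ws.standardization_diagnostic(ws.independent_contrasts(fixed, trait)))
            )
        assert np.mean(diags_fixed) < np.mean(diags_wrong)


class TestIndependentContrasts:
    def test_two_tip_closed_form(self):
        t = ws.read_newick("(A:1,B:1);")
        ic = ws.independent_contrasts(t, {"A": 3.0, "B": 1.0})
        assert ic.contrasts[0] == pytest.approx(2 / np.sqrt(2))

    def test_three_tip_closed_form(self, tree3):
        ic = ws.independent_contrasts(tree3, {"A": 4.0, "B": 2.0, "C": 1.0})
        np.testing.assert_allclose(
            sorted(ic.contrasts), sorted([2 / np.sqrt(2), 2 / np.sqrt(3.5)]), atol=1e-10
        )

    def test_count_is_tips_minus_one(self):
        for seed in range(5):
            spec = ws.SimulationSpec(seed=seed, n_taxa=4 + 3 * seed)
            phy = ws.simulate_tree(spec)
            trait = dict(zip(phy.tip_labels, np.arange(phy.n_tips, dtype=float)))
            assert len(ws.independent_contrasts(phy, trait).contrasts) == phy.n_tips - 1

    def test_polytomy_rejected(self):
        t = ws.read_newick("(A:1,B:1,C:1);")
        with pytest.raises(ValidationError, match="bifurcating"):
            ws.independent_contrasts(t, {"A": 1.0, "B": 2.0, "C": 3.0})

    def test_missing_tip_value_rejected(self, tree3):
        with pytest.raises(ValidationError):
            ws.independent_contrasts(tree3, {"A": 1.0, "B": 2.0})

    def test_slope_equals_gls_oracle(self, rng):
        for seed in range(8):
            spec = ws.SimulationSpec(seed=100 + seed, n_taxa=int(rng.integers(5, 16)))
            phy = ws.simulate_tree(spec)
            x = dict(zip(phy.tip_labels, rng.normal(size=phy.n_tips)))
            y = dict(zip(phy.tip_labels, rng.normal(size=phy.n_tips)))
            fit = ws.contrast_regression(ws.contrast_set(phy, x, y))
            assert fit.coefficients[0] == pytest.approx(
                oracles.gls_slope(phy, x, y), abs=1e-8
            )


class TestContrastRegression:
    def test_exact_proportionality(self):
        cs = ws.ContrastSet(
            contrasts_x=np.array([1.0, 2.0, 3.0]),
            contrasts_y=np.array([2.0, 4.0, 6.0]),
            contrast_sd=np.ones(3),
            positivized=np.zeros(3, dtype=bool),
        )
        fit = ws.contrast_regression(cs)
        assert fit.coefficients[0] == pytest.approx(2.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_df_anchor_for_37_tips(self):
        phy = ws.simulate_tree(ws.SimulationSpec(seed=0, n_taxa=37))
        rng = np.random.default_rng(0)
        x = dict(zip(phy.tip_labels, rng.normal(size=37)))
        y = dict(zip(phy.tip_labels, rng.normal(size=37)))
        fit = ws.contrast_regression(ws.contrast_set(phy, x, y))
        assert fit.df == (1, 35)

    def test_positivization_invariance(self, rng):
        x = rng.normal(size=20)
        y = 0.5 * x + rng.normal(scale=0.1, size=20)
        flip = rng.random(20) < 0.5
        sgn = np.where(flip, -1.0, 1.0)
        a = ws.contrast_regression(
            ws.ContrastSet(x, y, np.ones(20), np.zeros(20, bool))
        )
        b = ws.contrast_regression(
            ws.ContrastSet(x * sgn, y * sgn, np.ones(20), flip)
        )
        assert a.coefficients[0] == pytest.approx(b.coefficients[0])
        assert a.r_squared == pytest.approx(b.r_squared)


class TestBrownianSimulate:
    def test_two_tip_variance(self):
        t = ws.read_newick("(A:1,B:1);")
        sims = ws.brownian_simulate(t, 1.0, seed=0, n_rep=100_000)
        assert np.var(sims[:, 0] - sims[:, 1]) == pytest.approx(2.0, rel=0.02)

    def test_zero_rate_keeps_root_value(self, tree3):
        sims = ws.brownian_simulate(tree3, 0.0, seed=1, n_rep=5, root_value=7.0)
        assert np.all(sims == 7.0)

    def test_same_seed_same_matrix(self, tree3):
        a = ws.brownian_simulate(tree3, 1.0, seed=42, n_rep=10)
        b = ws.brownian_simulate(tree3, 1.0, seed=42, n_rep=10)
        np.testing.assert_array_equal(a, b)

    def test_contrast_variance_matches_rate(self):
        phy = ws.simulate_tree(ws.SimulationSpec(seed=3, n_taxa=12))
        sims = ws.brownian_simulate(phy, 2.5, seed=5, n_rep=400)
        s2 = [
            ws.independent_contrasts(
                phy, dict(zip(phy.tip_labels, row))
            ).sigma2_reml
            for row in sims
        ]
        assert np.mean(s2) == pytest.approx(2.5, rel=0.1)


class TestPhylogeneticAnova:
    def test_boundary_p_when_f_exceeds_all_sims(self):
        phy = ws.simulate_tree(ws.SimulationSpec(seed=9, n_taxa=10))
        tips = phy.tip_labels
        trait = {t: (0.0 if i < 5 else 100.0) for i, t in enumerate(tips)}
        groups = {t: ("a" if i < 5 else "b") for i, t in enumerate(tips)}
        res = ws.phylogenetic_anova(phy, trait, groups, n_sim=1000, seed=1)
        assert res.p_phylogenetic == pytest.approx(1 / 1001)

    def test_phylogenetic_p_exceeds_parametric_p_for_clade_groups(self):
        """Groups that coincide with a deep split inherit Brownian divergence;
        the simulation null absorbs it while the parametric F does not."""
        phy = ws.simulate_tree(ws.SimulationSpec(seed=21, n_taxa=16, max_basal_fraction=0.5))
        clade = ws.basal_clade(phy)
        groups = {t: ("basal" if t in clade else "rest") for t in phy.tip_labels}
        sims = ws.brownian_simulate(phy, 1.0, seed=2, n_rep=50)
        worse = 0
        for row in sims:
            trait = dict(zip(phy.tip_labels, row))
            res = ws.phylogenetic_anova(phy, trait, groups, n_sim=300, seed=3)
            worse += res.p_phylogenetic > res.p_parametric
        assert worse > 35  # overwhelmingly less significant under the BM null

    def test_single_tip_group_allowed_empty_rejected(self, tree3):
        trait = {"A": 1.0, "B": 2.0, "C": 3.0}
        with pytest.raises(ValidationError):
            ws.phylogenetic_anova(tree3, trait, {"A": "x", "B": "x", "C": "x"}, n_sim=100)
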