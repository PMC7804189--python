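import numpy as np
import pandas as pd
import pytest

from grexdissect.association import (
    CovariatePolicy,
    bh_fdr,
    expression_pcs,
    lrt_statistic,
    perm_p_from_counts,
    permutation_p,
    run_association,
    _design,
    _freedman_lane_parts,
)
from grexdissect.datatypes import CovariateTable, ExpressionBundle, Phenotype


def _status_and_gene_2x2():
    # 2x2 table [[10, 5], [5, 10]]: rows status 0/1, cols gene 0/1
    y = np.array([0] * 15 + [1] * 15, dtype=float)
    g = np.array([0] * 10 + [1] * 5 + [0] * 5 + [1] * 10, dtype=float)
    return y, g


class TestLrtStatistic:
    def test_constant_gene_gives_zero(self, rng):
        y = np.array([0, 1] * 20, dtype=float)
        stat, flagged = lrt_statistic(y, np.full(40, 3.0), rng.normal(size=(40, 2)))
        assert stat == pytest.approx(0.0, abs=1e-8)

    def test_g_test_closed_form(self):
        y, g = _status_and_gene_2x2()
        obs = np.array([[10, 5], [5, 10.0]])
        expected = obs.sum(1)[:, None] * obs.sum(0)[None, :] / obs.sum()
        g_stat = 2 * np.sum(obs * np.log(obs / expected))
        stat, _ = lrt_statistic(y, g)
        assert stat == pytest.approx(g_stat, abs=1e-6)
        assert stat == pytest.approx(3.398, abs=2e-3)

    def test_gene_equal_to_covariate_adds_nothing(self, rng):
        y = (rng.random(60) < 0.5).astype(float)
        y[0], y[1] = 0, 1
        cov = rng.normal(size=(60, 2))
        stat, _ = lrt_statistic(y, cov[:, 0], cov)
        assert stat == pytest.approx(0.0, abs=1e-8)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        y = (rng.random(150) < 0.4).astype(float)
        g = rng.normal(size=150) + 0.5 * y
        cov = rng.normal(size=(150, 3))
        X0 = sm.add_constant(cov)
        ll0 = sm.Logit(y, X0).fit(disp=0).llf
        ll1 = sm.Logit(y, np.column_stack([X0, g])).fit(disp=0).llf
        stat, _ = lrt_statistic(y, g, cov)
        assert stat == pytest.approx(2 * (ll1 - ll0), abs=1e-6)

    def test_affine_invariance(self, rng):
        y = (rng.random(100) < 0.5).astype(float)
        y[:2] = [0, 1]
        g = rng.normal(size=100)
        cov = rng.normal(size=(100, 2))
        s1, _ = lrt_statistic(y, g, cov)
        s2, _ = lrt_statistic(y, 3.0 * g + 7.0, cov)
        assert s1 == pytest.approx(s2, rel=1e-8)


class TestPermPFromCounts:
    def test_published_formula(self):
        assert perm_p_from_counts(1, 8000) == pytest.approx(1.25e-4)
        assert perm_p_from_counts(2, 8000) == pytest.approx(2.50e-4)

    def test_zero_exceedance_upper_bound(self):
        assert perm_p_from_counts(0, 1_000_000) == 1e-6

    def test_invalid(self):
        with pytest.raises(ValueError):
            perm_p_from_counts(-1, 100)
        with pytest.raises(ValueError):
            perm_p_from_counts(5, 4)


class TestFreedmanLane:
    def test_no_covariates_reduces_to_label_permutation(self, rng):
        """With an intercept-only design, fitted + permuted residuals is an
        exact permutation of the original gene variable."""
        g = rng.normal(size=7)
        C = _design(None, 7)
        fitted, resid = _freedman_lane_parts(g, C)
        np.testing.assert_allclose(fitted, g.mean(), atol=1e-12)
        perm = rng.permutation(7)
        reconstructed = fitted + resid[perm]
        np.testing.assert_allclose(np.sort(reconstructed), np.sort(g), atol=1e-10)

    def test_perm_p_affine_invariance(self, rng):
        y = (rng.random(80) < 0.5).astype(float)
        y[:2] = [0, 1]
        g = rng.normal(size=80)
        cov = rng.normal(size=(80, 2))
        r1 = permutation_p(y, g, cov, B_initial=300, B_max=300, seed=5, gene_id="a")
        r2 = permutation_p(y, 2.5 * g - 1.0, cov, B_initial=300, B_max=300, seed=5, gene_id="a")
        assert r1.perm_p == r2.perm_p
        assert r1.b_exceed == r2.b_exceed

    def test_determinism(self, rng):
        y = (rng.random(60) < 0.5).astype(float)
        y[:2] = [0, 1]
        g = rng.normal(size=60)
        r1 = permutation_p(y, g, None, B_initial=200, B_max=200, seed=9, gene_id="g")
        r2 = permutation_p(y, g, None, B_initial=200, B_max=200, seed=9, gene_id="g")
        assert r1.perm_p == r2.perm_p and r1.lrt_stat == r2.lrt_stat

    def test_escalation_on_strong_signal(self, rng):
        # a strong association exhausts the initial permutations without
        # exceedances and escalates to B_max
        y = np.array([0.0] * 50 + [1.0] * 50)
        g = y * 2 + rng.normal(0, 0.3, 100)
        res = permutation_p(y, g, None, B_initial=50, B_max=500, seed=3, gene_id="s")
        assert res.escalated
        assert res.B == 500
        if res.b_exceed == 0:
            assert res.p_is_upper_bound and res.perm_p == 1 / 500

    def test_analytic_close_to_perm_under_null(self, rng):
        y = (rng.random(300) < 0.5).astype(float)
        y[:2] = [0, 1]
        g = rng.normal(size=300)
        res = permutation_p(y, g, None, B_initial=2000, B_max=2000, seed=11, gene_id="n")
        assert res.analytic_p == pytest.approx(res.perm_p, abs=0.05)


class TestBhFdr:
    def test_step_up_by_hand(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_fdr([1.5])


class TestCovariatePolicy:
    def test_default_valid(self):
        p = CovariatePolicy()
        assert "expression_pc" not in p.tags("grex")
        assert "expression_pc" in p.tags("erex")

    def test_grex_with_expression_pcs_rejected(self):
        with pytest.raises(ValueError):
            CovariatePolicy({
                "observed": ("clinical", "expression_pc", "genotype_pc"),
                "grex": ("clinical", "expression_pc", "genotype_pc"),
                "erex": ("clinical", "expression_pc", "genotype_pc"),
            })

    def test_missing_genotype_pc_rejected(self):
        with pytest.raises(ValueError):
            CovariatePolicy({
                "observed": ("clinical", "expression_pc", "genotype_pc"),
                "grex": ("clinical",),
                "erex": ("clinical", "expression_pc", "genotype_pc"),
            })


def _mini_bundle(rng, n=80, G=4):
    samples = [f"s{i}" for i in range(n)]
    genes = [f"g{j}" for j in range(G)]
    observed = rng.normal(size=(n, G))
    grex = np.zeros((n, G))
    erex = observed.copy()
    bundle = ExpressionBundle(samples, genes, observed, grex, erex)
    status = np.zeros(n, dtype=int)
    status[rng.choice(n, n // 2, replace=False)] = 1
    pheno = Phenotype(samples, status)
    cov = CovariateTable(
        samples,
        pd.DataFrame({"age": rng.normal(size=n), "geno_pc1": rng.normal(size=n)},
                     index=samples),
        {"age": "clinical", "geno_pc1": "genotype_pc"},
    )
    return bundle, pheno, cov


class TestRunAssociation:
    def test_zero_grex_component(self, rng):
        bundle, pheno, cov = _mini_bundle(rng)
        table = run_association(bundle, pheno, cov, B_initial=100, B_max=100,
                                seed=1, components=("grex",), n_expression_pcs=2)
        assert np.allclose(table["lrt_stat"], 0.0)
        assert np.allclose(table["perm_p"], 1.0)

    def test_same_seed_identical(self, rng):
        bundle, pheno, cov = _mini_bundle(rng)
        t1 = run_association(bundle, pheno, cov, B_initial=100, B_max=100,
                             seed=4, components=("observed",), n_expression_pcs=2)
        t2 = run_association(bundle, pheno, cov, B_initial=100, B_max=100,
                             seed=4, components=("observed",), n_expression_pcs=2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_qvalues_are_bh_of_perm_p(self, rng):
        bundle, pheno, cov = _mini_bundle(rng, G=6)
        t = run_association(bundle, pheno, cov, B_initial=100, B_max=100,
                            seed=2, components=("observed",), n_expression_pcs=2)
        np.testing.assert_allclose(t["q_value"], bh_fdr(t["perm_p"]))


class TestExpressionPcs:
    def test_shapes_and_capture(self, rng):
        X = rng.normal(size=(50, 20))
        pcs = expression_pcs(X, 10)
        assert pcs.shape == (50, 10)
        # first PC captures the dominant direction of a rank-1 + noise matrix
        u = rng.normal(size=50)
        X1 = np.outer(u, np.ones(20)) * 3 + rng.normal(size=(50, 20))
        pc1 = expression_pcs(X1, 1)[:, 0]
        assert abs(np.corrcoef(pc1, u)[0, 1]) > 0.9
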