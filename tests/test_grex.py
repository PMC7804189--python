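import math

import numpy as np
import pandas as pd
import pytest

from grexdissect.datatypes import GenotypeMatrix, WeightMatrix
from grexdissect.grex import (
    estimate_h2,
    hwe_exact_p,
    maf,
    predict_grex,
    qc_filter,
    r2_h2_correlation,
    train_weights,
    PredictionPerformance,
    HeritabilityEstimate,
    _reml_neg_loglik,
)
from grexdissect.simulate import simulate_genotypes


def _geno(dosages, ref="A", alt="G", sample_prefix="s"):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    vids = [f"v{j + 1}" for j in range(m)]
    meta = pd.DataFrame(
        {"chrom": "1", "pos": np.arange(1, m + 1), "ref": ref, "alt": alt}, index=vids
    )
    return GenotypeMatrix([f"{sample_prefix}{i}" for i in range(n)], vids, dosages, meta)


class TestMaf:
    def test_allele_counting(self):
        assert maf(np.array([0, 1, 2, 2.0])) == pytest.approx(0.375)

    def test_monomorphic(self):
        assert maf(np.zeros(3)) == 0.0

    def test_maximal(self):
        assert maf(np.ones(4)) == 0.5

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            maf(np.array([]))


def _hwe_oracle(n_homref, n_het, n_homalt):
    """Exact-integer enumeration of the conditional heterozygote distribution."""
    n = n_homref + n_het + n_homalt
    rare = min(2 * n_homref + n_het, 2 * n_homalt + n_het)
    if rare == 0:
        return 1.0
    weights = {}
    for x in range(rare % 2, rare + 1, 2):
        a = (rare - x) // 2
        b = n - x - a
        if b < 0:
            continue
        weights[x] = (math.factorial(n) // (math.factorial(a) * math.factorial(x) * math.factorial(b))) * 2 ** x
    total = sum(weights.values())
    w_obs = weights[n_het]
    return sum(w for w in weights.values() if w <= w_obs) / total


class TestHweExact:
    def test_hand_enumeration(self):
        # configurations het in {0,2,4} carry integer weights 6:48:16
        assert hwe_exact_p(1, 2, 1) == pytest.approx(1.0)

    def test_monomorphic(self):
        assert hwe_exact_p(10, 0, 0) == 1.0

    def test_extreme_het_excess(self):
        assert hwe_exact_p(0, 100, 0) < 1e-6

    def test_matches_integer_oracle_exhaustively(self):
        """Agreement with exact-integer enumeration for every config with n <= 25."""
        for n in range(1, 26):
            for n_homref in range(n + 1):
                for n_het in range(n - n_homref + 1):
                    n_homalt = n - n_homref - n_het
                    got = hwe_exact_p(n_homref, n_het, n_homalt)
                    want = _hwe_oracle(n_homref, n_het, n_homalt)
                    assert got == pytest.approx(want, rel=1e-9), (n_homref, n_het, n_homalt)

    def test_matches_integer_oracle_at_n50(self, rng):
        for _ in range(200):
            parts = rng.multinomial(50, [0.5, 0.3, 0.2])
            got = hwe_exact_p(*parts)
            assert got == pytest.approx(_hwe_oracle(*parts), rel=1e-9)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            hwe_exact_p(0, 0, 0)
        with pytest.raises(ValueError):
            hwe_exact_p(-1, 2, 1)


class TestQcFilter:
    def test_strict_maf_threshold(self):
        # one ALT allele in 10 samples: MAF exactly 0.05 fails the strict rule
        d = np.zeros((10, 1))
        d[0, 0] = 1
        kept, qc = qc_filter(_geno(d))
        assert qc["maf"].iloc[0] == pytest.approx(0.05)
        assert not qc["pass"].iloc[0]
        assert kept.n_variants == 0

    def test_threshold_counting(self):
        # HWE-consistent variants with MAFs 0.02, 0.05, 0.06, 0.40 -> 2 retained
        n = 50
        cols = []
        for n_het, n_homalt in [(2, 0), (5, 0), (6, 0), (24, 8)]:
            col = np.array([2] * n_homalt + [1] * n_het + [0] * (n - n_het - n_homalt))
            cols.append(col)
        gm = _geno(np.column_stack(cols))
        kept, qc = qc_filter(gm)
        np.testing.assert_allclose(qc["maf"], [0.02, 0.05, 0.06, 0.40])
        assert (qc["hwe_p"] > 0.05).all()
        assert kept.variant_ids == ["v3", "v4"]

    def test_zero_thresholds_keep_polymorphic(self):
        d = np.array([[0, 0.0], [1, 0], [2, 0]])
        kept, qc = qc_filter(_geno(d), maf_threshold=0.0, hwe_threshold=0.0)
        assert kept.variant_ids == ["v1"]  # v2 is monomorphic (MAF 0)


class TestPredictGrex:
    def _weights(self, effect_allele="G"):
        table = pd.DataFrame(
            {"gene": ["g1", "g1"], "variant": ["v1", "v2"],
             "weight": [0.5, -1.0], "effect_allele": effect_allele}
        )
        return WeightMatrix("blood", table)

    def test_hand_dot_product(self):
        gm = _geno(np.array([[2.0, 0.0], [0.0, 1.0]]))
        grex, genes, report = predict_grex(gm, self._weights())
        assert genes == ["g1"]
        np.testing.assert_allclose(grex[:, 0], [1.0, -1.0])

    def test_ref_effect_allele_flips(self):
        gm = _geno(np.array([[2.0, 0.0], [0.0, 1.0]]))
        grex, _, _ = predict_grex(gm, self._weights(effect_allele="A"))
        # dosages flip to 2 - d: (0,2) -> -2.0 ; (2,1) -> 0.0
        np.testing.assert_allclose(grex[:, 0], [-2.0, 0.0])

    def test_zero_weights(self):
        gm = _geno(np.array([[1.0, 1.0], [2.0, 0.0]]))
        table = pd.DataFrame({"gene": ["g1"], "variant": ["v1"],
                              "weight": [0.0], "effect_allele": ["G"]})
        grex, genes, _ = predict_grex(gm, WeightMatrix("t", table))
        np.testing.assert_array_equal(grex[:, 0], [0.0, 0.0])

    def test_uncovered_gene_reported_not_errored(self):
        gm = _geno(np.array([[1.0], [2.0]]))
        table = pd.DataFrame({"gene": ["g9"], "variant": ["vX"],
                              "weight": [1.0], "effect_allele": ["G"]})
        grex, genes, report = predict_grex(gm, WeightMatrix("t", table))
        assert genes == []
        assert grex.shape == (2, 0)
        row = report[report["gene"] == "g9"].iloc[0]
        assert not row["kept"] and row["n_used_variants"] == 0

    def test_linearity(self, rng):
        d1 = rng.uniform(0, 1, size=(6, 3))
        d2 = rng.uniform(0, 1, size=(6, 3))
        table = pd.DataFrame({"gene": "g1", "variant": [f"v{j+1}" for j in range(3)],
                              "weight": rng.normal(size=3), "effect_allele": "G"})
        wm = WeightMatrix("t", table)
        g1, _, _ = predict_grex(_geno(d1), wm)
        g2, _, _ = predict_grex(_geno(d2), wm)
        gsum, _, _ = predict_grex(_geno(d1 + d2), wm)
        np.testing.assert_allclose(gsum, g1 + g2, atol=1e-10)


class TestTrainWeights:
    def test_noiseless_recovery(self):
        gm = simulate_genotypes(200, 5, (0.2, 0.4), seed=4)
        y = 0.7 * gm.dosages[:, 2]
        wm, perfs = train_weights(
            gm, y[:, None], ["g1"], {"g1": gm.variant_ids}, seed=0
        )
        entries = wm.entries_for_gene("g1")
        w3 = entries.set_index("variant")["weight"].get("v000003", 0.0)
        assert w3 == pytest.approx(0.7, abs=0.05)
        assert perfs[0].cv_r2 > 0.99

    def test_null_cv_r2_near_zero(self):
        gm = simulate_genotypes(500, 10, (0.2, 0.4), seed=5)
        rng = np.random.default_rng(6)
        y = rng.normal(size=500)
        _, perfs = train_weights(gm, y[:, None], ["g1"], {"g1": gm.variant_ids}, seed=1)
        assert perfs[0].cv_r2 < 0.05

    def test_determinism(self):
        gm = simulate_genotypes(100, 6, (0.2, 0.4), seed=7)
        rng = np.random.default_rng(8)
        y = (gm.dosages[:, 0] + rng.normal(0, 1, 100))[:, None]
        w1, p1 = train_weights(gm, y, ["g1"], {"g1": gm.variant_ids}, seed=42)
        w2, p2 = train_weights(gm, y, ["g1"], {"g1": gm.variant_ids}, seed=42)
        assert w1.table.equals(w2.table)
        assert p1[0].cv_r2 == p2[0].cv_r2

    def test_constant_expression_skipped(self):
        gm = simulate_genotypes(50, 4, (0.2, 0.4), seed=9)
        wm, perfs = train_weights(gm, np.ones((50, 1)), ["g1"], {"g1": gm.variant_ids})
        assert perfs == [] and wm.genes == []


def _genetic_phenotype(gm, h2, seed):
    rng = np.random.default_rng(seed)
    Z = (gm.dosages - gm.dosages.mean(0)) / gm.dosages.std(0)
    u = rng.normal(0, 1, gm.n_variants)
    g = Z @ u
    g = g / g.std() * np.sqrt(h2)
    return g + rng.normal(0, np.sqrt(1 - h2), gm.n_samples)


class TestEstimateH2:
    def test_grid_oracle(self):
        """REML optimum beats a 101-point grid on the profiled restricted likelihood."""
        for seed in range(4):
            gm = simulate_genotypes(150, 20, (0.1, 0.4), seed=seed)
            y = _genetic_phenotype(gm, 0.4, seed + 100)
            est = estimate_h2(gm, y)
            Z = (gm.dosages - gm.dosages.mean(0)) / gm.dosages.std(0)
            grm = Z @ Z.T / gm.n_variants
            lam, U = np.linalg.eigh(grm)
            yr, xr = U.T @ y, U.T @ np.ones(len(y))
            grid = np.linspace(0, 1 - 1e-9, 101)
            grid_nll = min(_reml_neg_loglik(h, lam, yr, xr) for h in grid)
            assert -est.loglik <= grid_nll + 1e-6

    def test_recovery(self):
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            gm = simulate_genotypes(400, 50, (0.1, 0.4), seed=1000 + rep)
            y = _genetic_phenotype(gm, 0.5, 2000 + rep)
            est = estimate_h2(gm, y)
            hits += 0.4 <= est.h2 <= 0.6
        assert hits >= 0.9 * n_rep

    def test_null_near_zero(self):
        vals = []
        for rep in range(10):
            gm = simulate_genotypes(300, 30, (0.1, 0.4), seed=rep)
            y = np.random.default_rng(50 + rep).normal(size=300)
            vals.append(estimate_h2(gm, y).h2)
        assert np.median(vals) < 0.05

    def test_noiseless_boundary(self):
        gm = simulate_genotypes(200, 20, (0.1, 0.4), seed=3)
        rng = np.random.default_rng(4)
        Z = (gm.dosages - gm.dosages.mean(0)) / gm.dosages.std(0)
        y = Z @ rng.normal(size=20)
        assert estimate_h2(gm, y).h2 >= 0.99

    def test_too_few_variants_raises(self):
        gm = simulate_genotypes(100, 1, (0.1, 0.4), seed=5)
        with pytest.raises(ValueError):
            estimate_h2(gm, np.zeros(100))


class TestR2H2Correlation:
    def _pairs(self, r2s, h2s):
        perfs = [PredictionPerformance(f"g{i}", v, 10) for i, v in enumerate(r2s)]
        hers = [HeritabilityEstimate(f"g{i}", v, 0.0, 5) for i, v in enumerate(h2s)]
        return perfs, hers

    def test_identity(self):
        p, h = self._pairs([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert r2_h2_correlation(p, h) == pytest.approx(1.0)

    def test_anticorrelated(self):
        p, h = self._pairs([1, 2, 3], [3, 2, 1])
        assert r2_h2_correlation(p, h) == pytest.approx(-1.0)

    def test_zero_variance_raises(self):
        p, h = self._pairs([0.2, 0.2, 0.2], [0.1, 0.2, 0.3])
        with pytest.raises(ValueError):
            r2_h2_correlation(p, h)
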