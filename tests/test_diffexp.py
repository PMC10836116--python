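import numpy as np
import pandas as pd
import pytest

from apa_rhythm.diffexp import (
    Contrast,
    estimate_dispersion,
    local_fdr,
    nb_wald,
    nb_wald_matrix,
    remove_pc1,
    remove_pc1_protected,
    run_contrasts,
    shrink_lfc,
    size_factors,
)

GROUPS10 = np.array([0] * 5 + [1] * 5)


class TestRemovePc1:
    def test_rank1_reduced_to_zero(self):
        rng = np.random.default_rng(0)
        X = np.outer(rng.normal(size=50), rng.normal(size=8))
        corrected = remove_pc1(X) - X.mean(axis=1, keepdims=True)
        assert np.linalg.norm(corrected) <= 1e-8 * np.linalg.norm(X)

    def test_idempotent_on_rank1(self):
        # once a rank-1 matrix is reduced to its row means, reapplying
        # changes nothing; generic matrices always have a next component
        rng = np.random.default_rng(1)
        X = np.outer(rng.normal(size=40), rng.normal(size=10)) + 5.0
        once = remove_pc1(X)
        assert np.allclose(remove_pc1(once), once, atol=1e-10)

    def test_means_preserved(self):
        rng = np.random.default_rng(2)
        X = rng.normal(5, 1, size=(30, 10))
        assert np.allclose(remove_pc1(X).mean(axis=1), X.mean(axis=1), atol=1e-8)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            remove_pc1(np.ones((5, 2)))

    def test_back_transform_floor(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 2, size=(20, 6))
        out = remove_pc1(X, back_transform=True)
        assert (out >= 0).all()

    def test_protected_preserves_group_means(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(100, 10))
        X[:10, 5:] += 2.0  # strong treatment effect would dominate PC1
        corr = remove_pc1_protected(X, GROUPS10)
        for g in (0, 1):
            assert np.allclose(
                corr[:, GROUPS10 == g].mean(axis=1),
                X[:, GROUPS10 == g].mean(axis=1),
                atol=1e-8,
            )


class TestDispersion:
    def test_constant_counts_floored(self):
        Y = np.full((5, 10), 20.0)
        alpha = estimate_dispersion(Y, GROUPS10)
        assert (alpha <= 1e-3).all()

    def test_poisson_limit(self):
        rng = np.random.default_rng(5)
        Y = rng.poisson(100.0, size=(200, 100)).astype(float)
        g = np.array([0] * 50 + [1] * 50)
        alpha = estimate_dispersion(Y, g)
        assert (alpha < 0.01).mean() >= 0.95

    def test_nb_recovery(self):
        rng = np.random.default_rng(6)
        npar = 1 / 0.2
        Y = rng.negative_binomial(npar, npar / (npar + 100), size=(200, 100)).astype(float)
        g = np.array([0] * 50 + [1] * 50)
        alpha = estimate_dispersion(Y, g)
        assert ((alpha >= 0.1) & (alpha <= 0.3)).mean() >= 0.9

    def test_zero_mean_nan(self):
        Y = np.zeros((3, 10))
        assert np.isnan(estimate_dispersion(Y, GROUPS10)).all()


class TestNbWald:
    def test_identical_groups_null(self):
        y = np.array([10.0, 12, 9, 11, 10] * 2)
        r = nb_wald(y, GROUPS10, np.ones(10), 0.05)
        assert r["log2fc_mle"] == pytest.approx(0.0, abs=1e-8)
        assert r["p"] == pytest.approx(1.0, abs=1e-6)

    def test_poisson_oracle_agreement(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        Y = rng.poisson(200.0, size=(10, 10)).astype(float)
        r = nb_wald_matrix(Y, GROUPS10, np.ones(10), np.full(10, 1e-12))
        X = sm.add_constant(GROUPS10.astype(float))
        for k in range(10):
            fit = sm.GLM(Y[k], X, family=sm.families.Poisson()).fit()
            assert r["log2fc_mle"][k] * np.log(2) == pytest.approx(
                fit.params[1], abs=1e-4
            )
            assert r["se"][k] * np.log(2) == pytest.approx(fit.bse[1], abs=1e-4)

    def test_planted_fold_change(self):
        rng = np.random.default_rng(8)
        npar = 1 / 0.01
        mu = np.where(GROUPS10 == 1, 800.0, 200.0)
        lfcs = []
        for _ in range(50):
            y = rng.negative_binomial(npar, npar / (npar + mu)).astype(float)
            lfcs.append(nb_wald(y, GROUPS10, np.ones(10), 0.01)["log2fc_mle"])
        assert np.mean(lfcs) == pytest.approx(2.0, abs=0.5)

    def test_all_zero(self):
        r = nb_wald(np.zeros(10), GROUPS10, np.ones(10), 0.05)
        assert r["p"] == 1.0 and r["log2fc_mle"] == 0.0

    def test_size_factor_offsets(self):
        # doubling one group's depth with equal abundance must give lfc ~ 0
        rng = np.random.default_rng(9)
        sf = np.where(GROUPS10 == 1, 2.0, 1.0)
        y = rng.poisson(100 * sf).astype(float)
        r = nb_wald(y, GROUPS10, sf, 1e-8)
        assert abs(r["log2fc_mle"]) < 0.5


class TestShrink:
    def test_tiny_se_keeps_mle(self):
        out = shrink_lfc(np.array([2.0]), np.array([1e-6]), prior_scale=0.5)
        assert out[0] == pytest.approx(2.0, abs=1e-3)

    def test_zero_mle_stays_zero(self):
        assert shrink_lfc(np.array([0.0]), np.array([0.5]))[0] == 0.0

    def test_shrinkage_bounded_and_sign_preserving(self):
        rng = np.random.default_rng(10)
        lfc = rng.normal(0, 2, 200)
        se = rng.uniform(0.05, 1.0, 200)
        out = shrink_lfc(lfc, se)
        assert (np.abs(out) <= np.abs(lfc) + 1e-9).all()
        assert np.all((np.sign(out) == np.sign(lfc)) | (out == 0))

    def test_infinite_se_shrinks_to_zero(self):
        assert shrink_lfc(np.array([3.0]), np.array([np.inf]))[0] == 0.0


class TestLocalFdr:
    def test_pure_null(self):
        rng = np.random.default_rng(11)
        z = rng.normal(0, 1, 10_000)
        lfdr = local_fdr(z)
        assert np.median(lfdr) >= 0.9
        assert ((lfdr >= 0) & (lfdr <= 1)).all()

    def test_shifted_component(self):
        rng = np.random.default_rng(12)
        z = np.concatenate([rng.normal(0, 1, 9_000), rng.normal(6, 1, 1_000)])
        lfdr = local_fdr(z)
        assert lfdr[-1000:].mean() < 0.2

    def test_too_few_values_warns(self):
        with pytest.warns(UserWarning, match="local FDR"):
            out = local_fdr(np.random.default_rng(0).normal(size=50))
        assert np.isnan(out).all()


class TestSizeFactors:
    def test_median_of_ratios(self):
        rng = np.random.default_rng(13)
        base = rng.uniform(50, 500, 100)
        depth = np.array([0.5, 1.0, 2.0, 1.5])
        Y = np.outer(base, depth)
        sf = size_factors(Y)
        assert np.allclose(sf / sf[1], depth / depth[1], rtol=1e-6)

    def test_total_fallback_geometric_mean_one(self):
        # with too few all-nonzero rows the fallback scales library totals
        # to geometric mean 1
        rng = np.random.default_rng(14)
        Y = rng.poisson(2, size=(30, 6)).astype(float)
        Y[0] = 0
        sf = size_factors(Y, min_informative=50)
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0, rel=1e-9)


class TestRunContrasts:
    def test_missing_group_error(self, de_samples):
        mat = pd.DataFrame(
            np.ones((10, 10)), columns=[s.sample_id for s in de_samples]
        )
        with pytest.raises(ValueError, match="R2"):
            run_contrasts(mat, de_samples, contrasts=(Contrast("R2", "ZT8"),))

    def test_swap_negates_lfc(self, de_samples):
        rng = np.random.default_rng(15)
        mat = pd.DataFrame(
            rng.poisson(100, size=(300, 10)).astype(float),
            columns=[s.sample_id for s in de_samples],
            index=[f"P{i}" for i in range(300)],
        )
        fwd = run_contrasts(mat, de_samples, contrasts=(Contrast("R0", "ZT6"),))
        rev = run_contrasts(mat, de_samples, contrasts=(Contrast("ZT6", "R0"),))
        assert np.allclose(fwd["log2fc_mle"], -rev["log2fc_mle"], atol=1e-8)

    def test_row_order_invariance(self, de_samples):
        rng = np.random.default_rng(16)
        mat = pd.DataFrame(
            rng.poisson(150, size=(250, 10)).astype(float),
            columns=[s.sample_id for s in de_samples],
            index=[f"P{i}" for i in range(250)],
        )
        a = run_contrasts(mat, de_samples, contrasts=(Contrast("R0", "ZT6"),))
        b = run_contrasts(mat.iloc[::-1], de_samples, contrasts=(Contrast("R0", "ZT6"),))
        m = a.merge(b, on="pac_id", suffixes=("_a", "_b"))
        assert np.allclose(m["p_a"], m["p_b"], atol=1e-8)

    def test_multi_apa_flag(self, de_samples):
        rng = np.random.default_rng(17)
        tcols = [i for i, s in enumerate(de_samples) if s.condition == "R0"]
        mu = np.full((300, 10), 200.0)
        mu[:40, tcols] *= 4  # effect on a minority so size factors stay neutral
        Y = rng.poisson(mu).astype(float)
        mat = pd.DataFrame(
            Y, columns=[s.sample_id for s in de_samples],
            index=[f"P{i}" for i in range(300)],
        )
        pac_gene = {f"P{i}": f"G{i % 150}" for i in range(300)}
        res = run_contrasts(
            mat, de_samples, contrasts=(Contrast("R0", "ZT6"),),
            multi_apa_genes={f"G{i}" for i in range(75)}, pac_gene=pac_gene,
        )
        assert res["significant"].any()
        assert (res["significant_multi_apa"] <= res["significant"]).all()
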