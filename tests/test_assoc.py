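"""Score tests, saddlepoint approximation, Firth fallback, streaming driver."""
import numpy as np
import pytest
from scipy.special import logit, ndtr

from mixscore.assoc import (
    Step2Config,
    adjust_genotype,
    calibrate_variance_ratio,
    firth_fit,
    merge_association_tsv,
    run_step2,
    score_test,
    spa_pvalue,
)
from mixscore.errors import DataError
from mixscore.genotype_io import VariantRecord, write_vcf_dosages
from mixscore.grm import GrmOperator
from mixscore.null_model import NullModelConfig, fit_null
from mixscore.simulate import sim_genotypes


class TestAdjustGenotype:
    def test_covariate_column_annihilated(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(50), rng.standard_normal(50)])
        w = rng.uniform(0.1, 0.3, 50)
        g = X[:, 1].copy()
        assert np.max(np.abs(adjust_genotype(g, X, w))) < 1e-10

    def test_intercept_only_constant_weights_centers(self):
        g = np.array([0.0, 1.0, 2.0, 1.0])
        X = np.ones((4, 1))
        got = adjust_genotype(g, X, np.full(4, 0.25))
        np.testing.assert_allclose(got, g - g.mean(), atol=1e-12)

    def test_matches_dense_weighted_projection(self):
        rng = np.random.default_rng(1)
        n = 80
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        w = rng.uniform(0.05, 0.25, n)
        g = rng.integers(0, 3, n).astype(float)
        W = np.diag(w)
        H = X @ np.linalg.solve(X.T @ W @ X, X.T @ W)
        np.testing.assert_allclose(adjust_genotype(g, X, w), g - H @ g,
                                   atol=1e-10)
        # weighted orthogonality to the covariates
        gt = adjust_genotype(g, X, w)
        assert np.max(np.abs(X.T @ (w * gt))) < 1e-10


class TestScoreTest:
    def test_matches_trend_test_without_covariates(self):
        rng = np.random.default_rng(5)
        n = 400
        g = rng.integers(0, 3, n).astype(float)
        y = (rng.random(n) < 0.3).astype(float)
        op = GrmOperator.from_factor(np.eye(n))
        fit = fit_null(y, np.ones((n, 1)), op, "binary",
                       NullModelConfig(fix_tau=0.0))
        gt = adjust_genotype(g, fit.X, fit.w)
        T, var_T = score_test(fit, gt, mode="exact", grm_op=op)
        # Cochran-Armitage trend chi-square from the 2x3 table
        pbar = y.mean()
        Tc = g @ y - pbar * g.sum()
        Vc = pbar * (1 - pbar) * ((g ** 2).sum() - g.sum() ** 2 / n)
        assert T ** 2 / var_T == pytest.approx(Tc ** 2 / Vc, rel=1e-8)

    def test_zero_genotype_gives_null_result(self, family_fit, family_cohort):
        T, var_T = score_test(family_fit, np.zeros(len(family_fit.y)),
                              mode="exact", grm_op=family_cohort["op"])
        assert T == 0.0 and var_T == 0.0

    def test_exact_and_ratio_modes_agree_on_log_pvalues(
            self, family_fit, family_cohort):
        op = family_cohort["op"]
        K = family_cohort["kinship"]
        rng = np.random.default_rng(9)
        markers = sim_genotypes(K, rng.uniform(0.1, 0.5, 60), rng)
        r_hat = calibrate_variance_ratio(family_fit, op, markers.values)
        test = sim_genotypes(K, np.random.default_rng(10).uniform(0.05, 0.5, 200),
                             np.random.default_rng(10))
        dmax = 0.0
        for j in range(200):
            gt = adjust_genotype(test.values[:, j], family_fit.X,
                                 family_fit.w)
            T, v_ex = score_test(family_fit, gt, mode="exact", grm_op=op)
            _, v_ra = score_test(family_fit, gt, mode="variance_ratio",
                                 variance_ratio=r_hat)
            p_ex = 2 * ndtr(-abs(T) / np.sqrt(v_ex))
            p_ra = 2 * ndtr(-abs(T) / np.sqrt(v_ra))
            dmax = max(dmax, abs(np.log10(p_ex) - np.log10(p_ra)))
        assert dmax < 0.1


class TestVarianceRatio:
    def test_near_one_without_relatedness(self):
        rng = np.random.default_rng(2)
        n = 500
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = (rng.random(n) < 0.3).astype(float)
        op = GrmOperator.from_factor(np.eye(n))
        fit = fit_null(y, X, op, "binary", NullModelConfig(fix_tau=0.0))
        markers = rng.integers(0, 3, size=(n, 40)).astype(float)
        r = calibrate_variance_ratio(fit, op, markers)
        assert r == pytest.approx(1.0, abs=0.02)

    def test_deterministic(self, family_fit, family_cohort):
        rng = np.random.default_rng(3)
        markers = sim_genotypes(family_cohort["kinship"],
                                rng.uniform(0.1, 0.5, 35), rng)
        a = calibrate_variance_ratio(family_fit, family_cohort["op"],
                                     markers.values, seed=1)
        b = calibrate_variance_ratio(family_fit, family_cohort["op"],
                                     markers.values, seed=1)
        assert a == b

    def test_requires_thirty_markers(self, family_fit, family_cohort):
        with pytest.raises(DataError, match="30"):
            calibrate_variance_ratio(family_fit, family_cohort["op"],
                                     np.ones((len(family_fit.y), 10)))


class TestSpa:
    def test_statistic_at_null_mean_gives_p_one(self, family_fit):
        g = np.random.default_rng(4).standard_normal(len(family_fit.y))
        p, ok = spa_pvalue(family_fit, g, 0.0)
        assert ok and p == 1.0

    def test_more_accurate_than_normal_under_imbalance(self):
        from mixscore.experiments import spa_accuracy_experiment

        res = spa_accuracy_experiment(seed=1)
        assert len(res["hard_points"]) > 0
        for pt in res["hard_points"]:
            assert pt["rel_spa"] < pt["rel_norm"]

    def test_normal_limit_balanced_large_n(self):
        # balanced case-control, mu = 0.5: CGF is nearly Gaussian and the
        # SPA p at |z| = 2 approaches 2*Phi(-2)
        rng = np.random.default_rng(6)
        n = 5000
        mu = np.full(n, 0.5)
        g = rng.standard_normal(n)
        g -= g.mean()
        var0 = float((g * g * mu * (1 - mu)).sum())
        T = 2.0 * np.sqrt(var0)

        from mixscore.null_model import NullModelFit
        fit = NullModelFit(trait_type="binary", tau_hat=0.0,
                           alpha_hat=np.zeros(1), mu_hat=mu,
                           b_hat=np.zeros(n), w=mu * (1 - mu),
                           residuals=np.zeros(n), converged=True,
                           outer_iterations=1, trace_probes_seed=0)
        p, ok = spa_pvalue(fit, g, T)
        assert ok
        assert p == pytest.approx(2 * ndtr(-2.0), rel=0.15)


class TestFirth:
    def test_intercept_only_closed_form(self):
        # k successes of n with the Jeffreys penalty: logit((k+1/2)/(n+1))
        y = np.array([1.0] * 3 + [0.0] * 7)
        beta, se, p = firth_fit(y, np.ones((10, 1)))
        assert beta == pytest.approx(logit(3.5 / 11), abs=1e-8)

    def test_finite_under_complete_separation(self):
        y = np.array([0.0, 0.0, 1.0, 1.0])
        X = np.column_stack([np.ones(4), [-2.0, -1.0, 1.0, 2.0]])
        beta, se, p = firth_fit(y, X)
        assert np.isfinite(beta) and np.isfinite(se) and 0 < p <= 1

    def test_matches_mle_on_large_balanced_data(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        n = 4000
        x = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x])
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.2 + 0.5 * x)))).astype(float)
        beta, se, _ = firth_fit(y, X)
        mle = sm.Logit(y, X).fit(disp=0).params[1]
        assert beta == pytest.approx(mle, rel=0.02)


class TestRunStep2:
    @pytest.fixture()
    def shard(self, tmp_path, family_fit, family_cohort):
        K = family_cohort["kinship"]
        rng = np.random.default_rng(8)
        block = sim_genotypes(K, rng.uniform(0.05, 0.5, 100), rng)
        block.sample_ids = list(family_fit.sample_ids or
                                [f"S{i + 1:06d}" for i in range(len(K))])
        for v, r2 in zip(block.variants, rng.uniform(0.5, 1.0, 100)):
            v.info_score = float(r2)
        path = tmp_path / "shard.vcf"
        write_vcf_dosages(path, block.variants, block.values,
                          block.sample_ids)
        return path

    def test_schema_and_probability_range(self, shard, family_fit,
                                          family_cohort, tmp_path):
        out = tmp_path / "out.tsv"
        r_hat = calibrate_variance_ratio(
            family_fit, family_cohort["op"],
            sim_genotypes(family_cohort["kinship"],
                          np.random.default_rng(1).uniform(0.1, 0.5, 30),
                          np.random.default_rng(1)).values)
        res = run_step2(family_fit, shard,
                        Step2Config(mode="variance_ratio", mac_min=10.0,
                                    variance_ratio=r_hat),
                        out_path=out)
        assert len(res.records) > 50
        assert all(0 < r.p_value <= 1 for r in res.records)

    def test_exact_mode_outputs(self, shard, family_fit, family_cohort,
                                tmp_path):
        out = tmp_path / "assoc.tsv"
        res = run_step2(family_fit, shard,
                        Step2Config(mode="exact", mac_min=10.0),
                        out_path=out, grm_op=family_cohort["op"])
        assert len(res.records) == res.tally.n_retained
        for rec in res.records:
            assert 0 < rec.p_value <= 1 and 0 < rec.p_normal <= 1
            assert rec.var_T > 0
        lines = out.read_text().splitlines()
        assert lines[0].startswith("CHR\tPOS\tID")
        assert len(lines) == len(res.records) + 1

    def test_sharding_invariance_byte_identical(self, shard, family_fit,
                                                family_cohort, tmp_path):
        cfg = Step2Config(mode="exact", mac_min=10.0)
        whole = tmp_path / "whole.tsv"
        run_step2(family_fit, shard, cfg, out_path=whole,
                  grm_op=family_cohort["op"])
        header, *body = shard.read_text().splitlines(keepends=True)
        meta = [ln for ln in [header] + body if ln.startswith("#")]
        data = [ln for ln in body if not ln.startswith("#")]
        parts = []
        for i in range(4):
            sub = tmp_path / f"sub{i}.vcf"
            sub.write_text("".join(meta + data[i * 25:(i + 1) * 25]))
            out = tmp_path / f"sub{i}.tsv"
            run_step2(family_fit, sub, cfg, out_path=out,
                      grm_op=family_cohort["op"])
            parts.append(out)
        merged = tmp_path / "merged.tsv"
        merge_association_tsv(parts, merged)
        assert merged.read_bytes() == whole.read_bytes()

    def test_mac_filter_tallied(self, family_fit, family_cohort, tmp_path):
        n = len(family_fit.y)
        ids = family_fit.sample_ids or [f"S{i + 1:06d}" for i in range(n)]
        rare = np.zeros(n)
        rare[:3] = 1.0  # MAC 3
        common = np.random.default_rng(11).integers(0, 3, n).astype(float)
        variants = [VariantRecord("1", 1, "rare", "A", "C", 0.0, 0.0),
                    VariantRecord("1", 2, "common", "A", "C", 0.0, 0.0)]
        path = tmp_path / "two.vcf"
        write_vcf_dosages(path, variants, np.column_stack([rare, common]), ids)
        res = run_step2(family_fit, path,
                        Step2Config(mode="exact", mac_min=40.0),
                        grm_op=family_cohort["op"])
        assert res.tally.low_mac == 1
        assert [r.variant.id for r in res.records] == ["common"]

    def test_zero_sample_overlap_rejected(self, family_fit, tmp_path):
        variants = [VariantRecord("1", 1, "v", "A", "C", 0.0, 0.0)]
        path = tmp_path / "alien.vcf"
        write_vcf_dosages(path, variants, np.ones((3, 1)), ["x", "y", "z"])
        with pytest.raises(DataError, match="overlap"):
            run_step2(family_fit, path, Step2Config(mode="variance_ratio",
                                                    variance_ratio=1.0))

    def test_rerun_reproduces_bytes(self, shard, family_fit, family_cohort,
                                    tmp_path):
        cfg = Step2Config(mode="exact", mac_min=10.0)
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        run_step2(family_fit, shard, cfg, out_path=a,
                  grm_op=family_cohort["op"])
        run_step2(family_fit, shard, cfg, out_path=b,
                  grm_op=family_cohort["op"])
        assert a.read_bytes() == b.read_bytes()
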