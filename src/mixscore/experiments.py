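"""Reproducible study-condition experiments built from the simulator.

These functions define the package's standing validation experiments —
variance-component recovery, null-calibration, and saddlepoint tail
accuracy — at the cohort sizes documented in docs/methods.md.  They are
shared by the test suite and the acceptance script so both report the
same computations.
"""
from __future__ import annotations

import numpy as np
from scipy.special import ndtr
from scipy.stats import chi2

from .assoc import Step2Config, _test_one_variant, calibrate_variance_ratio
from .grm import GrmOperator
from .null_model import NullModelConfig, fit_null
from .simulate import (
    SimTruth,
    sim_binary_trait,
    sim_covariates,
    sim_genotypes,
    sim_kinship,
)

from scipy.linalg import cho_factor


def tau_recovery_experiment(n_replicates: int = 20, n_families: int = 200,
                            family_size: int = 10, relatedness: float = 0.5,
                            tau_true: float = 1.0, prevalence: float = 0.1,
                            seed: int = 1, n_probes: int = 10) -> dict:
    """Repeatedly simulate a family cohort and re-estimate tau.

    The fit uses an operator holding the generator's kinship exactly (via
    its Cholesky factor), so the experiment measures the estimator rather
    than genotype-sampling noise in the empirical GRM.
    """
    family_sizes = [family_size] * n_families
    kinship = sim_kinship(family_sizes, relatedness)
    L = np.linalg.cholesky(kinship)
    grm_op = GrmOperator.from_factor(L)
    taus = []
    for rep in range(n_replicates):
        truth = SimTruth(tau_true=tau_true, family_sizes=family_sizes,
                         relatedness=relatedness, prevalence=prevalence,
                         alpha=(0.0, 0.05, 0.2), seed=seed * 100003 + rep)
        X = sim_covariates(truth.n_samples, truth.rng("covariates"))
        y = sim_binary_trait(None, X, truth, kinship)
        cfg = NullModelConfig(n_probes=n_probes, seed=truth.seed + 7,
                              tol_outer=1e-3)
        fit = fit_null(y, X, grm_op, "binary", cfg)
        taus.append(fit.tau_hat)
    taus = np.asarray(taus)
    return {"taus": taus, "mean_tau": float(taus.mean()),
            "n_samples": n_families * family_size,
            "n_replicates": n_replicates}


def calibration_experiment(n_variants: int = 5000, n_families: int = 500,
                           family_size: int = 5, relatedness: float = 0.5,
                           tau_true: float = 1.0, prevalence: float = 0.2,
                           seed: int = 1) -> dict:
    """Type-I error and genomic inflation on null variants.

    One family cohort is simulated and the null model fitted with the
    generator's kinship held exactly in the operator; ``n_variants`` fresh
    kinship-structured variants with no effect on the trait are then
    tested in variance-ratio mode with the SPA applied in the tail,
    exactly as the production path would.
    """
    family_sizes = [family_size] * n_families
    truth = SimTruth(tau_true=tau_true, family_sizes=family_sizes,
                     relatedness=relatedness, prevalence=prevalence,
                     alpha=(0.0, 0.1, 0.3), maf_range=(0.05, 0.5), seed=seed)
    kinship = sim_kinship(family_sizes, relatedness)
    X = sim_covariates(truth.n_samples, truth.rng("covariates"))
    y = sim_binary_trait(None, X, truth, kinship)

    grm_op = GrmOperator.from_factor(np.linalg.cholesky(kinship))
    cfg = NullModelConfig(n_probes=10, seed=seed + 11, tol_outer=1e-3)
    fit = fit_null(y, X, grm_op, "binary", cfg)

    m_rng = truth.rng("markers")
    calib_block = sim_genotypes(kinship, m_rng.uniform(0.1, 0.5, 40), m_rng)
    r_hat = calibrate_variance_ratio(fit, grm_op, calib_block.values)
    fit.variance_ratio = r_hat

    test_rng = np.random.default_rng(seed + 101)
    test_mafs = test_rng.uniform(0.05, 0.5, size=n_variants)
    test_block = sim_genotypes(kinship, test_mafs, test_rng)

    s2cfg = Step2Config(mode="variance_ratio", variance_ratio=r_hat,
                        mac_min=0.0)
    XtW = fit.X.T * fit.w
    xtwx_cho = cho_factor(XtW @ fit.X)
    pvals, zs = [], []
    for j, rec in enumerate(test_block.variants):
        out = _test_one_variant(fit, rec, test_block.values[:, j], s2cfg,
                                None, xtwx_cho)
        if out is not None:
            pvals.append(out.p_value)
            zs.append(out.z)
    pvals = np.asarray(pvals)
    zs = np.asarray(zs)
    lambda_gc = float(np.median(zs**2) / chi2.ppf(0.5, df=1))
    return {"pvals": pvals, "type1_at_05": float((pvals <= 0.05).mean()),
            "lambda_gc": lambda_gc, "variance_ratio": r_hat,
            "n_variants_tested": len(pvals),
            "n_samples": truth.n_samples, "fit": fit}


def exact_score_distribution(g: np.ndarray, mu: np.ndarray):
    """Exact distribution of S = sum_i g_i y_i with y_i ~ Bernoulli(mu_i)
    for small integer-valued g, by direct convolution.

    Returns (support, pmf) of S.
    """
    g = np.asarray(g)
    if not np.all(g == g.astype(int)):
        raise ValueError("enumeration oracle needs integer-valued g")
    g = g.astype(int)
    max_s = int(g[g > 0].sum()) if (g > 0).any() else 0
    min_s = int(g[g < 0].sum()) if (g < 0).any() else 0
    pmf = np.zeros(max_s - min_s + 1)
    pmf[-min_s] = 1.0
    for gi, mi in zip(g, mu):
        if gi == 0:
            continue
        new = pmf * (1.0 - mi)
        shifted = np.zeros_like(pmf)
        if gi > 0:
            shifted[gi:] = pmf[:-gi] * mi
        else:
            shifted[:gi] = pmf[-gi:] * mi
        pmf = new + shifted
    support = np.arange(min_s, max_s + 1)
    return support, pmf


def spa_accuracy_experiment(seed: int = 1, n: int = 20,
                            case_mu: float = 0.05) -> dict:
    """Compare SPA and normal tail approximations against the enumeration
    oracle on a tiny imbalanced instance.

    Evaluates P(T >= q) at lattice points in the operating region of the
    SPA switch (exact tail below 0.05, where |z| > 2 would trigger it),
    using the unit-lattice form of the tail formula since the instance is
    integer-valued.  Reports the worst SPA relative error at the points
    where the normal tail errs by more than 2x.
    """
    from .assoc import _spa_tail

    rng = np.random.default_rng(seed)
    # fixed carrier design (half het, half hom-alt) so every sample is
    # informative and the lattice span is 1; heterogeneous rare-case
    # probabilities drawn around case_mu
    g = np.array([1.0] * (n // 2) + [2.0] * (n - n // 2))
    mu = rng.uniform(0.4 * case_mu, 2.0 * case_mu, size=n)
    support, pmf = exact_score_distribution(g, mu)
    mean_s = float(g @ mu)
    sd = float(np.sqrt((g * g * mu * (1 - mu)).sum()))
    results = []
    cum_upper = np.cumsum(pmf[::-1])[::-1]  # P(S >= s)
    for idx, s in enumerate(support):
        exact = float(cum_upper[idx])
        if not (1e-6 < exact < 0.05):
            continue
        q = s - mean_s  # tail point on the centered statistic T
        spa, ok = _spa_tail(q, g, mu, upper=True, lattice=True)
        if not ok:
            continue
        normal = float(ndtr(-q / sd))
        rel_spa = abs(spa - exact) / exact
        rel_norm = abs(normal - exact) / exact
        results.append({"s": int(s), "exact": exact, "spa": spa,
                        "normal": normal, "rel_spa": rel_spa,
                        "rel_norm": rel_norm})
    hard = [r for r in results
            if r["normal"] > 2 * r["exact"] or r["normal"] < r["exact"] / 2]
    worst = max((r["rel_spa"] for r in hard), default=float("nan"))
    return {"points": results, "hard_points": hard,
            "worst_spa_rel_err_hard": worst, "n": n}
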