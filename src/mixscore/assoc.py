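"""Step two: per-variant covariate-adjusted score tests.

Each dosage vector g is adjusted for covariates under the working weights
(g_tilde = g - X (X^T W X)^{-1} X^T W g), giving the score statistic
T = g_tilde^T (y - mu_hat) with null variance either computed exactly as
g_tilde^T P g_tilde through the fitted projection (one PCG solve per
variant) or approximated as r_hat * g_tilde^T W g_tilde with a variance
ratio r_hat calibrated once on a sample of markers.

For binary traits, normal-approximation p-values are replaced by the
saddlepoint approximation (SPA) in the tail (|z| above a trigger), which
keeps type-I error calibrated under extreme case-control imbalance; when
the resulting p-value is small, the effect size is re-estimated by Firth
penalized logistic regression, which remains finite under separation.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit, ndtr

from .errors import DataError, DomainError
from .genotype_io import (
    FilterTally,
    VariantRecord,
    filter_variants,
    read_vcf_dosages,
)
from .grm import GrmOperator
from .null_model import NullModelFit, apply_projection_P, load_fit

log = logging.getLogger(__name__)

TSV_HEADER = ("CHR\tPOS\tID\tREF\tALT\tAF_alt\tMAC\tN\tBETA\tSE\tTstat\t"
              "var_T\tp_normal\tp_value\tused_SPA\tused_Firth")

P_FLOOR = 1e-300


@dataclass
class AssociationRecord:
    variant: VariantRecord
    n: int
    score_T: float
    var_T: float
    z: float
    p_normal: float
    p_value: float
    used_spa: bool
    used_firth: bool
    beta: float
    se: float

    def to_tsv_row(self) -> str:
        v = self.variant
        return (f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref_allele}\t{v.alt_allele}\t"
                f"{v.alt_freq:.6g}\t{v.mac:.6g}\t{self.n}\t{self.beta:.6g}\t"
                f"{self.se:.6g}\t{self.score_T:.6g}\t{self.var_T:.6g}\t"
                f"{self.p_normal:.6g}\t{self.p_value:.6g}\t"
                f"{int(self.used_spa)}\t{int(self.used_firth)}")


@dataclass
class Step2Config:
    mac_min: float = 40.0
    info_min: float = 0.3
    mode: str = "exact"            # "exact" | "variance_ratio"
    spa_trigger: float = 2.0       # apply SPA when |z| exceeds this
    firth_trigger: float = 0.01    # Firth refit when p_value <= this
    variance_ratio: float | None = None


# ---------------------------------------------------------------------------
# genotype adjustment and the score test

def adjust_genotype(g: np.ndarray, X: np.ndarray, w: np.ndarray,
                    xtwx_cho=None) -> np.ndarray:
    """Residualize g against the covariates under the working weights W."""
    g = np.asarray(g, dtype=np.float64)
    if xtwx_cho is None:
        XtW = X.T * w
        xtwx_cho = cho_factor(XtW @ X)
    coef = cho_solve(xtwx_cho, X.T @ (w * g))
    return g - X @ coef


def score_test(fit: NullModelFit, g_tilde: np.ndarray, mode: str = "exact",
               grm_op: GrmOperator | None = None,
               variance_ratio: float | None = None) -> tuple[float, float]:
    """Score statistic T = g_tilde^T (y - mu_hat) and its null variance."""
    T = float(g_tilde @ (fit.y - fit.mu_hat))
    if mode == "exact":
        if grm_op is None:
            raise DataError("exact variance mode needs the GRM operator")
        var_T = float(g_tilde @ apply_projection_P(fit, grm_op, g_tilde))
    elif mode == "variance_ratio":
        if variance_ratio is None:
            variance_ratio = fit.variance_ratio
        if variance_ratio is None:
            raise DataError("variance_ratio mode needs a calibrated ratio")
        var_T = float(variance_ratio * (g_tilde * fit.w) @ g_tilde)
    else:
        raise DomainError(f"unknown variance mode {mode!r}")
    return T, var_T


def calibrate_variance_ratio(fit: NullModelFit, grm_op: GrmOperator,
                             marker_sample: np.ndarray,
                             seed: int = 0) -> float:
    """Mean ratio (g^T P g)/(g^T W g) over >= 30 adjusted random markers.

    The ratio relates the cheap diagonal variance to the full mixed-model
    variance; its per-marker coefficient of variation is logged and a
    warning emitted above 0.10.
    """
    marker_sample = np.asarray(marker_sample, dtype=np.float64)
    if marker_sample.ndim != 2 or marker_sample.shape[1] < 30:
        raise DataError("variance-ratio calibration needs >= 30 markers")
    XtW = fit.X.T * fit.w
    xtwx_cho = cho_factor(XtW @ fit.X)
    ratios = []
    for j in range(marker_sample.shape[1]):
        g = marker_sample[:, j]
        g_tilde = adjust_genotype(g, fit.X, fit.w, xtwx_cho=xtwx_cho)
        den = float((g_tilde * fit.w) @ g_tilde)
        if den <= 0:
            continue
        num = float(g_tilde @ apply_projection_P(fit, grm_op, g_tilde))
        ratios.append(num / den)
    ratios = np.asarray(ratios)
    r_hat = float(ratios.mean())
    cv = float(ratios.std(ddof=1) / abs(r_hat)) if len(ratios) > 1 else 0.0
    log.info("variance ratio: r=%.4f over %d markers (cv=%.3f)",
             r_hat, len(ratios), cv)
    if cv > 0.1:
        log.warning("variance-ratio coefficient of variation %.3f > 0.1", cv)
    return r_hat


# ---------------------------------------------------------------------------
# saddlepoint approximation

def _spa_cgf(t: float, g: np.ndarray, mu: np.ndarray, gmu: float):
    """K(t), K'(t), K''(t) of T = g^T(y - mu) with y_i ~ Bernoulli(mu_i)."""
    x = g * t
    # log(1 - mu + mu e^x), stable in both tails
    small = x < 30.0
    lterm = np.where(small,
                     np.log1p(mu * np.expm1(np.where(small, x, 0.0))),
                     x + np.log(mu + (1.0 - mu) * np.exp(-np.where(small, 0.0, x))))
    K = float(lterm.sum()) - t * gmu
    s = expit(x + np.log(mu / (1.0 - mu)))  # e^x mu / (1 - mu + mu e^x)
    K1 = float((g * s).sum()) - gmu
    K2 = float((g * g * s * (1.0 - s)).sum())
    return K, K1, K2


def _spa_tail(q: float, g: np.ndarray, mu: np.ndarray,
              upper: bool, lattice: bool = False) -> tuple[float, bool]:
    """P(T >= q) (upper) or P(T <= q) via the Barndorff-Nielsen formula.

    With ``lattice=True`` the statistic is treated as living on a unit
    lattice and u uses the Daniels correction (1 - e^{-zeta}) in place of
    zeta; the continuous form is the default for covariate-adjusted
    dosages.
    """
    gmu = float(g @ mu)
    var0 = float((g * g * mu * (1.0 - mu)).sum())
    if var0 <= 0:
        return 1.0, False
    # attainable range of K'
    k1_max = float((g * (g > 0)).sum()) - gmu
    k1_min = float((g * (g < 0)).sum()) - gmu
    if (upper and q >= k1_max) or (not upper and q <= k1_min):
        return 0.0, True
    if (upper and q <= k1_min) or (not upper and q >= k1_max):
        return 1.0, True
    # safeguarded Newton for K'(zeta) = q
    lo, hi = -1.0, 1.0
    for _ in range(200):
        if _spa_cgf(lo, g, mu, gmu)[1] < q:
            break
        lo *= 2.0
    for _ in range(200):
        if _spa_cgf(hi, g, mu, gmu)[1] > q:
            break
        hi *= 2.0
    zeta = q / var0
    zeta = min(max(zeta, lo), hi)
    ok = False
    for _ in range(100):
        K, K1, K2 = _spa_cgf(zeta, g, mu, gmu)
        diff = K1 - q
        if abs(diff) <= 1e-9 * (1.0 + abs(q)):
            ok = True
            break
        if diff > 0:
            hi = zeta
        else:
            lo = zeta
        step = diff / K2 if K2 > 0 else 0.0
        cand = zeta - step
        zeta = cand if lo < cand < hi else 0.5 * (lo + hi)
    if not ok:
        return math.nan, False
    K, _, K2 = _spa_cgf(zeta, g, mu, gmu)
    arg = 2.0 * (zeta * q - K)
    if arg < 0.0 or K2 <= 0.0:
        return math.nan, False
    w = math.copysign(math.sqrt(arg), zeta)
    if lattice:
        u = (1.0 - math.exp(-zeta)) * math.sqrt(K2) if upper \
            else (1.0 - math.exp(zeta)) * -math.sqrt(K2)
    else:
        u = zeta * math.sqrt(K2)
    if abs(w) < 1e-5 or abs(u) < 1e-8:
        # statistic at its null mean; normal limit
        tail = float(ndtr(-q / math.sqrt(var0)))
        return (tail if upper else 1.0 - tail), True
    r = w + math.log(u / w) / w
    tail = float(ndtr(-r)) if upper else float(ndtr(r))
    return tail, True


def spa_pvalue(fit: NullModelFit, g_tilde: np.ndarray,
               T: float) -> tuple[float, bool]:
    """Two-sided saddlepoint p-value for the score statistic.

    Both tails are evaluated at +/- |T|; on root-finder failure the caller
    should fall back to the normal approximation (converged flag False).
    """
    if fit.trait_type != "binary":
        raise DomainError("the saddlepoint approximation applies to binary traits")
    mu = fit.mu_hat
    q = abs(T)
    up, ok1 = _spa_tail(q, g_tilde, mu, upper=True)
    lo, ok2 = _spa_tail(-q, g_tilde, mu, upper=False)
    if not (ok1 and ok2) or not np.isfinite(up + lo):
        return math.nan, False
    p = min(1.0, max(up + lo, P_FLOOR))
    return p, True


# ---------------------------------------------------------------------------
# Firth penalized logistic regression

def firth_fit(y: np.ndarray, design_with_g: np.ndarray, max_iter: int = 50,
              tol: float = 1e-8) -> tuple[float, float, float]:
    """Jeffreys-penalized logistic fit; returns (beta, se, Wald p) for the
    last design column (the genotype).

    The penalty 0.5*log det(X^T W X) keeps estimates finite even under
    complete separation; fitting is by modified Fisher scoring.
    """
    y = np.asarray(y, dtype=np.float64)
    X = np.asarray(design_with_g, dtype=np.float64)
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = np.log((y.mean() + 1e-6) / (1.0 - y.mean() + 1e-6))
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        XtW = X.T * w
        info = XtW @ X
        cho = cho_factor(info)
        # hat diagonal h_i of W^{1/2} X (X^T W X)^{-1} X^T W^{1/2}
        XtW_half = X.T * np.sqrt(w)
        h = np.einsum("ij,ij->j", XtW_half, cho_solve(cho, XtW_half))
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = cho_solve(cho, score)
        # step-halving on overshoot
        limit = 5.0
        norm_step = np.max(np.abs(step))
        if norm_step > limit:
            step *= limit / norm_step
        beta_new = beta + step
        if np.max(np.abs(step)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    if not converged:
        log.warning("Firth fit reached %d iterations without convergence",
                    max_iter)
    eta = X @ beta
    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    info = (X.T * w) @ X
    cov = np.linalg.inv(info)
    se = math.sqrt(cov[-1, -1])
    zstat = beta[-1] / se
    pval = max(2.0 * float(ndtr(-abs(zstat))), P_FLOOR)
    return float(beta[-1]), se, pval


# ---------------------------------------------------------------------------
# streaming driver

@dataclass
class Step2Result:
    records: list[AssociationRecord]
    tally: FilterTally
    n_untestable: int = 0
    n_dropped_samples: int = 0


def _test_one_variant(fit: NullModelFit, rec: VariantRecord, g: np.ndarray,
                      config: Step2Config, grm_op: GrmOperator | None,
                      xtwx_cho) -> AssociationRecord | None:
    n = len(g)
    finite = np.isfinite(g)
    if finite.sum() == 0:
        return None
    if not finite.all():
        g = g.copy()
        g[~finite] = g[finite].mean()
    g_tilde = adjust_genotype(g, fit.X, fit.w, xtwx_cho=xtwx_cho)
    T, var_T = score_test(fit, g_tilde, mode=config.mode, grm_op=grm_op,
                          variance_ratio=config.variance_ratio)
    if not np.isfinite(var_T) or var_T <= 0:
        return None
    z = T / math.sqrt(var_T)
    p_normal = max(2.0 * float(ndtr(-abs(z))), P_FLOOR)
    p_value = p_normal
    used_spa = False
    if fit.trait_type == "binary" and abs(z) > config.spa_trigger:
        p_spa, ok = spa_pvalue(fit, g_tilde, T)
        if ok:
            p_value = p_spa
            used_spa = True
    beta = T / var_T
    se = 1.0 / math.sqrt(var_T)
    used_firth = False
    if fit.trait_type == "binary" and p_value <= config.firth_trigger:
        try:
            beta, se, _ = firth_fit(fit.y, np.column_stack([fit.X, g]))
            used_firth = True
        except (np.linalg.LinAlgError, ValueError):
            log.warning("Firth refit failed for %s; keeping score effect",
                        rec.id)
    return AssociationRecord(variant=rec, n=n, score_T=T, var_T=var_T, z=z,
                             p_normal=p_normal, p_value=p_value,
                             used_spa=used_spa, used_firth=used_firth,
                             beta=beta, se=se)


def run_step2(fit: NullModelFit | str | Path, vcf_shard,
              config: Step2Config | None = None,
              out_path=None, grm_op: GrmOperator | None = None,
              info_key: str = "R2") -> Step2Result:
    """Stream a dosage VCF shard through the score test; optionally write a
    TSV of summary statistics.  Output rows are a pure function of the null
    fit, the shard and the configuration."""
    if isinstance(fit, (str, Path)):
        fit = load_fit(fit)
    config = config or Step2Config()
    reader = read_vcf_dosages(vcf_shard, info_key=info_key)
    vcf_samples = reader.samples
    if fit.sample_ids is not None:
        fit_ids = list(fit.sample_ids)
        pos = {s: i for i, s in enumerate(vcf_samples)}
        keep = [pos[s] for s in fit_ids if s in pos]
        if len(keep) == 0:
            raise DataError("no overlapping samples between null fit and shard")
        n_dropped = len(vcf_samples) - len(keep)
        if len(keep) != len(fit_ids):
            raise DataError(
                f"shard lacks {len(fit_ids) - len(keep)} samples present in "
                "the null fit")
        sel = np.asarray(keep)
    else:
        if len(vcf_samples) != len(fit.y):
            raise DataError("shard sample count differs from the null fit")
        sel = np.arange(len(vcf_samples))
        n_dropped = 0
    if n_dropped:
        log.info("run_step2: dropped %d unmatched shard samples", n_dropped)

    XtW = fit.X.T * fit.w
    xtwx_cho = cho_factor(XtW @ fit.X)
    tally = FilterTally()
    records: list[AssociationRecord] = []
    n_untestable = 0
    from .genotype_io import _variant_stats

    for rec, dose in reader:
        g = dose[sel]
        freq, mac, nn = _variant_stats(g)
        rec.alt_freq, rec.mac, rec.n_nonmissing = freq, mac, nn
        kept, t = filter_variants([rec], mac_min=config.mac_min,
                                  info_min=config.info_min)
        tally.n_input += 1
        tally.low_mac += t.low_mac
        tally.low_info += t.low_info
        if not kept:
            continue
        tally.n_retained += 1
        out = _test_one_variant(fit, rec, g, config, grm_op, xtwx_cho)
        if out is None:
            n_untestable += 1
            log.info("variant %s untestable (zero variance)", rec.id)
            continue
        records.append(out)

    if out_path is not None:
        write_association_tsv(records, out_path)
    return Step2Result(records=records, tally=tally,
                       n_untestable=n_untestable,
                       n_dropped_samples=n_dropped)


def write_association_tsv(records: Sequence[AssociationRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(TSV_HEADER + "\n")
        for rec in records:
            fh.write(rec.to_tsv_row() + "\n")


def merge_association_tsv(paths: Sequence, out_path) -> None:
    """Concatenate per-shard TSVs, keeping a single header."""
    with open(out_path, "w") as out:
        out.write(TSV_HEADER + "\n")
        for p in paths:
            with open(p) as fh:
                header = fh.readline().rstrip("\n")
                if header != TSV_HEADER:
                    raise DataError(f"{p} does not look like an association TSV")
                for line in fh:
                    out.write(line)
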