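"""Synthetic cohorts with known relatedness, variance component, and
case-control imbalance.

Relatedness is a block-diagonal family kinship (1 on the diagonal, a
constant coefficient within families, 0 across).  Genotypes follow a
liability-threshold model: a latent Gaussian with the kinship as its
correlation is cut at Hardy-Weinberg quantiles for each marker's MAF,
yielding hard calls in {0, 1, 2} whose familial correlation approximates
the kinship.  Traits are generated in the model's own generative
direction: logit(P(y=1)) = X alpha + G beta + b with b ~ N(0, tau * K)
for binary traits, and y = X alpha + G beta + b + e for quantitative ones.

All randomness flows from a single master seed through named substreams,
so every artifact is reproducible bit-for-bit.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .errors import DomainError
from .genotype_io import (
    RawGenotypeBlock,
    VariantRecord,
    write_bed,
    write_vcf_dosages,
)


@dataclass
class SimTruth:
    """Ground truth for a simulated cohort."""

    tau_true: float = 1.0
    family_sizes: list[int] = field(default_factory=lambda: [10] * 200)
    relatedness: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_markers: int = 2000
    prevalence: float = 0.1
    alpha: tuple[float, ...] = (0.0,)
    sigma2: float = 1.0
    causal_effects: dict[int, float] = field(default_factory=dict)
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return int(sum(self.family_sizes))

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise DomainError("maf_range must lie in (0, 0.5]")
        if not 0.0 < self.prevalence < 1.0:
            raise DomainError("prevalence must lie in (0, 1)")
        if self.relatedness < 0.0 or self.relatedness >= 1.0:
            raise DomainError("relatedness must lie in [0, 1)")

    def rng(self, substream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, _STREAMS[substream]]))


_STREAMS = {"genotypes": 1, "trait": 2, "covariates": 3, "dosage_qc": 4,
            "markers": 5}


def sim_kinship(family_sizes, relatedness: float) -> np.ndarray:
    """Block-diagonal kinship: 1 on the diagonal, `relatedness` within
    families, 0 across.  PSD by construction for relatedness in [0, 1)."""
    if relatedness < 0.0 or relatedness >= 1.0:
        raise DomainError("relatedness must lie in [0, 1)")
    if any(s < 1 for s in family_sizes):
        raise DomainError("family sizes must be >= 1")
    n = int(sum(family_sizes))
    K = np.zeros((n, n))
    start = 0
    for size in family_sizes:
        K[start:start + size, start:start + size] = relatedness
        start += size
    np.fill_diagonal(K, 1.0)
    return K


def _kinship_chol(kinship: np.ndarray) -> np.ndarray:
    # jitter-free: family-block kinship with r < 1 is PD
    return np.linalg.cholesky(kinship)


def sim_genotypes(kinship: np.ndarray, mafs: np.ndarray,
                  seed: int | np.random.Generator) -> RawGenotypeBlock:
    """Liability-threshold genotypes: latent N(0, K) per marker, cut at the
    Hardy-Weinberg quantiles of each MAF (ALT allele = minor)."""
    mafs = np.asarray(mafs, dtype=np.float64)
    if np.any(mafs <= 0) or np.any(mafs > 0.5):
        raise DomainError("mafs must lie in (0, 0.5]")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n = kinship.shape[0]
    m = len(mafs)
    L = _kinship_chol(kinship)
    Z = L @ rng.standard_normal((n, m))
    p = mafs
    # P(G=0) = (1-p)^2, P(G<=1) = 1 - p^2 under Hardy-Weinberg
    t0 = norm.ppf((1.0 - p) ** 2)
    t1 = norm.ppf(1.0 - p**2)
    G = (Z > t0[None, :]).astype(np.float64) + (Z > t1[None, :])
    variants = []
    for j in range(m):
        alt = float(G[:, j].sum())
        freq = alt / (2 * n)
        variants.append(VariantRecord(
            chrom="1", pos=j + 1, id=f"sim{j + 1}", ref_allele="A",
            alt_allele="C", alt_freq=freq, mac=min(alt, 2 * n - alt),
            info_score=None, n_nonmissing=n,
        ))
    sample_ids = [f"S{i + 1:06d}" for i in range(n)]
    return RawGenotypeBlock(values=G, variants=variants, sample_ids=sample_ids)


def sim_covariates(n: int, rng: np.random.Generator) -> np.ndarray:
    """Intercept + standardized age + sex indicator."""
    age = rng.standard_normal(n)
    sex = rng.integers(0, 2, size=n).astype(np.float64)
    return np.column_stack([np.ones(n), age, sex])


def _linear_predictor(genotypes: RawGenotypeBlock | None, X: np.ndarray,
                      truth: SimTruth, kinship: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    alpha = np.zeros(X.shape[1])
    alpha[:len(truth.alpha)] = truth.alpha
    eta = X @ alpha
    if truth.causal_effects and genotypes is not None:
        for j, beta in truth.causal_effects.items():
            eta += beta * genotypes.values[:, j]
    if truth.tau_true > 0:
        L = _kinship_chol(kinship)
        eta += np.sqrt(truth.tau_true) * (L @ rng.standard_normal(n))
    return eta


def sim_binary_trait(genotypes: RawGenotypeBlock | None, X: np.ndarray,
                     truth: SimTruth, kinship: np.ndarray) -> np.ndarray:
    """Bernoulli trait on the logistic scale with b ~ N(0, tau*K).

    The intercept offset is tuned by bisection so the expected case
    fraction matches the target prevalence.
    """
    rng = truth.rng("trait")
    eta = _linear_predictor(genotypes, X, truth, kinship, rng)

    def mean_prob(c: float) -> float:
        return float(expit(c + eta).mean())

    lo, hi = -40.0, 40.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if mean_prob(mid) < truth.prevalence:
            lo = mid
        else:
            hi = mid
    c = (lo + hi) / 2.0
    return (rng.random(X.shape[0]) < expit(c + eta)).astype(np.float64)


def sim_quantitative_trait(genotypes: RawGenotypeBlock | None, X: np.ndarray,
                           truth: SimTruth, kinship: np.ndarray) -> np.ndarray:
    """Gaussian trait y = X alpha + G beta + b + e, e ~ N(0, sigma^2 I)."""
    rng = truth.rng("trait")
    eta = _linear_predictor(genotypes, X, truth, kinship, rng)
    return eta + np.sqrt(truth.sigma2) * rng.standard_normal(X.shape[0])


def write_cohort(out_dir, truth: SimTruth, trait_type: str = "binary",
                 info_range: tuple[float, float] = (0.8, 1.0)) -> dict:
    """Materialize a cohort as BED/BIM/FAM + dosage VCF + phenotype TSV so
    the real readers are exercised end to end.  Returns file paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    kinship = sim_kinship(truth.family_sizes, truth.relatedness)
    g_rng = truth.rng("genotypes")
    mafs = g_rng.uniform(*truth.maf_range, size=truth.n_markers)
    block = sim_genotypes(kinship, mafs, g_rng)
    X = sim_covariates(truth.n_samples, truth.rng("covariates"))
    if trait_type == "binary":
        y = sim_binary_trait(block, X, truth, kinship)
    else:
        y = sim_quantitative_trait(block, X, truth, kinship)

    prefix = out_dir / "cohort"
    write_bed(block, prefix)
    qc_rng = truth.rng("dosage_qc")
    info = qc_rng.uniform(*info_range, size=truth.n_markers)
    for v, r2 in zip(block.variants, info):
        v.info_score = float(r2)
    vcf_path = out_dir / "cohort.vcf"
    write_vcf_dosages(vcf_path, block.variants, block.values,
                      block.sample_ids)
    pheno_path = out_dir / "phenotypes.tsv"
    with open(pheno_path, "w") as fh:
        fh.write("sample_id\ttrait\tage\tsex\n")
        for sid, yi, age, sex in zip(block.sample_ids, y, X[:, 1], X[:, 2]):
            if trait_type == "binary":
                fh.write(f"{sid}\t{int(yi)}\t{age:.6f}\t{int(sex)}\n")
            else:
                fh.write(f"{sid}\t{yi:.6f}\t{age:.6f}\t{int(sex)}\n")
    return {"bed_prefix": str(prefix), "vcf": str(vcf_path),
            "phenotypes": str(pheno_path), "kinship": kinship,
            "genotypes": block, "X": X, "y": y}
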