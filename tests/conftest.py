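import numpy as np
import pytest

from mixscore.grm import GrmOperator
from mixscore.null_model import NullModelConfig, fit_null
from mixscore.simulate import (
    SimTruth,
    sim_binary_trait,
    sim_covariates,
    sim_kinship,
)


@pytest.fixture(scope="session")
def family_cohort():
    """A 600-sample family cohort (120 families of 5, relatedness 0.5) with
    a binary trait generated at tau=1, prevalence 0.3."""
    family_sizes = [5] * 120
    kinship = sim_kinship(family_sizes, 0.5)
    truth = SimTruth(tau_true=1.0, family_sizes=family_sizes,
                     relatedness=0.5, prevalence=0.3,
                     alpha=(0.0, 0.1, 0.3), seed=21)
    X = sim_covariates(truth.n_samples, truth.rng("covariates"))
    y = sim_binary_trait(None, X, truth, kinship)
    L = np.linalg.cholesky(kinship)
    op = GrmOperator.from_factor(L)
    return {"kinship": kinship, "X": X, "y": y, "op": op, "truth": truth}


@pytest.fixture(scope="session")
def family_fit(family_cohort):
    """Converged binary null fit on the family cohort."""
    cfg = NullModelConfig(n_probes=20, seed=3)
    n = len(family_cohort["y"])
    fit = fit_null(family_cohort["y"], family_cohort["X"],
                   family_cohort["op"], "binary", cfg,
                   sample_ids=[f"S{i + 1:06d}" for i in range(n)])
    assert fit.converged
    return fit
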