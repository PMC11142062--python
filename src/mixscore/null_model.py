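"""Step one: fit the null generalized linear mixed model.

Model: g(E[y]) = X alpha + b with b ~ N(0, tau * psi), fitted with the
genetic effect fixed at zero.  The fitter is penalized quasi-likelihood
(PQL): at each outer iteration the working response

    z = X alpha + b + W^{-1}(y - mu)

is regressed under the working covariance Sigma = W^{-1} + tau * psi,
with every Sigma^{-1} application performed by preconditioned conjugate
gradient against the implicit partitioned GRM, and tau updated by one
average-information REML step whose trace terms are estimated with
Rademacher probe vectors (Hutchinson).  Quantitative traits use the
two-component covariance sigma^2 I + tau * psi with both components
estimated.

The fitted object carries everything step two needs: fitted means,
working weights, tau, and the cached Sigma^{-1} X block enabling fast
applications of the REML projection
P = Sigma^{-1} - Sigma^{-1} X (X^T Sigma^{-1} X)^{-1} X^T Sigma^{-1}.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import cho_factor, cho_solve, qr
from scipy.special import expit
from scipy.stats import rankdata, norm

from .errors import ConvergenceError, DataError, DomainError
from .grm import GrmOperator, grm_matvec, sigma_matvec
from .solver import jacobi_preconditioner, pcg_solve


@dataclass
class NullModelConfig:
    tol_outer: float = 1e-4
    max_outer: int = 30
    n_probes: int = 30
    seed: int = 20240501
    pcg_tol: float = 1e-5
    pcg_max_iter: int = 1500
    tau_init: float = 0.1          # binary-trait initial variance component
    fix_tau: float | None = None   # pin tau (e.g. 0 to disable the GRM)
    estimate_dispersion: bool = False  # free working-scale dispersion (binary)
    inverse_normalize: bool = False  # rank-based INT for quantitative traits
    w_floor: float = 1e-8


@dataclass
class NullModelFit:
    trait_type: str
    tau_hat: float
    alpha_hat: np.ndarray
    mu_hat: np.ndarray
    b_hat: np.ndarray
    w: np.ndarray
    residuals: np.ndarray
    converged: bool
    outer_iterations: int
    trace_probes_seed: int
    sigma2_hat: float = 1.0        # residual variance (quantitative)
    dispersion: float = 1.0        # working-scale dispersion phi (binary)
    y: np.ndarray = field(default=None, repr=False)
    X: np.ndarray = field(default=None, repr=False)
    sample_ids: list[str] | None = None
    variance_ratio: float | None = None
    tau_trajectory: list[float] = field(default_factory=list)
    pcg_total_iterations: int = 0
    # projection cache
    _sigma_inv_X: np.ndarray = field(default=None, repr=False)
    _xtsix_cho: tuple = field(default=None, repr=False)
    _w_inv: np.ndarray = field(default=None, repr=False)
    _grm_diag: np.ndarray = field(default=None, repr=False)


def _check_design(X: np.ndarray) -> None:
    n, p = X.shape
    if p > n:
        raise DataError("more covariates than samples")
    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(n, p) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < p:
        bad = sorted(int(j) for j in piv[rank:])
        raise DataError(f"design matrix is rank deficient; dependent "
                        f"columns (0-based): {bad}")


def rank_inverse_normal(y: np.ndarray, offset: float = 0.5) -> np.ndarray:
    """Rank-based inverse-normal transform (Blom-type offset)."""
    r = rankdata(y)
    return norm.ppf((r - offset) / (len(y) - 2 * offset + 1))


class _SigmaSolver:
    """Caches the PCG context for a fixed (tau, w_inv) working covariance."""

    def __init__(self, grm_op: GrmOperator, tau: float, w_inv: np.ndarray,
                 grm_diag: np.ndarray, config: NullModelConfig):
        self.grm_op = grm_op
        self.tau = tau
        self.w_inv = w_inv
        self.config = config
        self.precond = jacobi_preconditioner(w_inv + tau * grm_diag)
        self.total_iterations = 0

    def apply(self, v: np.ndarray) -> np.ndarray:
        return sigma_matvec(self.grm_op, self.tau, self.w_inv, v)

    def solve(self, rhs: np.ndarray, x0: np.ndarray | None = None) -> np.ndarray:
        if self.tau == 0.0:
            return rhs / self.w_inv  # Sigma is diagonal
        res = pcg_solve(self.apply, rhs, preconditioner=self.precond,
                        tol=self.config.pcg_tol,
                        max_iter=self.config.pcg_max_iter, x0=x0)
        self.total_iterations += res.iterations
        if not res.converged:
            raise ConvergenceError(
                f"PCG failed to reach tol {self.config.pcg_tol} in "
                f"{self.config.pcg_max_iter} iterations "
                f"(residual {res.relative_residual:.3e})")
        return res.solution

    def solve_many(self, Rhs: np.ndarray,
                   X0: np.ndarray | None = None) -> np.ndarray:
        out = np.empty_like(Rhs)
        for j in range(Rhs.shape[1]):
            x0 = X0[:, j] if X0 is not None else None
            out[:, j] = self.solve(Rhs[:, j], x0=x0)
        return out


def _projection_apply(solver: _SigmaSolver, SiX: np.ndarray, xtsix_cho,
                      v: np.ndarray,
                      Siv: np.ndarray | None = None) -> np.ndarray:
    """P v = Sigma^{-1} v - Sigma^{-1}X (X^T Sigma^{-1} X)^{-1} X^T Sigma^{-1} v."""
    if Siv is None:
        Siv = solver.solve(v)
    return Siv - SiX @ cho_solve(xtsix_cho, SiX.T @ v)


def _rademacher_probes(n: int, k: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.choice((-1.0, 1.0), size=(n, k))


def _ai_terms(solver: _SigmaSolver, SiX: np.ndarray, xtsix_cho,
              Pz: np.ndarray, probes: np.ndarray,
              grm_op: GrmOperator, need_identity: bool):
    """Score/AI ingredients shared by the binary and quantitative updates.

    Returns (psi_Pz, P_psi_Pz, tr_P_psi_hat, tr_P_hat, PU) where trace
    estimates use the supplied probe block and tr_P_hat/PU are None unless
    ``need_identity``.
    """
    psi_Pz = grm_matvec(grm_op, Pz)
    P_psi_Pz = _projection_apply(solver, SiX, xtsix_cho, psi_Pz)
    k = probes.shape[1]
    SiU = solver.solve_many(probes)
    PU = SiU - SiX @ cho_solve(xtsix_cho, SiX.T @ probes)
    tr_p_psi = 0.0
    tr_p = 0.0
    for j in range(k):
        psi_u = grm_matvec(grm_op, probes[:, j])
        tr_p_psi += float(PU[:, j] @ psi_u)
        if need_identity:
            tr_p += float(PU[:, j] @ probes[:, j])
    tr_p_psi /= k
    tr_p = tr_p / k if need_identity else None
    return psi_Pz, P_psi_Pz, tr_p_psi, tr_p, PU


def _irls_logistic(y: np.ndarray, X: np.ndarray, tol: float = 1e-10,
                   max_iter: int = 60) -> np.ndarray:
    """Plain logistic regression by iteratively reweighted least squares."""
    alpha = np.zeros(X.shape[1])
    alpha[0] = np.log((y.mean() + 1e-6) / (1 - y.mean() + 1e-6))
    for _ in range(max_iter):
        eta = X @ alpha
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        WX = X * w[:, None]
        new = np.linalg.solve(X.T @ WX, WX.T @ z)
        if np.max(np.abs(new - alpha)) < tol:
            alpha = new
            break
        alpha = new
    return alpha


def fit_null(y: np.ndarray, X: np.ndarray, grm_op: GrmOperator,
             trait_type: str, config: NullModelConfig | None = None,
             sample_ids: list[str] | None = None) -> NullModelFit:
    """Fit the null mixed model; see the module docstring for the scheme."""
    config = config or NullModelConfig()
    y = np.asarray(y, dtype=np.float64)
    X = np.asarray(X, dtype=np.float64)
    if y.shape[0] != X.shape[0] or y.shape[0] != grm_op.n_samples:
        raise DataError("y, X and the GRM operator disagree on N")
    _check_design(X)
    if trait_type == "binary":
        if not np.all(np.isin(y, (0.0, 1.0))):
            raise DataError("binary trait must be coded 0/1")
        return _fit_binary(y, X, grm_op, config, sample_ids)
    if trait_type == "quantitative":
        if config.inverse_normalize:
            y = rank_inverse_normal(y)
        return _fit_quantitative(y, X, grm_op, config, sample_ids)
    raise DomainError(f"unknown trait_type {trait_type!r}")


def _fit_binary(y, X, grm_op, config, sample_ids) -> NullModelFit:
    """PQL with joint (phi, tau) AI-REML on the working model.

    The working covariance is Sigma = phi * W^{-1} + tau * psi with the
    working-scale dispersion phi fixed at 1 by default (the standard
    binary-GLMM convention).  ``config.estimate_dispersion=True`` frees phi
    (Breslow-Clayton quasi-likelihood), which removes much of PQL's
    downward bias in tau when the kinship is family-factor-only, but is
    unidentified -- and therefore unstable -- when psi carries an identity
    component and the working weights are near-constant (see the methods
    note).
    """
    n = len(y)
    grm_diag = grm_op.diagonal()
    probes = _rademacher_probes(n, config.n_probes, config.seed)
    alpha = _irls_logistic(y, X)
    eta = X @ alpha
    b = np.zeros(n)
    tau = config.tau_init if config.fix_tau is None else config.fix_tau
    phi = 1.0
    tau_traj = [tau]
    converged = False
    SiX = xtsix_cho = Siz = None
    total_pcg = 0
    outer = 0
    phi_floor = 0.05
    for outer in range(1, config.max_outer + 1):
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), config.w_floor, None)
        w_inv = 1.0 / w
        z = eta + (y - mu) / w
        solver = _SigmaSolver(grm_op, tau, phi * w_inv, grm_diag, config)
        SiX = solver.solve_many(X, X0=SiX)
        Siz = solver.solve(z, x0=Siz)
        xtsix_cho = cho_factor(X.T @ SiX)
        alpha_new = cho_solve(xtsix_cho, SiX.T @ z)
        Pz = Siz - SiX @ alpha_new  # = Sigma^{-1}(z - X alpha)
        b_new = tau * grm_matvec(grm_op, Pz) if tau > 0 else np.zeros(n)
        eta = X @ alpha_new + b_new

        d_alpha = float(np.max(np.abs(alpha_new - alpha)))
        alpha, b = alpha_new, b_new
        if config.fix_tau is not None and not config.estimate_dispersion:
            total_pcg += solver.total_iterations
            if d_alpha < config.tol_outer:
                converged = True
                break
            continue

        psi_Pz, P_psi_Pz, tr_p_psi, _, PU = _ai_terms(
            solver, SiX, xtsix_cho, Pz, probes, grm_op, need_identity=False)
        s_tau = 0.5 * (float(Pz @ psi_Pz) - tr_p_psi)
        if config.estimate_dispersion:
            v_phi = w_inv * Pz
            P_v_phi = _projection_apply(solver, SiX, xtsix_cho, v_phi)
            tr_p_phi = float(np.mean(np.einsum(
                "ij,ij->j", PU, w_inv[:, None] * probes)))
            s_phi = 0.5 * (float(Pz @ v_phi) - tr_p_phi)
            ai = 0.5 * np.array([
                [float(v_phi @ P_v_phi), float(v_phi @ P_psi_Pz)],
                [float(v_phi @ P_psi_Pz), float(psi_Pz @ P_psi_Pz)],
            ])
            scores = np.array([s_phi, s_tau])
            delta, *_ = np.linalg.lstsq(ai, scores, rcond=1e-10)
            if config.fix_tau is not None:
                delta[1] = 0.0
            phi_new, tau_new = phi + delta[0], tau + delta[1]
            halvings = 0
            while (phi_new < phi_floor or tau_new < 0.0) and halvings < 30:
                delta /= 2.0
                phi_new, tau_new = phi + delta[0], tau + delta[1]
                halvings += 1
            phi_new = max(phi_new, phi_floor)
            tau_new = max(tau_new, 0.0)
            if tau_new < 1e-6 and s_tau < 0.0:
                tau_new = 0.0
        else:
            ai_tt = 0.5 * float(psi_Pz @ P_psi_Pz)
            phi_new = phi
            tau_new = _damped_tau_update(tau, s_tau, ai_tt)
        total_pcg += solver.total_iterations
        d_theta = max(
            abs(tau_new - tau) / (tau + config.tol_outer),
            abs(phi_new - phi) / (phi + config.tol_outer),
        )
        tau_traj.append(tau_new)
        tau, phi = tau_new, phi_new
        if max(d_theta, d_alpha) < config.tol_outer:
            converged = True
            break

    # refresh the projection cache at the final (w, phi, tau)
    mu = expit(eta)
    w = np.clip(mu * (1 - mu), config.w_floor, None)
    solver = _SigmaSolver(grm_op, tau, phi / w, grm_diag, config)
    SiX = solver.solve_many(X, X0=SiX)
    xtsix_cho = cho_factor(X.T @ SiX)
    total_pcg += solver.total_iterations
    return NullModelFit(
        trait_type="binary", tau_hat=tau, alpha_hat=alpha, mu_hat=mu,
        b_hat=b, w=w, residuals=y - mu, converged=converged,
        outer_iterations=outer, trace_probes_seed=config.seed,
        sigma2_hat=1.0, dispersion=phi, y=y, X=X, sample_ids=sample_ids,
        tau_trajectory=tau_traj, pcg_total_iterations=total_pcg,
        _sigma_inv_X=SiX, _xtsix_cho=xtsix_cho, _w_inv=phi / w,
        _grm_diag=grm_diag,
    )


def _damped_tau_update(tau: float, score: float, ai: float) -> float:
    if not np.isfinite(ai) or ai <= 0:
        step = np.sign(score) * 0.1 * max(tau, 0.1)
    else:
        step = score / ai
    if tau == 0.0 and score <= 0.0:
        return 0.0
    tau_new = tau + step
    halvings = 0
    while tau_new < 0.0 and halvings < 30:
        step /= 2.0
        tau_new = tau + step
        halvings += 1
    if tau_new < 0.0 or (tau_new < 1e-6 and score < 0.0):
        return 0.0
    return tau_new


def _fit_quantitative(y, X, grm_op, config, sample_ids) -> NullModelFit:
    n = len(y)
    grm_diag = grm_op.diagonal()
    probes = _rademacher_probes(n, config.n_probes, config.seed)
    var_y = float(np.var(y, ddof=1))
    sigma2 = var_y / 2.0
    tau = var_y / 2.0 if config.fix_tau is None else config.fix_tau
    floor = 1e-8 * var_y
    tau_traj = [tau]
    converged = False
    alpha = np.zeros(X.shape[1])
    SiX = Siz = xtsix_cho = None
    total_pcg = 0
    outer = 0
    for outer in range(1, config.max_outer + 1):
        w_inv = np.full(n, sigma2)
        solver = _SigmaSolver(grm_op, tau, w_inv, grm_diag, config)
        SiX = solver.solve_many(X, X0=SiX)
        Siz = solver.solve(y, x0=Siz)
        xtsix_cho = cho_factor(X.T @ SiX)
        alpha_new = cho_solve(xtsix_cho, SiX.T @ y)
        Pz = Siz - SiX @ alpha_new
        d_alpha = float(np.max(np.abs(alpha_new - alpha)))
        alpha = alpha_new

        psi_Pz, P_psi_Pz, tr_p_psi, tr_p, PU = _ai_terms(
            solver, SiX, xtsix_cho, Pz, probes, grm_op, need_identity=True)
        P_Pz = _projection_apply(solver, SiX, xtsix_cho, Pz)
        s_sigma = 0.5 * (float(Pz @ Pz) - tr_p)
        s_tau = 0.5 * (float(Pz @ psi_Pz) - tr_p_psi)
        ai = 0.5 * np.array([
            [float(Pz @ P_Pz), float(Pz @ P_psi_Pz)],
            [float(Pz @ P_psi_Pz), float(psi_Pz @ P_psi_Pz)],
        ])
        scores = np.array([s_sigma, s_tau])
        delta, *_ = np.linalg.lstsq(ai, scores, rcond=1e-10)
        if config.fix_tau is not None:
            delta[1] = 0.0
        sigma2_new, tau_new = sigma2 + delta[0], tau + delta[1]
        halvings = 0
        while (sigma2_new < floor or tau_new < 0.0) and halvings < 30:
            delta /= 2.0
            sigma2_new, tau_new = sigma2 + delta[0], tau + delta[1]
            halvings += 1
        sigma2_new = max(sigma2_new, floor)
        tau_new = max(tau_new, 0.0)
        total_pcg += solver.total_iterations
        d_theta = max(abs(sigma2_new - sigma2) / (sigma2 + config.tol_outer),
                      abs(tau_new - tau) / (tau + config.tol_outer))
        sigma2, tau = sigma2_new, tau_new
        tau_traj.append(tau)
        if max(d_theta, d_alpha / max(1.0, np.max(np.abs(alpha)))) \
                < config.tol_outer:
            converged = True
            break

    # final coefficient/projection refresh at the converged (sigma2, tau)
    w_inv = np.full(n, sigma2)
    solver = _SigmaSolver(grm_op, tau, w_inv, grm_diag, config)
    SiX = solver.solve_many(X, X0=SiX)
    xtsix_cho = cho_factor(X.T @ SiX)
    alpha = cho_solve(xtsix_cho, SiX.T @ y)
    Pz = solver.solve(y, x0=Siz) - SiX @ alpha
    b = tau * grm_matvec(grm_op, Pz) if tau > 0 else np.zeros(n)
    mu = X @ alpha + b
    total_pcg += solver.total_iterations
    w = np.full(n, 1.0 / sigma2)
    return NullModelFit(
        trait_type="quantitative", tau_hat=tau, alpha_hat=alpha, mu_hat=mu,
        b_hat=b, w=w, residuals=y - mu, converged=converged,
        outer_iterations=outer, trace_probes_seed=config.seed,
        sigma2_hat=sigma2, y=y, X=X, sample_ids=sample_ids,
        tau_trajectory=tau_traj, pcg_total_iterations=total_pcg,
        _sigma_inv_X=SiX, _xtsix_cho=xtsix_cho, _w_inv=w_inv,
        _grm_diag=grm_diag,
    )


def estimate_tau_ai_step(current_fit: NullModelFit, grm_op: GrmOperator,
                         n_probes: int, seed: int,
                         config: NullModelConfig | None = None) -> float:
    """One average-information REML update of tau from a fitted state.

    Deterministic given the seed; the trace terms use ``n_probes``
    Rademacher probes and the update is damped to keep tau >= 0.
    """
    if n_probes < 1:
        raise DomainError("n_probes must be >= 1")
    config = config or NullModelConfig()
    fit = current_fit
    n = len(fit.mu_hat)
    tau = fit.tau_hat
    if fit.trait_type == "binary":
        w_inv = fit.dispersion / fit.w
        z = (fit.X @ fit.alpha_hat + fit.b_hat
             + (fit.y - fit.mu_hat) / fit.w)
    else:
        w_inv = np.full(n, fit.sigma2_hat)
        z = fit.y
    grm_diag = grm_op.diagonal()
    solver = _SigmaSolver(grm_op, tau, w_inv, grm_diag, config)
    SiX = solver.solve_many(fit.X)
    xtsix_cho = cho_factor(fit.X.T @ SiX)
    Siz = solver.solve(z)
    Pz = Siz - SiX @ cho_solve(xtsix_cho, SiX.T @ z)
    probes = _rademacher_probes(n, n_probes, seed)
    psi_Pz, P_psi_Pz, tr_p_psi, _, _ = _ai_terms(
        solver, SiX, xtsix_cho, Pz, probes, grm_op, need_identity=False)
    score = 0.5 * (float(Pz @ psi_Pz) - tr_p_psi)
    ai = 0.5 * float(psi_Pz @ P_psi_Pz)
    if not np.isfinite(ai):
        raise ConvergenceError("non-finite average-information term")
    return _damped_tau_update(tau, score, ai)


def apply_projection_P(fit: NullModelFit, grm_op: GrmOperator,
                       v: np.ndarray,
                       config: NullModelConfig | None = None) -> np.ndarray:
    """Apply the REML projection P at the fitted (tau, W) to a vector."""
    if not fit.converged:
        raise ConvergenceError("projection requires a converged fit")
    config = config or NullModelConfig()
    solver = _SigmaSolver(grm_op, fit.tau_hat, fit._w_inv, fit._grm_diag,
                          config)
    return _projection_apply(solver, fit._sigma_inv_X, fit._xtsix_cho, v)


# ---------------------------------------------------------------------------
# artifact serialization: JSON scalars + npz vector sidecar

def save_fit(fit: NullModelFit, prefix) -> tuple[Path, Path]:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "trait_type": fit.trait_type,
        "tau_hat": fit.tau_hat,
        "sigma2_hat": fit.sigma2_hat,
        "dispersion": fit.dispersion,
        "converged": fit.converged,
        "outer_iterations": fit.outer_iterations,
        "trace_probes_seed": fit.trace_probes_seed,
        "variance_ratio": fit.variance_ratio,
        "tau_trajectory": fit.tau_trajectory,
        "pcg_total_iterations": fit.pcg_total_iterations,
        "sample_ids": fit.sample_ids,
    }
    json_path = prefix.with_suffix(".json")
    npz_path = prefix.with_suffix(".npz")
    json_path.write_text(json.dumps(meta, indent=1))
    cho_mat, lower = fit._xtsix_cho
    np.savez(npz_path, alpha_hat=fit.alpha_hat, mu_hat=fit.mu_hat,
             b_hat=fit.b_hat, w=fit.w, residuals=fit.residuals, y=fit.y,
             X=fit.X, sigma_inv_X=fit._sigma_inv_X, xtsix_cho=cho_mat,
             xtsix_lower=np.array(lower), w_inv=fit._w_inv,
             grm_diag=fit._grm_diag)
    return json_path, npz_path


def load_fit(prefix) -> NullModelFit:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    arr = np.load(prefix.with_suffix(".npz"))
    return NullModelFit(
        trait_type=meta["trait_type"], tau_hat=meta["tau_hat"],
        alpha_hat=arr["alpha_hat"], mu_hat=arr["mu_hat"],
        b_hat=arr["b_hat"], w=arr["w"], residuals=arr["residuals"],
        converged=meta["converged"],
        outer_iterations=meta["outer_iterations"],
        trace_probes_seed=meta["trace_probes_seed"],
        sigma2_hat=meta["sigma2_hat"],
        dispersion=meta.get("dispersion", 1.0), y=arr["y"], X=arr["X"],
        sample_ids=meta["sample_ids"],
        variance_ratio=meta["variance_ratio"],
        tau_trajectory=meta["tau_trajectory"],
        pcg_total_iterations=meta["pcg_total_iterations"],
        _sigma_inv_X=arr["sigma_inv_X"],
        _xtsix_cho=(arr["xtsix_cho"], bool(arr["xtsix_lower"])),
        _w_inv=arr["w_inv"], _grm_diag=arr["grm_diag"],
    )
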