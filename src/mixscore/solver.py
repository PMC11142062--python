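"""Preconditioned conjugate gradient for implicit SPD operators.

The null-model fitter solves Sigma x = b where Sigma = W^{-1} + tau*psi is
only available as an operator-vector product.  The loop below is the
textbook PCG recursion with one operator application per iteration; the
true residual is recomputed from scratch every ``recompute_every``
iterations to guard against recursion drift.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import DomainError, NumericalBreakdownError

Operator = Callable[[np.ndarray], np.ndarray]


@dataclass
class PcgResult:
    solution: np.ndarray
    iterations: int
    relative_residual: float
    converged: bool
    residual_history: list[float] = field(default_factory=list)


def jacobi_preconditioner(diagonal_estimate: np.ndarray) -> Operator:
    """Elementwise division by a positive diagonal estimate."""
    d = np.asarray(diagonal_estimate, dtype=np.float64)
    if np.any(d <= 0) or not np.all(np.isfinite(d)):
        raise DomainError("preconditioner diagonal must be positive and finite")
    return lambda r: r / d


def pcg_solve(apply_operator: Operator, b: np.ndarray,
              preconditioner: Operator | None = None,
              tol: float = 1e-5, max_iter: int = 1500,
              x0: np.ndarray | None = None,
              recompute_every: int = 50) -> PcgResult:
    """Solve A x = b for an SPD operator; converged when ||b - A x|| <= tol ||b||."""
    if tol <= 0:
        raise DomainError("tol must be > 0")
    b = np.asarray(b, dtype=np.float64)
    if not np.all(np.isfinite(b)):
        raise DomainError("right-hand side contains non-finite values")
    b_norm = float(np.linalg.norm(b))
    if b_norm == 0.0:
        return PcgResult(solution=np.zeros_like(b), iterations=0,
                         relative_residual=0.0, converged=True)
    if x0 is None:
        x = np.zeros_like(b)
        r = b.copy()
    else:
        x = np.array(x0, dtype=np.float64, copy=True)
        r = b - apply_operator(x)
    precond = preconditioner if preconditioner is not None else (lambda v: v)
    z = precond(r)
    p = z.copy()
    rz = float(r @ z)
    history: list[float] = []
    res = float(np.linalg.norm(r)) / b_norm
    for k in range(1, max_iter + 1):
        Ap = apply_operator(p)
        pAp = float(p @ Ap)
        if not np.isfinite(pAp) or pAp <= 0.0:
            raise NumericalBreakdownError(
                f"PCG breakdown at iteration {k}: p^T A p = {pAp}")
        alpha = rz / pAp
        x += alpha * p
        r -= alpha * Ap
        if k % recompute_every == 0:
            r = b - apply_operator(x)
        res = float(np.linalg.norm(r)) / b_norm
        if not np.isfinite(res):
            raise NumericalBreakdownError(f"non-finite residual at iteration {k}")
        history.append(res)
        if res <= tol:
            return PcgResult(solution=x, iterations=k, relative_residual=res,
                             converged=True, residual_history=history)
        z = precond(r)
        rz_new = float(r @ z)
        beta = rz_new / rz
        p = z + beta * p
        rz = rz_new
    return PcgResult(solution=x, iterations=max_iter, relative_residual=res,
                     converged=False, residual_history=history)
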