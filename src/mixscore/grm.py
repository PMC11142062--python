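"""Implicit genetic relationship matrix (GRM) as column partitions.

The GRM psi = (1/M) A A^T over the N x M standardized genotype matrix A is
never materialized: it is held as an ordered list of column partitions
A[:, s_i:e_i] and applied to vectors partition by partition,

    psi v = (1/M) * sum_i  A[:, s_i:e_i] ( A[:, s_i:e_i]^T v ),

two matrix-vector products per partition with the partial results summed.
The result is independent of the partitioning.  Partition buffers are kept
in single precision by default (4-byte accounting, matching how device
memory budgets are planned) with the accumulation in double precision; a
full-double mode exists for oracle tests.

A dense oracle (`build_explicit_grm`) is provided for small N.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DimensionError, DomainError
from .genotype_io import StandardizedBlock

BYTES_PER_VALUE = 4  # single-precision accounting used for partition budgets


def partition_plan(n_markers: int, n_samples: int,
                   max_bytes_per_partition: int,
                   n_partitions: int | None = None) -> list[tuple[int, int]]:
    """Column ranges [(s_i, e_i), ...] for a byte budget per partition.

    The budget rule: at most floor(max_bytes / (4 N)) columns per partition,
    with columns spread as evenly as the resulting partition count allows.
    An explicit ``n_partitions`` overrides the count (still checked against
    the budget), reproducing e.g. an even 16-way split of 132,096 columns
    into 8,256-column device buffers.
    """
    if n_markers < 1 or n_samples < 1:
        raise DomainError("n_markers and n_samples must be >= 1")
    max_cols = max_bytes_per_partition // (BYTES_PER_VALUE * n_samples)
    if max_cols < 1:
        raise ConfigurationError(
            f"partition budget {max_bytes_per_partition} B holds no column of "
            f"{BYTES_PER_VALUE * n_samples} B")
    if n_partitions is None:
        n_partitions = -(-n_markers // max_cols)
    cols_per = -(-n_markers // n_partitions)
    if cols_per > max_cols:
        raise ConfigurationError(
            f"{n_partitions} partitions need {cols_per} columns each, "
            f"budget allows {max_cols}")
    bounds = []
    start = 0
    while start < n_markers:
        end = min(start + cols_per, n_markers)
        bounds.append((start, end))
        start = end
    return bounds


@dataclass
class GrmOperator:
    """psi = (1/M) A A^T assembled from disjoint column partitions of A."""

    partitions: list[StandardizedBlock]
    n_samples: int
    n_markers: int
    scale: bool = True  # apply the 1/M multiplier
    precision: str = "single"  # "single" | "double"
    _buffers: list[np.ndarray] = field(default_factory=list, repr=False)

    def __post_init__(self):
        covered = 0
        for part in self.partitions:
            if part.n_samples != self.n_samples:
                raise DimensionError("partition row count != n_samples")
            if part.start_index != covered:
                raise DimensionError("partitions must cover [0, M) disjointly "
                                     "and in order")
            covered = part.end_index
        if covered != self.n_markers:
            raise DimensionError(f"partitions cover [0, {covered}), expected "
                                 f"[0, {self.n_markers})")
        if self.n_markers < 1:
            raise DomainError("n_markers must be >= 1")
        dtype = np.float32 if self.precision == "single" else np.float64
        self._buffers = [np.ascontiguousarray(p.values, dtype=dtype)
                         for p in self.partitions]

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_matrix(cls, A: np.ndarray, max_bytes_per_partition: int | None = None,
                    n_partitions: int | None = None, scale: bool = True,
                    precision: str = "single") -> "GrmOperator":
        """Build the operator from an in-memory standardized matrix."""
        A = np.asarray(A, dtype=np.float64)
        n, m = A.shape
        if max_bytes_per_partition is None and n_partitions is None:
            bounds = [(0, m)]
        else:
            budget = (max_bytes_per_partition if max_bytes_per_partition
                      is not None else BYTES_PER_VALUE * n * m)
            bounds = partition_plan(m, n, budget, n_partitions=n_partitions)
        parts = [StandardizedBlock(values=A[:, s:e], start_index=s, end_index=e)
                 for s, e in bounds]
        return cls(partitions=parts, n_samples=n, n_markers=m, scale=scale,
                   precision=precision)

    @classmethod
    def from_factor(cls, L: np.ndarray, precision: str = "double") -> "GrmOperator":
        """Operator with psi = L L^T exactly (no 1/M scaling).

        Used to represent a known dense kinship through its Cholesky factor,
        e.g. in parameter-recovery experiments.
        """
        L = np.asarray(L, dtype=np.float64)
        part = StandardizedBlock(values=L, start_index=0, end_index=L.shape[1])
        return cls(partitions=[part], n_samples=L.shape[0],
                   n_markers=L.shape[1], scale=False, precision=precision)

    # -- products --------------------------------------------------------
    def matvec(self, v: np.ndarray) -> np.ndarray:
        """(1/M) sum_i A_i (A_i^T v), evaluated per partition."""
        v = np.asarray(v, dtype=np.float64)
        if v.shape != (self.n_samples,):
            raise DimensionError(f"vector length {v.shape} != ({self.n_samples},)")
        acc = np.zeros(self.n_samples, dtype=np.float64)
        for buf in self._buffers:
            if buf.dtype == np.float32:
                v32 = v.astype(np.float32)
                y = buf.T @ v32
                acc += (buf @ y).astype(np.float64)
            else:
                acc += buf @ (buf.T @ v)
        if self.scale:
            acc /= self.n_markers
        return acc

    def diagonal(self) -> np.ndarray:
        """Exact diag(psi) as per-partition row sums of squares (over M)."""
        d = np.zeros(self.n_samples, dtype=np.float64)
        for buf in self._buffers:
            d += np.square(buf, dtype=np.float64).sum(axis=1)
        if self.scale:
            d /= self.n_markers
        return d


def partition_columns(block_source, max_bytes_per_partition: int,
                      scale: bool = True, precision: str = "single",
                      n_partitions: int | None = None) -> GrmOperator:
    """Partition the columns of a standardized matrix into a GrmOperator.

    ``block_source`` is a StandardizedBlock or an N x M array holding the
    full standardized step-one genotype matrix.
    """
    A = (block_source.values if isinstance(block_source, StandardizedBlock)
         else np.asarray(block_source))
    return GrmOperator.from_matrix(A, max_bytes_per_partition=max_bytes_per_partition,
                                   n_partitions=n_partitions, scale=scale,
                                   precision=precision)


def grm_matvec(op: GrmOperator, v: np.ndarray) -> np.ndarray:
    """psi v through the partitioned two-step products."""
    return op.matvec(v)


def sigma_matvec(op: GrmOperator, tau: float, w_inv: np.ndarray,
                 v: np.ndarray) -> np.ndarray:
    """Apply Sigma = W^{-1} + tau * psi, the null-model working covariance."""
    if tau < 0:
        raise DomainError("tau must be >= 0")
    w_inv = np.asarray(w_inv, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if np.any(w_inv <= 0):
        raise DomainError("w_inv entries must be > 0")
    out = w_inv * v
    if tau > 0:
        out = out + tau * op.matvec(v)
    return out


def build_explicit_grm(op: GrmOperator, oracle_cap: int = 2000) -> np.ndarray:
    """Dense psi for small N; refuses above ``oracle_cap`` (oracle-only)."""
    if op.n_samples > oracle_cap:
        raise ConfigurationError(
            f"explicit GRM refused for N={op.n_samples} > cap {oracle_cap}")
    G = np.zeros((op.n_samples, op.n_samples), dtype=np.float64)
    for part in op.partitions:
        A = np.asarray(part.values, dtype=np.float64)
        G += A @ A.T
    if op.scale:
        G /= op.n_markers
    return (G + G.T) / 2.0
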