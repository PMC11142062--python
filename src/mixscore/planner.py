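"""Resource-planning arithmetic and deterministic variant sharding.

Device-count planning assumes the standardized genotype matrix is held in
single precision (4 bytes per value) and decimal gigabytes (10^9 bytes):

    n_gpu = ceil(4 * M * N / (gpu_mem_gb * 10^9))

Sharding partitions a variant index into contiguous, order-preserving
pieces whose sizes differ by at most one, so that per-shard association
jobs can run independently and merge back to the unsharded result.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .errors import DomainError

GB = 10**9
BYTES_PER_VALUE = 4


@dataclass
class ResourcePlan:
    n_gpu: int
    bytes_total: int
    gpu_mem_gb: float
    m_markers: int
    n_samples: int


def plan_gpus(m_markers: int, n_samples: int, gpu_mem_gb: float) -> ResourcePlan:
    """Number of devices needed to hold the 4-byte N x M genotype matrix."""
    if m_markers < 1 or n_samples < 1 or gpu_mem_gb <= 0:
        raise DomainError("m_markers, n_samples must be >= 1 and gpu_mem_gb > 0")
    bytes_total = BYTES_PER_VALUE * m_markers * n_samples
    n_gpu = max(1, math.ceil(bytes_total / (gpu_mem_gb * GB)))
    return ResourcePlan(n_gpu=n_gpu, bytes_total=bytes_total,
                        gpu_mem_gb=gpu_mem_gb, m_markers=m_markers,
                        n_samples=n_samples)


def grm_memory_gb(n_samples: int, bytes_per_value: int = 4) -> float:
    """Footprint of a dense N x N GRM in decimal gigabytes."""
    if n_samples < 1:
        raise DomainError("n_samples must be >= 1")
    if bytes_per_value not in (4, 8):
        raise DomainError("bytes_per_value must be 4 or 8")
    return n_samples**2 * bytes_per_value / GB


def shard_variants(variant_index: Sequence, n_shards: int) -> list[list]:
    """Contiguous shards with sizes differing by at most 1; concatenation of
    the shards reproduces the input exactly.  Empty shards (n_shards beyond
    the variant count) are dropped."""
    if n_shards < 1:
        raise DomainError("n_shards must be >= 1")
    items = list(variant_index)
    n = len(items)
    base, extra = divmod(n, n_shards)
    shards = []
    start = 0
    for i in range(n_shards):
        size = base + (1 if i < extra else 0)
        if size == 0:
            continue
        shards.append(items[start:start + size])
        start += size
    return shards
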