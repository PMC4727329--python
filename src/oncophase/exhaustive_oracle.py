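"""Brute-force ground truth for tiny progression instances.

Enumerates every ordered surjective partition of the n mutation genes onto K
phases (there are K! * S(n,K) of them, S the Stirling number of the second
kind), computes each partition's exact objective by direct per-sample
enumeration of prefix lengths, and returns the global optimum. Exists purely
to certify the MILP on instances small enough for full enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Mapping

import numpy as np

from ._solver import MilpBuilder
from .exceptions import ContractError
from .matrix_io import MutationMatrix
from .preprocess import ConnectivityMatrix

__all__ = ["OracleResult", "enumerate_optimum", "min_flips_milp_fixed_partition"]

_MAX_N = 8
_MAX_K = 4


@dataclass
class OracleResult:
    best_objective: float
    best_partitions: list[dict[str, int]]
    n_partitions_searched: int


def _flips_for_assignment(counts: np.ndarray, K: int) -> int:
    """Exact minimal flips by enumerating prefix length L per sample."""
    total = 0
    for row in counts:
        best = None
        for L in range(K + 1):
            cost = 0.0
            for k in range(K):
                if k < L:
                    cost += row[k] - 1 if row[k] >= 1 else 1
                else:
                    cost += row[k]
            if best is None or cost < best:
                best = cost
        total += best
    return int(round(total))


def enumerate_optimum(
    M: MutationMatrix,
    C: ConnectivityMatrix,
    K: int,
    W: float = 0.5,
) -> OracleResult:
    """Global optimum of the progression objective by exhaustive search.

    Refuses instances beyond n=8 genes or K=4 phases; the search space is
    K^n assignments.
    """
    n = M.n_genes
    if n > _MAX_N or K > _MAX_K:
        raise ContractError(
            f"exhaustive search is guarded to n <= {_MAX_N}, K <= {_MAX_K} "
            f"(got n={n}, K={K})"
        )
    if K > n:
        raise ContractError(f"no surjective partition of {n} genes onto {K} phases")
    m, r = M.n_samples, C.n_expr_genes
    # sum_k pE_hk collapses to the row sum of C for every partition, so the
    # expression term is a partition-independent constant.
    term2 = W / (K * r) * C.values.sum()
    w1 = (1.0 - W) / (m * n)

    best_obj: float | None = None
    best: list[dict[str, int]] = []
    searched = 0
    Mv = M.values
    for assign in product(range(K), repeat=n):
        if len(set(assign)) != K:
            continue
        searched += 1
        indicator = np.zeros((n, K))
        for j, k in enumerate(assign):
            indicator[j, k] = 1.0
        counts = Mv @ indicator
        flips = _flips_for_assignment(counts, K)
        obj = w1 * flips - term2
        if best_obj is None or obj < best_obj - 1e-12:
            best_obj = obj
            best = [{g: k + 1 for g, k in zip(M.gene_ids, assign)}]
        elif abs(obj - best_obj) <= 1e-12:
            best.append({g: k + 1 for g, k in zip(M.gene_ids, assign)})
    return OracleResult(best_objective=best_obj, best_partitions=best, n_partitions_searched=searched)


def min_flips_milp_fixed_partition(
    M: MutationMatrix, partition: Mapping[str, int], K: int
) -> int:
    """Minimal flips for a fixed partition, by direct MILP over the a/f
    variables (progression + support constraints only).

    Serves as the independent check of the closed-form prefix minimization in
    ``flip_cost_given_partition``.
    """
    m, n = M.n_samples, M.n_genes
    indicator = np.zeros((n, K))
    for j, g in enumerate(M.gene_ids):
        indicator[j, partition[g] - 1] = 1.0
    if not (indicator.sum(axis=0) >= 1).all():
        raise ContractError("partition leaves an empty phase")
    counts = M.values @ indicator  # (m, K)

    b = MilpBuilder()
    idx_a = np.array([[b.add_binary() for _ in range(K)] for _ in range(m)])
    idx_f = np.array([[b.add_binary() for _ in range(K)] for _ in range(m)])
    obj: dict[int, float] = {}
    for i in range(m):
        for k in range(K):
            obj[idx_a[i, k]] = -1.0
            obj[idx_f[i, k]] = 2.0
    b.set_objective(obj)
    for i in range(m):
        for k in range(K - 1):
            b.add_constraint({idx_a[i, k]: 1.0, idx_a[i, k + 1]: -1.0}, 0.0, np.inf)
        for k in range(K):
            b.add_constraint({idx_a[i, k]: -1.0, idx_f[i, k]: 1.0}, -counts[i, k], np.inf)
    res = b.solve(mip_gap=1e-9)
    return int(round(res.objective + counts.sum()))
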