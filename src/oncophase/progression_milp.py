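"""The cancer-progression mixed integer linear program.

The model jointly partitions n mutation genes into K ordered phases and
soft-assigns r expression genes to those phases, from an m-sample
cross-sectional cohort. Decision variables:

- ``p^M[j,k]`` (binary): mutation gene j belongs to phase k;
- ``a[i,k]`` (binary): sample i is considered mutated in phase k after
  corrections; rows are prefixes (a phase can only be active if all earlier
  phases are);
- ``f[i,k]`` (binary): a 0->1 flip is needed to make phase k active in
  sample i;
- ``p^E[h,k]`` (continuous in [0,1]): the probability mass of expression
  gene h on phase k, fixed by the connectivity matrix through
  ``p^E[h,k] = sum_j C[h,j] p^M[j,k]``.

The objective trades off, with weights (1-W, W), the number of corrections
("flips") needed to make the mutation matrix satisfy per-phase exclusivity
and cross-phase progression, against the total expression mass captured:

    min  (1-W)/(m n) * sum_{i,k} ( sum_j M[i,j] p^M[j,k] - a[i,k] + 2 f[i,k] )
         - W/(K r) * sum_{h,k} p^E[h,k]

subject to: each mutation gene in exactly one phase; each phase nonempty;
a-rows non-increasing in k; a[i,k] <= f[i,k] + sum_j M[i,j] p^M[j,k]; and the
p^E coupling above. Two further printed inequalities (nonnegativity of the
p^E sums per gene and per phase) are kept for fidelity even though they are
implied by nonnegative C.

Note a structural property of this formulation: summing the coupling
constraint over k gives sum_k p^E[h,k] = sum_j C[h,j] for every feasible
solution, so the expression term is a constant once C is fixed (equal to
W/K per fully-normalized row). The expression data therefore shapes the
*assignment* of expression genes to phases, not the choice of mutation
partition. The solution object reports both objective terms separately so
this is visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._solver import MilpBuilder, SolveResult
from .exceptions import ContractError, DomainError
from .matrix_io import MutationMatrix
from .preprocess import ConnectivityMatrix

__all__ = [
    "MilpConfig",
    "ProgressionModel",
    "ProgressionSolution",
    "ValidationReport",
    "build_model",
    "solve",
    "flip_cost_given_partition",
    "assign_expression",
    "validate_solution",
    "k_selection_diagnostic",
]


@dataclass
class MilpConfig:
    """Solve-time configuration.

    K is the externally chosen number of phases; W in [0,1] weights the
    expression term (1-W goes to the flip term). ``seed`` is recorded for
    provenance; the HiGHS solve itself is deterministic.
    """

    K: int
    W: float = 0.5
    solver: str = "highs"
    mip_gap: float = 1e-9
    time_limit: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise DomainError(f"K must be >= 1, got {self.K}")
        if not (0.0 <= self.W <= 1.0):
            raise DomainError(f"W must lie in [0, 1], got {self.W}")


@dataclass
class ProgressionModel:
    """A built (unsolved) model plus the index bookkeeping to read it back."""

    builder: MilpBuilder
    M: MutationMatrix
    C: ConnectivityMatrix
    cfg: MilpConfig
    idx_p: np.ndarray  # (n, K) variable indices
    idx_a: np.ndarray  # (m, K)
    idx_f: np.ndarray  # (m, K)
    idx_pE: np.ndarray  # (r, K)

    @property
    def variable_counts(self) -> dict[str, int]:
        return {
            "binary": self.builder.n_binary,
            "continuous": self.builder.n_continuous,
        }

    @property
    def constraint_counts(self) -> dict[str, int]:
        return dict(self.builder.constraint_families)


@dataclass
class ProgressionSolution:
    """A solved phase structure with flip diagnostics and objective breakdown."""

    phase_of_mut_gene: dict[str, int]  # 1-based phase index
    p_E: np.ndarray  # (r, K)
    phase_of_expr_gene: dict[str, int | None]
    a: np.ndarray  # (m, K) binary
    f: np.ndarray  # (m, K) binary
    per_sample_prefix: list[int]
    flip_count: int
    objective_value: float
    term1: float
    term2: float
    config: MilpConfig
    sample_ids: tuple[str, ...]
    mut_gene_ids: tuple[str, ...]
    expr_gene_ids: tuple[str, ...]
    solver_status: str = "optimal"
    solver_gap: float | None = None
    solver_seconds: float = 0.0
    connectivity_normalized: bool = True

    @property
    def K(self) -> int:
        return self.config.K

    def mutation_phases(self) -> list[list[str]]:
        """Mutation genes per phase, 0-indexed list of length K."""
        out: list[list[str]] = [[] for _ in range(self.K)]
        for g in self.mut_gene_ids:
            out[self.phase_of_mut_gene[g] - 1].append(g)
        return out

    def expression_phases(self) -> list[list[str]]:
        out: list[list[str]] = [[] for _ in range(self.K)]
        for g in self.expr_gene_ids:
            k = self.phase_of_expr_gene[g]
            if k is not None:
                out[k - 1].append(g)
        return out

    def unassigned_expr_genes(self) -> list[str]:
        return [g for g in self.expr_gene_ids if self.phase_of_expr_gene[g] is None]

    def to_dict(self) -> dict:
        mut_phases = self.mutation_phases()
        expr_phases = self.expression_phases()
        return {
            "config": {
                "K": self.config.K,
                "W": self.config.W,
                "solver": self.config.solver,
                "mip_gap": self.config.mip_gap,
                "time_limit": self.config.time_limit,
                "seed": self.config.seed,
                "connectivity_normalized": self.connectivity_normalized,
            },
            "phases": [
                {
                    "phase": k + 1,
                    "mutation_genes": mut_phases[k],
                    "expression_genes": expr_phases[k],
                }
                for k in range(self.K)
            ],
            "unassigned_expression_genes": self.unassigned_expr_genes(),
            "p_E": self.p_E.tolist(),
            "flips": {
                "total": int(self.flip_count),
                "per_sample_prefix": [int(x) for x in self.per_sample_prefix],
            },
            "objective": {
                "value": self.objective_value,
                "term1": self.term1,
                "term2": self.term2,
            },
            "solver": {
                "status": self.solver_status,
                "gap": self.solver_gap,
                "seconds": self.solver_seconds,
            },
        }


def build_model(
    M: MutationMatrix, C: ConnectivityMatrix, cfg: MilpConfig
) -> ProgressionModel:
    """Assemble the MILP for a cohort.

    Variable layout: n*K binary phase indicators, m*K binary activity, m*K
    binary flip indicators, r*K continuous expression probabilities.
    """
    if C.mut_gene_ids != M.gene_ids:
        raise ContractError(
            "connectivity columns must match the mutation matrix's gene labels"
        )
    m, n = M.n_samples, M.n_genes
    r, K, W = C.n_expr_genes, cfg.K, cfg.W
    if K > n:
        raise ContractError(
            f"K={K} phases cannot all be nonempty with only n={n} mutation "
            "genes (each gene belongs to exactly one phase)"
        )

    b = MilpBuilder()
    idx_p = np.array([[b.add_binary() for _ in range(K)] for _ in range(n)])
    idx_a = np.array([[b.add_binary() for _ in range(K)] for _ in range(m)])
    idx_f = np.array([[b.add_binary() for _ in range(K)] for _ in range(m)])
    idx_pE = np.array(
        [[b.add_continuous(0.0, 1.0) for _ in range(K)] for _ in range(r)]
    )

    Mv = M.values.astype(float)
    col_sums = Mv.sum(axis=0)  # sum_i M[i,j]

    # objective: (1-W)/(mn) [ sum_j colsum_j * sum_k p_jk - sum a + 2 sum f ]
    #            - W/(Kr) sum pE
    obj: dict[int, float] = {}
    w1 = (1.0 - W) / (m * n)
    w2 = W / (K * r)
    for j in range(n):
        for k in range(K):
            obj[idx_p[j, k]] = w1 * col_sums[j]
    for i in range(m):
        for k in range(K):
            obj[idx_a[i, k]] = -w1
            obj[idx_f[i, k]] = 2.0 * w1
    for h in range(r):
        for k in range(K):
            obj[idx_pE[h, k]] = -w2
    b.set_objective(obj)

    # C1: each mutation gene in exactly one phase
    for j in range(n):
        b.add_constraint({idx_p[j, k]: 1.0 for k in range(K)}, 1.0, 1.0, family="C1")
    # C2: sum_k pE_hk >= 0 (printed; implied by variable bounds)
    for h in range(r):
        b.add_constraint({idx_pE[h, k]: 1.0 for k in range(K)}, 0.0, np.inf, family="C2")
    # C3: each phase holds at least one mutation gene
    for k in range(K):
        b.add_constraint({idx_p[j, k]: 1.0 for j in range(n)}, 1.0, np.inf, family="C3")
    # C4: sum_h pE_hk >= 0 (printed; implied)
    for k in range(K):
        b.add_constraint({idx_pE[h, k]: 1.0 for h in range(r)}, 0.0, np.inf, family="C4")
    # C5: activity rows are prefixes: a_ik >= a_i,k+1
    for i in range(m):
        for k in range(K - 1):
            b.add_constraint(
                {idx_a[i, k]: 1.0, idx_a[i, k + 1]: -1.0}, 0.0, np.inf, family="C5"
            )
    # C6: a_ik <= f_ik + sum_j M_ij p_jk
    for i in range(m):
        mut_j = np.nonzero(M.values[i])[0]
        for k in range(K):
            coeffs = {idx_a[i, k]: -1.0, idx_f[i, k]: 1.0}
            for j in mut_j:
                coeffs[idx_p[j, k]] = 1.0
            b.add_constraint(coeffs, 0.0, np.inf, family="C6")
    # C7: pE_hk = sum_j C_hj p_jk
    Cv = C.values
    for h in range(r):
        nz = np.nonzero(Cv[h])[0]
        for k in range(K):
            coeffs = {idx_pE[h, k]: -1.0}
            for j in nz:
                coeffs[idx_p[j, k]] = Cv[h, j]
            b.add_constraint(coeffs, 0.0, 0.0, family="C7")

    return ProgressionModel(b, M, C, cfg, idx_p, idx_a, idx_f, idx_pE)


def flip_cost_given_partition(
    M: MutationMatrix,
    partition: Mapping[str, int],
    K: int,
) -> tuple[int, list[int]]:
    """Minimal number of matrix corrections for a fixed gene partition.

    For sample i with m_ik mutations falling in phase k, activating the
    prefix of length L costs (m_ik - 1) per active phase that has mutations,
    1 per active phase that has none (a 0->1 flip), and m_ik per inactive
    phase (silencing every mutation there). The cost is minimized over
    L in {0..K} per sample; ties break to the shortest prefix.

    Returns (total flips, per-sample optimal prefix lengths).
    """
    genes = set(partition)
    if genes != set(M.gene_ids):
        raise ContractError("partition must assign every mutation gene exactly once")
    phases = set(partition.values())
    if phases - set(range(1, K + 1)):
        raise ContractError(f"partition uses phases outside 1..{K}")
    if len(phases) != K:
        missing = sorted(set(range(1, K + 1)) - phases)
        raise ContractError(f"empty phase(s) in partition: {missing}")

    indicator = np.zeros((M.n_genes, K))
    for j, g in enumerate(M.gene_ids):
        indicator[j, partition[g] - 1] = 1.0
    counts = M.values @ indicator  # (m, K): m_ik

    active_cost = np.where(counts >= 1, counts - 1, 1.0)  # cost if phase k <= L
    inactive_cost = counts  # cost if phase k > L
    # cost(L) = sum_{k<=L} active + sum_{k>L} inactive, vectorized over samples
    cum_active = np.concatenate(
        [np.zeros((counts.shape[0], 1)), np.cumsum(active_cost, axis=1)], axis=1
    )
    cum_inactive = np.concatenate(
        [np.zeros((counts.shape[0], 1)), np.cumsum(inactive_cost, axis=1)], axis=1
    )
    total_inactive = cum_inactive[:, -1:]
    costs = cum_active + (total_inactive - cum_inactive)  # (m, K+1), col L
    prefixes = np.argmin(costs, axis=1)  # first minimum -> shortest prefix
    total = costs[np.arange(costs.shape[0]), prefixes].sum()
    return int(round(total)), [int(L) for L in prefixes]


def assign_expression(
    C: ConnectivityMatrix, phase_of_mut_gene: Mapping[str, int], K: int | None = None
) -> tuple[np.ndarray, dict[str, int | None]]:
    """Soft and hard expression-gene assignments from a mutation partition.

    p_E[h,k] is gene h's connectivity mass on the genes of phase k. The hard
    assignment is the argmax phase, ties broken to the earliest phase; genes
    with an all-zero connectivity row stay unassigned.
    """
    if K is None:
        K = max(phase_of_mut_gene.values())
    indicator = np.zeros((C.n_mut_genes, K))
    for j, g in enumerate(C.mut_gene_ids):
        indicator[j, phase_of_mut_gene[g] - 1] = 1.0
    p_E = C.values @ indicator
    zero = C.zero_rows()
    hard: dict[str, int | None] = {}
    argmax = np.argmax(p_E, axis=1)  # np.argmax returns the first (earliest) max
    for h, g in enumerate(C.expr_gene_ids):
        hard[g] = None if zero[h] else int(argmax[h]) + 1
    return p_E, hard


def solve(model: ProgressionModel, cfg: MilpConfig | None = None) -> ProgressionSolution:
    """Solve a built model and extract a canonical solution.

    The mutation partition is read off the p^M variables; the activity/flip
    variables and the flip count are then re-derived from that partition by
    the exact per-sample prefix minimization, which reproduces the solver's
    optimum for W < 1 and supplies meaningful flip diagnostics when W = 1
    (where the flip term has zero weight and the solver's a/f are arbitrary).
    """
    cfg = cfg or model.cfg
    res: SolveResult = model.builder.solve(
        mip_gap=cfg.mip_gap, time_limit=cfg.time_limit
    )
    M, C = model.M, model.C
    m, n = M.n_samples, M.n_genes
    r, K, W = C.n_expr_genes, cfg.K, cfg.W

    p_vals = res.x[model.idx_p]  # (n, K)
    phase_idx = np.argmax(p_vals, axis=1)
    partition = {g: int(phase_idx[j]) + 1 for j, g in enumerate(M.gene_ids)}

    flip_count, prefixes = flip_cost_given_partition(M, partition, K)
    indicator = np.zeros((n, K))
    for j in range(n):
        indicator[j, phase_idx[j]] = 1.0
    counts = M.values @ indicator
    a = np.zeros((m, K), dtype=np.int8)
    f = np.zeros((m, K), dtype=np.int8)
    for i, L in enumerate(prefixes):
        a[i, :L] = 1
        f[i, :L] = (counts[i, :L] == 0).astype(np.int8)

    p_E, hard = assign_expression(C, partition, K)
    term1 = (1.0 - W) / (m * n) * flip_count
    term2 = W / (K * r) * p_E.sum()
    return ProgressionSolution(
        phase_of_mut_gene=partition,
        p_E=p_E,
        phase_of_expr_gene=hard,
        a=a,
        f=f,
        per_sample_prefix=prefixes,
        flip_count=flip_count,
        objective_value=term1 - term2,
        term1=term1,
        term2=term2,
        config=cfg,
        sample_ids=M.sample_ids,
        mut_gene_ids=M.gene_ids,
        expr_gene_ids=C.expr_gene_ids,
        solver_status=res.status,
        solver_gap=res.gap,
        solver_seconds=res.seconds,
        connectivity_normalized=C.normalized,
    )


@dataclass
class ValidationReport:
    """Per-invariant pass/fail results for a solved model."""

    checks: dict[str, tuple[bool, str]] = field(default_factory=dict)

    def record(self, name: str, ok: bool, detail: str = "") -> None:
        self.checks[name] = (bool(ok), detail)

    @property
    def passed(self) -> bool:
        return all(ok for ok, _ in self.checks.values())

    def failures(self) -> list[str]:
        return [name for name, (ok, _) in self.checks.items() if not ok]

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "checks": {k: {"ok": ok, "detail": d} for k, (ok, d) in self.checks.items()},
        }


def validate_solution(
    M: MutationMatrix,
    C: ConnectivityMatrix,
    cfg: MilpConfig,
    solution: ProgressionSolution,
    tol: float = 1e-8,
) -> ValidationReport:
    """Re-check every structural invariant of a solution against raw data."""
    rep = ValidationReport()
    K = cfg.K
    m, n, r = M.n_samples, M.n_genes, C.n_expr_genes

    phases = [solution.phase_of_mut_gene.get(g) for g in M.gene_ids]
    rep.record(
        "C1_each_gene_one_phase",
        set(solution.phase_of_mut_gene) == set(M.gene_ids)
        and all(p is not None and 1 <= p <= K for p in phases),
        "every mutation gene mapped to exactly one phase in 1..K",
    )
    counts_per_phase = [sum(1 for p in phases if p == k + 1) for k in range(K)]
    rep.record(
        "C3_nonempty_phases",
        all(c >= 1 for c in counts_per_phase),
        f"genes per phase: {counts_per_phase}",
    )
    a = np.asarray(solution.a)
    rep.record(
        "C5_activity_prefix",
        a.shape == (m, K) and bool((np.diff(a, axis=1) <= 0).all()),
        "each a row non-increasing in k",
    )
    indicator = np.zeros((n, K))
    for j, g in enumerate(M.gene_ids):
        indicator[j, phases[j] - 1] = 1.0
    mut_counts = M.values @ indicator
    rep.record(
        "C6_activity_supported",
        bool((a <= np.asarray(solution.f) + mut_counts + tol).all()),
        "a_ik <= f_ik + sum_j M_ij p_jk",
    )
    p_E_expected = C.values @ indicator
    rep.record(
        "C7_expression_coupling",
        np.allclose(solution.p_E, p_E_expected, atol=tol),
        "p_E equals C times the phase indicator",
    )
    flips, _ = flip_cost_given_partition(M, solution.phase_of_mut_gene, K)
    rep.record(
        "flip_count_consistent",
        solution.flip_count == flips,
        f"reported {solution.flip_count}, recomputed {flips}",
    )
    W = cfg.W
    term1 = (1.0 - W) / (m * n) * flips
    term2 = W / (K * r) * p_E_expected.sum()
    rep.record(
        "objective_recomputed",
        abs((term1 - term2) - solution.objective_value) <= tol,
        f"recomputed {term1 - term2:.12g} vs reported {solution.objective_value:.12g}",
    )
    return rep


def k_selection_diagnostic(
    solution_real: ProgressionSolution,
    solution_random_control: ProgressionSolution,
) -> dict:
    """Side-by-side phase-occupancy summary for a cohort of interest and a
    random-gene negative control run at the same K.

    A genuine progression signal spreads expression genes over several
    phases; the random control typically piles most of them into one phase
    and leaves the zero-connectivity genes unassigned. The summary is for a
    human choosing K; no automatic decision is made.
    """
    if solution_real.K != solution_random_control.K:
        raise ContractError(
            f"both solutions must use the same K "
            f"(got {solution_real.K} and {solution_random_control.K})"
        )

    def _summary(sol: ProgressionSolution) -> dict:
        mut_counts = [len(p) for p in sol.mutation_phases()]
        expr_counts = [len(p) for p in sol.expression_phases()]
        r = len(sol.expr_gene_ids)
        assigned = sum(expr_counts)
        return {
            "K": sol.K,
            "mutation_genes_per_phase": mut_counts,
            "expression_genes_per_phase": expr_counts,
            "fraction_expr_in_largest_phase": (max(expr_counts) / assigned) if assigned else 0.0,
            "fraction_expr_unassigned": (r - assigned) / r if r else 0.0,
        }

    return {"real": _summary(solution_real), "random_control": _summary(solution_random_control)}
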