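"""Synthetic cohorts with the statistical structure the progression model assumes.

Three generators:

- :func:`simulate_planted` — the planted prefix-progression model. Mutation
  genes are split as evenly as possible across K ordered phases; each sample
  draws a prefix length L uniformly from {0..K} and mutates exactly one
  uniformly chosen gene in every phase up to L (per-phase exclusivity +
  progression hold exactly before noise). Each expression gene is wired to a
  single mutation gene and flags outlier expression precisely in the samples
  where that gene is mutated. Independent Bernoulli flips then corrupt both
  matrices at configurable false-positive / false-negative / expression-noise
  rates.
- :func:`simulate_degenerate` — the noiseless extreme: one-hot connectivity
  rows (each expression gene tied to exactly one mutation gene). Downstream,
  every expression gene must land in its wired gene's phase.
- :func:`simulate_random_control` — a negative control with i.i.d. Bernoulli
  mutations, no phase structure, and a chosen fraction of expression genes
  given all-zero connectivity (these must end up unassigned).

All generators are deterministic given their seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import ContractError
from .matrix_io import BinaryExpressionMatrix, MutationMatrix, write_matrix
from .preprocess import ConnectivityMatrix, write_connectivity

__all__ = [
    "PlantedCohort",
    "simulate_planted",
    "simulate_degenerate",
    "simulate_random_control",
    "simulate_continuous_expression",
]


@dataclass
class PlantedCohort:
    """A generated cohort plus its ground truth.

    ``wiring`` maps each expression gene to the mutation gene driving it
    (None for zero-connectivity genes); ``true_partition`` / ``true_prefix``
    are None for the random control, which has no planted structure.
    ``M_clean`` / ``E_clean`` are the pre-noise matrices.
    """

    M: MutationMatrix
    E_bin: BinaryExpressionMatrix
    C_true: ConnectivityMatrix
    wiring: dict[str, str | None]
    true_partition: dict[str, int] | None
    true_prefix: list[int] | None
    fp_rate: float
    fn_rate: float
    expr_noise: float
    seed: int
    M_clean: np.ndarray | None = None
    E_clean: np.ndarray | None = None

    @property
    def n_flips_M(self) -> int:
        """Noise flips actually injected into M (Hamming distance to clean)."""
        if self.M_clean is None:
            return 0
        return int(np.sum(self.M.values != self.M_clean))

    @property
    def n_flips_E(self) -> int:
        if self.E_clean is None:
            return 0
        return int(np.sum(self.E_bin.values != self.E_clean))

    def write(self, outdir: str | Path) -> None:
        """Write M.tsv, E_bin.tsv, C_true.tsv and truth.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_matrix(self.M, outdir / "M.tsv")
        write_matrix(self.E_bin, outdir / "E_bin.tsv")
        write_connectivity(self.C_true, outdir / "C_true.tsv")
        truth = {
            "wiring": self.wiring,
            "true_partition": self.true_partition,
            "true_prefix": self.true_prefix,
            "fp_rate": self.fp_rate,
            "fn_rate": self.fn_rate,
            "expr_noise": self.expr_noise,
            "seed": self.seed,
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")


def _labels(prefix: str, count: int) -> tuple[str, ...]:
    width = len(str(count))
    return tuple(f"{prefix}{i + 1:0{width}d}" for i in range(count))


def _balanced_partition(n: int, K: int) -> dict[int, int]:
    """Gene index -> phase (1-based), phase sizes as equal as possible."""
    return {j: (j % K) + 1 for j in range(n)}


def simulate_planted(
    m: int,
    n: int,
    r: int,
    K: int,
    fp_rate: float = 0.0,
    fn_rate: float = 0.0,
    expr_noise: float = 0.0,
    seed: int = 0,
) -> PlantedCohort:
    """Planted prefix-progression cohort with optional Bernoulli corruption."""
    if not (n >= K >= 1):
        raise ContractError(f"need n >= K >= 1, got n={n}, K={K}")
    if r < 1:
        raise ContractError("need at least one expression gene")
    for name, rate in (("fp_rate", fp_rate), ("fn_rate", fn_rate), ("expr_noise", expr_noise)):
        if not (0.0 <= rate < 0.5):
            raise ContractError(f"{name} must lie in [0, 0.5), got {rate}")
    rng = np.random.default_rng(seed)
    samples = _labels("S", m)
    mut_genes = _labels("MG", n)
    expr_genes = _labels("EG", r)

    part_idx = _balanced_partition(n, K)
    phase_members = [
        [j for j in range(n) if part_idx[j] == k + 1] for k in range(K)
    ]

    M_clean = np.zeros((m, n), dtype=np.int8)
    prefixes = rng.integers(0, K + 1, size=m)
    for i, L in enumerate(prefixes):
        for k in range(int(L)):
            j = phase_members[k][rng.integers(len(phase_members[k]))]
            M_clean[i, j] = 1

    wired = rng.integers(0, n, size=r)
    E_clean = M_clean[:, wired].astype(np.int8)

    M_noisy = M_clean.copy()
    if fp_rate > 0 or fn_rate > 0:
        u = rng.random(M_clean.shape)
        flip = np.where(M_clean == 0, u < fp_rate, u < fn_rate)
        M_noisy = np.where(flip, 1 - M_clean, M_clean).astype(np.int8)
    E_noisy = E_clean.copy()
    if expr_noise > 0:
        flip = rng.random(E_clean.shape) < expr_noise
        E_noisy = np.where(flip, 1 - E_clean, E_clean).astype(np.int8)

    C_vals = np.zeros((r, n))
    C_vals[np.arange(r), wired] = 1.0
    return PlantedCohort(
        M=MutationMatrix(samples, mut_genes, M_noisy),
        E_bin=BinaryExpressionMatrix(samples, expr_genes, E_noisy),
        C_true=ConnectivityMatrix(expr_genes, mut_genes, C_vals, normalized=True),
        wiring={expr_genes[h]: mut_genes[wired[h]] for h in range(r)},
        true_partition={mut_genes[j]: part_idx[j] for j in range(n)},
        true_prefix=[int(L) for L in prefixes],
        fp_rate=fp_rate,
        fn_rate=fn_rate,
        expr_noise=expr_noise,
        seed=seed,
        M_clean=M_clean,
        E_clean=E_clean,
    )


def simulate_degenerate(m: int, n: int, r: int, K: int, seed: int = 0) -> PlantedCohort:
    """Noiseless cohort with one-hot connectivity (each expression gene tied
    to one uniformly chosen mutation gene); requires r >= n >= K."""
    if not (r >= n >= K):
        raise ContractError(f"degenerate design requires r >= n >= K, got r={r}, n={n}, K={K}")
    return simulate_planted(m, n, r, K, fp_rate=0.0, fn_rate=0.0, expr_noise=0.0, seed=seed)


def simulate_random_control(
    m: int,
    n: int,
    r: int,
    zero_connectivity_fraction: float = 0.2,
    seed: int = 0,
    mutation_rate: float = 0.1,
) -> PlantedCohort:
    """Negative-control cohort: no phase structure, a chosen fraction of
    expression genes structurally disconnected.

    Exactly ceil(fraction * r) expression genes get all-zero outlier columns
    (hence all-zero connectivity rows -> unassigned downstream); the rest
    copy the mutation column of a uniformly chosen gene. Every mutation gene
    is guaranteed at least one mutated sample so wired genes stay connected.
    """
    if not (0.0 <= zero_connectivity_fraction <= 1.0):
        raise ContractError("zero_connectivity_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    samples = _labels("S", m)
    mut_genes = _labels("MG", n)
    expr_genes = _labels("EG", r)

    M = (rng.random((m, n)) < mutation_rate).astype(np.int8)
    for j in np.nonzero(M.sum(axis=0) == 0)[0]:
        M[rng.integers(m), j] = 1

    z = math.ceil(zero_connectivity_fraction * r)
    disconnected = set(rng.choice(r, size=z, replace=False).tolist())
    E = np.zeros((m, r), dtype=np.int8)
    wiring: dict[str, str | None] = {}
    for h in range(r):
        if h in disconnected:
            wiring[expr_genes[h]] = None
        else:
            j = int(rng.integers(n))
            wiring[expr_genes[h]] = mut_genes[j]
            E[:, h] = M[:, j]

    C_vals = E.astype(np.int64).T @ M.astype(np.int64)
    return PlantedCohort(
        M=MutationMatrix(samples, mut_genes, M),
        E_bin=BinaryExpressionMatrix(samples, expr_genes, E),
        C_true=ConnectivityMatrix(expr_genes, mut_genes, C_vals.astype(float)),
        wiring=wiring,
        true_partition=None,
        true_prefix=None,
        fp_rate=0.0,
        fn_rate=0.0,
        expr_noise=0.0,
        seed=seed,
    )


def simulate_continuous_expression(
    m: int,
    r: int,
    outlier_fraction: float = 0.02,
    effect_size: float = 6.0,
    seed: int = 0,
):
    """Gaussian log-expression with planted outliers, for exercising the
    percentile binarizer. Returns (ExpressionMatrix, boolean outlier mask)."""
    from .matrix_io import ExpressionMatrix

    rng = np.random.default_rng(seed)
    values = rng.normal(0.0, 1.0, size=(m, r))
    mask = rng.random((m, r)) < outlier_fraction
    signs = np.where(rng.random((m, r)) < 0.5, -1.0, 1.0)
    values = values + mask * signs * effect_size
    return (
        ExpressionMatrix(_labels("S", m), _labels("EG", r), values),
        mask,
    )
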