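# oncophase

Infer the temporal order of cancer driver events from **cross-sectional**
cohorts — one measurement per patient — by jointly partitioning mutated genes
and abnormally expressed genes into an ordered sequence of *progression
phases*.

The package is aimed at computational cancer biologists working with matched
somatic-mutation and gene-expression matrices (e.g. TCGA-style cohorts). It
provides the full pipeline: a 20/20-rule driver screen over MAF variant
tables, percentile-outlier binarization of expression, construction of the
mutation–expression connectivity matrix, the core mixed integer linear
program that orders the phases, an exhaustive enumeration oracle for
verification, and synthetic cohort generators.

## The model

Input is an m×n binary mutation matrix **M** (samples × mutation genes) and
an m×r expression matrix **E**. Expression is reduced to outlier indicators
(1st/99th percentile per gene), and a connectivity matrix
**C ≡ E_binᵀ·M** (r×n) counts, for each expression gene h and mutation gene
j, the samples where h is an expression outlier while j is mutated; rows of C
are then scaled to sum to 1.

A *phase* k ∈ {1..K} is defined jointly by a set of mutation genes (exactly
one of which is mutated per sample active in that phase) and the expression
genes whose abnormal expression those mutations explain. The MILP chooses
binary phase indicators p^M_{jk}, per-sample activity a_{ik} and flip
indicators f_{ik}, and continuous expression probabilities p^E_{hk} ∈ [0,1]:

```
min  (1−W)/(m·n) · Σ_{i,k} ( Σ_j M_ij p^M_jk − a_ik + 2 f_ik )
     − W/(K·r) · Σ_{h,k} p^E_hk

s.t.  Σ_k p^M_jk = 1                    (each mutation gene in one phase)
      Σ_j p^M_jk ≥ 1                    (no empty phase)
      a_ik ≥ a_{i,k+1}                  (progression: activity is a prefix)
      a_ik ≤ f_ik + Σ_j M_ij p^M_jk    (activity needs a mutation or a flip)
      p^E_hk = Σ_j C_hj p^M_jk         (expression follows connectivity)
```

The first objective term counts the 0→1 and 1→0 corrections ("flips") needed
to make the cohort satisfy per-phase exclusivity and cross-phase progression
— the cost of attributing violations to passenger mutations and call errors.
The second term aggregates the expression mass captured by the phases; W
trades the two off. Solving is exact, via HiGHS branch-and-cut
(`scipy.optimize.milp`), to a default relative gap of 1e-9.

Each expression gene is finally assigned to its argmax-probability phase
(earliest phase on ties); genes with an all-zero connectivity row stay
unassigned.

## Worked example

Simulate a noisy planted-progression cohort (200 samples, 12 mutation genes
in 3 phases, 40 wired expression genes, 2 % false positive/negative rates)
and recover the phase structure:

```python
from oncophase import (MilpConfig, build_model, solve,
                       flip_cost_given_partition, simulate_planted)

cohort = simulate_planted(m=200, n=12, r=40, K=3,
                          fp_rate=0.02, fn_rate=0.02, seed=7)
sol = solve(build_model(cohort.M, cohort.C_true, MilpConfig(K=3, W=0.5)))

print("flips needed  :", sol.flip_count)
for k, genes in enumerate(sol.mutation_phases(), 1):
    n_expr = len(sol.expression_phases()[k - 1])
    print(f"phase {k}: mutation genes {genes}  ({n_expr} expression genes)")
```

Output:

```
flips needed  : 35
phase 1: mutation genes ['MG01', 'MG04', 'MG07', 'MG10']  (15 expression genes)
phase 2: mutation genes ['MG02', 'MG05', 'MG08', 'MG11']  (17 expression genes)
phase 3: mutation genes ['MG03', 'MG06', 'MG09', 'MG12']  (8 expression genes)
```

All 12 mutation genes land in their planted phase, every expression gene
follows its wired mutation gene, and the 35 corrections equal the planted
partition's own flip cost — the noise the simulation injected, no more. The
solve is proven optimal (gap 0) in under a second.

The same pipeline is available from the shell:

```sh
oncophase simulate --mode planted -m 200 -n 12 -r 40 -K 3 --fp 0.02 --fn 0.02 --seed 7 -o cohort/
oncophase infer --mutations cohort/M.tsv --connectivity cohort/C_true.tsv -K 3 -o solution.json
oncophase validate --mutations cohort/M.tsv --connectivity cohort/C_true.tsv --solution solution.json
```

Other subcommands: `drivers` (20/20-rule screen over a MAF file),
`binarize`, `connect`, `oracle` (exhaustive enumeration on tiny instances),
and `run` (full pipeline from a YAML config).

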