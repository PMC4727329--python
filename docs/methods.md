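# Methods

## Problem and model

Cross-sectional cancer cohorts measure each patient once, so the temporal
order of driver events must be inferred *across* patients. The model assumes:

1. **Exclusivity** — within one progression phase, each sample carries at
   most one driver mutation, and each mutation gene belongs to exactly one
   phase.
2. **Progression** — a sample can only carry a phase-(k+1) mutation if it
   carries a phase-k mutation; after corrections, each sample's phase
   activity is a prefix of the phase sequence.
3. **Causality** — mutations in a phase drive the abnormal expression of
   that phase's expression genes; a sample inactive in a phase shows normal
   expression for that phase's genes.
4. **Connectivity-weighted assignment** — an expression gene joins the phase
   to which its mutation co-occurrence mass points.

Real cohorts violate 1–2 because of passenger mutations and false
positive/negative calls. The MILP therefore buys feasibility with *flips* —
0→1 or 1→0 corrections of mutation entries — and minimizes their count,
normalized by the m·n matrix size and weighted (1−W), while maximizing the
expression probability mass Σ p^E_{hk}, normalized by K·r and weighted W.
The decision variables, objective and the seven constraint families are
listed in the README; the implementation keeps the p^E variables and both
printed nonnegativity constraints in the model verbatim, even though the
coupling constraint determines p^E and nonnegativity of C makes the two
inequalities vacuous. `assign_expression` recomputes p^E independently of
the solver as a cross-check.

## Structural properties worth knowing

- **The expression term is constant given C.** Summing the coupling
  constraint over phases gives Σ_k p^E_hk = Σ_j C_hj for every feasible
  solution. With fully row-normalized C the second objective term equals
  W/K exactly (W(r−z)/(K·r) with z all-zero rows); the optimal mutation
  partition is therefore invariant to W. The expression data still
  determines *where each expression gene goes* — via the argmax of p^E —
  just not which mutation partition wins. Whether an unnormalized C (which
  would also leave the term constant, but was plausibly not intended to) is
  preferable can be explored with `--no-normalize`; the row-normalized form
  is the default and the one all guarantees here refer to.
- **Flip cost decomposes per sample.** For a fixed partition, sample i with
  m_ik mutations in phase k and prefix length L costs
  Σ_{k≤L} (m_ik−1 if m_ik≥1 else 1) + Σ_{k>L} m_ik; the optimum over
  L ∈ {0..K} is taken per sample. This closed form
  (`flip_cost_given_partition`) is verified against direct MILP minimization
  with the partition frozen, and doubles as the inner loop of the
  exhaustive oracle.
- **Sensitivity.** Toggling one mutation entry changes any partition's cost
  by exactly one, so the optimal flip count moves by at most one in either
  direction. (It can *decrease* when the added entry completes a broken
  progression.)

## Numerical and design choices

- **Solver.** HiGHS branch-and-cut through `scipy.optimize.milp`, behind a
  thin builder interface (binary/continuous variables, linear constraints,
  linear objective) so another exact backend could be substituted. Default
  relative MIP gap 1e-9: the instances this package targets (tens of genes)
  solve to proven optimality in seconds, and oracle-equivalence tests need
  exact optima. HiGHS is deterministic for a fixed model; the config's
  `seed` is recorded for provenance.
- **Multiple optima.** No canonicalization of partitions is imposed;
  correctness is judged on objective value. Phase 1 is earliest; the
  progression constraint is a_{ik} ≥ a_{i,k+1}.
- **Canonical a/f extraction.** After solving, the activity and flip
  variables are re-derived from the recovered partition by the per-sample
  prefix minimization (shortest prefix on ties). For W < 1 this reproduces
  the solver's optimum exactly; at W = 1 the flip term has zero weight and
  the solver's a/f are arbitrary, so the re-derivation keeps flip
  diagnostics meaningful without changing the objective value.
- **Expression assignment.** Hard assignment is argmax_k p^E_hk with ties
  broken to the earliest phase (a convention — the earliest phase that
  explains the gene); genes with zero connectivity rows stay unassigned
  rather than dividing by zero during normalization. Expression exclusivity
  is deliberately not enforced: several expression genes may change in one
  phase.
- **Binarization.** Per-gene percentiles use linear interpolation between
  order statistics with inclusive thresholds (≤ q_lo, ≥ q_hi), defaults
  1 and 99. Inclusive comparisons guarantee at least one flagged sample per
  side for any non-degenerate gene; zero-spread (constant) genes yield no
  outliers. Cells are never imputed; incomplete matrices are an error.
- **Driver screen.** "Recurrent at the same amino-acid position" is
  operationalized as ≥ `recurrence_min` (default 2) missense/in-frame
  records at one residue; records without a parsable residue position count
  toward totals but never toward recurrence. Score thresholds are strict
  (> 20 %), and the variant minimum ("at least 20") counts records, not
  distinct samples. Silent and unclassified (splice, UTR, ...) variants
  count toward the denominator only.

## Synthetic cohorts

The generators produce the conditions the model assumes, so that recovery
claims are checkable against known ground truth:

- **Planted prefix-progression** (`simulate_planted`): n genes split as
  evenly as possible over K phases; each sample draws a prefix length
  uniformly from {0..K} (samples with no driver events exist in real
  cohorts) and mutates exactly one uniformly chosen gene per phase within
  it. Each expression gene is wired to one uniformly chosen mutation gene
  and mirrors its mutation column. Noise is injected as independent
  Bernoulli flips — false positives and false negatives on M, symmetric
  flips on the binary expression — mimicking passenger mutations and call
  errors. Defaults m=200, n=12, r=40, K=3 match the scale at which the
  pipeline is exercised end to end.
- **Degenerate one-hot cohorts** (`simulate_degenerate`): the noiseless
  extreme in which every connectivity row is one-hot. Downstream, every
  expression gene must land in its wired gene's phase; the simulation study
  sizes used for verification are m=50, n=9, r=30 with K ∈ {2,3,4} over 10
  seeds.
- **Random negative control** (`simulate_random_control`): i.i.d. Bernoulli
  mutations (default rate 0.1, every gene forced to have ≥ 1 mutated
  sample), no phase structure, and an exact ⌈fraction·r⌉ of expression
  genes given all-zero connectivity — these must come back unassigned. The
  side-by-side summary (`k_selection_diagnostic`) supports the heuristic of
  choosing K where the cohort of interest separates from the control; the
  choice itself is left to the analyst.

What the generators do **not** emulate: mutational signatures, gene-length
or expression-level dependent mutation rates, copy-number events,
correlated noise between samples, or continuous expression distributions
(an optional Gaussian-with-outliers mode exists solely to exercise the
binarizer). Passing tests on these cohorts show the optimizer and pipeline
are correct under the model's own assumptions — not that real tumors follow
a single linear progression.

## Verification strategy

An exhaustive oracle enumerates all K!·S(n,K) ordered surjective partitions
(guarded to n ≤ 8, K ≤ 4) and computes exact objectives by per-sample
enumeration of prefix lengths — independently of the solver path. The MILP
must match it to 1e-8 on random instances; the flip closed form must match a
frozen-partition MILP; solved models are re-validated constraint by
constraint from raw data. Problem sizes in tests (up to m=200, n=12) keep
the full suite to seconds while covering every constraint family.

## Known limitations

- Exact branch-and-cut does not scale to hundreds of mutation genes;
  the intended regime is a driver-screened gene set (tens of genes).
- K is externally chosen; the package provides the negative-control
  comparison, not an automatic selection rule.
- Hard expression assignment by argmax discards the (often informative)
  full p^E distribution, which is retained in the solution object for
  users who want it.
- With row-normalized C, W has no effect on the recovered mutation
  partition (see the constancy property above); it only rescales the
  reported objective.
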