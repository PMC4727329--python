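import numpy as np
import pytest

from oncophase import (
    ConnectivityMatrix,
    MilpConfig,
    MutationMatrix,
    assign_expression,
    build_model,
    flip_cost_given_partition,
    k_selection_diagnostic,
    normalize_rows,
    solve,
    validate_solution,
)
from oncophase.exceptions import ContractError, DomainError


def _matrix(rows, genes=None):
    rows = np.asarray(rows)
    genes = genes or tuple(chr(ord("A") + j) for j in range(rows.shape[1]))
    return MutationMatrix(
        tuple(f"s{i}" for i in range(rows.shape[0])), genes, rows
    )


def _uniform_C(M, r=2):
    vals = np.full((r, M.n_genes), 1.0 / M.n_genes)
    return ConnectivityMatrix(
        tuple(f"e{h}" for h in range(r)), M.gene_ids, vals, normalized=True
    )


class TestBuildModel:
    def test_variable_and_constraint_counts(self):
        M = _matrix([[1, 0], [0, 1], [1, 1]])
        C = _uniform_C(M, r=2)
        model = build_model(M, C, MilpConfig(K=2))
        assert model.variable_counts == {"binary": 16, "continuous": 4}
        assert model.constraint_counts == {
            "C1": 2, "C2": 2, "C3": 2, "C4": 2, "C5": 3, "C6": 6, "C7": 4,
        }

    def test_k_larger_than_n_rejected_up_front(self):
        M = _matrix([[1, 0]])
        with pytest.raises(ContractError, match="K=3"):
            build_model(M, _uniform_C(M), MilpConfig(K=3))

    def test_gene_label_mismatch_rejected(self):
        M = _matrix([[1, 0]])
        C = ConnectivityMatrix(("e1",), ("X", "Y"), np.array([[0.5, 0.5]]), normalized=True)
        with pytest.raises(ContractError):
            build_model(M, C, MilpConfig(K=2))

    def test_invalid_weight_rejected(self):
        with pytest.raises(DomainError):
            MilpConfig(K=2, W=1.5)


class TestSolve:
    def test_recovers_progression_with_one_flip(self, four_sample_matrix, unit_connectivity):
        """Three samples support A-before-B; the lone B-only sample costs one
        flip. The swapped ordering would cost two."""
        sol = solve(build_model(four_sample_matrix, unit_connectivity, MilpConfig(K=2)))
        assert sol.phase_of_mut_gene == {"A": 1, "B": 2}
        assert sol.flip_count == 1
        swapped, _ = flip_cost_given_partition(four_sample_matrix, {"A": 2, "B": 1}, 2)
        assert swapped == 2

    def test_perfect_prefix_structure_needs_no_flips(self):
        M = _matrix([[1, 0], [1, 1], [1, 1], [0, 0]])
        sol = solve(build_model(M, _uniform_C(M), MilpConfig(K=2)))
        assert sol.flip_count == 0
        assert sol.term1 == 0.0

    def test_weight_zero_drops_expression_term(self, four_sample_matrix, unit_connectivity):
        sol = solve(build_model(four_sample_matrix, unit_connectivity, MilpConfig(K=2, W=0.0)))
        assert sol.term2 == 0.0
        assert sol.objective_value == pytest.approx(sol.term1)

    def test_all_zero_mutation_matrix_feasible_with_zero_flips(self):
        M = _matrix(np.zeros((3, 2), dtype=int))
        sol = solve(build_model(M, _uniform_C(M), MilpConfig(K=2)))
        assert sol.flip_count == 0
        assert sol.term1 == 0.0
        assert not sol.a.any() and not sol.f.any()

    def test_term2_equals_w_over_k_for_fully_normalized_C(self, four_sample_matrix):
        """With every connectivity row summing to 1, the expression term is the
        constant W/K for any feasible solution."""
        for W in (0.25, 0.5, 1.0):
            C = _uniform_C(four_sample_matrix, r=3)
            sol = solve(build_model(four_sample_matrix, C, MilpConfig(K=2, W=W)))
            assert sol.term2 == pytest.approx(W / 2, abs=1e-10)

    def test_term2_with_zero_rows(self, four_sample_matrix):
        vals = np.array([[0.5, 0.5], [0.0, 0.0], [1.0, 0.0]])
        C = ConnectivityMatrix(("e1", "e2", "e3"), ("A", "B"), vals, normalized=True)
        sol = solve(build_model(four_sample_matrix, C, MilpConfig(K=2, W=0.5)))
        # z=1 zero row of r=3: term2 = W (r - z) / (K r)
        assert sol.term2 == pytest.approx(0.5 * 2 / (2 * 3), abs=1e-10)

    def test_a_rows_are_prefixes(self, four_sample_matrix, unit_connectivity):
        sol = solve(build_model(four_sample_matrix, unit_connectivity, MilpConfig(K=2)))
        assert (np.diff(sol.a, axis=1) <= 0).all()


class TestFlipCostGivenPartition:
    # three genes, partition A,B -> phase 1, C -> phase 2
    PART = {"A": 1, "B": 1, "C": 2}

    @pytest.mark.parametrize(
        "row,expected_flips,expected_prefix",
        [
            ([1, 0, 1], 0, 2),  # counts (1,1): perfect progression
            ([1, 1, 0], 1, 1),  # counts (2,0): silence one extra phase-1 entry
            ([0, 0, 1], 1, 0),  # counts (0,1): drop the orphan late mutation
        ],
    )
    def test_single_sample_cases(self, row, expected_flips, expected_prefix):
        M = _matrix([row])
        total, prefixes = flip_cost_given_partition(M, self.PART, 2)
        assert total == expected_flips
        assert prefixes == [expected_prefix]

    def test_empty_phase_rejected(self):
        M = _matrix([[1, 0]])
        with pytest.raises(ContractError):
            flip_cost_given_partition(M, {"A": 1, "B": 1}, 2)

    def test_spurious_entry_changes_optimum_by_at_most_one(self):
        """Toggling one mutation entry moves the optimal flip count by at most 1
        (each per-sample prefix cost changes by exactly one)."""
        from oncophase.exhaustive_oracle import enumerate_optimum

        rng = np.random.default_rng(21)
        for _ in range(10):
            m, n, K = 4, 4, 2
            Mv = (rng.random((m, n)) < 0.4).astype(np.int8)
            M = _matrix(Mv)
            C = _uniform_C(M)
            base = enumerate_optimum(M, C, K, W=0.0).best_objective * (m * n)
            i, j = rng.integers(m), rng.integers(n)
            Mv2 = Mv.copy()
            Mv2[i, j] = 1 - Mv2[i, j]
            pert = enumerate_optimum(_matrix(Mv2), C, K, W=0.0).best_objective * (m * n)
            assert abs(pert - base) <= 1 + 1e-9


class TestAssignExpression:
    def test_one_hot_row_follows_wired_gene(self):
        C = ConnectivityMatrix(("e1",), ("A", "B"), np.array([[0.0, 1.0]]), normalized=True)
        p_E, hard = assign_expression(C, {"A": 1, "B": 2}, K=2)
        assert hard["e1"] == 2
        assert p_E[0, 1] == pytest.approx(1.0)

    def test_zero_row_unassigned(self):
        C = ConnectivityMatrix(("e1",), ("A", "B"), np.zeros((1, 2)), normalized=True)
        _, hard = assign_expression(C, {"A": 1, "B": 2}, K=2)
        assert hard["e1"] is None

    def test_tie_breaks_to_earliest_phase(self):
        C = ConnectivityMatrix(("e1",), ("A", "B"), np.array([[0.5, 0.5]]), normalized=True)
        _, hard = assign_expression(C, {"A": 1, "B": 2}, K=2)
        assert hard["e1"] == 1


class TestValidateSolution:
    def test_solver_output_passes_all_checks(self, four_sample_matrix, unit_connectivity):
        cfg = MilpConfig(K=2)
        sol = solve(build_model(four_sample_matrix, unit_connectivity, cfg))
        rep = validate_solution(four_sample_matrix, unit_connectivity, cfg, sol)
        assert rep.passed, rep.failures()

    def test_corrupted_activity_matrix_fails_prefix_check(
        self, four_sample_matrix, unit_connectivity
    ):
        cfg = MilpConfig(K=2)
        sol = solve(build_model(four_sample_matrix, unit_connectivity, cfg))
        sol.a = sol.a.copy()
        sol.a[0] = [0, 1]  # violates monotonicity
        rep = validate_solution(four_sample_matrix, unit_connectivity, cfg, sol)
        assert "C5_activity_prefix" in rep.failures()

    def test_objective_recomputation_tolerance(self, four_sample_matrix, unit_connectivity):
        cfg = MilpConfig(K=2)
        sol = solve(build_model(four_sample_matrix, unit_connectivity, cfg))
        rep = validate_solution(four_sample_matrix, unit_connectivity, cfg, sol)
        assert rep.checks["objective_recomputed"][0]
        sol.objective_value += 1e-3
        rep2 = validate_solution(four_sample_matrix, unit_connectivity, cfg, sol)
        assert "objective_recomputed" in rep2.failures()


class TestKSelectionDiagnostic:
    def test_identical_inputs_give_identical_summaries(
        self, four_sample_matrix, unit_connectivity
    ):
        sol = solve(build_model(four_sample_matrix, unit_connectivity, MilpConfig(K=2)))
        d = k_selection_diagnostic(sol, sol)
        assert d["real"] == d["random_control"]

    def test_mismatched_k_rejected(self, four_sample_matrix, unit_connectivity):
        M3 = _matrix([[1, 0, 0], [1, 1, 0], [1, 1, 1]])
        sol2 = solve(build_model(four_sample_matrix, unit_connectivity, MilpConfig(K=2)))
        sol3 = solve(build_model(M3, _uniform_C(M3), MilpConfig(K=3)))
        with pytest.raises(ContractError):
            k_selection_diagnostic(sol2, sol3)

    def test_degenerate_spreads_while_random_control_concentrates(self):
        from oncophase.synthetic_data import simulate_degenerate, simulate_random_control

        K = 3
        deg = simulate_degenerate(40, 6, 18, K, seed=2)
        sol_deg = solve(build_model(deg.M, deg.C_true, MilpConfig(K=K)))
        rand = simulate_random_control(40, 6, 18, zero_connectivity_fraction=0.2, seed=2)
        C = normalize_rows(rand.C_true)
        sol_rand = solve(build_model(rand.M, C, MilpConfig(K=K)))
        d = k_selection_diagnostic(sol_deg, sol_rand)
        assert d["real"]["fraction_expr_unassigned"] == 0.0
        assert d["random_control"]["fraction_expr_unassigned"] == pytest.approx(0.2, abs=0.05)
        # planted multi-phase structure: no single phase hoards every gene
        assert d["real"]["fraction_expr_in_largest_phase"] < 1.0
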