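"""LP core: examples, invariants, and the brute-force vertex oracle."""

import itertools

import numpy as np
import pytest

from gliorfba.core_model import (
    Metabolite,
    ModelError,
    Objective,
    ObjectiveSense,
    Reaction,
    SolveStatus,
    StoichiometricModel,
)
from gliorfba.exemplar_builder import generate_random_model
from gliorfba.fba_engine import (
    BoundsOverlay,
    FbaSolver,
    check_solution,
    solve_fba,
)


def vertex_enumeration_optimum(model, c):
    """Independent oracle: maximum of c'v over the flux polytope.

    Enumerates candidate vertices of {v : S v = 0, lb <= v <= ub} by fixing
    every subset of n - rank(S) variables at a bound and solving for the
    rest; keeps feasible solutions and returns the best objective.  The
    polytope is bounded (finite bounds) and nonempty (0 is feasible when
    every bound interval contains it), so the optimum is attained at a
    vertex.
    """

    S = model.S
    lb, ub = model.bounds_arrays()
    n = model.n
    r = int(np.linalg.matrix_rank(S))
    best = -np.inf
    tol = 1e-7
    for free in itertools.combinations(range(n), n - r):
        basic = [j for j in range(n) if j not in free]
        S_b = S[:, basic]
        if np.linalg.matrix_rank(S_b) < r:
            continue
        for corner in itertools.product(*[(lb[j], ub[j]) for j in free]):
            rhs = -S[:, list(free)] @ np.array(corner)
            v_b, residuals, *_ = np.linalg.lstsq(S_b, rhs, rcond=None)
            v = np.zeros(n)
            v[list(free)] = corner
            v[basic] = v_b
            if np.max(np.abs(S @ v)) > tol:
                continue
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            best = max(best, float(c @ v))
    return best


def _chain_model():
    mets = [Metabolite(id=m, name=m) for m in ("A", "B")]
    rxns = [
        Reaction(id="EX_A", stoichiometry={"A": 1}, lb=0, ub=10),
        Reaction(id="R", stoichiometry={"A": -1, "B": 1}, lb=0, ub=1000),
        Reaction(id="EX_B", stoichiometry={"B": -1}, lb=0, ub=1000),
    ]
    return StoichiometricModel(mets, rxns)


class TestSolveFba:
    def test_bottleneck_chain(self):
        model = _chain_model()
        sol = solve_fba(model, Objective("maxB", {"EX_B": 1.0}))
        assert sol.status is SolveStatus.OPTIMAL
        assert sol.objective_value == pytest.approx(10.0)
        assert [sol.fluxes[r] for r in ("EX_A", "R", "EX_B")] == pytest.approx(
            [10.0, 10.0, 10.0]
        )

    def test_overlay_closes_uptake(self):
        model = _chain_model()
        sol = solve_fba(
            model, Objective("maxB", {"EX_B": 1.0}),
            BoundsOverlay({"EX_A": (0.0, 0.0)}),
        )
        assert sol.objective_value == pytest.approx(0.0)

    def test_infeasible_reports_forced_reactions(self):
        model = _chain_model()
        sol = solve_fba(
            model, Objective("maxB", {"EX_B": 1.0}),
            BoundsOverlay({"EX_A": (0.0, 0.0), "EX_B": (5.0, 10.0)}),
        )
        assert sol.status is SolveStatus.INFEASIBLE
        assert "EX_B" in sol.infeasibility_report

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_vertex_enumeration(self, seed):
        model, _, _ = generate_random_model(seed, m=5, n=7)
        c = np.zeros(model.n)
        c[model.n - 1] = 1.0  # maximize the last boundary exchange
        objective = Objective("max_last", {model.reactions[-1].id: 1.0})
        sol = FbaSolver(model).solve(objective)
        assert sol.status is SolveStatus.OPTIMAL
        oracle = vertex_enumeration_optimum(model, c)
        assert sol.objective_value == pytest.approx(oracle, abs=1e-6)


class TestLpInvariants:
    def test_tightening_bounds_never_improves(self):
        model = _chain_model()
        objective = Objective("maxB", {"EX_B": 1.0})
        solver = FbaSolver(model)
        base = solver.solve(objective).objective_value
        for cap in (8.0, 5.0, 1.0, 0.0):
            tightened = solver.solve(
                objective, BoundsOverlay({"EX_A": (0.0, cap)})
            ).objective_value
            assert tightened <= base + 1e-9
            base = tightened

    @pytest.mark.parametrize("k", [0.5, 2.0, 10.0])
    def test_scaling_bounds_scales_optimum(self, k):
        model, _, _ = generate_random_model(3, m=5, n=7)
        objective = Objective("max_last", {model.reactions[-1].id: 1.0})
        base = FbaSolver(model).solve(objective).objective_value
        overlay = BoundsOverlay(
            {r.id: (k * r.lb, k * r.ub) for r in model.reactions}
        )
        scaled = FbaSolver(model).solve(objective, overlay).objective_value
        assert scaled == pytest.approx(k * base, abs=1e-6)

    def test_all_exchanges_closed_gives_zero(self):
        model = _chain_model()
        overlay = BoundsOverlay({"EX_A": (0.0, 0.0), "EX_B": (0.0, 0.0)})
        sol = FbaSolver(model).solve(Objective("maxB", {"EX_B": 1.0}), overlay)
        assert sol.objective_value == pytest.approx(0.0)
        assert all(abs(v) < 1e-9 for v in sol.fluxes.values())

    def test_parsimonious_representative_is_deterministic(self):
        model, _, _ = generate_random_model(7, m=6, n=8)
        objective = Objective("max_last", {model.reactions[-1].id: 1.0})
        sol1 = FbaSolver(model).solve(objective)
        sol2 = FbaSolver(model).solve(objective)
        assert sol1.fluxes == sol2.fluxes


class TestOverlay:
    def test_composition_takes_tightest(self):
        overlay = BoundsOverlay({"R": (-5.0, 5.0)})
        overlay.tighten("R", -10.0, 2.0)
        assert overlay["R"] == (-5.0, 2.0)

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ModelError):
            BoundsOverlay({"R": (3.0, 1.0)})

    def test_empty_composition_rejected(self):
        overlay = BoundsOverlay({"R": (2.0, 5.0)})
        with pytest.raises(ModelError, match="empty"):
            overlay.tighten("R", -1.0, 1.0)


class TestCheckSolution:
    def test_optimal_solution_verifies(self):
        model = _chain_model()
        sol = solve_fba(model, Objective("maxB", {"EX_B": 1.0}))
        report = check_solution(model, sol)
        assert report.ok
        assert report.max_residual <= 1e-6

    def test_perturbed_fluxes_flag_violated_rows(self):
        model = _chain_model()
        sol = solve_fba(model, Objective("maxB", {"EX_B": 1.0}))
        broken_fluxes = dict(sol.fluxes)
        broken_fluxes["R"] += 0.5  # breaks mass balance on A and B
        broken = type(sol)(
            fluxes=broken_fluxes,
            objective_value=sol.objective_value,
            status=sol.status,
        )
        report = check_solution(model, broken)
        assert not report.ok
        assert set(report.residuals) == {"A", "B"}

    def test_exemplar_solutions_verify(self, bundle):
        solver = FbaSolver(bundle.model)
        for cond in bundle.conditions.values():
            sol = solver.solve(cond.objective, cond.bounds_overlay)
            report = check_solution(
                bundle.model, sol, overlay=cond.bounds_overlay
            )
            assert report.ok, report.bound_violations
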