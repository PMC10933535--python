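"""Linear-programming core: solve S v = 0, lb <= v <= ub for an objective.

Solves are delegated to scipy's HiGHS interface.  Because flux polytopes
routinely have alternate optima, a second (parsimonious) solve fixes the
objective at its optimum and minimizes the total absolute flux, so that the
returned flux vector is a deterministic, reproducible representative.  Only
flux signs and qualitative orderings should be read as biology; the exact
degenerate representative is a numerical convention.

``solve_fba`` memoizes on the effective bounds + objective: inside the
integrated simulation the bounds change only at regulatory ticks, so the
fourteen metabolic ticks in between pose the identical LP and the cached
solution is reused without refactorizing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import linprog

from .core_model import (
    FluxSolution,
    ModelError,
    Objective,
    ObjectiveSense,
    SolveStatus,
    StoichiometricModel,
)

__all__ = ["BoundsOverlay", "FbaSolver", "solve_fba", "check_solution", "SolutionReport"]

LP_TOLERANCE = 1e-9
VERIFY_TOLERANCE = 1e-6


class BoundsOverlay(dict):
    """reaction-id -> (lb, ub) overrides applied on top of model defaults.

    Composing two overlays takes the intersection (tightest bounds win).
    """

    def __init__(self, mapping: Mapping[str, tuple[float, float]] | None = None):
        super().__init__()
        if mapping:
            for rxn_id, (lb, ub) in mapping.items():
                self.set_bounds(rxn_id, lb, ub)

    def set_bounds(self, rxn_id: str, lb: float, ub: float) -> None:
        if lb > ub:
            raise ModelError(f"overlay for {rxn_id!r}: lb {lb} > ub {ub}")
        self[rxn_id] = (float(lb), float(ub))

    def tighten(self, rxn_id: str, lb: float, ub: float) -> None:
        """Intersect with existing bounds for this reaction."""

        if rxn_id in self:
            lb0, ub0 = self[rxn_id]
            lb, ub = max(lb, lb0), min(ub, ub0)
        if lb > ub:
            raise ModelError(
                f"overlay composition for {rxn_id!r} is empty: ({lb}, {ub})"
            )
        self[rxn_id] = (float(lb), float(ub))

    def merged(self, other: "BoundsOverlay") -> "BoundsOverlay":
        out = BoundsOverlay(self)
        for rxn_id, (lb, ub) in other.items():
            out.tighten(rxn_id, lb, ub)
        return out


def _effective_bounds(
    model: StoichiometricModel, overlay: Mapping[str, tuple[float, float]] | None
) -> tuple[np.ndarray, np.ndarray]:
    lb, ub = model.bounds_arrays()
    if overlay:
        for rxn_id, (lo, hi) in overlay.items():
            j = model.reaction_index(rxn_id)
            lb[j], ub[j] = lo, hi
            if lo > hi:
                raise ModelError(f"overlay for {rxn_id!r}: lb {lo} > ub {hi}")
    return lb, ub


@dataclass
class FbaSolver:
    """FBA solver bound to one model, with an LP memo across calls.

    The memo key is (objective identity, effective bounds); hit counting is
    exposed so callers can verify how many distinct LPs a simulation posed.
    """

    model: StoichiometricModel
    parsimonious: bool = True
    lp_tolerance: float = LP_TOLERANCE
    n_calls: int = 0
    n_lp_solves: int = 0
    _memo: dict = field(default_factory=dict, repr=False)

    def solve(
        self,
        objective: Objective,
        overlay: Mapping[str, tuple[float, float]] | None = None,
    ) -> FluxSolution:
        self.n_calls += 1
        lb, ub = _effective_bounds(self.model, overlay)
        key = (id(objective), lb.tobytes(), ub.tobytes())
        cached = self._memo.get(key)
        if cached is not None:
            return cached
        solution = self._solve_uncached(objective, lb, ub)
        self._memo[key] = solution
        return solution

    def _solve_uncached(
        self, objective: Objective, lb: np.ndarray, ub: np.ndarray
    ) -> FluxSolution:
        model = self.model
        c = objective.vector(model)
        sense = 1.0 if objective.sense is ObjectiveSense.MINIMIZE else -1.0
        n = model.n
        bounds = list(zip(lb, ub))
        self.n_lp_solves += 1
        res = linprog(
            sense * c,
            A_eq=model.S,
            b_eq=np.zeros(model.m),
            bounds=bounds,
            method="highs",
            options={"primal_feasibility_tolerance": self.lp_tolerance,
                     "dual_feasibility_tolerance": self.lp_tolerance},
        )
        if res.status == 2:
            return _infeasible_solution(model, _infeasibility_report(model, lb, ub))
        if res.status == 3:
            direction = model.reactions[int(np.argmax(np.abs(c)))].id
            return _unbounded_solution(model, direction)
        if res.status != 0:
            raise ModelError(f"LP solver failure: {res.message}")
        # res.fun is on the minimized scale; undo the sense flip
        objective_value = float(-res.fun) if sense < 0 else float(res.fun)
        v = res.x
        if self.parsimonious:
            v = self._parsimonious_refit(c, sense, objective_value, lb, ub)
        fluxes = {r.id: float(v[j]) for j, r in enumerate(model.reactions)}
        return FluxSolution(
            fluxes=fluxes,
            objective_value=objective_value,
            status=SolveStatus.OPTIMAL,
        )

    def _parsimonious_refit(
        self,
        c: np.ndarray,
        sense: float,
        objective_value: float,
        lb: np.ndarray,
        ub: np.ndarray,
    ) -> np.ndarray:
        """Fix the objective at its optimum, minimize sum |v|.

        Standard split-variable formulation: v = p - q with p, q >= 0 and
        minimize 1'(p+q).  The objective is pinned with a two-sided
        constraint at a small relative tolerance so the refit LP is never
        artificially infeasible.
        """

        model = self.model
        n = model.n
        m = model.m
        # variables: p (n), q (n)
        A_eq = np.hstack([model.S, -model.S])
        b_eq = np.zeros(m)
        eps = 1e-9 * max(1.0, abs(objective_value))
        # sense*c'v <= sense*objective_value is the optimal face; enforce both sides
        A_ub = np.vstack([
            np.hstack([c, -c]),
            np.hstack([-c, c]),
        ])
        b_ub = np.array([objective_value + eps, -(objective_value - eps)])
        bounds = (
            [(max(0.0, l), max(0.0, u)) for l, u in zip(lb, ub)]
            + [(max(0.0, -u), max(0.0, -l)) for l, u in zip(lb, ub)]
        )
        self.n_lp_solves += 1
        res = linprog(
            np.ones(2 * n),
            A_eq=A_eq,
            b_eq=b_eq,
            A_ub=A_ub,
            b_ub=b_ub,
            bounds=bounds,
            method="highs",
        )
        if res.status != 0:
            raise ModelError(f"parsimonious refit failed: {res.message}")
        return res.x[:n] - res.x[n:]


def _infeasible_solution(model: StoichiometricModel, report: str) -> FluxSolution:
    sol = FluxSolution(
        fluxes={r.id: float("nan") for r in model.reactions},
        objective_value=float("nan"),
        status=SolveStatus.INFEASIBLE,
    )
    object.__setattr__(sol, "infeasibility_report", report)
    return sol


def _unbounded_solution(model: StoichiometricModel, direction: str) -> FluxSolution:
    sol = FluxSolution(
        fluxes={r.id: float("nan") for r in model.reactions},
        objective_value=float("inf"),
        status=SolveStatus.UNBOUNDED,
    )
    object.__setattr__(sol, "unbounded_direction", direction)
    return sol


def _infeasibility_report(
    model: StoichiometricModel, lb: np.ndarray, ub: np.ndarray
) -> str:
    """Name constraints that pin fluxes away from zero (the usual culprits).

    S v = 0 with v = 0 is feasible whenever every bound interval contains 0,
    so infeasibility implies some forced-nonzero bound interacts badly with
    mass balance; we report those reactions.
    """

    forced = [
        model.reactions[j].id
        for j in range(model.n)
        if lb[j] > 0 or ub[j] < 0
    ]
    if forced:
        return (
            "LP infeasible; reactions with bounds excluding zero flux: "
            + ", ".join(forced)
        )
    return "LP infeasible (no obvious forced-nonzero bound; check overlays)"


def solve_fba(
    model: StoichiometricModel,
    objective: Objective,
    overlay: Mapping[str, tuple[float, float]] | None = None,
    parsimonious: bool = True,
) -> FluxSolution:
    """One-shot FBA solve (convenience wrapper around :class:`FbaSolver`)."""

    return FbaSolver(model, parsimonious=parsimonious).solve(objective, overlay)


@dataclass(frozen=True)
class SolutionReport:
    """Residuals and bound violations for one flux solution."""

    max_residual: float
    residuals: Mapping[str, float]
    bound_violations: Mapping[str, float]

    @property
    def ok(self) -> bool:
        return not self.bound_violations and self.max_residual <= self._tol

    _tol: float = VERIFY_TOLERANCE


def check_solution(
    model: StoichiometricModel,
    solution: FluxSolution,
    tol: float = VERIFY_TOLERANCE,
    overlay: Mapping[str, tuple[float, float]] | None = None,
) -> SolutionReport:
    """Verify S v = 0 and bound satisfaction within ``tol``."""

    if solution.status is not SolveStatus.OPTIMAL:
        raise ModelError("check_solution expects an optimal solution")
    v = np.array([solution.fluxes[r.id] for r in model.reactions])
    residual_vec = model.S @ v
    residuals = {
        model.metabolites[i].id: float(residual_vec[i])
        for i in np.flatnonzero(np.abs(residual_vec) > tol)
    }
    lb, ub = _effective_bounds(model, overlay)
    violations: dict[str, float] = {}
    for j, rxn in enumerate(model.reactions):
        excess = max(lb[j] - v[j], v[j] - ub[j])
        if excess > tol:
            violations[rxn.id] = float(excess)
    return SolutionReport(
        max_residual=float(np.max(np.abs(residual_vec))),
        residuals=residuals,
        bound_violations=violations,
        _tol=tol,
    )
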