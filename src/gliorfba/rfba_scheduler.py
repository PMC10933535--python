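"""The integrated rFBA loop: fast metabolic ticks nested in slow regulatory ticks.

Each regulatory tick (``dt_reg``, default 1):

1. read the current metabolite pools;
2. advance the Boolean network one synchronous step against those pools;
3. derive the bounds overlay from the regulatory links (an active controller
   switches its target reaction off; an inactive one restores defaults);
4. run ``floor(dt_reg / dt_met)`` metabolic ticks (14 with the defaults),
   each solving FBA under the current overlay and integrating the pools:
   ``conc <- max(0, conc + pool_scale * dt_met * sum(sign * flux))``.

Reads-then-acts ordering avoids same-tick circularity between the two
layers; the 0.02 remainder of 1 / 0.07 is dropped.  Everything is
deterministic given the inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .boolean_engine import evaluate_expr, synchronous_step
from .core_model import (
    BooleanNetwork,
    FluxSolution,
    InactivePolicy,
    MetabolitePool,
    ModelError,
    Objective,
    RegulatoryLink,
    SimulationConfig,
    SolveStatus,
    StoichiometricModel,
    Trajectory,
)
from .fba_engine import BoundsOverlay, FbaSolver

__all__ = [
    "ScenarioCondition",
    "pool_update",
    "apply_regulatory_constraints",
    "run_simulation",
]


@dataclass
class ScenarioCondition:
    """One growth condition: objective + condition-specific bound restrictions.

    The glioma condition maximizes the Growth_Glioma pseudo-reaction
    (combined OAA/GSH/succinate output); the astrocyte condition maximizes
    ATP-synthase flux.  ``bounds_overlay`` carries the condition-specific
    reaction restrictions and ``input_states`` overrides input-node states.
    """

    name: str
    objective: Objective
    bounds_overlay: BoundsOverlay = field(default_factory=BoundsOverlay)
    input_states: dict[str, int] = field(default_factory=dict)


def pool_update(
    pools: Sequence[MetabolitePool],
    solution: FluxSolution,
    dt_met: float,
    scale: float = 1.0,
) -> list[str]:
    """Integrate pool concentrations one metabolic tick (in place).

    Each pool moves by ``scale * dt_met * sum(sign * flux)`` over its coupled
    transport reactions and is clamped at zero.  Returns labels for pools
    that clamped this tick so the caller can log them as events.
    """

    if solution.status is not SolveStatus.OPTIMAL:
        raise ModelError("pool_update requires an optimal flux solution")
    clamped: list[str] = []
    for pool in pools:
        if not pool.coupled_transport_reactions:
            continue
        rate = 0.0
        for rxn_id, sign in pool.coupled_transport_reactions:
            rate += sign * solution.fluxes[rxn_id]
        new_conc = pool.concentration + scale * dt_met * rate
        if new_conc < 0.0:
            new_conc = 0.0
            clamped.append(pool.metabolite_id)
        pool.concentration = new_conc
    return clamped


def apply_regulatory_constraints(
    links: Sequence[RegulatoryLink],
    state: Mapping[str, int],
    model: StoichiometricModel,
    pools: Mapping[str, float] | None = None,
) -> BoundsOverlay:
    """Derive the bounds overlay imposed by the signalling state.

    A link whose controller evaluates TRUE switches its target reaction off
    (zeroed or scaled bounds); FALSE leaves the default bounds untouched.
    Multiple links on one reaction compose by intersection.
    """

    overlay = BoundsOverlay()
    for link in links:
        if not model.has_reaction(link.target_reaction_id):
            raise ModelError(
                f"regulatory link targets unknown reaction "
                f"{link.target_reaction_id!r}"
            )
        if evaluate_expr(link.controller, state, pools):
            rxn = model.reaction(link.target_reaction_id)
            if link.inactive_policy is InactivePolicy.ZERO_BOUNDS:
                overlay.tighten(rxn.id, 0.0, 0.0)
            else:
                overlay.tighten(
                    rxn.id, rxn.lb * link.scale_factor, rxn.ub * link.scale_factor
                )
    return overlay


def run_simulation(
    model: StoichiometricModel,
    network: BooleanNetwork,
    pools: Sequence[MetabolitePool],
    links: Sequence[RegulatoryLink],
    condition: ScenarioCondition,
    config: SimulationConfig,
    solver: FbaSolver | None = None,
) -> Trajectory:
    """Run the full two-timescale simulation and record every metabolic tick."""

    if solver is None:
        solver = FbaSolver(model, lp_tolerance=config.lp_tolerance)
    network = _with_condition_inputs(network, condition)
    pools = [
        MetabolitePool(
            p.metabolite_id,
            p.initial_concentration,
            coupled_transport_reactions=list(p.coupled_transport_reactions),
        )
        for p in pools
    ]
    pool_map = {p.metabolite_id: p for p in pools}

    trajectory = Trajectory()
    state = network.initial_state()
    ticks_per_reg = config.met_ticks_per_reg_tick
    prev_overlay_key: tuple | None = None
    time = 0.0

    # perturbation edits beat the condition overlay on the edited reactions
    perturbed = getattr(model, "perturbed_reaction_ids", set())
    condition_overlay = BoundsOverlay(
        {r: b for r, b in condition.bounds_overlay.items() if r not in perturbed}
    )

    for reg_step in range(config.n_steps):
        pool_view = {m: p.concentration for m, p in pool_map.items()}
        state = synchronous_step(network, state, pool_view)
        reg_overlay = apply_regulatory_constraints(links, state, model, pool_view)
        # a firing link replaces the condition's bounds for its target:
        # the regulatory switch governs the reaction outright
        overlay = BoundsOverlay(condition_overlay)
        overlay.update(reg_overlay)
        overlay_key = tuple(sorted(overlay.items()))
        if overlay_key != prev_overlay_key and reg_step > 0:
            trajectory.log_event(time, f"bounds switch: {_overlay_label(reg_overlay)}")
        prev_overlay_key = overlay_key

        for _ in range(ticks_per_reg):
            solution = solver.solve(condition.objective, overlay)
            if solution.status is not SolveStatus.OPTIMAL:
                if config.on_infeasible == "zero-fluxes" and (
                    solution.status is SolveStatus.INFEASIBLE
                ):
                    solution = FluxSolution(
                        fluxes={r.id: 0.0 for r in model.reactions},
                        objective_value=0.0,
                        status=SolveStatus.OPTIMAL,
                    )
                    trajectory.log_event(time, "infeasible LP: zero-flux fallback")
                else:
                    report = getattr(solution, "infeasibility_report", "")
                    raise ModelError(
                        f"FBA {solution.status.value} at t={time:.2f}"
                        + (f": {report}" if report else "")
                    )
            clamped = pool_update(pools, solution, config.dt_met, config.pool_scale)
            for met in clamped:
                trajectory.log_event(time, f"pool clamped at 0: {met}")
            time += config.dt_met
            trajectory.record(
                time,
                reg_step,
                state,
                solution,
                {m: p.concentration for m, p in pool_map.items()},
            )
    return trajectory


def _with_condition_inputs(
    network: BooleanNetwork, condition: ScenarioCondition
) -> BooleanNetwork:
    if not condition.input_states:
        return network
    unknown = set(condition.input_states) - set(network.input_states)
    if unknown:
        raise ModelError(
            f"condition {condition.name!r} sets non-input nodes: {sorted(unknown)}"
        )
    merged = dict(network.input_states)
    merged.update(condition.input_states)
    return BooleanNetwork(list(network.nodes), dict(network.rules), merged)


def _overlay_label(overlay: BoundsOverlay) -> str:
    if not overlay:
        return "all links inactive"
    return ", ".join(f"{r}->({lb:g},{ub:g})" for r, (lb, ub) in sorted(overlay.items()))
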