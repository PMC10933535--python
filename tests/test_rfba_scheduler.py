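"""The integrated loop: pool integration, bound switching, bookkeeping."""

import numpy as np
import pytest

from gliorfba.boolean_engine import synchronous_step
from gliorfba.core_model import (
    BooleanNetwork,
    FluxSolution,
    InactivePolicy,
    Metabolite,
    MetabolitePool,
    ModelError,
    NodeRef,
    Objective,
    Reaction,
    RegulatoryLink,
    SimulationConfig,
    SolveStatus,
    StoichiometricModel,
)
from gliorfba.fba_engine import FbaSolver
from gliorfba.rfba_scheduler import (
    ScenarioCondition,
    apply_regulatory_constraints,
    pool_update,
    run_simulation,
)


def _solution(**fluxes):
    return FluxSolution(fluxes=fluxes, objective_value=0.0, status=SolveStatus.OPTIMAL)


class TestPoolUpdate:
    def test_uncoupled_pool_is_constant(self):
        pool = MetabolitePool("X", 1.0)
        pool_update([pool], _solution(R=5.0), dt_met=0.07)
        assert pool.concentration == 1.0

    def test_uptake_drain_with_default_dt(self):
        """A unit uptake flux with sign -1 drains 0.07 mM per metabolic tick."""

        pool = MetabolitePool(
            "Glucose_T", 1.0, coupled_transport_reactions=[("GLCup", -1.0)]
        )
        pool_update([pool], _solution(GLCup=1.0), dt_met=0.07, scale=1.0)
        assert pool.concentration == pytest.approx(0.93)

    def test_clamping_at_zero_is_reported(self):
        pool = MetabolitePool(
            "X", 0.05, coupled_transport_reactions=[("R", -1.0)]
        )
        clamped = pool_update([pool], _solution(R=1.0), dt_met=1.0)
        assert pool.concentration == 0.0
        assert clamped == ["X"]


def _tiny_model():
    mets = [Metabolite(id="A", name="A"), Metabolite(id="B", name="B")]
    rxns = [
        Reaction(id="EX_A", stoichiometry={"A": 1}, lb=0, ub=4),
        Reaction(id="FAT", stoichiometry={"A": -1, "B": 1}, lb=0, ub=1000),
        Reaction(id="EX_B", stoichiometry={"B": -1}, lb=0, ub=1000),
    ]
    return StoichiometricModel(mets, rxns)


class TestApplyRegulatoryConstraints:
    def test_active_controller_zeroes_bounds(self):
        model = _tiny_model()
        link = RegulatoryLink(target_reaction_id="FAT", controller=NodeRef("AMPK"))
        overlay = apply_regulatory_constraints([link], {"AMPK": 1}, model)
        assert overlay["FAT"] == (0.0, 0.0)

    def test_inactive_controller_restores_defaults(self):
        model = _tiny_model()
        link = RegulatoryLink(target_reaction_id="FAT", controller=NodeRef("AMPK"))
        overlay = apply_regulatory_constraints([link], {"AMPK": 0}, model)
        assert "FAT" not in overlay

    def test_two_links_intersect(self):
        model = _tiny_model()
        links = [
            RegulatoryLink("FAT", NodeRef("X"), InactivePolicy.SCALE, 0.5),
            RegulatoryLink("FAT", NodeRef("Y"), InactivePolicy.SCALE, 0.25),
        ]
        overlay = apply_regulatory_constraints(links, {"X": 1, "Y": 1}, model)
        assert overlay["FAT"] == (0.0, 250.0)

    def test_unknown_target_rejected(self):
        model = _tiny_model()
        link = RegulatoryLink("GONE", NodeRef("X"))
        with pytest.raises(ModelError, match="GONE"):
            apply_regulatory_constraints([link], {"X": 1}, model)


def _tiny_condition():
    return ScenarioCondition(
        name="toy", objective=Objective("maxB", {"EX_B": 1.0})
    )


def _decoupled_network():
    return BooleanNetwork(
        nodes=["i", "x"],
        rules={"x": NodeRef("i")},
        input_states={"i": 1},
    )


class TestRunSimulation:
    def test_time_bookkeeping(self):
        """n_steps regulatory ticks produce floor(dt_reg/dt_met) = 14
        metabolic ticks each with the default time scales."""

        config = SimulationConfig(n_steps=5)
        assert config.met_ticks_per_reg_tick == 14
        traj = run_simulation(
            _tiny_model(), _decoupled_network(), [], [], _tiny_condition(), config
        )
        assert len(traj) == 5 * 14
        assert traj.times[-1] == pytest.approx(5 * 14 * 0.07)

    def test_decoupled_limit_matches_plain_boolean_dynamics(self):
        """Without predicates or links, the Boolean layer evolves exactly as
        the standalone engine and the fluxes never change."""

        net = _decoupled_network()
        traj = run_simulation(
            _tiny_model(), net, [], [], _tiny_condition(),
            SimulationConfig(n_steps=6),
        )
        state = net.initial_state()
        for reg_state in traj.regulatory_states():
            state = synchronous_step(net, state)
            assert reg_state == state
        flux_matrix = np.array(
            [[sol.fluxes[r.id] for r in _tiny_model().reactions]
             for sol in traj.fluxes]
        )
        assert np.all(flux_matrix == flux_matrix[0])

    def test_link_switches_flux_after_pool_crossing(self):
        """Once the pool drops below threshold the controller fires and the
        target reaction's flux is zero from the next metabolic tick on."""

        from gliorfba.model_io import parse_rule

        net = BooleanNetwork(
            nodes=["AMPK_T"],
            rules={"AMPK_T": parse_rule("not((Glucose_T)>=0.5)")},
            input_states={},
        )
        pools = [
            MetabolitePool(
                "Glucose_T", 1.0,
                coupled_transport_reactions=[("EX_B", -1.0)],
            )
        ]
        link = RegulatoryLink("FAT", NodeRef("AMPK_T"))
        config = SimulationConfig(n_steps=4, pool_scale=1.0)
        traj = run_simulation(
            _tiny_model(), net, pools, [link], _tiny_condition(), config
        )
        fat = traj.flux_series("FAT")
        ampk = np.array([s["AMPK_T"] for s in traj.boolean_states])
        # the pool drains at 4 flux * 0.07 per tick, crossing 0.5 during the
        # second regulatory tick; AMPK fires at the third
        assert ampk[0] == 0 and ampk[-1] == 1
        assert np.all(fat[ampk == 1] == 0.0)
        assert np.all(fat[ampk == 0] > 0.0)
        assert any("bounds switch" in label for _, label in traj.events)

    def test_replay_is_bit_identical(self, bundle):
        from gliorfba.exemplar_builder import exemplar_config

        runs = []
        for _ in range(2):
            traj = run_simulation(
                bundle.model, bundle.network, bundle.pools, bundle.links,
                bundle.condition("glioma"), exemplar_config("glioma", n_steps=40),
            )
            runs.append(traj)
        assert runs[0].pools == runs[1].pools
        assert runs[0].boolean_states == runs[1].boolean_states
        assert [s.fluxes for s in runs[0].fluxes] == [s.fluxes for s in runs[1].fluxes]

    def test_frozen_pools_reduce_to_constant_bounds_fba(self, bundle):
        """With pools pinned far above every threshold the run is plain
        Boolean dynamics plus one constant-bounds FBA solution."""

        from gliorfba.exemplar_builder import exemplar_config

        rich_pools = [
            MetabolitePool(p.metabolite_id, 100.0)  # uncoupled: constant
            for p in bundle.pools
        ]
        traj = run_simulation(
            bundle.model, bundle.network, rich_pools, bundle.links,
            bundle.condition("glioma"), exemplar_config("glioma", n_steps=20),
        )
        flux0 = traj.fluxes[0].fluxes
        assert all(sol.fluxes == flux0 for sol in traj.fluxes)
        assert all(p == traj.pools[0] for p in traj.pools)

    def test_infeasible_zero_flux_fallback(self):
        model = _tiny_model()
        condition = ScenarioCondition(
            name="broken",
            objective=Objective("maxB", {"EX_B": 1.0}),
        )
        condition.bounds_overlay.set_bounds("EX_A", 0.0, 0.0)
        condition.bounds_overlay.set_bounds("EX_B", 2.0, 3.0)
        config = SimulationConfig(n_steps=2, on_infeasible="zero-fluxes")
        traj = run_simulation(
            model, _decoupled_network(), [], [], condition, config
        )
        assert all(v == 0.0 for v in traj.fluxes[0].fluxes.values())
        assert any("infeasible" in label for _, label in traj.events)
        with pytest.raises(ModelError, match="infeasible"):
            run_simulation(
                model, _decoupled_network(), [], [], condition,
                SimulationConfig(n_steps=2),
            )
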