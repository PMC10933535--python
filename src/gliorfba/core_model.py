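"""Core domain types for the multicellular metabolic-signalling model.

The model couples a stoichiometric metabolic network (glioma, T-cell,
macrophage, plus a shared extracellular compartment) with a Boolean
signalling network.  Metabolic state is a flux vector ``v`` satisfying the
steady-state mass balance ``S v = 0`` within per-reaction bounds; signalling
state is a vector of 0/1 node activities updated synchronously.  The two
layers talk through (i) threshold predicates on metabolite pools that appear
as leaves of Boolean rules and (ii) regulatory links that switch reaction
bounds off while a controlling Boolean expression is active.

Naming follows the cell-suffix convention of the underlying model:
``_C`` glioma (lower-case ``_c`` in a few historical metabolite names such
as ``OAA_c``), ``_T`` T-cell, ``_M1`` / ``_M2`` macrophage, ``_EXT`` the
shared extracellular space.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "CellTag",
    "Comparator",
    "Metabolite",
    "Reaction",
    "StoichiometricModel",
    "Objective",
    "ObjectiveSense",
    "SolveStatus",
    "FluxSolution",
    "ThresholdPredicate",
    "NodeRef",
    "Const",
    "Not",
    "And",
    "Or",
    "BooleanExpr",
    "BooleanNetwork",
    "MetabolitePool",
    "RegulatoryLink",
    "InactivePolicy",
    "SimulationConfig",
    "Trajectory",
    "ModelError",
    "build_stoichiometric_matrix",
    "default_bounds",
    "DEFAULT_CAPACITY",
]

#: Default flux capacity (arbitrary flux units) applied when a reaction table
#: leaves bounds blank: reversible reactions get (-1000, 1000).
DEFAULT_CAPACITY = 1000.0

#: Tolerance for coefficient equality checks.
COEFF_TOL = 1e-9


class ModelError(ValueError):
    """Raised when a model component violates a structural invariant."""


class CellTag(str, enum.Enum):
    """Which cell a metabolite/reaction belongs to; EXT is shared space."""

    C = "C"      # glioma (astrocyte under the normal condition)
    T = "T"      # T-cell
    M1 = "M1"    # macrophage (pro-inflammatory program)
    M2 = "M2"    # macrophage (anti-inflammatory program)
    EXT = "EXT"  # shared extracellular compartment


_SUFFIX_TO_TAG = {
    "_c": CellTag.C,
    "_C": CellTag.C,
    "_T": CellTag.T,
    "_M1": CellTag.M1,
    "_M2": CellTag.M2,
    "_EXT": CellTag.EXT,
}


def _suffix_tag(identifier: str) -> CellTag | None:
    for suffix in ("_EXT", "_M1", "_M2", "_T", "_c", "_C"):
        if identifier.endswith(suffix):
            return _SUFFIX_TO_TAG[suffix]
    return None


@dataclass(frozen=True)
class Metabolite:
    """A named metabolite in one cellular compartment.

    EXT metabolites are the only species shared between cells; all
    cross-feeding goes through them.
    """

    id: str
    name: str = ""
    cell_tag: CellTag = CellTag.EXT
    exchangeable: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelError("metabolite id must be non-empty")
        tag = _suffix_tag(self.id)
        if tag is not None and tag is not self.cell_tag:
            warnings.warn(
                f"metabolite {self.id!r}: suffix suggests {tag.value} "
                f"but cell_tag is {self.cell_tag.value}",
                stacklevel=2,
            )


@dataclass(frozen=True)
class Reaction:
    """A reaction column: signed stoichiometry plus flux bounds.

    Coefficients are negative for consumed species and positive for produced
    ones.  ``is_exchange`` marks reactions that move matter across the system
    boundary or between a cell and the EXT compartment.
    """

    id: str
    stoichiometry: Mapping[str, float]
    lb: float
    ub: float
    reversible: bool = False
    cell_tag: CellTag = CellTag.EXT
    pathway_tag: str = ""
    is_exchange: bool = False

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ModelError(f"reaction {self.id!r}: empty stoichiometry")
        if self.lb > self.ub:
            raise ModelError(
                f"reaction {self.id!r}: lb {self.lb} > ub {self.ub}"
            )
        if not self.reversible and self.lb < 0 < self.ub:
            raise ModelError(
                f"reaction {self.id!r}: irreversible but bounds straddle 0 "
                f"({self.lb}, {self.ub})"
            )


def default_bounds(reversible: bool, backward: bool = False) -> tuple[float, float]:
    """Default capacity bounds for a reaction.

    Reversible reactions get (-1000, 1000); irreversible forward (0, 1000);
    irreversible backward (-1000, 0).
    """

    if reversible:
        return (-DEFAULT_CAPACITY, DEFAULT_CAPACITY)
    if backward:
        return (-DEFAULT_CAPACITY, 0.0)
    return (0.0, DEFAULT_CAPACITY)


class StoichiometricModel:
    """The stoichiometric matrix S (metabolites x reactions) plus metadata."""

    def __init__(
        self,
        metabolites: Sequence[Metabolite],
        reactions: Sequence[Reaction],
        S: np.ndarray | None = None,
    ) -> None:
        self.metabolites = list(metabolites)
        self.reactions = list(reactions)
        if not self.metabolites or not self.reactions:
            raise ModelError("model must have at least one metabolite and reaction")
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dupes = sorted({i for i in met_ids if met_ids.count(i) > 1})
            raise ModelError(f"duplicate metabolite ids: {dupes}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dupes = sorted({i for i in rxn_ids if rxn_ids.count(i) > 1})
            raise ModelError(f"duplicate reaction ids: {dupes}")
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: j for j, r in enumerate(self.reactions)}
        if S is None:
            S = _stoich_matrix(self.reactions, self._met_index)
        self.S = S

    # -- lookups ---------------------------------------------------------

    @property
    def m(self) -> int:
        return len(self.metabolites)

    @property
    def n(self) -> int:
        return len(self.reactions)

    def metabolite_index(self, met_id: str) -> int:
        try:
            return self._met_index[met_id]
        except KeyError:
            raise ModelError(f"unknown metabolite id {met_id!r}") from None

    def reaction_index(self, rxn_id: str) -> int:
        try:
            return self._rxn_index[rxn_id]
        except KeyError:
            raise ModelError(f"unknown reaction id {rxn_id!r}") from None

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self.reaction_index(rxn_id)]

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lb for r in self.reactions], dtype=float)
        ub = np.array([r.ub for r in self.reactions], dtype=float)
        return lb, ub

    def copy(self) -> "StoichiometricModel":
        return StoichiometricModel(list(self.metabolites), list(self.reactions))

    def __repr__(self) -> str:
        return f"StoichiometricModel(m={self.m}, n={self.n})"


def _stoich_matrix(
    reactions: Sequence[Reaction], met_index: Mapping[str, int]
) -> np.ndarray:
    S = np.zeros((len(met_index), len(reactions)))
    for j, rxn in enumerate(reactions):
        for met_id, coeff in rxn.stoichiometry.items():
            try:
                i = met_index[met_id]
            except KeyError:
                raise ModelError(
                    f"reaction {rxn.id!r} references unknown metabolite "
                    f"{met_id!r}"
                ) from None
            S[i, j] = coeff
    return S


def build_stoichiometric_matrix(
    reactions: Sequence[Reaction], metabolites: Sequence[Metabolite]
) -> StoichiometricModel:
    """Assemble the m x n matrix S from reaction stoichiometries.

    Column order follows the reaction list, row order the metabolite list.
    Metabolites never referenced by any reaction give all-zero rows, which is
    legal but usually a curation slip, so a warning is emitted.
    """

    model = StoichiometricModel(metabolites, reactions)
    zero_rows = np.flatnonzero(~np.any(model.S != 0.0, axis=1))
    if zero_rows.size:
        names = [model.metabolites[i].id for i in zero_rows]
        warnings.warn(f"metabolites unused by any reaction: {names}", stacklevel=2)
    return model


class ObjectiveSense(str, enum.Enum):
    MAXIMIZE = "maximize"
    MINIMIZE = "minimize"


@dataclass(frozen=True)
class Objective:
    """A linear objective over reaction fluxes."""

    name: str
    coefficients: Mapping[str, float]
    sense: ObjectiveSense = ObjectiveSense.MAXIMIZE

    def __post_init__(self) -> None:
        if not any(abs(w) > COEFF_TOL for w in self.coefficients.values()):
            raise ModelError(f"objective {self.name!r} has no nonzero weight")

    def vector(self, model: StoichiometricModel) -> np.ndarray:
        c = np.zeros(model.n)
        for rxn_id, weight in self.coefficients.items():
            c[model.reaction_index(rxn_id)] = weight
        return c


class SolveStatus(str, enum.Enum):
    OPTIMAL = "optimal"
    INFEASIBLE = "infeasible"
    UNBOUNDED = "unbounded"


@dataclass(frozen=True)
class FluxSolution:
    """Result of one FBA solve."""

    fluxes: Mapping[str, float]
    objective_value: float
    status: SolveStatus

    def flux(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]


class Comparator(str, enum.Enum):
    GT = ">"
    GE = ">="


# ---------------------------------------------------------------------------
# Boolean expressions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdPredicate:
    """Leaf comparing a metabolite pool concentration to a cutoff (mM).

    GE is true at the threshold exactly; GT is false there.
    """

    metabolite_id: str
    comparator: Comparator
    threshold: float

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ModelError(
                f"predicate on {self.metabolite_id!r}: negative threshold"
            )

    def evaluate(self, concentration: float) -> bool:
        if self.comparator is Comparator.GE:
            return concentration >= self.threshold
        return concentration > self.threshold


@dataclass(frozen=True)
class NodeRef:
    node_id: str


@dataclass(frozen=True)
class Const:
    value: bool


@dataclass(frozen=True)
class Not:
    operand: "BooleanExpr"


@dataclass(frozen=True)
class And:
    operands: tuple["BooleanExpr", ...]


@dataclass(frozen=True)
class Or:
    operands: tuple["BooleanExpr", ...]


BooleanExpr = NodeRef | Const | Not | And | Or | ThresholdPredicate


def expr_node_refs(expr: BooleanExpr) -> set[str]:
    """All signalling-node ids referenced by an expression tree."""

    if isinstance(expr, NodeRef):
        return {expr.node_id}
    if isinstance(expr, Not):
        return expr_node_refs(expr.operand)
    if isinstance(expr, (And, Or)):
        out: set[str] = set()
        for op in expr.operands:
            out |= expr_node_refs(op)
        return out
    return set()


def expr_pool_refs(expr: BooleanExpr) -> set[str]:
    """All metabolite-pool ids referenced by threshold predicates."""

    if isinstance(expr, ThresholdPredicate):
        return {expr.metabolite_id}
    if isinstance(expr, Not):
        return expr_pool_refs(expr.operand)
    if isinstance(expr, (And, Or)):
        out: set[str] = set()
        for op in expr.operands:
            out |= expr_pool_refs(op)
        return out
    return set()


@dataclass
class BooleanNetwork:
    """Synchronous Boolean network with clamped input nodes.

    Input nodes (no upstream regulation) carry fixed states; every other
    node has exactly one update rule.
    """

    nodes: list[str]
    rules: dict[str, BooleanExpr]
    input_states: dict[str, int]

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise ModelError("duplicate node ids in network")
        node_set = set(self.nodes)
        for node in self.nodes:
            if node in self.input_states and node in self.rules:
                raise ModelError(f"input node {node!r} must not have a rule")
            if node not in self.input_states and node not in self.rules:
                raise ModelError(f"non-input node {node!r} lacks a rule")
        for node, expr in self.rules.items():
            if node not in node_set:
                raise ModelError(f"rule for undeclared node {node!r}")
            missing = expr_node_refs(expr) - node_set
            if missing:
                raise ModelError(
                    f"rule for {node!r} references unknown nodes: {sorted(missing)}"
                )
        for node, state in self.input_states.items():
            if node not in node_set:
                raise ModelError(f"input state for undeclared node {node!r}")
            if state not in (0, 1):
                raise ModelError(f"input state for {node!r} must be 0/1")

    @property
    def input_nodes(self) -> list[str]:
        return [n for n in self.nodes if n in self.input_states]

    def pool_refs(self) -> set[str]:
        out: set[str] = set()
        for expr in self.rules.values():
            out |= expr_pool_refs(expr)
        return out

    def initial_state(self) -> dict[str, int]:
        """Inputs at their fixed states, every other node inactive (0)."""

        return {
            n: self.input_states.get(n, 0) for n in self.nodes
        }


@dataclass
class MetabolitePool:
    """A bridging concentration between fluxes and threshold predicates.

    ``coupled_transport_reactions`` lists (reaction_id, sign) pairs; the
    pool's rate of change is the signed sum of those fluxes.
    """

    metabolite_id: str
    initial_concentration: float
    concentration: float | None = None
    coupled_transport_reactions: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.initial_concentration < 0:
            raise ModelError(
                f"pool {self.metabolite_id!r}: negative initial concentration"
            )
        if self.concentration is None:
            self.concentration = self.initial_concentration
        if self.concentration < 0:
            raise ModelError(f"pool {self.metabolite_id!r}: negative concentration")


class InactivePolicy(str, enum.Enum):
    ZERO_BOUNDS = "zero_bounds"
    SCALE = "scale"


@dataclass(frozen=True)
class RegulatoryLink:
    """A signalling-state -> reaction-bound constraint.

    While ``controller`` evaluates TRUE the target reaction's bounds are
    replaced according to ``inactive_policy`` (the gene product is switched
    *off* by the active controller, e.g. AMPK blocking fatty-acid transport);
    when the controller is FALSE the default bounds are restored.
    """

    target_reaction_id: str
    controller: BooleanExpr
    inactive_policy: InactivePolicy = InactivePolicy.ZERO_BOUNDS
    scale_factor: float = 0.0
    name: str = ""


@dataclass
class SimulationConfig:
    """Time-scale and solver settings for the integrated rFBA loop.

    Metabolism runs on fast ticks (``dt_met``), transcription/signalling on
    slow ticks (``dt_reg``); ``n_steps`` counts regulatory ticks.
    ``pool_scale`` converts flux units x time into concentration units (mM).
    """

    dt_met: float = 0.07
    dt_reg: float = 1.0
    n_steps: int = 2000
    lp_tolerance: float = 1e-9
    verification_tolerance: float = 1e-6
    pool_scale: float = 1.0
    condition: str = "glioma"
    seed: int = 0
    on_infeasible: str = "error"  # or "zero-fluxes"

    def __post_init__(self) -> None:
        if not self.dt_met < self.dt_reg:
            raise ModelError("dt_met must be smaller than dt_reg")
        if self.n_steps <= 0:
            raise ModelError("n_steps must be positive")
        if self.lp_tolerance <= 0 or self.verification_tolerance <= 0:
            raise ModelError("tolerances must be positive")

    @property
    def met_ticks_per_reg_tick(self) -> int:
        return int(self.dt_reg / self.dt_met)


@dataclass
class Trajectory:
    """Time-indexed record of Boolean states, fluxes and pool levels.

    Rows are metabolic ticks; regulatory ticks are flagged so that
    signalling readouts can be computed on the slow time base.
    """

    times: list[float] = field(default_factory=list)
    reg_steps: list[int] = field(default_factory=list)
    boolean_states: list[dict[str, int]] = field(default_factory=list)
    fluxes: list[FluxSolution] = field(default_factory=list)
    pools: list[dict[str, float]] = field(default_factory=list)
    events: list[tuple[float, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.times)

    def record(
        self,
        time: float,
        reg_step: int,
        state: Mapping[str, int],
        solution: FluxSolution,
        pools: Mapping[str, float],
    ) -> None:
        # References are stored as-is; callers hand over fresh objects.
        self.times.append(time)
        self.reg_steps.append(reg_step)
        self.boolean_states.append(state)  # type: ignore[arg-type]
        self.fluxes.append(solution)
        self.pools.append(dict(pools))

    def log_event(self, time: float, label: str) -> None:
        self.events.append((time, label))

    # regulatory-tick views -------------------------------------------------

    def regulatory_states(self) -> list[dict[str, int]]:
        """One Boolean state per regulatory tick (first metabolic tick of each)."""

        out: list[dict[str, int]] = []
        seen = -1
        for step, state in zip(self.reg_steps, self.boolean_states):
            if step != seen:
                out.append(state)
                seen = step
        return out

    def flux_series(self, rxn_id: str) -> np.ndarray:
        return np.array([sol.fluxes[rxn_id] for sol in self.fluxes])

    def pool_series(self, met_id: str) -> np.ndarray:
        return np.array([p[met_id] for p in self.pools])
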