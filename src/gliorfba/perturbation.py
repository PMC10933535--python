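"""The intervention scenarios, expressed as declarative model edits.

Three named scenarios are bundled, mirroring the in-silico screens the
framework was built for:

``succ_oaa``
    Modulate the macrophage-side exchange of the TCA intermediates
    succinate and oxaloacetate: the outward OAA exchange is closed (the
    recovery regime shows no OAA export) and the succinate exchange
    stoichiometry is rescaled.

``glutamate_block``
    Block glutamate uptake by the T-cell.

``ampk_glutamate``
    The glutamate block combined with enabling the AMPK regulatory link
    (``Pa_T = AMPK_T``): while AMPK_T is active the T-cell fatty-acid
    transport reaction is switched off.

Perturbations are pure: ``apply_perturbations`` returns edited copies and
never touches the originals, so an empty spec list is the identity and the
baseline trajectory is bit-reproducible.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

from .core_model import (
    ModelError,
    NodeRef,
    Reaction,
    RegulatoryLink,
    StoichiometricModel,
)

__all__ = [
    "PerturbationKind",
    "PerturbationSpec",
    "apply_perturbations",
    "scenario",
    "SCENARIO_NAMES",
]


class PerturbationKind(str, enum.Enum):
    BLOCK_REACTION = "block_reaction"
    SET_BOUNDS = "set_bounds"
    RESCALE_EXCHANGE_STOICH = "rescale_exchange_stoich"
    ADD_REG_LINK = "add_reg_link"


@dataclass(frozen=True)
class PerturbationSpec:
    """One declarative edit to the model or its regulatory links."""

    kind: PerturbationKind
    target: str
    parameters: tuple[float, ...] = ()
    link: RegulatoryLink | None = None

    def __post_init__(self) -> None:
        if self.kind is PerturbationKind.SET_BOUNDS:
            if len(self.parameters) != 2:
                raise ModelError("SET_BOUNDS needs (lb, ub)")
            lb, ub = self.parameters
            if lb > ub:
                raise ModelError(f"SET_BOUNDS on {self.target!r}: lb > ub")
        if self.kind is PerturbationKind.RESCALE_EXCHANGE_STOICH:
            if len(self.parameters) != 1 or self.parameters[0] <= 0:
                raise ModelError("RESCALE_EXCHANGE_STOICH needs a factor > 0")
        if self.kind is PerturbationKind.ADD_REG_LINK and self.link is None:
            raise ModelError("ADD_REG_LINK needs a RegulatoryLink")


def apply_perturbations(
    model: StoichiometricModel,
    links: Sequence[RegulatoryLink],
    specs: Sequence[PerturbationSpec],
) -> tuple[StoichiometricModel, list[RegulatoryLink]]:
    """Apply edits, returning (model', links'); originals are untouched."""

    by_target: dict[str, PerturbationKind] = {}
    for spec in specs:
        if spec.kind is PerturbationKind.ADD_REG_LINK:
            continue
        if spec.target in by_target:
            raise ModelError(
                f"conflicting perturbations on {spec.target!r} "
                f"({by_target[spec.target].value} vs {spec.kind.value})"
            )
        by_target[spec.target] = spec.kind

    reactions = {r.id: r for r in model.reactions}
    new_links = list(links)
    for spec in specs:
        if spec.kind is PerturbationKind.ADD_REG_LINK:
            assert spec.link is not None
            new_links.append(spec.link)
            continue
        if spec.target not in reactions:
            raise ModelError(f"perturbation targets unknown reaction {spec.target!r}")
        rxn = reactions[spec.target]
        if spec.kind is PerturbationKind.BLOCK_REACTION:
            reactions[spec.target] = _with_bounds(rxn, 0.0, 0.0)
        elif spec.kind is PerturbationKind.SET_BOUNDS:
            lb, ub = spec.parameters
            reactions[spec.target] = _with_bounds(rxn, lb, ub)
        elif spec.kind is PerturbationKind.RESCALE_EXCHANGE_STOICH:
            factor = spec.parameters[0]
            if not rxn.is_exchange:
                raise ModelError(
                    f"RESCALE_EXCHANGE_STOICH on non-exchange reaction {rxn.id!r}"
                )
            scaled = {m: c * factor for m, c in rxn.stoichiometry.items()}
            reactions[spec.target] = Reaction(
                id=rxn.id,
                stoichiometry=scaled,
                lb=rxn.lb,
                ub=rxn.ub,
                reversible=rxn.reversible,
                cell_tag=rxn.cell_tag,
                pathway_tag=rxn.pathway_tag,
                is_exchange=rxn.is_exchange,
            )
    new_model = StoichiometricModel(
        list(model.metabolites), [reactions[r.id] for r in model.reactions]
    )
    # record which reactions were edited so schedulers give the perturbed
    # bounds precedence over condition overlays for those reactions
    edited = set(by_target) | set(
        getattr(model, "perturbed_reaction_ids", set())
    )
    new_model.perturbed_reaction_ids = edited
    return new_model, new_links


def _with_bounds(rxn: Reaction, lb: float, ub: float) -> Reaction:
    return Reaction(
        id=rxn.id,
        stoichiometry=rxn.stoichiometry,
        lb=lb,
        ub=ub,
        reversible=rxn.reversible,
        cell_tag=rxn.cell_tag,
        pathway_tag=rxn.pathway_tag,
        is_exchange=rxn.is_exchange,
    )


# ---------------------------------------------------------------------------
# Named scenarios (reaction ids follow the bundled exemplar model)
#
# The published screens give only qualitative outcomes, not the numeric
# rescaling used; the succinate factor is therefore an exposed parameter.
# ---------------------------------------------------------------------------

SCENARIO_NAMES = ("succ_oaa", "glutamate_block", "ampk_glutamate")

GLUTAMATE_UPTAKE_T = "GLUup_T"
FATTY_ACID_TRANSPORT_T = "FAT_T"
OAA_EXCHANGE_M = "OAAex_M1"
SUCC_EXCHANGE_M = "SUCCex_M1"

AMPK_LINK = RegulatoryLink(
    target_reaction_id=FATTY_ACID_TRANSPORT_T,
    controller=NodeRef("AMPK_T"),
    name="Pa_T=AMPK_T",
)


def scenario(name: str, succinate_factor: float = 0.5) -> list[PerturbationSpec]:
    """Return the perturbation bundle for one named scenario."""

    if name == "glutamate_block":
        return [
            PerturbationSpec(PerturbationKind.BLOCK_REACTION, GLUTAMATE_UPTAKE_T)
        ]
    if name == "ampk_glutamate":
        return [
            PerturbationSpec(PerturbationKind.BLOCK_REACTION, GLUTAMATE_UPTAKE_T),
            PerturbationSpec(
                PerturbationKind.ADD_REG_LINK,
                FATTY_ACID_TRANSPORT_T,
                link=AMPK_LINK,
            ),
        ]
    if name == "succ_oaa":
        return [
            PerturbationSpec(
                PerturbationKind.SET_BOUNDS, OAA_EXCHANGE_M, (0.0, 0.0)
            ),
            PerturbationSpec(
                PerturbationKind.RESCALE_EXCHANGE_STOICH,
                SUCC_EXCHANGE_M,
                (succinate_factor,),
            ),
        ]
    raise ModelError(
        f"unknown scenario {name!r}; expected one of {SCENARIO_NAMES}"
    )
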