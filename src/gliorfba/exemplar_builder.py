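"""Deterministic construction of the bundled three-cell exemplar model.

The published multicellular reconstruction (326 reactions, 357 metabolites,
192 signalling molecules) lives in supplementary files without a public
accession, so this module builds a reduced surrogate that encodes, verbatim,
every regulatory rule, objective and bound convention the main text prints:

* per cell (glioma ``_c``/``_C``, T-cell ``_T``, macrophage ``_M1``):
  glucose uptake + lumped glycolysis, lactate dehydrogenase + lactate
  export, pyruvate dehydrogenase (PYDH) + an abridged TCA cycle
  (AcCoA/OAA -> AKG -> succinate -> OAA), an electron-transport lump plus
  the ATP-synthase reaction with the printed ADP+Pi+4H = H2O+ATP+3H
  stoichiometry, an ATP-maintenance demand, fatty-acid transport + FAO,
  glutamine uptake/glutaminolysis, glutamate exchange (incl. the glioma
  cystine-glutamate antiporter xCT), an arginine branch (NOS vs arginase),
  oxygen uptake, and a ROS branch (glutathione-dependent scavenging vs
  superoxide dismutase);
* cross-feeding through ``_EXT`` species: glucose/glutamine/arginine/
  cystine/fatty-acid/oxygen supplies, lactate and glutamate pools, and the
  macrophage-to-glioma OAA and succinate shuttles;
* the signalling side: the six printed regulatory rules plus a minimal
  upstream layer of input nodes, the Th1/Th2/Treg/M1/M2 marker nodes, and
  the AMPK -> fatty-acid-transport link (disabled by default);
* metabolite pools ``Glucose_T``, ``Glutamine_T``, ``Arginine_T``,
  ``Lactate_T``, ``Succinate_M1`` with thresholds 0.5/0.5/0.02/3/1 mM.

All numbers here (supply rates, maintenance demands, condition-specific
bound restrictions, pool initial values) are surrogate study conditions
chosen once so that the two conditions reproduce the qualitative metabolic
and phenotype regimes the framework targets; they are written into the
bundle so users can inspect and change them.  ``generate_random_model``
produces small seeded random models for oracle-based property testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core_model import (
    BooleanNetwork,
    CellTag,
    Metabolite,
    MetabolitePool,
    ModelError,
    Objective,
    ObjectiveSense,
    Reaction,
    RegulatoryLink,
    SimulationConfig,
    StoichiometricModel,
    build_stoichiometric_matrix,
    default_bounds,
)
from .fba_engine import BoundsOverlay, FbaSolver
from .model_io import _suffix_to_tag, parse_formula, parse_rule
from .rfba_scheduler import ScenarioCondition

__all__ = [
    "ExemplarBundle",
    "build_exemplar",
    "generate_random_model",
    "exemplar_config",
    "write_bundle",
]


# ---------------------------------------------------------------------------
# Reaction table of the exemplar (shared skeleton, per-cell instantiation)
# ---------------------------------------------------------------------------

def _cell_reactions(cell: str, tag: CellTag) -> list[tuple]:
    """Reaction rows for one cell; ``{c}`` expands to the cell suffix."""

    def f(template: str) -> str:
        return template.replace("{c}", cell)

    rows = [
        # (id, formula, reversible, pathway, is_exchange)
        (f("GLCup_{c}"), f("1 Glc_EXT = 1 Glc_{c}"), False, "glycolysis", True),
        # cytosolic NADH (NADHc) is tracked separately from mitochondrial
        # NADH: without an open shuttle, glycolytic redox can only be
        # cleared through lactate, which is what couples glycolysis to
        # lactate export in the tumour regime
        (
            f("GLYC_{c}"),
            f("1 Glc_{c} + 2 ADP_{c} + 2 Pi_{c} = 2 Pyr_{c} + 2 ATP_{c} + 2 NADHc_{c}"),
            False,
            "glycolysis",
            False,
        ),
        (f("LDH_{c}"), f("1 Pyr_{c} + 1 NADHc_{c} = 1 Lac_{c}"), False, "glycolysis", False),
        # malate-aspartate shuttle lump (closed by default; the astrocyte
        # condition opens the glial one)
        (f("SHUT_{c}"), f("1 NADHc_{c} = 1 NADH_{c}"), False, "OXPHOS", False),
        (f("LACex_{c}"), f("1 Lac_{c} = 1 Lac_EXT"), False, "glycolysis", True),
        (f("PYDH_{c}"), f("1 Pyr_{c} = 1 AcCoA_{c} + 1 NADH_{c}"), False, "TCA", False),
        (
            f("CS_{c}"),
            f("1 AcCoA_{c} + 1 OAA_{c} = 1 AKG_{c} + 1 NADH_{c}"),
            False,
            "TCA",
            False,
        ),
        (f("AKGDH_{c}"), f("1 AKG_{c} = 1 Succ_{c} + 1 NADH_{c}"), False, "TCA", False),
        (f("SDHMDH_{c}"), f("1 Succ_{c} = 1 OAA_{c} + 1 NADH_{c}"), False, "TCA", False),
        (f("PC_{c}"), f("1 Pyr_{c} + 1 ATP_{c} = 1 OAA_{c} + 1 ADP_{c} + 1 Pi_{c}"), False, "TCA", False),
        # malic-enzyme lump: cataplerotic OAA -> pyruvate, closing the loop
        # that lets glutamate and arginine carbon be fully oxidized
        (f("ME_{c}"), f("1 OAA_{c} = 1 Pyr_{c}"), False, "TCA", False),
        # electron transport lump (complex I-IV): oxidizes NADH, pumps the
        # protons the ATP synthase consumes, leaks a little superoxide
        (
            f("ETC_{c}"),
            f("1 NADH_{c} + 0.5 O2_{c} = 1 H2O_{c} + 4 H_in_{c} + 0.1 ROS_{c}"),
            False,
            "OXPHOS",
            False,
        ),
        # the printed ATP-synthase stoichiometry; proton sides are kept as
        # distinct species so the column does not self-cancel
        (
            f("ATPS_{c}"),
            f("1 ADP_{c} + 1 Pi_{c} + 4 H_in_{c} = 1 H2O_{c} + 1 ATP_{c} + 3 H_out_{c}"),
            False,
            "OXPHOS",
            False,
        ),
        (f("Hsink_{c}"), f("1 H_out_{c} ="), False, "OXPHOS", True),
        (f("H2Osink_{c}"), f("1 H2O_{c} ="), False, "OXPHOS", True),
        (f("ATPM_{c}"), f("1 ATP_{c} = 1 ADP_{c} + 1 Pi_{c}"), False, "maintenance", False),
        (f("O2up_{c}"), f("1 O2_EXT = 1 O2_{c}"), False, "OXPHOS", True),
        # fatty-acid oxidation
        (f("FAT_{c}"), f("1 FA_EXT = 1 FA_{c}"), False, "FAO", True),
        (f("FAO_{c}"), f("1 FA_{c} = 2 AcCoA_{c} + 2 NADH_{c}"), False, "FAO", False),
        # glutamine / glutamate
        (f("GLNup_{c}"), f("1 Gln_EXT = 1 Gln_{c}"), False, "GLS", True),
        (f("GLS_{c}"), f("1 Gln_{c} = 1 Glu_{c}"), False, "GLS", False),
        (f("GDH_{c}"), f("1 Glu_{c} = 1 AKG_{c} + 1 NADH_{c}"), False, "GLS", False),
        # arginine branch
        (f("ARGup_{c}"), f("1 Arg_EXT = 1 Arg_{c}"), False, "arginine", True),
        (f("NOS_{c}"), f("1 Arg_{c} + 0.5 O2_{c} = 1 NO_EXT"), False, "arginine", False),
        # ROS handling lump: superoxide dismutase + catalase; molecular
        # oxygen is deliberately not regenerated by the lump so ROS cannot
        # become a hidden O2 source for the respiratory chain
        (f("SOD_{c}"), f("2 ROS_{c} = 1 H2O2_{c}"), False, "redox", False),
        (f("CAT_{c}"), f("1 H2O2_{c} = 1 H2O_{c}"), False, "redox", False),
    ]
    return [(rid, formula, rev, tag, pw, ex) for rid, formula, rev, pw, ex in rows]


def _exemplar_reactions() -> list[Reaction]:
    rows: list[tuple] = []
    rows += _cell_reactions("c", CellTag.C)
    rows += _cell_reactions("T", CellTag.T)
    rows += _cell_reactions("M1", CellTag.M1)

    # glioma-only machinery -------------------------------------------------
    rows += [
        # cystine-glutamate antiporter: cystine in, glutamate out
        ("xCT_c", "1 Cys2_EXT + 1 Glu_c = 1 Cys_c + 1 Glu_EXT", False, CellTag.C,
         "redox", True),
        # low-capacity direct cystine import (xCT-independent backup)
        ("CYSup_c", "1 Cys2_EXT = 1 Cys_c", False, CellTag.C, "redox", True),
        # glutathione synthesis lump (amino-acid activation, cystine
        # reduction and transport folded in as 4 ATP per GSH)
        ("GSHS_c", "1 Cys_c + 1 Glu_c + 4 ATP_c = 1 GSH_c + 4 ADP_c + 4 Pi_c",
         False, CellTag.C, "redox", False),
        # glutathione-dependent ROS scavenging (consumes GSH)
        ("GPX_c", "2 ROS_c + 1 GSH_c = 1 H2O_c", False, CellTag.C,
         "redox", False),
        # plain glutamate export (irreversible under glioma dominance; the
        # astrocyte condition re-opens the uptake direction) and the
        # accumulation (storage) overflow, which generates oxidative stress
        ("GLUex_c", "1 Glu_c = 1 Glu_EXT", False, CellTag.C, "GLS", True),
        ("GLUstore_c", "1 Glu_c = 0.5 ROS_c", False, CellTag.C, "GLS", False),
        # growth pseudo-reaction: combined OAA + GSH + succinate demand
        ("Growth_Glioma", "1 OAA_c + 1 GSH_c + 1 Succ_c =", False, CellTag.C,
         "objective", False),
    ]

    # T-cell-only -----------------------------------------------------------
    rows += [
        ("GLUup_T", "1 Glu_EXT = 1 Glu_T", False, CellTag.T, "GLS", True),
        # arginine catabolism to TCA fuel (arginase/OAT/P5C lump); the ATP
        # activation cost makes this the T-cell's fuel of last resort
        ("ARGcat_T", "1 Arg_T + 1 ATP_T = 1 AKG_T + 1 ADP_T + 1 Pi_T",
         False, CellTag.T, "arginine", False),
        # pyruvate overflow valve: lets the T-cell fully oxidise anaplerotic
        # fuels (glutamate, arginine) by venting the cataplerotic pyruvate
        ("PYRex_T", "1 Pyr_T = 1 Pyr_EXT", False, CellTag.T, "glycolysis", True),
    ]

    # macrophage-only -------------------------------------------------------
    rows += [
        ("ARGase_M1", "1 Arg_M1 = 1 Orn_M1", False, CellTag.M1, "arginine", False),
        # ornithine feeds the TCA via a transaminase lump
        ("OAT_M1", "1 Orn_M1 = 1 AKG_M1", False, CellTag.M1, "arginine", False),
        ("OAAex_M1", "1 OAA_M1 = 1 OAA_EXT", False, CellTag.M1, "TCA", True),
        ("SUCCex_M1", "1 Succ_M1 = 1 Succ_EXT", False, CellTag.M1, "TCA", True),
        ("SUCCsink", "1 Succ_EXT =", False, CellTag.EXT, "TCA", True),
    ]

    # glioma sourcing of macrophage-exported OAA
    rows += [
        ("OAAup_c", "1 OAA_EXT = 1 OAA_c", False, CellTag.C, "TCA", True),
    ]

    # environment boundary exchanges (written as EXT -> nothing; negative
    # flux = supply into the system)
    boundary = [
        ("EX_Glc", "Glc_EXT"),
        ("EX_Gln", "Gln_EXT"),
        ("EX_Arg", "Arg_EXT"),
        ("EX_Cys2", "Cys2_EXT"),
        ("EX_FA", "FA_EXT"),
        ("EX_O2", "O2_EXT"),
        ("EX_Lac", "Lac_EXT"),
        ("EX_Glu", "Glu_EXT"),
        ("EX_NO", "NO_EXT"),
        ("EX_OAA", "OAA_EXT"),
        ("EX_Pyr", "Pyr_EXT"),
    ]
    rows += [
        (f"{rid}", f"1 {met} =", True, CellTag.EXT, "boundary", True)
        for rid, met in boundary
    ]

    reactions = []
    for rid, formula, rev, tag, pathway, is_ex in rows:
        lb, ub = default_bounds(rev)
        stoich = parse_formula(formula)
        # glioma succinate keeps the lower-case historical name succ_c
        if "Succ_c" in stoich:
            stoich = {("succ_c" if m == "Succ_c" else m): c for m, c in stoich.items()}
        reactions.append(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lb=lb,
                ub=ub,
                reversible=rev,
                cell_tag=tag,
                pathway_tag=pathway,
                is_exchange=is_ex,
            )
        )
    return reactions


def _exemplar_metabolites(reactions: list[Reaction]) -> list[Metabolite]:
    seen: dict[str, None] = {}
    for rxn in reactions:
        for met in rxn.stoichiometry:
            seen.setdefault(met, None)
    return [
        Metabolite(
            id=met,
            name=met,
            cell_tag=_suffix_to_tag(met),
            exchangeable=met.endswith("_EXT"),
        )
        for met in seen
    ]


# ---------------------------------------------------------------------------
# Environment supplies and per-condition bound restrictions
# ---------------------------------------------------------------------------

#: total nutrient supplies (boundary exchange lower bounds; negative = inflow).
#: The glucose supply is deliberately tight: under the glioma objective the
#: tumour cell's demand is served first and the immune cells run on the
#: remainder, which is what makes the recovery scenarios measurable.
_SUPPLIES = {
    "EX_Glc": (-1.3, 1000.0),
    "EX_Gln": (-2.0, 1000.0),
    "EX_Arg": (-1.0, 1000.0),
    "EX_Cys2": (-1.0, 1000.0),
    "EX_FA": (-2.0, 1000.0),
    "EX_O2": (-8.0, 1000.0),
    "EX_Lac": (0.0, 1000.0),   # lactate only leaves the system
    "EX_Glu": (0.0, 0.0),      # glutamate stays inside the microenvironment
    "EX_NO": (0.0, 1000.0),
    "EX_OAA": (0.0, 0.0),      # OAA shuttles between cells only
    "EX_Pyr": (0.0, 1000.0),   # pyruvate overflow leaves the system
}

#: shared bound restrictions (both conditions)
_COMMON = {
    # maintenance demands keep every cell metabolically active; the upper
    # bound stays open so ATP production above the floor is never infeasible
    "ATPM_c": (1.2, 1000.0),
    "ATPM_T": (1.4, 1000.0),
    "ATPM_M1": (0.5, 1000.0),
    # immune cells lack the redox shuttle (their glycolysis is fermentative)
    "SHUT_T": (0.0, 0.0),
    "SHUT_M1": (0.0, 0.0),
    # macrophage arginine handling: a fixed uptake must be disposed of via
    # NOS (to NO) or arginase (to ornithine and on into the TCA cycle)
    "ARGup_M1": (0.35, 0.35),
    # anaplerosis and cataplerosis are minor routes in the immune cells
    "PC_T": (0.0, 0.05),
    "PC_M1": (0.0, 0.05),
    # xCT-independent cystine import is a trickle
    "CYSup_c": (0.0, 0.1),
}

#: glioma-dominant condition (table-S6-style restrictions, surrogate values)
_GLIOMA_OVERLAY = {
    # glial cell: PYDH and complex IV restricted, xCT and FAO open, GDH
    # restricted, anaplerosis through pyruvate carboxylase available
    "PYDH_c": (0.0, 0.2),
    "ETC_c": (0.0, 1.0),
    "GDH_c": (0.0, 0.1),
    "xCT_c": (0.0, 1000.0),
    "FAT_c": (0.0, 2.0),
    "PC_c": (0.0, 0.2),
    # broken glial TCA cycle: succinate-to-OAA regeneration nearly off
    "SDHMDH_c": (0.0, 0.05),
    "SHUT_c": (0.0, 0.0),
    # glutamine-addicted glioma: forced uptake
    "GLNup_c": (0.6, 1000.0),
    # immune cells are nutrient-restricted under glioma dominance; the
    # T-cell constitutively imports a trickle of fatty acid (the reaction
    # the AMPK link switches off) and its pyruvate dehydrogenase is largely
    # inactive (aerobic-glycolysis phenotype)
    "GLCup_T": (0.0, 0.4),
    "GLCup_M1": (0.0, 0.1),
    "GLNup_T": (0.0, 0.05),
    "GLNup_M1": (0.0, 0.2),
    "PYDH_T": (0.0, 0.05),
    "ETC_T": (0.0, 1.2),
    "ETC_M1": (0.0, 1.0),
    "FAT_T": (0.05, 0.05),
    "FAT_M1": (0.0, 0.5),
    "GLUup_T": (0.0, 1.0),
    "ARGup_T": (0.0, 0.3),
}

#: normal astrocyte condition
_ASTROCYTE_OVERLAY = {
    # astrocyte: OXPHOS open, xCT closed, FAO off, PYDH open, GDH open,
    # astrocytes clear extracellular glutamate (uptake direction re-opened)
    "PYDH_c": (0.0, 1000.0),
    "ETC_c": (0.0, 1000.0),
    "GDH_c": (0.0, 1000.0),
    "xCT_c": (0.0, 0.0),
    "FAT_c": (0.0, 0.0),
    "PC_c": (0.0, 0.1),
    "SDHMDH_c": (0.0, 1000.0),
    "SHUT_c": (0.0, 1000.0),
    "PYDH_T": (0.0, 0.2),
    "GLNup_c": (0.0, 0.3),
    "GLUex_c": (-2.0, 1000.0),
    # immune cells see a permissive environment
    "GLCup_T": (0.0, 1.0),
    "GLCup_M1": (0.0, 1.0),
    "GLNup_T": (0.0, 0.5),
    "GLNup_M1": (0.0, 0.5),
    "ETC_T": (0.0, 1.0),
    "ETC_M1": (0.0, 1.0),
    "FAT_T": (0.0, 0.5),
    "FAT_M1": (0.0, 0.5),
    "GLUup_T": (0.0, 0.5),
    "ARGup_T": (0.0, 1.0),
}


# ---------------------------------------------------------------------------
# Signalling network
# ---------------------------------------------------------------------------

#: the six printed regulatory rules, verbatim (incl. the stray bracket in
#: the CD28 rule, which the parser normalizes with a warning)
PRINTED_RULES = {
    "CD28_T": "CD80_86_M1&not(ctla4_T)|[(Arginine_T)>0.02)]",
    "AMPK_T": "CAMKK_T&[not((Glucose_T)>=0.5)&not((Glutamine_T)>=0.5)]",
    "mTORC1_T": (
        "AKT_T&raptor_T&not(AMPK_T)|(AKT_T&raptor_T&not(PD_1_T))"
        "|AKT_T&raptor_T&[not(Lactate_T>3)]"
    ),
    "TGF_b_T": "FoxP3_T&[not(Glucose_T>=0.5)]",
    "HIF1A_M1": "(Succinate_M1>=1)|NF_kB_M1",
    "IFNg_T": "T_bet_T&(Glucose_T>=0.5)",
}

#: minimal marker layer wired around the printed rules (exemplar curation)
_MARKER_RULES = {
    # Th1 lineage: mTORC1-driven, CD28 co-stimulation required
    "T_bet_T": "mTORC1_T & CD28_T",
    # Th2 lineage: co-stimulation without the Th1 program
    "Gata3_T": "CD28_T & not(T_bet_T)",
    # Treg program: checkpoint signalling once mTORC1 is off, gated by the
    # Treg lineage's dependence on fatty-acid oxidation, self-sustained
    # through autocrine TGF-beta
    "FoxP3_T": "PD_1_T & not(mTORC1_T) & (FattyAcid_T > 1) | TGF_b_T",
    # anti-inflammatory macrophage program depends on arginine availability
    "ARG1_M2": "STAT6_M2 & (Arginine_T > 0.02)",
    # fatty-acid transport proxy node (the Pa_T = AMPK_T regulatory rule)
    "Pa_T": "AMPK_T",
}

#: input nodes and their fixed states per condition
_INPUT_STATES_GLIOMA = {
    "CD80_86_M1": 1,
    "ctla4_T": 1,
    "CAMKK_T": 1,
    "AKT_T": 1,
    "raptor_T": 1,
    "PD_1_T": 1,
    "NF_kB_M1": 0,
    "STAT6_M2": 1,
}
_INPUT_STATES_ASTROCYTE = {
    "CD80_86_M1": 1,
    "ctla4_T": 0,
    "CAMKK_T": 1,
    "AKT_T": 1,
    "raptor_T": 1,
    "PD_1_T": 0,
    "NF_kB_M1": 1,
    "STAT6_M2": 0,
}


def _exemplar_network(condition: str) -> BooleanNetwork:
    rules = {node: parse_rule(text) for node, text in PRINTED_RULES.items()}
    rules.update(
        {node: parse_rule(text) for node, text in _MARKER_RULES.items()}
    )
    inputs = dict(
        _INPUT_STATES_GLIOMA if condition == "glioma" else _INPUT_STATES_ASTROCYTE
    )
    nodes = list(inputs) + list(rules)
    return BooleanNetwork(nodes=nodes, rules=rules, input_states=inputs)


# ---------------------------------------------------------------------------
# Pools
# ---------------------------------------------------------------------------

def _exemplar_pools() -> list[MetabolitePool]:
    """Bridging pools: availability of each metabolite to the immune cells.

    Each pool integrates a competition balance: the cell's own uptake raises
    availability, the competing consumer's flux lowers it.  Initial values
    are surrogate basal concentrations chosen so the glioma-dominant
    baseline crosses each activation threshold within the 2000-step run.
    """

    return [
        # glucose available to the T-cell is eroded by the glial draw
        MetabolitePool(
            "Glucose_T", 1.0,
            coupled_transport_reactions=[("GLCup_c", -1.5)],
        ),
        MetabolitePool(
            "Glutamine_T", 1.0,
            coupled_transport_reactions=[("GLNup_c", -2.5)],
        ),
        # arginine availability falls with the T-cell's own catabolic use
        MetabolitePool(
            "Arginine_T", 0.5,
            coupled_transport_reactions=[("ARGcat_T", -6.0)],
        ),
        # environmental lactate accumulates with glial export
        MetabolitePool(
            "Lactate_T", 2.6,
            coupled_transport_reactions=[("LACex_c", +1.2)],
        ),
        # fatty acid available for T-cell oxidation accumulates with import
        MetabolitePool(
            "FattyAcid_T", 0.5,
            coupled_transport_reactions=[("FAT_T", +14.2)],
        ),
        MetabolitePool(
            "Succinate_M1", 1.0,
            coupled_transport_reactions=[("SUCCex_M1", +1.0)],
        ),
    ]


# ---------------------------------------------------------------------------
# Bundle assembly
# ---------------------------------------------------------------------------

@dataclass
class ExemplarBundle:
    """Everything needed to simulate: model, network, pools, links, conditions."""

    model: StoichiometricModel
    network: BooleanNetwork
    pools: list[MetabolitePool]
    links: list[RegulatoryLink]
    conditions: dict[str, ScenarioCondition]

    def condition(self, name: str) -> ScenarioCondition:
        try:
            return self.conditions[name]
        except KeyError:
            raise ModelError(
                f"unknown condition {name!r}; have {sorted(self.conditions)}"
            ) from None


def exemplar_config(condition: str = "glioma", n_steps: int = 2000) -> SimulationConfig:
    """The bundled study conditions: dt_met=0.07, dt_reg=1, pool_scale=8e-4.

    ``pool_scale`` converts flux units x time into mM; the surrogate value
    spreads threshold crossings over hundreds of regulatory ticks so the
    slow transcriptional layer responds on its own time scale.
    """

    return SimulationConfig(
        dt_met=0.07,
        dt_reg=1.0,
        n_steps=n_steps,
        pool_scale=8e-4,
        condition=condition,
    )


def build_exemplar() -> ExemplarBundle:
    """Build the reduced three-cell exemplar (seed-free, bit-stable)."""

    reactions = _exemplar_reactions()
    for rxn_id, (lb, ub) in {**_SUPPLIES, **_COMMON}.items():
        idx = next(i for i, r in enumerate(reactions) if r.id == rxn_id)
        r = reactions[idx]
        reactions[idx] = Reaction(
            id=r.id, stoichiometry=r.stoichiometry, lb=lb, ub=ub,
            reversible=r.reversible, cell_tag=r.cell_tag,
            pathway_tag=r.pathway_tag, is_exchange=r.is_exchange,
        )
    metabolites = _exemplar_metabolites(reactions)
    model = build_stoichiometric_matrix(reactions, metabolites)

    growth = Objective("Growth_Glioma", {"Growth_Glioma": 1.0},
                       ObjectiveSense.MAXIMIZE)
    atp_synthase = Objective("ATP_synthase", {"ATPS_c": 1.0},
                             ObjectiveSense.MAXIMIZE)

    conditions = {
        "glioma": ScenarioCondition(
            name="glioma",
            objective=growth,
            bounds_overlay=BoundsOverlay(_GLIOMA_OVERLAY),
            input_states=_INPUT_STATES_GLIOMA,
        ),
        "astrocyte": ScenarioCondition(
            name="astrocyte",
            objective=atp_synthase,
            bounds_overlay=BoundsOverlay(_ASTROCYTE_OVERLAY),
            input_states=_INPUT_STATES_ASTROCYTE,
        ),
    }

    bundle = ExemplarBundle(
        model=model,
        network=_exemplar_network("glioma"),
        pools=_exemplar_pools(),
        links=[],  # the AMPK link is enabled by the ampk_glutamate scenario
        conditions=conditions,
    )
    _self_check(bundle)
    return bundle


def _self_check(bundle: ExemplarBundle) -> None:
    """Build-time sanity: both conditions must be feasible with optimum > 0."""

    solver = FbaSolver(bundle.model)
    for name, cond in bundle.conditions.items():
        sol = solver.solve(cond.objective, cond.bounds_overlay)
        if sol.status.value != "optimal" or not sol.objective_value > 0:
            raise ModelError(
                f"exemplar self-check failed for condition {name!r}: "
                f"{sol.status.value}, objective {sol.objective_value}"
            )


# ---------------------------------------------------------------------------
# Seeded random toy models for property tests
# ---------------------------------------------------------------------------

def generate_random_model(
    seed: int, m: int = 6, n: int = 8, n_nodes: int = 0
) -> tuple[StoichiometricModel, BooleanNetwork | None, list[MetabolitePool]]:
    """Random connected toy model (+ optional random Boolean network).

    Every bound interval contains zero, so v = 0 is always feasible and the
    flux polytope is bounded: exactly the regime the brute-force vertex
    enumeration oracle can check.  Reproducible from the seed.
    """

    if n > 12 or n_nodes > 10:
        import warnings

        warnings.warn("sizes above (n=12, n_nodes=10) are slow in oracle mode")
    rng = np.random.default_rng(seed)
    mets = [Metabolite(id=f"M{i}", name=f"M{i}") for i in range(m)]

    reactions: list[Reaction] = []
    for j in range(n):
        k = int(rng.integers(1, min(4, m) + 1))
        chosen = rng.choice(m, size=k, replace=False)
        coeffs = {}
        for idx in chosen:
            coeff = float(rng.integers(1, 4)) * (1 if rng.random() < 0.5 else -1)
            coeffs[f"M{int(idx)}"] = coeff
        reversible = bool(rng.random() < 0.5)
        lb, ub = (
            (-float(rng.integers(1, 11)), float(rng.integers(1, 11)))
            if reversible
            else (0.0, float(rng.integers(1, 11)))
        )
        reactions.append(
            Reaction(
                id=f"R{j}", stoichiometry=coeffs, lb=lb, ub=ub,
                reversible=reversible,
            )
        )
    # boundary exchanges guarantee at least one feasible nonzero mode
    for i in range(min(2, m)):
        reactions.append(
            Reaction(
                id=f"EX{i}",
                stoichiometry={f"M{i}": -1.0},
                lb=-float(rng.integers(1, 11)),
                ub=float(rng.integers(1, 11)),
                reversible=True,
                is_exchange=True,
            )
        )
    model = StoichiometricModel(mets, reactions)

    network = None
    pools: list[MetabolitePool] = []
    if n_nodes:
        node_ids = [f"g{i}" for i in range(n_nodes)]
        n_inputs = max(1, n_nodes // 4)
        inputs = {node_ids[i]: int(rng.integers(0, 2)) for i in range(n_inputs)}
        pools = [
            MetabolitePool(f"P{i}", float(rng.uniform(0.0, 2.0)))
            for i in range(2)
        ]
        rules = {}
        for node in node_ids[n_inputs:]:
            rules[node] = _random_expr(rng, node_ids, pools, depth=2)
        network = BooleanNetwork(
            nodes=node_ids, rules=rules, input_states=inputs
        )
    return model, network, pools


def _random_expr(rng, node_ids, pools, depth):
    from .core_model import And, Const, NodeRef, Not, Or, ThresholdPredicate, Comparator

    if depth == 0 or rng.random() < 0.35:
        roll = rng.random()
        if roll < 0.65 or not pools:
            return NodeRef(str(rng.choice(node_ids)))
        if roll < 0.85:
            pool = pools[int(rng.integers(0, len(pools)))]
            cmp_ = Comparator.GE if rng.random() < 0.5 else Comparator.GT
            return ThresholdPredicate(
                pool.metabolite_id, cmp_, float(rng.uniform(0.0, 2.0))
            )
        return Const(bool(rng.integers(0, 2)))
    roll = rng.random()
    if roll < 0.3:
        return Not(_random_expr(rng, node_ids, pools, depth - 1))
    op = And if roll < 0.65 else Or
    k = int(rng.integers(2, 4))
    return op(tuple(_random_expr(rng, node_ids, pools, depth - 1) for _ in range(k)))


# ---------------------------------------------------------------------------
# Bundle serialization
# ---------------------------------------------------------------------------

def write_bundle(bundle: ExemplarBundle, out_dir: str | Path) -> None:
    """Write the model/rules/states/pools TSV bundle to a directory."""

    from . import model_io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model_io.write_model(bundle.model, out / "model.tsv")
    rule_lines = ["# Boolean rules (NODE = expression)"]
    for node, text in {**PRINTED_RULES, **_MARKER_RULES}.items():
        rule_lines.append(f"{node} = {text}")
    (out / "rules.txt").write_text("\n".join(rule_lines) + "\n")
    model_io.write_states(bundle.network.input_states, out / "states.tsv")
    model_io.write_pools(bundle.pools, out / "pools.tsv")
    overlay_rows = []
    for cond_name, cond in bundle.conditions.items():
        for rxn_id, (lb, ub) in sorted(cond.bounds_overlay.items()):
            overlay_rows.append(f"{cond_name}\t{rxn_id}\t{lb}\t{ub}")
    (out / "conditions.tsv").write_text(
        "condition\treaction\tlb\tub\n" + "\n".join(overlay_rows) + "\n"
    )
    (out / "README.txt").write_text(
        "Reduced three-cell exemplar bundle (synthetic surrogate for the\n"
        "full supplementary reconstruction; all rates and bounds are\n"
        "surrogate study conditions, not literature measurements).\n"
    )
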