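"""Qualitative validation panel for the bundled exemplar.

The framework's headline outputs are flux-direction and phenotype-ordering
statements, not printed numbers, so validation is a checklist of sign and
ordering assertions computed from end-to-end runs:

* glioma vs astrocyte baseline: lactate export, PYDH, ATP synthase, xCT
  glutamate release, glutamine uptake, and the Treg-over-Th1 ordering;
* glutamate-uptake blockage: T-cell glucose uptake and glioma SOD rise,
  glioma glutamate export ceases;
* succinate/OAA exchange modulation: outward OAA exchange ceases, NOS up,
  arginase down;
* AMPK + glutamate blockage: fatty-acid transport is off whenever AMPK_T
  is active, glucose and arginine uptake rise, the Th1 response exceeds
  Th2 and the Treg onset is the latest of all scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import Trajectory
from .exemplar_builder import build_exemplar, exemplar_config
from .perturbation import apply_perturbations, scenario
from .phenotype_readout import activation_profile
from .rfba_scheduler import run_simulation

__all__ = ["Check", "run_all_scenarios", "run_validation_panel"]

#: scenario keys in reporting order
SCENARIOS = ("baseline", "glutamate_block", "succ_oaa", "ampk_glutamate")


@dataclass(frozen=True)
class Check:
    """One qualitative assertion with its measured evidence."""

    description: str
    passed: bool
    detail: str


def run_all_scenarios(n_steps: int = 2000) -> dict[str, Trajectory]:
    """Run astrocyte + glioma baselines and the three intervention scenarios."""

    bundle = build_exemplar()
    out: dict[str, Trajectory] = {}
    for cond in ("astrocyte", "glioma"):
        out["astrocyte" if cond == "astrocyte" else "baseline"] = run_simulation(
            bundle.model, bundle.network, bundle.pools, bundle.links,
            bundle.condition(cond), exemplar_config(cond, n_steps),
        )
    for name in ("glutamate_block", "succ_oaa", "ampk_glutamate"):
        model, links = apply_perturbations(
            bundle.model, bundle.links, scenario(name)
        )
        out[name] = run_simulation(
            model, bundle.network, bundle.pools, links,
            bundle.condition("glioma"), exemplar_config("glioma", n_steps),
        )
    return out


def _mean(traj: Trajectory, rxn_id: str) -> float:
    return float(traj.flux_series(rxn_id).mean())


def run_validation_panel(
    n_steps: int = 2000,
    trajectories: dict[str, Trajectory] | None = None,
) -> list[Check]:
    """Compute the full qualitative checklist; returns one Check per assertion."""

    t = trajectories if trajectories is not None else run_all_scenarios(n_steps)
    astro, base = t["astrocyte"], t["baseline"]
    glu, soaa, ampk = t["glutamate_block"], t["succ_oaa"], t["ampk_glutamate"]
    checks: list[Check] = []

    def add(description: str, passed: bool, detail: str) -> None:
        checks.append(Check(description, bool(passed), detail))

    # -- baseline glioma vs astrocyte --------------------------------------
    lac_g, lac_a = _mean(base, "LACex_c"), _mean(astro, "LACex_c")
    add("glioma: lactate export > 0", lac_g > 1e-6, f"{lac_g:.3f}")
    add("glioma lactate export > astrocyte", lac_g > lac_a,
        f"{lac_g:.3f} vs {lac_a:.3f}")
    pydh_g, pydh_a = _mean(base, "PYDH_c"), _mean(astro, "PYDH_c")
    add("glioma PYDH < astrocyte PYDH", pydh_g < pydh_a,
        f"{pydh_g:.3f} vs {pydh_a:.3f}")
    atps_g, atps_a = _mean(base, "ATPS_c"), _mean(astro, "ATPS_c")
    add("astrocyte ATP synthase > 0", atps_a > 1e-6, f"{atps_a:.3f}")
    add("glioma ATP synthase < astrocyte", atps_g < atps_a,
        f"{atps_g:.3f} vs {atps_a:.3f}")
    xct = _mean(base, "xCT_c")
    add("glioma: glutamate release via xCT > 0", xct > 1e-6, f"{xct:.3f}")
    gln_g, gln_a = _mean(base, "GLNup_c"), _mean(astro, "GLNup_c")
    add("glioma glutamine uptake > astrocyte", gln_g > gln_a,
        f"{gln_g:.3f} vs {gln_a:.3f}")
    treg = activation_profile(base, "FoxP3_T").fraction_active
    th1 = activation_profile(base, "T_bet_T").fraction_active
    add("glioma baseline: Treg fraction > Th1 fraction", treg > th1,
        f"{treg:.3f} vs {th1:.3f}")

    # -- glutamate-uptake blockage -----------------------------------------
    glc_t = _mean(glu, "GLCup_T")
    glc_t0 = _mean(base, "GLCup_T")
    add("glutamate_block: T-cell glucose uptake increases", glc_t > glc_t0,
        f"{glc_t:.3f} vs {glc_t0:.3f}")
    sod = _mean(glu, "SOD_c")
    sod0 = _mean(base, "SOD_c")
    add("glutamate_block: glioma SOD flux increases", sod > sod0,
        f"{sod:.3f} vs {sod0:.3f}")
    glu_export = _mean(glu, "xCT_c") + _mean(glu, "GLUex_c")
    add("glutamate_block: glioma glutamate export ceases",
        abs(glu_export) < 1e-6, f"{glu_export:.4f}")

    # -- succinate/OAA exchange modulation ---------------------------------
    oaa = float(np.abs(soaa.flux_series("OAAex_M1")).max())
    add("succ_oaa: outward OAA exchange is zero", oaa < 1e-6, f"max |v|={oaa:.4f}")
    nos, nos0 = _mean(soaa, "NOS_M1"), _mean(base, "NOS_M1")
    add("succ_oaa: NOS flux increases", nos > nos0, f"{nos:.3f} vs {nos0:.3f}")
    argase, argase0 = _mean(soaa, "ARGase_M1"), _mean(base, "ARGase_M1")
    add("succ_oaa: arginase flux decreases", argase < argase0,
        f"{argase:.3f} vs {argase0:.3f}")

    # -- AMPK coupling + glutamate blockage --------------------------------
    fat = ampk.flux_series("FAT_T")
    ampk_state = np.array([s["AMPK_T"] for s in ampk.boolean_states])
    coupled_ok = bool(np.all(np.abs(fat[ampk_state == 1]) < 1e-9))
    add("ampk_glutamate: fatty-acid transport = 0 while AMPK_T = 1",
        coupled_ok,
        f"max |v| under AMPK: "
        f"{np.abs(fat[ampk_state == 1]).max() if (ampk_state == 1).any() else 0:.2e}")
    glc_t2 = _mean(ampk, "GLCup_T")
    add("ampk_glutamate: T-cell glucose uptake increases vs baseline",
        glc_t2 > glc_t0, f"{glc_t2:.3f} vs {glc_t0:.3f}")
    arg_t2, arg_t0 = _mean(ampk, "ARGup_T"), _mean(base, "ARGup_T")
    add("ampk_glutamate: T-cell arginine uptake increases vs baseline",
        arg_t2 > arg_t0, f"{arg_t2:.3f} vs {arg_t0:.3f}")
    th1_f = activation_profile(ampk, "T_bet_T").fraction_active
    th2_f = activation_profile(ampk, "Gata3_T").fraction_active
    add("ampk_glutamate: Th1 fraction > Th2 fraction", th1_f > th2_f,
        f"{th1_f:.3f} vs {th2_f:.3f}")
    onsets = {
        name: activation_profile(t[name], "FoxP3_T").onset
        for name in SCENARIOS
    }
    latest = all(
        onsets["ampk_glutamate"] > onsets[name]
        for name in SCENARIOS if name != "ampk_glutamate"
    )
    add("ampk_glutamate: Treg onset later than all other scenarios", latest,
        ", ".join(f"{k}={v:g}" for k, v in onsets.items()))
    return checks
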