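"""Immune-response and metabolic readouts derived from trajectories.

Phenotype markers follow the field's standard assignments: T_bet_T (with
IFNg_T) marks the Th1 response, Gata3_T the Th2 response, FoxP3_T (with
TGF_b_T) the Treg response, HIF1A_M1 the pro-inflammatory macrophage and
ARG1_M2 the anti-inflammatory macrophage.  Because the Boolean layer is
qualitative, "response strength" is quantified as the fraction of regulatory
ticks a marker is active, and response timing as the first regulatory tick
of activation (onset).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_model import ModelError, Trajectory

__all__ = [
    "PHENOTYPE_PANEL",
    "ActivationProfile",
    "activation_profile",
    "flux_panel",
    "response_comparison",
]

#: marker -> phenotype name
PHENOTYPE_PANEL: dict[str, str] = {
    "T_bet_T": "Th1",
    "Gata3_T": "Th2",
    "FoxP3_T": "Treg",
    "HIF1A_M1": "M1",
    "ARG1_M2": "M2",
}

#: secondary markers reported alongside the primary ones
AUXILIARY_MARKERS: dict[str, str] = {
    "IFNg_T": "Th1",
    "TGF_b_T": "Treg",
}


@dataclass(frozen=True)
class ActivationProfile:
    """Onset (1-based regulatory tick, inf if never), active count, fraction."""

    node: str
    onset: float
    total_active_steps: int
    fraction_active: float


def activation_profile(trajectory: Trajectory, node: str) -> ActivationProfile:
    """Activation statistics for one signalling node over regulatory ticks."""

    states = trajectory.regulatory_states()
    if not states:
        raise ModelError("empty trajectory")
    if node not in states[0]:
        raise ModelError(f"node {node!r} not recorded in trajectory")
    series = np.array([s[node] for s in states], dtype=int)
    active = int(series.sum())
    onset = math.inf
    nonzero = np.flatnonzero(series)
    if nonzero.size:
        onset = float(nonzero[0] + 1)  # 1-based regulatory tick
    return ActivationProfile(
        node=node,
        onset=onset,
        total_active_steps=active,
        fraction_active=active / len(series),
    )


def flux_panel(
    trajectory: Trajectory, reaction_ids: Sequence[str]
) -> pd.DataFrame:
    """Per-reaction summary (mean, sign, first/last values) over all ticks."""

    rows = []
    for rxn_id in reaction_ids:
        if rxn_id not in trajectory.fluxes[0].fluxes:
            raise ModelError(f"reaction {rxn_id!r} not recorded in trajectory")
        series = trajectory.flux_series(rxn_id)
        mean = float(series.mean())
        rows.append(
            {
                "reaction": rxn_id,
                "mean_flux": mean,
                "sign": int(np.sign(mean)) if abs(mean) > 1e-9 else 0,
                "first": float(series[0]),
                "last": float(series[-1]),
                "min": float(series.min()),
                "max": float(series.max()),
            }
        )
    return pd.DataFrame(rows).set_index("reaction")


def response_comparison(
    traj_a: Trajectory,
    traj_b: Trajectory,
    panel: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Marker-by-marker onset shifts and fraction-active changes (b - a).

    Antisymmetric under argument swap.  Both trajectories must record the
    same signalling network.
    """

    if panel is None:
        panel = PHENOTYPE_PANEL
    nodes_a = set(traj_a.boolean_states[0])
    nodes_b = set(traj_b.boolean_states[0])
    if nodes_a != nodes_b:
        raise ModelError("trajectories record different networks")
    rows = []
    for marker, phenotype in panel.items():
        prof_a = activation_profile(traj_a, marker)
        prof_b = activation_profile(traj_b, marker)
        rows.append(
            {
                "marker": marker,
                "phenotype": phenotype,
                "fraction_a": prof_a.fraction_active,
                "fraction_b": prof_b.fraction_active,
                "fraction_delta": prof_b.fraction_active - prof_a.fraction_active,
                "onset_a": prof_a.onset,
                "onset_b": prof_b.onset,
                "onset_shift": _onset_shift(prof_a.onset, prof_b.onset),
            }
        )
    return pd.DataFrame(rows).set_index("marker")


def _onset_shift(onset_a: float, onset_b: float) -> float:
    if math.isinf(onset_a) and math.isinf(onset_b):
        return 0.0
    return onset_b - onset_a
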