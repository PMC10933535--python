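"""Shared fixtures: the exemplar bundle and the full scenario trajectories.

The scenario runs use the bundled defaults (2000 regulatory steps, 14
metabolic ticks each); they are session-scoped because five end-to-end
simulations back a large share of the assertions.
"""

import warnings

import pytest

from gliorfba.exemplar_builder import build_exemplar
from gliorfba.validation import run_all_scenarios


@pytest.fixture(scope="session")
def bundle():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_exemplar()


@pytest.fixture(scope="session")
def scenario_trajectories():
    """astrocyte + glioma baselines and the three intervention scenarios."""

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_all_scenarios(n_steps=2000)
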