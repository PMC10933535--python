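"""Synchronous Boolean dynamics with metabolite-threshold predicates.

All non-input nodes are recomputed simultaneously from the previous state;
input nodes stay clamped at their fixed states.  Threshold predicates read a
metabolite-pool concentration: ``>=`` is true exactly at the threshold,
``>`` is not.  Attractors (fixed points or cycles) are found by hashing full
state vectors until the first repeat.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .core_model import (
    And,
    BooleanExpr,
    BooleanNetwork,
    Const,
    ModelError,
    NodeRef,
    Not,
    Or,
    ThresholdPredicate,
)

__all__ = [
    "evaluate_expr",
    "synchronous_step",
    "run_to_attractor",
    "AttractorResult",
]


def evaluate_expr(
    expr: BooleanExpr,
    state: Mapping[str, int],
    pools: Mapping[str, float] | None = None,
) -> int:
    """Evaluate one expression tree to 0/1 under a state and pool levels."""

    if isinstance(expr, NodeRef):
        try:
            return 1 if state[expr.node_id] else 0
        except KeyError:
            raise ModelError(f"unresolved node reference {expr.node_id!r}") from None
    if isinstance(expr, Const):
        return int(expr.value)
    if isinstance(expr, ThresholdPredicate):
        if pools is None or expr.metabolite_id not in pools:
            raise ModelError(
                f"unresolved pool reference {expr.metabolite_id!r} in predicate"
            )
        return int(expr.evaluate(pools[expr.metabolite_id]))
    if isinstance(expr, Not):
        return 1 - evaluate_expr(expr.operand, state, pools)
    if isinstance(expr, And):
        for op in expr.operands:
            if not evaluate_expr(op, state, pools):
                return 0
        return 1
    if isinstance(expr, Or):
        for op in expr.operands:
            if evaluate_expr(op, state, pools):
                return 1
        return 0
    raise TypeError(f"not a BooleanExpr: {expr!r}")


def synchronous_step(
    network: BooleanNetwork,
    state: Mapping[str, int],
    pools: Mapping[str, float] | None = None,
) -> dict[str, int]:
    """One synchronous update: every rule reads the *previous* state."""

    nxt: dict[str, int] = {}
    for node in network.nodes:
        if node in network.input_states:
            nxt[node] = network.input_states[node]
        else:
            nxt[node] = evaluate_expr(network.rules[node], state, pools)
    return nxt


@dataclass(frozen=True)
class AttractorResult:
    """Cycle (length 1 = steady state) plus transient length, if found."""

    attractor: tuple[dict[str, int], ...]
    transient_length: int
    found: bool

    @property
    def cycle_length(self) -> int:
        return len(self.attractor)


def run_to_attractor(
    network: BooleanNetwork,
    state: Mapping[str, int],
    pools: Mapping[str, float] | None = None,
    max_steps: int = 10_000,
) -> AttractorResult:
    """Iterate until the first repeated state; pools are held constant.

    Returns the cycle starting at its first occurrence and the number of
    steps before entering it.  If no repeat appears within ``max_steps``
    the result is flagged not-found rather than raising.
    """

    order = list(network.nodes)
    current = dict(state)
    seen: dict[tuple[int, ...], int] = {}
    history: list[dict[str, int]] = []
    for step in range(max_steps + 1):
        key = tuple(current[n] for n in order)
        if key in seen:
            start = seen[key]
            return AttractorResult(
                attractor=tuple(history[start:]),
                transient_length=start,
                found=True,
            )
        seen[key] = step
        history.append(current)
        current = synchronous_step(network, current, pools)
    return AttractorResult(attractor=(), transient_length=max_steps, found=False)
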