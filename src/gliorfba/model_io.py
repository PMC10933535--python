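"""Readers/writers for the model's tabular formats and the Boolean-rule grammar.

File formats
------------
reaction table
    TSV with columns ``id, name, formula, lb, ub, reversible, cell, pathway,
    exchange``.  Formulas look like ``1 ADP_c + 1 Pi_c + 4 H_in_c = 1 H2O_c +
    1 ATP_c + 3 H_out_c``; coefficients default to 1, ``=``/``=>``/``->``/
    ``<=>`` all separate the two sides, and an empty right-hand side denotes a
    boundary exchange.  Blank bounds are filled from the reversibility default
    (+-1000).

rule file
    One ``NODE = expression`` per line, ``#`` comments.  The expression
    grammar: identifiers ``[A-Za-z][A-Za-z0-9_]*``; ``&`` (AND), ``|`` (OR),
    ``not(...)`` or ``!`` (NOT); round and square brackets are interchangeable
    grouping; threshold predicates ``ID > NUM`` / ``ID >= NUM`` (the
    identifier may itself be parenthesised, as in ``not((Glucose_T)>=0.5)``).
    Precedence: NOT > AND > OR.  ``<`` and ``<=`` are rejected explicitly.
    A stray unmatched closing bracket (one appears verbatim in the published
    CD28 rule) is dropped with a warning rather than guessed around silently.

states / pools tables
    TSV ``node <tab> state`` and ``metabolite <tab> initial_mM
    [<tab> coupled]`` where ``coupled`` lists signed transport couplings as
    ``RXN:+1,RXN2:-1``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pandas as pd

from .core_model import (
    And,
    BooleanExpr,
    BooleanNetwork,
    CellTag,
    Comparator,
    Const,
    Metabolite,
    MetabolitePool,
    ModelError,
    NodeRef,
    Not,
    Or,
    Reaction,
    StoichiometricModel,
    ThresholdPredicate,
    Trajectory,
    build_stoichiometric_matrix,
    default_bounds,
)

__all__ = [
    "RuleSource",
    "RuleSyntaxError",
    "parse_rule",
    "serialize_rule",
    "read_rules",
    "read_model",
    "write_model",
    "read_states",
    "write_states",
    "read_pools",
    "write_pools",
    "write_trajectory",
    "validate_bundle",
]

IDENT_RE = re.compile(r"[A-Za-z][A-Za-z0-9_]*")


@dataclass(frozen=True)
class RuleSource:
    """One raw rule line before parsing."""

    node_id: str
    rule_text: str
    line_number: int

    def __post_init__(self) -> None:
        if not self.rule_text.strip():
            raise ModelError(f"line {self.line_number}: empty rule text")
        if not IDENT_RE.fullmatch(self.node_id):
            raise ModelError(
                f"line {self.line_number}: bad node id {self.node_id!r}"
            )


class RuleSyntaxError(ModelError):
    """Rule text does not conform to the grammar."""

    def __init__(self, message: str, column: int, line: int | None = None):
        loc = f"line {line}, " if line is not None else ""
        super().__init__(f"{loc}column {column}: {message}")
        self.column = column
        self.line = line


# ---------------------------------------------------------------------------
# Tokenizer
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""
    (?P<WS>\s+)
  | (?P<NUM>\d+\.\d+|\.\d+|\d+)
  | (?P<ID>[A-Za-z][A-Za-z0-9_]*)
  | (?P<GE>>=)
  | (?P<GT>>)
  | (?P<BADCMP><=|<|==)
  | (?P<AND>&)
  | (?P<OR>\|)
  | (?P<NOTOP>!)
  | (?P<LPAR>[\(\[])
  | (?P<RPAR>[\)\]])
    """,
    re.VERBOSE,
)

# Unicode look-alikes that appear in typeset rule text.
_NORMALIZE = str.maketrans({
    "∣": "|",   # DIVIDES, used for OR in print
    "−": "-",   # minus sign
    "∧": "&",
    "∨": "|",
    "¬": "!",
})


def _drop_stray_closers(text: str) -> str:
    """Remove unmatched/mismatched closing brackets, warning per drop.

    Round and square brackets are interchangeable groupers, but a closer
    must still have *some* opener outstanding; e.g. the published CD28 rule
    contains ``[(Arginine_T)>0.02)]`` whose middle ``)`` has no partner.
    """

    out: list[str] = []
    depth = 0
    dropped: list[int] = []
    for i, ch in enumerate(text):
        if ch in "([":
            depth += 1
        elif ch in ")]":
            # bracket kinds are synonyms, so balance is pure depth counting;
            # a closer with nothing outstanding is the stray one
            if depth == 0:
                dropped.append(i)
                continue
            depth -= 1
        out.append(ch)
    if dropped:
        warnings.warn(
            f"dropped unmatched closing bracket(s) at column(s) "
            f"{[d + 1 for d in dropped]} in rule {text!r}",
            stacklevel=3,
        )
    return "".join(out)


def _tokenize(text: str) -> Iterator[tuple[str, str, int]]:
    pos = 0
    while pos < len(text):
        match = _TOKEN_RE.match(text, pos)
        if match is None:
            raise RuleSyntaxError(f"unexpected character {text[pos]!r}", pos + 1)
        kind = match.lastgroup
        assert kind is not None
        if kind == "BADCMP":
            raise RuleSyntaxError(
                f"comparator {match.group()!r} is not supported; only > and >= "
                "threshold predicates are defined",
                pos + 1,
            )
        if kind != "WS":
            yield kind, match.group(), pos + 1
        pos = match.end()
    yield "EOF", "", len(text) + 1


class _Parser:
    """Recursive-descent parser for the rule grammar (NOT > AND > OR)."""

    def __init__(self, text: str):
        self.text = text
        self.tokens = list(_tokenize(text))
        self.i = 0

    def peek(self) -> tuple[str, str, int]:
        return self.tokens[self.i]

    def next(self) -> tuple[str, str, int]:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, kind: str) -> tuple[str, str, int]:
        tok = self.next()
        if tok[0] != kind:
            raise RuleSyntaxError(
                f"expected {kind}, found {tok[1]!r}", tok[2]
            )
        return tok

    # grammar -----------------------------------------------------------

    def parse(self) -> BooleanExpr:
        expr = self.or_expr()
        tok = self.peek()
        if tok[0] != "EOF":
            raise RuleSyntaxError(f"trailing input {tok[1]!r}", tok[2])
        return expr

    def or_expr(self) -> BooleanExpr:
        operands = [self.and_expr()]
        while self.peek()[0] == "OR":
            self.next()
            operands.append(self.and_expr())
        return operands[0] if len(operands) == 1 else Or(tuple(operands))

    def and_expr(self) -> BooleanExpr:
        operands = [self.not_expr()]
        while self.peek()[0] == "AND":
            self.next()
            operands.append(self.not_expr())
        return operands[0] if len(operands) == 1 else And(tuple(operands))

    def not_expr(self) -> BooleanExpr:
        kind, value, col = self.peek()
        if kind == "NOTOP":
            self.next()
            return Not(self.not_expr())
        if kind == "ID" and value == "not":
            self.next()
            if self.peek()[0] != "LPAR":
                raise RuleSyntaxError("'not' must be followed by (...)", col)
            return Not(self.comparison())
        return self.comparison()

    def comparison(self) -> BooleanExpr:
        operand = self.primary()
        kind, value, col = self.peek()
        if kind in ("GE", "GT"):
            self.next()
            if not isinstance(operand, NodeRef):
                raise RuleSyntaxError(
                    "threshold comparison applies to a single identifier", col
                )
            num_tok = self.expect("NUM")
            comparator = Comparator.GE if kind == "GE" else Comparator.GT
            return ThresholdPredicate(operand.node_id, comparator, float(num_tok[1]))
        return operand

    def primary(self) -> BooleanExpr:
        kind, value, col = self.next()
        if kind == "LPAR":
            inner = self.or_expr()
            self.expect("RPAR")
            # the group may itself be the left side of a comparison,
            # e.g. (Glucose_T)>=0.5 -- handled by re-checking here
            nxt = self.peek()
            if nxt[0] in ("GE", "GT"):
                if not isinstance(inner, NodeRef):
                    raise RuleSyntaxError(
                        "threshold comparison applies to a single identifier",
                        nxt[2],
                    )
                self.next()
                num_tok = self.expect("NUM")
                comparator = Comparator.GE if nxt[0] == "GE" else Comparator.GT
                return ThresholdPredicate(
                    inner.node_id, comparator, float(num_tok[1])
                )
            return inner
        if kind == "ID":
            if value == "not":
                if self.peek()[0] != "LPAR":
                    raise RuleSyntaxError("'not' must be followed by (...)", col)
                return Not(self.primary())
            return NodeRef(value)
        if kind == "NUM":
            if value in ("0", "1"):
                return Const(value == "1")
            raise RuleSyntaxError(
                f"bare number {value!r}; only 0/1 constants are allowed", col
            )
        raise RuleSyntaxError(f"unexpected token {value!r}", col)


def parse_rule(text: str) -> BooleanExpr:
    """Parse one rule expression into a ``BooleanExpr`` tree."""

    normalized = _drop_stray_closers(text.translate(_NORMALIZE))
    return _Parser(normalized).parse()


def serialize_rule(expr: BooleanExpr) -> str:
    """Render an expression tree back to grammar-conformant text."""

    if isinstance(expr, NodeRef):
        return expr.node_id
    if isinstance(expr, Const):
        return "1" if expr.value else "0"
    if isinstance(expr, ThresholdPredicate):
        num = repr(expr.threshold) if expr.threshold % 1 else str(int(expr.threshold))
        return f"({expr.metabolite_id} {expr.comparator.value} {num})"
    if isinstance(expr, Not):
        return f"not({serialize_rule(expr.operand)})"
    if isinstance(expr, And):
        parts = []
        for op in expr.operands:
            text = serialize_rule(op)
            # parenthesize nested conjunctions too so that associativity
            # flattening cannot change the tree on re-parse
            if isinstance(op, (Or, And)):
                text = f"({text})"
            parts.append(text)
        return " & ".join(parts)
    if isinstance(expr, Or):
        parts = []
        for op in expr.operands:
            text = serialize_rule(op)
            if isinstance(op, Or):
                text = f"({text})"
            parts.append(text)
        return " | ".join(parts)
    raise TypeError(f"not a BooleanExpr: {expr!r}")


def read_rules(path: str | Path) -> list[RuleSource]:
    """Read a ``NODE = expression`` rule file, skipping blanks and comments."""

    sources: list[RuleSource] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ModelError(f"line {lineno}: expected 'NODE = expression'")
        node_id, rule_text = line.split("=", 1)
        sources.append(RuleSource(node_id.strip(), rule_text.strip(), lineno))
    return sources


# ---------------------------------------------------------------------------
# Reaction tables
# ---------------------------------------------------------------------------

_ARROW_RE = re.compile(r"<=>|=>|->|=")
_TERM_RE = re.compile(r"^\s*(?:(\d+(?:\.\d+)?|\.\d+)\s+)?([A-Za-z][A-Za-z0-9_]*)\s*$")


def parse_formula(formula: str) -> dict[str, float]:
    """Parse ``1 A + 2 B = 1 C`` into signed stoichiometric coefficients."""

    pieces = _ARROW_RE.split(formula, maxsplit=1)
    if len(pieces) == 1:
        raise ModelError(f"formula {formula!r} has no '=' separator")
    stoich: dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            match = _TERM_RE.match(term)
            if match is None:
                raise ModelError(f"malformed term {term.strip()!r} in {formula!r}")
            coeff = float(match.group(1)) if match.group(1) else 1.0
            met = match.group(2)
            stoich[met] = stoich.get(met, 0.0) + sign * coeff

    add_side(pieces[0], -1.0)
    add_side(pieces[1], +1.0)
    stoich = {m: c for m, c in stoich.items() if c != 0.0}
    if not stoich:
        raise ModelError(f"formula {formula!r} cancels to nothing")
    return stoich


_TRUE_STRINGS = {"true", "1", "yes", "t"}


def _parse_bool(value: object) -> bool:
    return str(value).strip().lower() in _TRUE_STRINGS


def read_model(path: str | Path) -> StoichiometricModel:
    """Read a reaction-table TSV into a stoichiometric model.

    Metabolites are auto-registered from formulas, with cell tags inferred
    from the id suffix (EXT species are flagged exchangeable).
    """

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"id", "formula", "reversible"}
    missing = required - set(df.columns)
    if missing:
        raise ModelError(f"reaction table missing columns: {sorted(missing)}")

    reactions: list[Reaction] = []
    met_order: dict[str, None] = {}
    seen_ids: set[str] = set()
    for _, row in df.iterrows():
        rxn_id = row["id"].strip()
        if rxn_id in seen_ids:
            raise ModelError(f"duplicate reaction id {rxn_id!r}")
        seen_ids.add(rxn_id)
        try:
            stoich = parse_formula(row["formula"])
        except ModelError as err:
            raise ModelError(f"reaction {rxn_id!r}: {err}") from None
        reversible = _parse_bool(row["reversible"])
        lb_raw = row.get("lb", "").strip()
        ub_raw = row.get("ub", "").strip()
        lb_def, ub_def = default_bounds(reversible)
        lb = float(lb_raw) if lb_raw else lb_def
        ub = float(ub_raw) if ub_raw else ub_def
        cell = row.get("cell", "").strip() or "EXT"
        reactions.append(
            Reaction(
                id=rxn_id,
                stoichiometry=stoich,
                lb=lb,
                ub=ub,
                reversible=reversible,
                cell_tag=CellTag(cell),
                pathway_tag=row.get("pathway", "").strip(),
                is_exchange=_parse_bool(row.get("exchange", "")),
            )
        )
        for met in stoich:
            met_order.setdefault(met, None)

    metabolites = []
    for met_id in met_order:
        tag = _suffix_to_tag(met_id)
        metabolites.append(
            Metabolite(
                id=met_id,
                name=met_id,
                cell_tag=tag,
                exchangeable=(tag is CellTag.EXT),
            )
        )
    return build_stoichiometric_matrix(reactions, metabolites)


def _suffix_to_tag(met_id: str) -> CellTag:
    for suffix, tag in (
        ("_EXT", CellTag.EXT),
        ("_M1", CellTag.M1),
        ("_M2", CellTag.M2),
        ("_T", CellTag.T),
        ("_c", CellTag.C),
        ("_C", CellTag.C),
    ):
        if met_id.endswith(suffix):
            return tag
    return CellTag.EXT


def write_model(model: StoichiometricModel, path: str | Path) -> None:
    """Write a model back to the reaction-table TSV format."""

    rows = []
    for rxn in model.reactions:
        lhs = " + ".join(
            f"{_fmt_coeff(-c)} {m}" for m, c in rxn.stoichiometry.items() if c < 0
        )
        rhs = " + ".join(
            f"{_fmt_coeff(c)} {m}" for m, c in rxn.stoichiometry.items() if c > 0
        )
        rows.append(
            {
                "id": rxn.id,
                "name": rxn.id,
                "formula": f"{lhs} = {rhs}".strip(),
                "lb": rxn.lb,
                "ub": rxn.ub,
                "reversible": str(rxn.reversible).lower(),
                "cell": rxn.cell_tag.value,
                "pathway": rxn.pathway_tag,
                "exchange": str(rxn.is_exchange).lower(),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _fmt_coeff(value: float) -> str:
    return str(int(value)) if value == int(value) else repr(value)


# ---------------------------------------------------------------------------
# States / pools / trajectory tables
# ---------------------------------------------------------------------------

def read_states(path: str | Path) -> dict[str, int]:
    """Read the input-node state table (``node <tab> state``)."""

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if not {"node", "state"} <= set(df.columns):
        raise ModelError("states table needs columns: node, state")
    states: dict[str, int] = {}
    for _, row in df.iterrows():
        node = row["node"].strip()
        if node in states:
            raise ModelError(f"duplicate node {node!r} in states table")
        value = int(row["state"])
        if value not in (0, 1):
            raise ModelError(f"node {node!r}: state must be 0/1")
        states[node] = value
    return states


def write_states(states: Mapping[str, int], path: str | Path) -> None:
    pd.DataFrame(
        {"node": list(states), "state": list(states.values())}
    ).to_csv(path, sep="\t", index=False)


def read_pools(path: str | Path) -> list[MetabolitePool]:
    """Read the metabolite-pool table.

    Columns: ``metabolite``, ``initial_mM`` (blank means 0) and optional
    ``coupled`` with comma-separated ``RXN:+1`` entries.
    """

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if not {"metabolite", "initial_mM"} <= set(df.columns):
        raise ModelError("pools table needs columns: metabolite, initial_mM")
    pools: list[MetabolitePool] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        met = row["metabolite"].strip()
        if met in seen:
            raise ModelError(f"duplicate pool {met!r}")
        seen.add(met)
        initial_raw = row["initial_mM"].strip()
        initial = float(initial_raw) if initial_raw else 0.0
        coupled: list[tuple[str, float]] = []
        raw = row.get("coupled", "").strip()
        if raw:
            for entry in raw.split(","):
                rxn, _, sign = entry.strip().partition(":")
                if not sign:
                    raise ModelError(f"pool {met!r}: bad coupling {entry!r}")
                coupled.append((rxn.strip(), float(sign)))
        pools.append(
            MetabolitePool(
                metabolite_id=met,
                initial_concentration=initial,
                coupled_transport_reactions=coupled,
            )
        )
    return pools


def write_pools(pools: Sequence[MetabolitePool], path: str | Path) -> None:
    rows = []
    for pool in pools:
        coupled = ",".join(
            f"{rxn}:{_fmt_sign(sign)}"
            for rxn, sign in pool.coupled_transport_reactions
        )
        rows.append(
            {
                "metabolite": pool.metabolite_id,
                "initial_mM": pool.initial_concentration,
                "coupled": coupled,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _fmt_sign(value: float) -> str:
    if value == int(value):
        return f"{int(value):+d}"
    return f"{value:+g}"


def write_trajectory(
    trajectory: Trajectory,
    path: str | Path,
    every: int = 1,
    reactions: Sequence[str] | None = None,
) -> None:
    """Write a trajectory in long format (time, kind, id, value).

    ``every`` keeps one metabolic tick in that many; ``reactions`` limits
    which flux series are written (all by default).  Events are always
    written.
    """

    if every < 1:
        raise ModelError("every must be >= 1")
    rows: list[tuple[float, str, str, float]] = []
    for k in range(0, len(trajectory), every):
        t = trajectory.times[k]
        for node, value in trajectory.boolean_states[k].items():
            rows.append((t, "state", node, float(value)))
        sol = trajectory.fluxes[k]
        for rxn_id, flux in sol.fluxes.items():
            if reactions is None or rxn_id in reactions:
                rows.append((t, "flux", rxn_id, flux))
        for met, conc in trajectory.pools[k].items():
            rows.append((t, "pool", met, conc))
    df = pd.DataFrame(rows, columns=["time", "kind", "id", "value"])
    df.to_csv(path, sep="\t", index=False)
    events_path = Path(path).with_suffix(".events.tsv")
    pd.DataFrame(trajectory.events, columns=["time", "label"]).to_csv(
        events_path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Cross-component validation
# ---------------------------------------------------------------------------

def validate_bundle(
    model: StoichiometricModel,
    network: BooleanNetwork,
    pools: Sequence[MetabolitePool],
) -> None:
    """Check that rules, pools and model resolve against each other.

    Raises listing every unknown id; also rejects a zero-initialised pool
    that a threshold predicate depends on (almost certainly a blank cell in
    the pools table rather than a deliberate choice).
    """

    problems: list[str] = []
    pool_ids = {p.metabolite_id for p in pools}
    pool_by_id = {p.metabolite_id: p for p in pools}

    missing_pools = network.pool_refs() - pool_ids
    if missing_pools:
        problems.append(f"rules reference unknown pools: {sorted(missing_pools)}")
    for pool in pools:
        for rxn_id, _ in pool.coupled_transport_reactions:
            if not model.has_reaction(rxn_id):
                problems.append(
                    f"pool {pool.metabolite_id!r} couples to unknown reaction "
                    f"{rxn_id!r}"
                )
    for met_id in network.pool_refs() & pool_ids:
        if pool_by_id[met_id].initial_concentration == 0.0:
            problems.append(
                f"pool {met_id!r} is referenced by a threshold predicate but "
                "has initial concentration 0 (blank table cell?)"
            )
    if problems:
        raise ModelError("; ".join(problems))
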