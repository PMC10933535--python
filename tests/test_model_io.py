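"""Rule grammar, tabular readers/writers, round-trips."""

import numpy as np
import pytest

from gliorfba.core_model import (
    And,
    Comparator,
    Const,
    ModelError,
    NodeRef,
    Not,
    Or,
    ThresholdPredicate,
)
from gliorfba import model_io
from gliorfba.model_io import (
    RuleSource,
    RuleSyntaxError,
    parse_formula,
    parse_rule,
    read_model,
    read_pools,
    read_rules,
    read_states,
    serialize_rule,
    validate_bundle,
    write_pools,
    write_states,
)


class TestParseRule:
    def test_or_precedence_below_and(self):
        expr = parse_rule("a & b | c")
        assert isinstance(expr, Or)
        assert isinstance(expr.operands[0], And)
        assert expr.operands[1] == NodeRef("c")

    def test_not_forms_equivalent(self):
        assert parse_rule("not(a) & b") == parse_rule("!a & b")

    def test_published_cd28_rule_with_stray_bracket(self):
        """The CD28 rule is printed with an unbalanced bracket; parsing must
        normalize it (with a warning) into OR(AND(...), predicate)."""

        with pytest.warns(UserWarning, match="unmatched"):
            expr = parse_rule("CD80_86_M1&not(ctla4_T)|[(Arginine_T)>0.02)]")
        assert isinstance(expr, Or)
        left, right = expr.operands
        assert left == And((NodeRef("CD80_86_M1"), Not(NodeRef("ctla4_T"))))
        assert right == ThresholdPredicate("Arginine_T", Comparator.GT, 0.02)

    def test_hif1a_rule(self):
        expr = parse_rule("(Succinate_M1>=1)|NF_kB_M1")
        assert expr == Or((
            ThresholdPredicate("Succinate_M1", Comparator.GE, 1.0),
            NodeRef("NF_kB_M1"),
        ))

    def test_square_brackets_are_grouping(self):
        assert parse_rule("[a | b] & c") == parse_rule("(a | b) & c")

    def test_parenthesised_identifier_comparison(self):
        expr = parse_rule("not((Glucose_T)>=0.5)")
        assert expr == Not(ThresholdPredicate("Glucose_T", Comparator.GE, 0.5))

    @pytest.mark.parametrize("bad", ["(Glucose_T)<0.5", "a <= 1", "x < 2"])
    def test_unknown_comparators_rejected(self, bad):
        with pytest.raises(RuleSyntaxError, match="comparator"):
            parse_rule(bad)

    def test_syntax_error_reports_column(self):
        with pytest.raises(RuleSyntaxError, match="column"):
            parse_rule("a & & b")

    def test_comparison_needs_identifier(self):
        with pytest.raises(RuleSyntaxError, match="identifier"):
            parse_rule("(a & b) > 1")

    def test_constants(self):
        assert parse_rule("1") == Const(True)
        assert parse_rule("0 | x") == Or((Const(False), NodeRef("x")))


def _random_expr(rng, depth=3):
    nodes = ["a", "b", "c", "d"]
    if depth == 0 or rng.random() < 0.3:
        roll = rng.random()
        if roll < 0.6:
            return NodeRef(str(rng.choice(nodes)))
        if roll < 0.85:
            cmp_ = Comparator.GE if rng.random() < 0.5 else Comparator.GT
            return ThresholdPredicate("P", cmp_, round(float(rng.uniform(0, 3)), 2))
        return Const(bool(rng.integers(0, 2)))
    roll = rng.random()
    if roll < 0.3:
        return Not(_random_expr(rng, depth - 1))
    op = And if roll < 0.65 else Or
    return op(tuple(_random_expr(rng, depth - 1) for _ in range(int(rng.integers(2, 4)))))


@pytest.mark.parametrize("seed", range(30))
def test_serialize_parse_round_trip(seed):
    """parse(serialize(expr)) is structurally the identity."""

    rng = np.random.default_rng(seed)
    expr = _random_expr(rng)
    assert parse_rule(serialize_rule(expr)) == expr


class TestRuleFile:
    def test_read_rules_skips_comments(self, tmp_path):
        path = tmp_path / "rules.txt"
        path.write_text("# header\nA = b & c\n\nB = !A  # inline\n")
        sources = read_rules(path)
        assert [(s.node_id, s.line_number) for s in sources] == [("A", 2), ("B", 4)]

    def test_empty_rule_text_rejected(self):
        with pytest.raises(ModelError, match="empty"):
            RuleSource("A", "   ", 3)


class TestReactionTable:
    def test_parse_formula_signed_coefficients(self):
        stoich = parse_formula("1 ADP + 1 Pi + 4 H_in = 1 H2O + 1 ATP + 3 H_out")
        assert stoich == {"ADP": -1, "Pi": -1, "H_in": -4,
                          "H2O": 1, "ATP": 1, "H_out": 3}

    def test_parse_formula_defaults_and_boundary(self):
        assert parse_formula("A + 2 B = C") == {"A": -1, "B": -2, "C": 1}
        assert parse_formula("1 Glc_EXT =") == {"Glc_EXT": -1}

    def test_toy_table(self, tmp_path):
        path = tmp_path / "model.tsv"
        path.write_text(
            "id\tname\tformula\tlb\tub\treversible\tcell\tpathway\texchange\n"
            "EX_A\tA in\t1 A_EXT =\t-10\t0\tfalse\tEXT\tboundary\ttrue\n"
            "T1\tuptake\t1 A_EXT = 1 A_T\t\t\tfalse\tT\tcore\ttrue\n"
            "R1\tconv\t1 A_T = 2 B_T\t\t\ttrue\tT\tcore\tfalse\n"
        )
        model = read_model(path)
        assert (model.m, model.n) == (3, 3)
        # blank bounds fall back to the reversibility defaults
        assert (model.reaction("T1").lb, model.reaction("T1").ub) == (0.0, 1000.0)
        assert (model.reaction("R1").lb, model.reaction("R1").ub) == (-1000.0, 1000.0)

    def test_duplicate_reaction_rejected(self, tmp_path):
        path = tmp_path / "model.tsv"
        path.write_text(
            "id\tformula\treversible\n"
            "R\t1 A = 1 B\tfalse\nR\t1 B = 1 A\tfalse\n"
        )
        with pytest.raises(ModelError, match="duplicate"):
            read_model(path)

    def test_model_round_trip(self, bundle, tmp_path):
        """model -> write -> read is the identity on ids, bounds, stoichiometry."""

        path = tmp_path / "model.tsv"
        model_io.write_model(bundle.model, path)
        again = read_model(path)
        assert [r.id for r in again.reactions] == [r.id for r in bundle.model.reactions]
        for r1, r2 in zip(bundle.model.reactions, again.reactions):
            assert dict(r1.stoichiometry) == dict(r2.stoichiometry)
            assert (r1.lb, r1.ub, r1.reversible) == (r2.lb, r2.ub, r2.reversible)
            assert (r1.cell_tag, r1.is_exchange) == (r2.cell_tag, r2.is_exchange)
        assert np.array_equal(again.S, bundle.model.S)


class TestStatesAndPools:
    def test_states_round_trip(self, tmp_path):
        states = {f"N{i}": i % 2 for i in range(34)}
        path = tmp_path / "states.tsv"
        write_states(states, path)
        assert read_states(path) == states

    def test_pools_round_trip(self, tmp_path):
        pools = [
            model_io.MetabolitePool(
                "Glucose_T", 1.0,
                coupled_transport_reactions=[("GLCup_c", -1.5)],
            ),
            model_io.MetabolitePool("Inert", 0.25),
        ]
        path = tmp_path / "pools.tsv"
        write_pools(pools, path)
        again = read_pools(path)
        assert [p.metabolite_id for p in again] == ["Glucose_T", "Inert"]
        assert again[0].coupled_transport_reactions == [("GLCup_c", -1.5)]
        assert again[1].initial_concentration == 0.25

    def test_bad_state_value_rejected(self, tmp_path):
        path = tmp_path / "states.tsv"
        path.write_text("node\tstate\nA\t2\n")
        with pytest.raises(ModelError, match="0/1"):
            read_states(path)

    def test_zero_pool_behind_predicate_rejected(self, bundle):
        pools = [
            model_io.MetabolitePool(p.metabolite_id, 0.0)
            for p in bundle.pools
        ]
        with pytest.raises(ModelError, match="initial concentration 0"):
            validate_bundle(bundle.model, bundle.network, pools)

    def test_unknown_coupled_reaction_listed(self, bundle):
        pools = list(bundle.pools) + [
            model_io.MetabolitePool(
                "Ghost", 1.0, coupled_transport_reactions=[("NOPE", 1.0)]
            )
        ]
        with pytest.raises(ModelError, match="NOPE"):
            validate_bundle(bundle.model, bundle.network, pools)


def test_write_trajectory_long_format(bundle, tmp_path):
    """Trajectories serialize to (time, kind, id, value) rows plus events."""

    import pandas as pd
    from gliorfba.exemplar_builder import exemplar_config
    from gliorfba.rfba_scheduler import run_simulation

    traj = run_simulation(
        bundle.model, bundle.network, bundle.pools, bundle.links,
        bundle.condition("glioma"), exemplar_config("glioma", n_steps=3),
    )
    path = tmp_path / "traj.tsv"
    model_io.write_trajectory(traj, path, every=14, reactions=["LACex_c"])
    df = pd.read_csv(path, sep="\t")
    assert set(df.columns) == {"time", "kind", "id", "value"}
    assert set(df["kind"]) == {"state", "flux", "pool"}
    assert set(df.loc[df.kind == "flux", "id"]) == {"LACex_c"}
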