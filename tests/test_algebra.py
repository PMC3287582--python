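"""Unit tests for the expression algebra and its operational semantics."""

import pytest

from npdl.algebra import (
    ArityError,
    GuardednessError,
    ProcessRegistry,
    UnknownNameError,
    alt,
    atom,
    enabled,
    guard,
    is_trace,
    make,
    name_ref,
    par,
    rep_n,
    rep_star,
    rewrite_extended,
    seq,
    step,
    terminated,
    trace_equivalent,
    traces,
    validate_expression,
    iter_nodes,
)
from npdl.text import parse_expression as P


class TestMake:
    def test_leaf_construction(self):
        leaf = make("atom", name="PCR_exon7")
        assert leaf.kind == "atom" and leaf.symbol.name == "PCR_exon7"
        assert leaf.symbol.kind == "regular"

    def test_binary_construction(self):
        e = make("seq", atom("a"), atom("b"))
        assert (e.kind, e.left.symbol.name, e.right.symbol.name) == ("seq", "a", "b")

    @pytest.mark.parametrize("bad", [0, -1, None, 1.5])
    def test_rep_n_requires_positive_count(self, bad):
        with pytest.raises(ArityError):
            make("rep_n", atom("a"), n=bad)

    def test_arity_violations(self):
        with pytest.raises(ArityError):
            make("seq", atom("a"))
        with pytest.raises(ArityError):
            make("rep_star", atom("a"), atom("b"))
        with pytest.raises(ArityError):
            make("no_such_kind", atom("a"))

    def test_reserved_symbols(self):
        assert atom("GO").symbol.kind == "silent"
        assert atom("END").symbol.kind == "terminal"


class TestEnabledStep:
    def test_sequence_head_only(self):
        assert {a for a, _ in enabled(P("a . b"))} == {"a"}

    def test_parallel_both_heads(self):
        assert {a for a, _ in enabled(P("a || b"))} == {"a", "b"}

    def test_false_guard_excludes_branch(self):
        e = P("a % r + b")
        ctx = lambda ref: (not False) if ref.negated else False  # r false
        assert {a for a, _ in enabled(e, ctx=ctx)} == {"b"}
        # consistency with the bounded-trace oracle under r fixed false
        assert traces(e, rule_values={"r": False}) == frozenset({("b",)})

    def test_step_consumes_sequence_head(self):
        e = P("a . b")
        (_, path), = enabled(e)
        assert step(e, path) == P("b")

    def test_step_merge_leaves_sibling(self):
        e = P("a || b")
        path = next(p for a, p in enabled(e) if a == "a")
        assert step(e, path) == P("b")

    def test_residual_trace_set(self):
        e = P("(a || b) . c")
        path = next(p for a, p in enabled(e) if a == "b")
        residual = step(e, path)
        assert traces(residual) == frozenset({("a", "c")})

    def test_step_requires_enabled_path(self):
        with pytest.raises(Exception):
            step(P("a . b"), ("R",))

    def test_residuals_deterministic(self):
        e = P("(a + a) . b || a ?*")
        ms = enabled(e)
        # each occurrence path appears exactly once
        paths = [p for _, p in ms]
        assert len(paths) == len(set(paths))


class TestTerminated:
    def test_empty_residual_after_full_run(self):
        e = P("a . b")
        r = e
        for act in ("a", "b"):
            path = next(p for a, p in enabled(r) if a == act)
            r = step(r, path)
        assert terminated(r)

    def test_unfinished_sequence_not_terminated(self):
        assert not terminated(P("a . b"))

    def test_one_or_more_repetition_terminates_after_one(self):
        e = P("a ?*")
        (_, path), = enabled(e)
        r = step(e, path)
        assert terminated(r)
        assert ("a",) in traces(e)  # the oracle agrees: one execution suffices
        # but zero executions do not: the empty trace is absent
        assert () not in traces(e)


class TestTraces:
    def test_sequence(self):
        assert traces(P("a . b")) == frozenset({("a", "b")})

    def test_two_interleavings(self):
        assert traces(P("a || b")) == frozenset({("a", "b"), ("b", "a")})

    def test_interleaving_then_sequence(self):
        assert traces(P("(a || b) . c"), loop_bound=1) == frozenset(
            {("a", "b", "c"), ("b", "a", "c")})

    def test_loop_bound_controls_unrolling(self):
        assert traces(P("a ?*"), loop_bound=3) == frozenset(
            {("a",), ("a", "a"), ("a", "a", "a")})

    def test_silent_actions_elided(self):
        assert traces(P("a . GO . b")) == frozenset({("a", "b")})

    def test_guarded_recursion_traces(self):
        reg = ProcessRegistry()
        reg.define("X", alt(atom("a"), seq(atom("a"), name_ref("X"))))
        got = traces(name_ref("X"), reg, loop_bound=3)
        assert got == frozenset({("a",), ("a", "a"), ("a", "a", "a")})

    def test_is_trace_matches_enumeration(self):
        e = P("(a || b . c) . d ?2")
        ts = traces(e, loop_bound=2)
        for t in ts:
            assert is_trace(e, t, loop_bound=2)
        assert not is_trace(e, ("d",), loop_bound=2)
        assert not is_trace(e, ("a", "b"), loop_bound=2)


class TestWorkflowPatterns:
    def test_multi_merge_fires_continuation_once_per_branch(self):
        ts = traces(P("(a & b) . c"))
        assert ts  # non-empty
        for t in ts:
            assert t.count("c") == 2

    def test_discriminator_fires_continuation_once(self):
        ts = traces(P("(a ^ b) . c"))
        for t in ts:
            assert t.count("c") == 1
        # the continuation never precedes the first branch completion
        for t in ts:
            assert t.index("c") >= 1

    def test_interleaved_parallel_is_sequential_permutations(self):
        assert traces(P("(a . b) |* (c . d)")) == frozenset(
            {("a", "b", "c", "d"), ("c", "d", "a", "b")})


class TestRewrite:
    def test_bounded_repetition_unrolls(self):
        out, _ = rewrite_extended(P("a ?3"))
        assert out == P("a . a . a")

    def test_unbounded_repetition_becomes_recursion(self):
        out, reg = rewrite_extended(P("a ?*"))
        assert out.kind == "name_ref"
        body = reg.resolve(out.ref_name)
        # X ::= a + a . X
        assert body == alt(atom("a"), seq(atom("a"), name_ref(out.ref_name)))
        for lb in (1, 2, 3):
            assert trace_equivalent(P("a ?*"), out, reg, loop_bound=lb)

    def test_function_repetition_rewrites_like_unbounded(self):
        out_f, reg_f = rewrite_extended(P("a ?f(count)"))
        out_s, reg_s = rewrite_extended(P("a ?*"))
        assert traces(out_f, reg_f, 3) == traces(out_s, reg_s, 3)

    @pytest.mark.parametrize("text", [
        "(a & b) . c",
        "(a ^ b) . c",
        "a |* b",
        "(a ?* ^ b) . c",
        "(a ^ b) . c ?*",
        "(a % r + b) ?2",
    ])
    def test_rewrite_preserves_traces(self, text):
        e = P(text)
        out, reg = rewrite_extended(e)
        assert traces(e, loop_bound=2) == traces(out, reg, loop_bound=2)

    @pytest.mark.parametrize("text", ["(a & b) . c", "(a ^ b) . c", "a ?* . b |* c"])
    def test_rewrite_output_uses_basic_operators_only(self, text):
        allowed = {"atom", "name_ref", "seq", "alt", "par", "guard"}
        out, reg = rewrite_extended(P(text))
        assert {n.kind for n in iter_nodes(out)} <= allowed | {"skip"}
        for _, body in reg.items():
            assert {n.kind for n in iter_nodes(body)} <= allowed

    def test_strip_guards_flag(self):
        out, _ = rewrite_extended(P("a % r . b"), strip_guards=True)
        assert all(n.kind != "guard" for n in iter_nodes(out))


class TestEquivalence:
    def test_choice_commutative(self):
        assert trace_equivalent(P("a + b"), P("b + a"))

    def test_sequence_not_commutative(self):
        assert not trace_equivalent(P("a . b"), P("b . a"))

    def test_multi_merge_against_manual_expansion(self):
        assert trace_equivalent(P("(a & b) . c"), P("(a . c) || (b . c)"))

    def test_left_distribution_of_seq_over_choice(self):
        assert trace_equivalent(P("a . (b + c)"), P("a . b + a . c"))


class TestGuardedness:
    def test_rejects_unguarded_self_reference(self):
        reg = ProcessRegistry()
        reg.define("X", alt(name_ref("X"), atom("a")))  # X ::= X + a
        with pytest.raises(GuardednessError):
            reg.validate()

    def test_accepts_guarded_recursion(self):
        reg = ProcessRegistry()
        reg.define("X", alt(atom("a"), seq(atom("a"), name_ref("X"))))
        reg.validate()

    def test_rejects_unguarded_mutual_recursion(self):
        reg = ProcessRegistry()
        reg.define("X", name_ref("Y"))
        reg.define("Y", alt(name_ref("X"), atom("a")))
        with pytest.raises(GuardednessError):
            reg.validate()

    def test_unresolved_reference(self):
        reg = ProcessRegistry()
        reg.define("X", seq(atom("a"), name_ref("Missing")))
        with pytest.raises(UnknownNameError):
            reg.validate()


class TestStaticValidation:
    def test_terminal_must_be_tail(self):
        validate_expression(P("(a || b) . END"))
        with pytest.raises(ArityError):
            validate_expression(P("END . a"))
        with pytest.raises(ArityError):
            validate_expression(P("a || END"))

    def test_oracle_conformance_small(self):
        """Every maximal enabled/step run of a small expression yields an
        oracle trace, and every oracle trace is reachable."""
        e = P("(a || b) . (c + d)")
        expected = traces(e, loop_bound=1)
        reached = set()

        def walk(expr, prefix):
            ms = sorted(enabled(expr), key=lambda ap: ap[1])
            if terminated(expr) and not ms:
                reached.add(tuple(prefix))
            if terminated(expr) and ms:
                reached.add(tuple(prefix))
            for act, path in ms:
                walk(step(expr, path), prefix + [act])

        walk(e, [])
        complete = {t for t in reached if t in expected}
        assert complete == expected
        # nothing outside the oracle set is a completed run
        for t in reached:
            if terminated_from(e, t):
                assert t in expected


def terminated_from(expr, trace):
    """Replay a trace through enabled/step; True if it ends terminable."""
    r = expr
    for act in trace:
        match = [p for a, p in sorted(enabled(r), key=lambda ap: ap[1]) if a == act]
        if not match:
            return False
        r = step(r, match[0])
    return terminated(r)
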