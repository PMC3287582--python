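"""Static analysis of control-flow expressions: traces, equivalence,
rewriting the extended operators to basic ones.

The bounded trace oracle enumerates every complete run (repetitions
unrolled at most loop_bound times, silent GO elided); trace equivalence
compares two expressions' run sets; rewrite_extended eliminates the
workflow operators (|*, &, ^, ?n, ?*, ?f) in favour of ., +, || and
guarded recursion.
"""

from npdl import (
    parse_expression,
    rewrite_extended,
    serialize_expression,
    trace_equivalent,
    traces,
)

e = parse_expression("(a || b) . c")
print("traces of (a || b) . c:", sorted(traces(e)))
# two interleavings of the parallel pair, each followed by c

print("choice commutes:",
      trace_equivalent(parse_expression("a + b"), parse_expression("b + a")))
print("sequence does not:",
      trace_equivalent(parse_expression("a . b"), parse_expression("b . a")))

rep = parse_expression("a ?*")
print("one-or-more repetition at loop bound 3:",
      sorted(traces(rep, loop_bound=3)))
# {a, aa, aaa}: ?* requires at least one execution

out, reg = rewrite_extended(rep)
print("rewritten to recursion:", serialize_expression(out), "where")
for name, body in reg.items():
    print(f"  define {name} = {serialize_expression(body)} ;")
# X ::= a + a . X is the classic guarded-recursion form of one-or-more

mm, mreg = rewrite_extended(parse_expression("(a & b) . c"))
print("multi-merge rewrites to:", serialize_expression(mm))
print("equivalent:",
      trace_equivalent(parse_expression("(a & b) . c"), mm, mreg))
# each branch completion fires the continuation once: (a . c) || (b . c)
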