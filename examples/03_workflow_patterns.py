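"""The workflow-pattern operators in action: multi-merge, discriminator,
interleaved parallel, and conditional gates.

These are the control-flow patterns a laboratory needs beyond plain
sequence/choice/parallel: fire a continuation per branch (&), fire it once
on the first completion (^), serialize two branches in either order (|*),
and hold a step until a Boolean rule is true (%).
"""

from npdl import ProcessRegistry, instantiate, parse_expression, traces

# multi-merge: analysis runs once per completing preparation branch
for t in sorted(traces(parse_expression("(prep_A & prep_B) . analysis"))):
    print("  &:", " -> ".join(t))
print("analysis fires twice in every run\n")

# discriminator: the first screening to finish triggers the report; the
# slower one still runs to completion but triggers nothing
for t in sorted(traces(parse_expression("(screen1 ^ screen2) . report"))):
    print("  ^:", " -> ".join(t))
print("report fires exactly once, after the first completion\n")

# interleaved parallel: one branch at a time, either order, no overlap
for t in sorted(traces(parse_expression("(wash . stain) |* (mix . load)"))):
    print("  |*:", " -> ".join(t))
print("the two-step branches never interleave\n")

# conditional execution: a guarded step is withheld while its rule is false.
# The ?* wrapper keeps prepare repeatable, so a failure can be recovered —
# without it a failed prepare would deadlock the instance (lifecycle
# "stuck", flagged for supervisor attention).
reg = ProcessRegistry()
reg.define("T", parse_expression("prepare ?* . (measure % ok_prepare)"))
inst = instantiate("T", reg)
print("released:", sorted({s.action for s in inst.released()}))
inst.report("prepare", "complete", "failed")
print("after a failed prepare:", sorted({s.action for s in inst.released()}))
# measure stays gated: only a later ok completion of prepare opens it
inst.report("prepare", "complete", "ok")
print("after prepare ok:", sorted({s.action for s in inst.released()}))
inst.report("measure", "complete", "ok")
print("after measure ok:", inst.lifecycle)

reg2 = ProcessRegistry()
reg2.define("D", parse_expression("prepare . (measure % ok_prepare)"))
dead = instantiate("D", reg2)
dead.report("prepare", "complete", "failed")
print("without ?*, a failed prepare leaves the instance:", dead.lifecycle)
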