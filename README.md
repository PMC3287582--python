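# npdl — a process-algebra workflow engine for genetic-testing management

`npdl` is a library (plus a thin command-line tool) for laboratories that
run many genetic tests in parallel and change their protocols often. It
lets an end user define a test as nothing more than a list of procedures
with execution-order integers; the package compiles that definition into a
formally analysable control-flow expression, checks it, and then interprets
the expression at run time to release the right bench steps at the right
moment, track every sample, and record a complete audit log. The target
users are developers of laboratory information management systems (LIMS)
and computational groups who want workflow control with formal guarantees
rather than hard-coded state machines.

## The model

Control flow is an ACP-style process algebra. Atomic actions are laboratory
procedures (one PCR, one extraction); expressions are built from

| notation | meaning |
|---|---|
| `P . Q` | sequential composition |
| `P + Q` | alternative composition (choice) |
| `P \|\| Q` | free merge — pure interleaving |
| `P \|* Q` | interleaved parallel routing: branches run one at a time, either order |
| `P & Q` | multi-merge: each branch completion fires the sequential continuation once |
| `P ^ Q` | discriminator: the first branch to complete fires the continuation once |
| `P ?*`, `P ?n`, `P ?f` | one-or-more / exactly-n / function-limited repetition |
| `P % r`, `P %! r` | conditional execution while Boolean rule `r` holds (or fails) |

`GO` is the unique silent action (fired by the system, elided from traces)
and `END` the unique terminal action — its release marks test completion.
The observational equivalence throughout is weak trace equivalence:
equality of complete-run sets with silent actions removed. The extended
operators add no expressive power: `rewrite_extended` eliminates them in
favour of `.`, `+`, `||` and guarded recursion, and the bounded trace
oracle verifies the equivalence.

A user-defined test compiles to a canonical form: procedures with the same
execution order are composed with `||`, groups are chained with `.` in
ascending order, each procedure `p` becomes `(p ?*) . (GO % ok_p)` so it
can be repeated until its last outcome is ok, and `END` closes the
expression.

## Worked example: the SMA test

Spinal muscular atrophy testing probes SMN1 exons 7 and 8 for the common
deletion; the two PCRs are independent and share one execution order.
Running `python examples/01_define_and_run_sma.py` prints:

```
compiled expression: ( PCR_exon7 ?* . GO % ok_PCR_exon7 || PCR_exon8 ?* . GO % ok_PCR_exon8 ) . END
released at start:   ['PCR_exon7', 'PCR_exon8']
after exon 7 ok:     ['PCR_exon7', 'PCR_exon8']
after exon 8 ok:    lifecycle = finished

sequence,action,status,outcome,timestamp
1,PCR_exon7,released,,2020-01-01T08:00:00
2,PCR_exon8,released,,2020-01-01T08:01:00
3,PCR_exon7,completed,ok,2020-01-01T08:02:00
4,PCR_exon8,completed,ok,2020-01-01T08:03:00
5,END,completed,ok,2020-01-01T08:04:00
```

Both PCRs are released immediately (they are parallel). After exon 7
completes, exon 8 is still pending **and exon 7 remains released** — the
`?*` keeps it repeatable in case the gel is unreadable. Once both have
completed with outcome ok, the two `GO` gates open silently and the engine
itself fires `END`: the test is finished, and the event log is the full
audit trail.

The other examples show static analysis (`02_analyze_expressions.py`), the
workflow-pattern operators (`03_workflow_patterns.py`), and a desk-scale
laboratory with the relational store and the two work-queue views
(`04_lab_repository_and_queues.py`). The same flows are available from the
shell via the `npdl` command (`npdl demo-sma`, `npdl queue --procedure
'PCR*'`, `npdl report --instance … --status complete`, …).

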