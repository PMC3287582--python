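# Methods

This note records the semantics the package implements, the choices made
where the design was genuinely open, the parameters that matter, and what
the synthetic generators do and do not emulate.

## Operational semantics

Expressions are interpreted in derivative style. `moves(E)` returns the
enabled initial actions of `E`, each with an *occurrence path* (a stable
identifier disambiguating equal labels in different branches) and the
*residual* expression left after consuming it; `terminated(E)` says whether
`E` may successfully terminate now with no obligatory work remaining.
Repeated `moves`/`step` application generates exactly the runs of `E`.
The merge `||` is pure interleaving: the processes of a genetics laboratory
never communicate, so ACP's communication/synchronisation merge is not
implemented.

**Observational equivalence** is weak trace equivalence: two expressions
are equal when their sets of complete runs coincide after the silent `GO`
is elided. `GO` is an internal "go on" marker fired by the system; a
laboratory observes only the bench procedures, so traces are the right
observations. Bisimulation or failures equivalence would distinguish more
than any user of the system can see.

**Repetition.** `?*` is one-or-more: a laboratory procedure written into a
test is performed at least once; "can be repeated as needed" refers to
re-execution, not to skipping. Its residual after one body is the internal
zero-or-more form, which both offers another execution and allows
termination. `?n` behaves as n sequential copies. `?f` is fixed to `?n` at
instantiation time by evaluating the named function against the instance
context; for static analysis (traces, rewriting) it is read as `?*`. The
two readings can differ in one corner — inside a discriminator branch an
`?n` withholds branch completion until all n copies are done, while `?*`
completes after the first — so run-time conformance checks are stated
against the instantiated form. A `?f` occurring behind a process-name
reference is analysed as `?*` as well; the instantiation-time evaluation
applies to the definition body being instantiated.

**Guards** are dynamic: `(P % r)` offers `P`'s initial actions only while
`r` evaluates true at the moment of the query; nothing is cached. A
residual that is not terminated and offers no moves is a deadlock: the
engine flags the instance as `stuck`. Three rule families are built in:
`ok_<procedure>` (true iff that procedure's last recorded outcome is ok)
and the constants `always`/`never`. `never` also gives the rewriter a
basic-operator encoding of a dead end (`GO % never`).

**Multi-merge and discriminator are context-sensitive.** The workflow
readings of `&` and `^` refer to "the continuation": `(L & R) . C` runs
`L` and `R` in parallel and fires `C` once per branch completion, so every
complete run of `(a & b) . c` contains `c` exactly twice; `(L ^ R) . C`
fires `C` exactly once, at the first branch completion, while the other
branch runs to completion with its completion absorbed. The continuation
is resolved *statically*, at expression load: a normalisation pass rewrites
`(L & R) . C` to `(L . C) || (R . C)` and turns a discriminator into an
internal race node carrying its continuation. The continuation never
crosses a repetition body, a guard, a parallel branch or a process-name
boundary — those scopes are sealed, and a bare `&` degenerates to `||`.
Static resolution was chosen over dynamic capture because repetition
unfolding creates new sequential contexts at run time, and capturing those
would make the meaning of an expression depend on its execution history.
Branch completion is eager: a branch counts as complete at the first point
its residual can terminate. One consequence worth knowing: sequential
composition does not right-distribute over choice when the left operand
contains `&` or `^` (the duplicated continuations choose independently);
the distribution law holds for all context-free operators.

**Discriminator race.** "First branch to complete" depends on the
interleaved run, so `^` has no compositional encoding into basic
operators. The rewriter compiles the race phase — pairs of branch
residuals, neither yet able to terminate — into fresh recursive
definitions, and on the resolving move continues compositionally with
`continuation || rest-of-other-branch`. When a branch itself contains
unbounded repetition or a name reference, its race phase is compiled at
the analysis depth (the loop bound, default 2), and trace equality is
guaranteed at that bound; race phases without unbounded loops are exact at
every bound. All other rewrites (`?n` unrolling, `?*`/`?f` to
`X ::= E + E . X`, `|*` to `(L . R) + (R . L)`, `&` distribution) are
exact at any bound.

## The bounded oracle and equivalence checking

`traces(E, loop_bound=k)` enumerates every complete run reachable with
each repetition/recursion unrolled at most k times (default 2 — enough to
distinguish one-or-more from exactly-once and to exercise every loop
twice), eliding silent actions; enumeration stops with an error past the
state cap (default 10^5 distinct residuals). `is_trace` decides membership
without enumerating the set. `trace_equivalent` decides equality of the
complete-trace sets by canonicalising the determinized bounded transition
systems (subset construction over the silent closure, bottom-up
minimal-acyclic-DFA signatures, dead ends pruned): interleaving-heavy
expressions have factorially many traces but only polynomially many
determinized states, so this is the only form that scales, and it is
cross-checked against literal `traces` equality on small inputs in the
test-suite. Expression nodes are hash-consed with cached structural
hashes; equality is then almost always pointer identity, which the subset
construction relies on.

## The engine

An instance's state is its residual expression, a fact table (per
procedure: times executed, last outcome), and an append-only event log.

* **Released steps** form the weak enabled set: every regular action
  reachable through silent moves alone. Silent steps are committed lazily —
  only when needed to consume a chosen user action or to reach `END`.
  Eager commitment would discard alternatives: after one PCR of a parallel
  pair completes, its ok-gate could fire immediately, but that would
  silently withdraw the repeat option the `?*` still offers. For queue
  purposes, each action contributes the occurrences of the first
  silent-reachable state in breadth-first order in which it is enabled.
* **Terminal handling:** as soon as `END` is reachable through silent
  steps only, the engine commits that path, logs `END` as a system
  completion, and sets the lifecycle to `finished` — the release of the
  terminal action is what marks test completion.
* **The four statuses:** `complete` consumes the occurrence (leftmost
  unless an explicit path is given), records the outcome, and re-derives
  the released set; `repeat` increments the execution count and records
  the outcome, leaving the residual unchanged (the latest outcome wins);
  `cancel` closes the instance as `canceled`; `finish` yields `finished`
  when the residual can terminate and `forced_finished` otherwise — the
  distinction preserves auditability of tests closed early.
* **Determinism and replay.** All tie-breaks (which occurrence, which
  silent path) take the first option in breadth-first, left-to-right
  order, and timestamps come from an injected clock, so replaying the
  user-initiated events of a log on a fresh instance reproduces residual,
  facts, lifecycle and the log itself bit for bit. Consecutive silent
  steps are capped (default 10^4) to catch ill-formed definitions.

Failed outcomes realise the repeat arrows of a test chart without an
explicit loop operator at engine level: a failed completion sets
`ok_<p>` false, the gate stays shut, and the `?*` keeps the procedure
released until a later ok completion.

## The test compiler

A test definition (procedures + execution-order integers + name,
description, duration in days, cost) compiles to
`G1 . G2 . … . Gk . END`, groups ascending by order, each group the
`||`-composition of `(p ?*) . (GO % ok_p)`. One gate per procedure (rather
than one per group) keeps each procedure individually repeatable until its
own success is recorded. Repetition is compiled into the expression, not
handled ad hoc by the engine, so static analysis sees the repeat
capability. Execution orders need not be consecutive; only their ranking
matters. Generated `ok_*` rule names are reserved: registering a user rule
with that prefix is an error.

## Persistence

An embedded SQLite store (plain-SQL DDL shipped as a migration file; dates
as ISO-8601 text) holds versioned process definitions as NPDL text,
the procedure catalog, tests, patients, samples, orders, instances and
events. Mid-execution residuals serialize through the same grammar — the
ACP constants `1` (empty process) and `0` (deadlock) plus the desugaring
of internal repetition/race forms keep every residual reparsable — and an
instance's facts are re-derived from its event log on load, so the work
queue is a pure function of persisted state. The procedure filter supports
exact names and a trailing-`*` prefix (enough for "all pending PCRs"
without inventing a query language); the disease filter selects one test's
orders.

## Synthetic generators

No external datasets exist for this problem; the generators make every
module testable from a seed (identical spec ⇒ identical output, no global
random state).

* `generate_random_expression` draws operator-weighted ASTs (sequence-heavy
  by default, every operator reachable, guards over named rules, recursion
  only through the repetition operators so guardedness holds by
  construction). Draws whose pattern-resolved form exceeds `max_atoms`
  atom occurrences (default 12) are redrawn deterministically: parallel
  width drives the analysis state space exponentially, and generated
  expressions are required to be enumerable under the oracle's state cap.
* `generate_workload` emulates a genetics laboratory at desk scale: a
  catalog of typical molecular procedures, tests of 1–4 procedures in 1–3
  order groups — the first is always the SMA shape (two parallel PCRs in
  one group) — plus patients, samples and orders. Scale defaults (5
  patients, 3 tests) are desk-checkable sizes; nothing in the machinery
  depends on them.
* `simulate` drives an instance with a seeded technician policy:
  uniformly chosen released steps, configurable repeat and failure
  probabilities, never re-completing a procedure whose last outcome is ok
  (repeats of successful work happen only through the explicit repeat
  status), and finishing with configurable probability once the residual
  allows termination.

What passing tests on this synthetic world do *not* show: real protocols
have data-dependent branching rules, human users race each other on shared
queues (the engine assumes a single writer per instance), and wet-lab
failures are not independent coin flips. The generators exercise the
control-flow semantics, not laboratory biology.

## Numerical and procedural choices

* Loop bound 2 and state cap 10^5 by default; both configurable
  everywhere they appear.
* Sizes used by the verification suite: 500 random expressions (depth ≤ 4)
  for rewrite soundness, 200 operand triples for the law suite (drawn
  without `&`/`^`, which are context-sensitive by design — see above),
  500 random definitions for engine/oracle conformance with membership
  checked at a bound covering the run length, realizability checked
  exhaustively on definitions of at most 6 atoms, 1000 ASTs for the parser
  round-trip. At these sizes the whole suite runs in well under a minute.
* The concrete grammar is this package's own dialect (identifiers,
  postfix repetition/guards binding tightest, then `.`, then one shared
  left-associative merge level `|| |* & ^`, then `+`; `#` comments;
  minimal-parenthesis serializer that round-trips structurally).
* Instance ids are caller-supplied or random; every deterministic test
  supplies them. Timestamps default to a fixed-start, fixed-step clock.

## Known limitations

* No communication/synchronisation merge, no bisimulation-grade
  equivalences, no stochastic or timed extensions.
* Discriminator branches containing unbounded loops rewrite exactly only
  at the configured analysis depth.
* The trace machinery is bounded by construction; properties are verified
  at the configured loop bound, not proved for all unrollings.
* Single writer per instance; no compensation for wet-lab work already
  performed when a test is canceled.
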