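"""Seeded synthetic generators: random expressions, lab workloads, policies.

No external datasets exist for this problem; everything the test-suite and
the demos need is generated here, deterministically from an explicit seed
(identical spec => bit-identical output, no global random state).

``generate_workload`` emulates a genetics-laboratory routine at desk scale:
a catalog of typical molecular procedures (DNA extraction, per-exon PCRs,
purification, sequencing, DHPLC screening, analysis...), tests composed of
1-4 procedures in 1-3 order groups — including SMA-shaped tests whose two
PCRs share one order group and therefore run in parallel — plus patients,
one or more DNA samples each, and test orders.  ``simulate`` then drives a
running instance with a random report policy (configurable repeat and
failure probabilities), standing in for the technicians working through
their queues.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .algebra import (
    ProcessExpr,
    RuleRef,
    alt,
    atom,
    disc,
    guard,
    ipar,
    mmerge,
    par,
    rep_f,
    rep_n,
    rep_star,
    seq,
)
from .builder import ProcedureCatalog, ProcedureDef, TestDefinition, TestItem
from .engine import ProcessInstance
from .repository import Patient, Sample, TestOrder

__all__ = [
    "ExprSpec",
    "WorkloadSpec",
    "generate_random_expression",
    "generate_workload",
    "Workload",
    "SimulationResult",
    "simulate",
]


# ---------------------------------------------------------------------------
# random expressions
# ---------------------------------------------------------------------------

#: operator weights used when none are given; sequence-heavy like real
#: laboratory flows, with every operator reachable
DEFAULT_OP_WEIGHTS = {
    "seq": 6, "alt": 3, "par": 3, "ipar": 1, "mmerge": 1, "disc": 1,
    "rep_star": 1, "rep_n": 1, "rep_f": 1, "guard": 1,
}


@dataclass(frozen=True)
class ExprSpec:
    """Recipe for one random expression (same spec => same expression).

    ``max_atoms`` bounds the number of atomic actions: parallel and
    multi-merge state spaces grow exponentially with width, and generated
    expressions must stay enumerable under the oracle's state cap, so
    oversized draws are deterministically redrawn.
    """

    seed: int
    max_depth: int = 4
    alphabet: Tuple[str, ...] = ("a", "b", "c", "d", "e")
    op_weights: Optional[Dict[str, int]] = None
    rule_names: Tuple[str, ...] = ("r1", "r2")
    func_names: Tuple[str, ...] = ("f1",)
    max_rep_n: int = 3
    max_atoms: int = 12


def generate_random_expression(spec: ExprSpec) -> ProcessExpr:
    """A structurally valid random expression of depth <= ``max_depth``.

    Leaves are atoms from the alphabet; recursion appears only through the
    repetition operators, so guardedness holds by construction.
    """
    rng = random.Random(spec.seed)
    weights = dict(spec.op_weights or DEFAULT_OP_WEIGHTS)
    ops = sorted(weights)
    wts = [weights[o] for o in ops]

    def gen(depth: int) -> ProcessExpr:
        if depth <= 0:
            return atom(rng.choice(spec.alphabet))
        op = rng.choices(ops, weights=wts)[0]
        if op == "seq":
            return seq(gen(depth - 1), gen(depth - 1))
        if op == "alt":
            return alt(gen(depth - 1), gen(depth - 1))
        if op == "par":
            return par(gen(depth - 1), gen(depth - 1))
        if op == "ipar":
            return ipar(gen(depth - 1), gen(depth - 1))
        if op == "mmerge":
            return mmerge(gen(depth - 1), gen(depth - 1))
        if op == "disc":
            return disc(gen(depth - 1), gen(depth - 1))
        if op == "rep_star":
            return rep_star(gen(depth - 1))
        if op == "rep_n":
            return rep_n(gen(depth - 1), rng.randint(1, spec.max_rep_n))
        if op == "rep_f":
            return rep_f(gen(depth - 1), rng.choice(spec.func_names))
        if op == "guard":
            return guard(gen(depth - 1),
                         RuleRef(rng.choice(spec.rule_names),
                                 negated=rng.random() < 0.25))
        raise AssertionError(op)

    if spec.max_depth <= 0:
        return gen(0)  # depth 0: a single atom
    from .algebra import resolve_patterns
    while True:
        e = gen(rng.randint(1, spec.max_depth))
        # measure atom *occurrences* of the pattern-resolved form (the AST
        # may share subterms): multi-merge duplicates its continuation, so
        # the raw count understates the state space
        if _atom_occurrences(resolve_patterns(e),
                             cap=4 * spec.max_atoms) <= spec.max_atoms:
            return e


def _atom_occurrences(expr: ProcessExpr, cap: int) -> int:
    count = 0
    stack = [expr]
    while stack and count <= cap:
        node = stack.pop()
        if node.kind == "atom":
            count += 1
        for child in (node.left, node.right, node.cont):
            if child is not None:
                stack.append(child)
    return count


# ---------------------------------------------------------------------------
# lab workloads
# ---------------------------------------------------------------------------

_PROCEDURE_POOL = (
    "DNA_extraction", "PCR_exon7", "PCR_exon8", "PCR_exon1", "PCR_exon45",
    "DNA_purification", "sequencing_reaction", "DHPLC_screening",
    "fragment_analysis", "MLPA", "restriction_digest", "gel_electrophoresis",
    "analysis",
)

_DISEASE_POOL = (
    "SMA", "DMD", "CF", "LGMD", "FSHD", "OPMD", "CMT", "SCA", "FRDA", "MJD",
)

_FIRST_NAMES = ("Ana", "Bruno", "Carla", "Diego", "Elisa", "Fabio", "Gilda",
                "Hugo", "Iara", "Joao", "Karen", "Luis")
_LAST_NAMES = ("Silva", "Santos", "Oliveira", "Souza", "Costa", "Pereira",
               "Almeida", "Nascimento")


@dataclass(frozen=True)
class WorkloadSpec:
    """Recipe for a synthetic laboratory workload."""

    seed: int
    n_patients: int = 5
    n_tests: int = 3
    max_procedures_per_test: int = 4
    max_order_groups: int = 3
    max_samples_per_patient: int = 2
    start_date: str = "2020-01-06"


@dataclass
class Workload:
    catalog: ProcedureCatalog
    tests: List[TestDefinition]
    patients: List[Patient]
    samples: List[Sample]
    orders: List[TestOrder]


def generate_workload(spec: WorkloadSpec) -> Workload:
    """A consistent synthetic dataset: catalog, valid tests, patients,
    samples and orders referencing only generated entities.

    The first generated test is always SMA-shaped — two parallel PCRs in a
    single order group — so the canonical worked example is present in every
    workload.
    """
    if spec.n_patients < 1 or spec.n_tests < 1:
        raise ValueError("counts must be >= 1")
    rng = random.Random(spec.seed)
    catalog = ProcedureCatalog(
        ProcedureDef(name, description=f"{name.replace('_', ' ')} procedure",
                     technique="molecular genetics",
                     reagents=("standard reagent kit",))
        for name in _PROCEDURE_POOL)

    tests: List[TestDefinition] = []
    sma = TestDefinition(
        name="SMA", description="Spinal muscular atrophy: SMN1 exon 7/8 deletion",
        duration_days=7, cost=120.0,
        items=(TestItem("PCR_exon7", 1), TestItem("PCR_exon8", 1)))
    tests.append(sma)
    diseases = [d for d in _DISEASE_POOL if d != "SMA"]
    for i in range(spec.n_tests - 1):
        disease = diseases[i % len(diseases)] + ("" if i < len(diseases) else str(i))
        n_procs = rng.randint(1, spec.max_procedures_per_test)
        procs = rng.sample(_PROCEDURE_POOL, n_procs)
        n_groups = rng.randint(1, min(spec.max_order_groups, n_procs))
        items = []
        for j, p in enumerate(procs):
            order = (j % n_groups) + 1
            items.append(TestItem(p, order))
        tests.append(TestDefinition(
            name=disease, description=f"{disease} diagnostic test",
            duration_days=rng.randint(3, 30), cost=round(rng.uniform(50, 500), 2),
            items=tuple(items)))

    patients = [Patient(1000 + i, f"{rng.choice(_FIRST_NAMES)} {rng.choice(_LAST_NAMES)}")
                for i in range(spec.n_patients)]
    samples: List[Sample] = []
    for p in patients:
        for k in range(rng.randint(1, spec.max_samples_per_patient)):
            samples.append(Sample(f"DNA{p.number}{chr(ord('a') + k)}", p.number))
    orders = []
    for i, s in enumerate(samples):
        test = rng.choice(tests)
        day = rng.randint(0, 28)
        month_day = 6 + day
        date = f"2020-01-{min(month_day, 31):02d}" if spec.start_date.startswith("2020-01") \
            else spec.start_date
        orders.append(TestOrder(id=i + 1, sample=s.dna_number,
                                test=test.name, request_date=date))
    return Workload(catalog=catalog, tests=tests, patients=patients,
                    samples=samples, orders=orders)


# ---------------------------------------------------------------------------
# execution policies
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    finished: bool
    stuck: bool
    lifecycle: str
    observed: List[str] = field(default_factory=list)  # silent-elided actions
    n_completions: int = 0
    n_repeats: int = 0


def simulate(instance: ProcessInstance,
             policy_seed: int,
             repeat_prob: float = 0.0,
             fail_prob: float = 0.0,
             fail_actions: Sequence[str] = (),
             max_repeats_per_action: int = 2,
             finish_prob: float = 0.5,
             max_steps: int = 60) -> SimulationResult:
    """Drive a running instance to a terminal lifecycle with a seeded random
    report policy.

    At each turn one released step is chosen uniformly; it is repeated with
    ``repeat_prob`` (at most ``max_repeats_per_action`` times per action) or
    completed, with outcome failed at ``fail_prob`` (actions listed in
    ``fail_actions`` always fail).  When the residual allows successful
    termination the run finishes with ``finish_prob`` per turn.  A stuck
    instance is reported in the result, not raised.
    """
    from .algebra import terminated

    rng = random.Random(policy_seed)
    result = SimulationResult(finished=False, stuck=False,
                              lifecycle=instance.lifecycle)
    repeats: Dict[str, int] = {}
    for ev in instance.log:  # terminal may fire during instantiation
        if ev.status == "completed":
            result.observed.append(ev.action)
    steps = 0
    while instance.lifecycle == "running" and steps < max_steps:
        steps += 1
        if terminated(instance.residual, instance.registry,
                      instance.ctx.eval_rule) and rng.random() < finish_prob:
            instance.report("", "finish")
            break
        released = instance.released()
        if not released:
            break
        actions = sorted({s.action for s in released})
        # a technician does not redo work that already succeeded; repeats of
        # ok procedures happen only through the explicit repeat status
        fresh = [a for a in actions
                 if instance.ctx.facts.get(a) is None
                 or instance.ctx.facts[a].last_outcome != "ok"]
        choice = rng.choice(fresh or actions)
        if (rng.random() < repeat_prob
                and repeats.get(choice, 0) < max_repeats_per_action):
            repeats[choice] = repeats.get(choice, 0) + 1
            instance.report(choice, "repeat")
            result.n_repeats += 1
            continue
        outcome = "failed" if (choice in fail_actions
                               or rng.random() < fail_prob) else "ok"
        n_before = len(instance.log)
        instance.report(choice, "complete", outcome)
        result.n_completions += 1
        for ev in instance.log[n_before:]:
            if ev.status == "completed":
                result.observed.append(ev.action)
    result.lifecycle = instance.lifecycle
    result.finished = instance.lifecycle in ("finished",)
    result.stuck = instance.lifecycle == "stuck"
    return result
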