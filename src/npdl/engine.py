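"""Instance execution: release steps, apply status reports, keep the log.

A :class:`ProcessInstance` is one running test for one sample.  Its state is
the *residual* process expression (what remains to be done), an evaluation
context of per-procedure facts, and an append-only event log.  The engine

* releases the user-visible steps by analysing the residual: the released
  set is the weak enabled set — every regular action reachable through
  silent ``GO`` steps alone.  Silent steps are committed lazily, only when
  needed to consume a chosen user action or to reach the terminal ``END``;
  this keeps alternatives (such as the repeat option of a just-completed
  procedure) open as long as the algebra allows them.
* fires the terminal ``END`` itself as soon as it is reachable through
  silent steps only, and marks the instance finished — the release of END
  is what signals completion of a test.
* applies the four execution statuses a laboratory user can report:
  ``complete`` (consume the step, record the outcome), ``repeat`` (log a
  re-execution, leave the residual unchanged), ``cancel`` (abort the test)
  and ``finish`` (close the test; if obligatory work remains the instance
  is marked force-finished rather than finished).

All nondeterministic choices (which occurrence of a label to consume, which
silent path to commit) default to the first in breadth-first, left-to-right
order, so a log replayed on a fresh instance reproduces the final state
exactly.
"""

from __future__ import annotations

import csv
import io
import json
import uuid
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .algebra import (
    _mk_node,
    BUILTIN_RULES,
    NpdlError,
    ProcessExpr,
    ProcessRegistry,
    RuleRef,
    UnknownNameError,
    iter_nodes,
    moves,
    rep_n,
    terminated,
)

__all__ = [
    "EngineError",
    "NotReleasedError",
    "InstanceNotRunning",
    "EvaluationContext",
    "ExecutionEvent",
    "ReleasedStep",
    "ProcessInstance",
    "TickClock",
    "ReplayClock",
    "instantiate",
    "replay",
    "facts_from_events",
    "OK_RULE_PREFIX",
    "DEFAULT_TAU_CAP",
]

OK_RULE_PREFIX = "ok_"
DEFAULT_TAU_CAP = 10_000

STATUSES = ("complete", "repeat", "cancel", "finish")
OUTCOMES = ("ok", "failed")


class EngineError(NpdlError):
    pass


class NotReleasedError(EngineError):
    """The reported action is not currently released."""


class InstanceNotRunning(EngineError):
    """A report or query requires a running instance."""


# ---------------------------------------------------------------------------
# clocks
# ---------------------------------------------------------------------------

class TickClock:
    """Deterministic clock: fixed start, fixed increment per call."""

    def __init__(self, start: str = "2020-01-01T08:00:00",
                 step_seconds: int = 60) -> None:
        from datetime import datetime, timedelta
        self._t = datetime.fromisoformat(start)
        self._dt = timedelta(seconds=step_seconds)

    def __call__(self) -> str:
        t = self._t
        self._t = t + self._dt
        return t.isoformat()


class ReplayClock:
    """Replays a recorded sequence of timestamps (for event-log replay)."""

    def __init__(self, timestamps: Sequence[str]) -> None:
        self._ts = list(timestamps)
        self._i = 0

    def __call__(self) -> str:
        if self._i < len(self._ts):
            t = self._ts[self._i]
            self._i += 1
            return t
        return self._ts[-1] if self._ts else "1970-01-01T00:00:00"


# ---------------------------------------------------------------------------
# evaluation context
# ---------------------------------------------------------------------------

@dataclass
class FactRecord:
    times_executed: int = 0
    last_outcome: str = "pending"  # ok | failed | pending


@dataclass
class EvaluationContext:
    """Facts about procedure executions plus the rule/function registries.

    Rule evaluation is pure and deterministic given the facts.  Three rule
    families resolve implicitly: ``ok_<procedure>`` is true iff that
    procedure's last outcome is ok, and ``always``/``never`` are constants.
    """

    facts: Dict[str, FactRecord] = field(default_factory=dict)
    rules: Dict[str, Callable[[Mapping[str, FactRecord]], bool]] = field(default_factory=dict)
    functions: Dict[str, Callable[[Mapping[str, FactRecord]], int]] = field(default_factory=dict)

    def fact(self, name: str) -> FactRecord:
        return self.facts.setdefault(name, FactRecord())

    def can_resolve_rule(self, name: str) -> bool:
        return (name in self.rules or name in BUILTIN_RULES
                or name.startswith(OK_RULE_PREFIX))

    def eval_rule(self, ref: RuleRef) -> bool:
        if ref.name in self.rules:
            value = bool(self.rules[ref.name](self.facts))
        elif ref.name in BUILTIN_RULES:
            value = BUILTIN_RULES[ref.name]
        elif ref.name.startswith(OK_RULE_PREFIX):
            proc = ref.name[len(OK_RULE_PREFIX):]
            rec = self.facts.get(proc)
            value = rec is not None and rec.last_outcome == "ok"
        else:
            raise UnknownNameError(f"unresolvable rule {ref.name!r}")
        return (not value) if ref.negated else value

    def eval_function(self, name: str) -> int:
        if name not in self.functions:
            raise UnknownNameError(f"unresolvable function {name!r}")
        value = int(self.functions[name](self.facts))
        if value < 1:
            raise EngineError(f"function {name!r} returned {value}; must be >= 1")
        return value


# ---------------------------------------------------------------------------
# events and released steps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExecutionEvent:
    seq: int
    action: str
    status: str       # released | completed | repeated | test_canceled | test_finished
    outcome: str      # ok | failed | "" (not applicable)
    timestamp: str    # ISO-8601
    path: str = ""    # resolved occurrence path (audit trail)


@dataclass(frozen=True)
class ReleasedStep:
    """One released occurrence of a procedure, ready for a status report."""

    action: str
    silent_prefix: Tuple[Tuple[str, ...], ...]  # silent steps to commit first
    path: Tuple[str, ...]                       # occurrence within that state


# ---------------------------------------------------------------------------
# the instance
# ---------------------------------------------------------------------------

class ProcessInstance:
    """A running test for one sample; created via :func:`instantiate`."""

    def __init__(self, instance_id: str, definition_name: str,
                 definition_version: int, registry: ProcessRegistry,
                 residual: ProcessExpr, ctx: EvaluationContext,
                 clock: Optional[Callable[[], str]] = None,
                 tau_cap: int = DEFAULT_TAU_CAP) -> None:
        self.id = instance_id
        self.definition_name = definition_name
        self.definition_version = definition_version
        self.registry = registry
        self.residual = residual
        self.ctx = ctx
        self.lifecycle = "running"  # running finished forced_finished canceled stuck
        self.log: List[ExecutionEvent] = []
        self.clock = clock or TickClock()
        self.tau_cap = tau_cap
        self._released: List[ReleasedStep] = []
        self._released_logged: Set[str] = set()

    # -- helpers -----------------------------------------------------------

    def _rule_ctx(self) -> Callable[[RuleRef], bool]:
        return self.ctx.eval_rule

    def _log(self, action: str, status: str, outcome: str = "",
             path: Tuple[str, ...] = ()) -> None:
        self.log.append(ExecutionEvent(
            seq=len(self.log) + 1, action=action, status=status,
            outcome=outcome, timestamp=self.clock(), path="/".join(path)))

    def _silent_closure(self) -> List[Tuple[ProcessExpr, Tuple[Tuple[str, ...], ...]]]:
        """States reachable from the residual by silent moves only, in
        deterministic breadth-first order, each with its committing path."""
        start = self.residual
        seen = {start}
        queue: List[Tuple[ProcessExpr, Tuple[Tuple[str, ...], ...]]] = [(start, ())]
        out = []
        while queue:
            e, pref = queue.pop(0)
            out.append((e, pref))
            if len(out) > self.tau_cap:
                raise EngineError("silent auto-advance exceeded the step cap")
            for m in moves(e, self.registry, self._rule_ctx()):
                if m.symbol.kind == "silent" and m.residual not in seen:
                    seen.add(m.residual)
                    queue.append((m.residual, pref + (m.path,)))
        return out

    def _commit_silent(self, prefix: Tuple[Tuple[str, ...], ...]) -> None:
        for p in prefix:
            for m in moves(self.residual, self.registry, self._rule_ctx()):
                if m.path == p:
                    self.residual = m.residual
                    break
            else:  # pragma: no cover - prefix comes from the closure
                raise EngineError("silent path no longer enabled")

    def _advance(self) -> None:
        """Fire END if silently reachable; otherwise recompute releases and
        detect finished/stuck states."""
        closure = self._silent_closure()
        rule_ctx = self._rule_ctx()
        # terminal auto-handling: the release of END completes the test
        for e, pref in closure:
            for m in moves(e, self.registry, rule_ctx):
                if m.symbol.kind == "terminal":
                    self._commit_silent(pref)
                    self.residual = m.residual
                    self._log(m.symbol.name, "completed", "ok", m.path)
                    self.lifecycle = "finished"
                    self._released = []
                    return
        # released steps: for each action, all occurrences in the first
        # closure state where it is enabled
        released: List[ReleasedStep] = []
        seen_actions: Set[str] = set()
        for e, pref in closure:
            state_moves = [m for m in moves(e, self.registry, rule_ctx)
                           if m.symbol.kind == "regular"]
            here = [m.symbol.name for m in state_moves]
            for m in state_moves:
                if m.symbol.name not in seen_actions:
                    released.append(ReleasedStep(m.symbol.name, pref, m.path))
            seen_actions.update(here)
        self._released = released
        if not released:
            for e, pref in closure:
                if terminated(e, self.registry, rule_ctx):
                    self._commit_silent(pref)
                    self.lifecycle = "finished"
                    return
            self.lifecycle = "stuck"
            return
        for step_ in released:
            if step_.action not in self._released_logged:
                self._log(step_.action, "released")
        self._released_logged = {s.action for s in released}

    # -- public API --------------------------------------------------------

    def released(self) -> List[ReleasedStep]:
        """The procedures currently awaiting a status report."""
        if self.lifecycle in ("canceled",):
            raise InstanceNotRunning(f"instance {self.id} is {self.lifecycle}")
        if self.lifecycle != "running":
            return []
        return list(self._released)

    def released_actions(self) -> List[str]:
        return [s.action for s in self.released()] if self.lifecycle == "running" else []

    def report(self, action: str, status: str, outcome: str = "ok",
               path: Optional[Tuple[str, ...]] = None) -> "ProcessInstance":
        """Apply one user status report; returns self for chaining."""
        if status not in STATUSES:
            raise EngineError(f"unknown status {status!r}")
        if outcome not in OUTCOMES:
            raise EngineError(f"unknown outcome {outcome!r}")
        if self.lifecycle != "running":
            raise InstanceNotRunning(
                f"instance {self.id} is {self.lifecycle}, not running")

        if status == "cancel":
            self._log(action, "test_canceled")
            self.lifecycle = "canceled"
            self._released = []
            return self

        if status == "finish":
            done = terminated(self.residual, self.registry, self._rule_ctx())
            self._log(action, "test_finished")
            self.lifecycle = "finished" if done else "forced_finished"
            self._released = []
            return self

        candidates = [s for s in self._released if s.action == action]
        if not candidates:
            raise NotReleasedError(f"procedure {action!r} is not released")

        if status == "repeat":
            rec = self.ctx.fact(action)
            rec.times_executed += 1
            rec.last_outcome = outcome
            self._log(action, "repeated", outcome)
            return self

        # complete: leftmost occurrence unless an explicit path is given
        chosen = candidates[0]
        if path is not None:
            for c in candidates:
                if c.path == tuple(path):
                    chosen = c
                    break
            else:
                raise NotReleasedError(
                    f"occurrence {path!r} of {action!r} is not released")
        self._commit_silent(chosen.silent_prefix)
        for m in moves(self.residual, self.registry, self._rule_ctx()):
            if m.path == chosen.path:
                self.residual = m.residual
                break
        else:  # pragma: no cover - guarded by the released computation
            raise NotReleasedError(f"occurrence of {action!r} vanished")
        rec = self.ctx.fact(action)
        rec.times_executed += 1
        rec.last_outcome = outcome
        self._log(action, "completed", outcome, chosen.path)
        self._advance()
        return self

    # -- exports -----------------------------------------------------------

    def log_to_csv(self) -> str:
        buf = io.StringIO()
        w = csv.writer(buf)
        w.writerow(["sequence", "action", "status", "outcome", "timestamp"])
        for ev in self.log:
            w.writerow([ev.seq, ev.action, ev.status, ev.outcome, ev.timestamp])
        return buf.getvalue()

    def log_to_json(self) -> str:
        return json.dumps([ev.__dict__ for ev in self.log], indent=2)


# ---------------------------------------------------------------------------
# instantiation and replay
# ---------------------------------------------------------------------------

def _resolve_rep_f(expr: ProcessExpr, ctx: EvaluationContext) -> ProcessExpr:
    """Evaluate every f-limited repetition against the instance context,
    fixing it to a number-limited repetition (done once, at instantiation)."""
    if expr.kind == "rep_f":
        inner = _resolve_rep_f(expr.left, ctx)
        return rep_n(inner, ctx.eval_function(expr.func_name))
    kw = {}
    for f in ("left", "right", "cont"):
        child = getattr(expr, f)
        if child is not None:
            kw[f] = _resolve_rep_f(child, ctx)
    if not kw:
        return expr
    return _mk_node(expr.kind, symbol=expr.symbol, ref_name=expr.ref_name,
                       n=expr.n, func_name=expr.func_name, rule=expr.rule,
                       **{**{"left": expr.left, "right": expr.right, "cont": expr.cont},
                          **kw})


def _check_rules_resolvable(expr: ProcessExpr, registry: ProcessRegistry,
                            ctx: EvaluationContext,
                            _seen: Optional[Set[str]] = None) -> None:
    seen = _seen if _seen is not None else set()
    for node in iter_nodes(expr):
        if node.kind == "guard" and not ctx.can_resolve_rule(node.rule.name):
            raise UnknownNameError(f"unresolvable rule {node.rule.name!r}")
        if node.kind == "rep_f" and node.func_name not in ctx.functions:
            raise UnknownNameError(f"unresolvable function {node.func_name!r}")
        if node.kind == "name_ref" and node.ref_name not in seen:
            seen.add(node.ref_name)
            _check_rules_resolvable(registry.resolve(node.ref_name), registry,
                                    ctx, seen)


def instantiate(definition_name: str,
                registry: ProcessRegistry,
                initial_facts: Optional[Mapping[str, str]] = None,
                rules: Optional[Dict[str, Callable]] = None,
                functions: Optional[Dict[str, Callable]] = None,
                instance_id: Optional[str] = None,
                clock: Optional[Callable[[], str]] = None,
                tau_cap: int = DEFAULT_TAU_CAP) -> ProcessInstance:
    """Create and start a process instance for *definition_name*.

    ``initial_facts`` maps procedure names to an initial last outcome.
    Raises if the definition is unknown, recursion is unguarded, or a rule
    or repetition function cannot be resolved.
    """
    registry.validate()
    expr = registry.resolve(definition_name)
    version = registry.version(definition_name)
    for rname in (rules or {}):
        if rname.startswith(OK_RULE_PREFIX) or rname in BUILTIN_RULES:
            raise EngineError(
                f"rule name {rname!r} collides with a built-in rule family")
    ctx = EvaluationContext(rules=dict(rules or {}), functions=dict(functions or {}))
    for proc, outcome in (initial_facts or {}).items():
        ctx.facts[proc] = FactRecord(times_executed=0, last_outcome=outcome)
    _check_rules_resolvable(expr, registry, ctx)
    expr = _resolve_rep_f(expr, ctx)
    inst = ProcessInstance(
        instance_id=instance_id or ("inst-" + uuid.uuid4().hex[:12]),
        definition_name=definition_name, definition_version=version,
        registry=registry, residual=expr, ctx=ctx, clock=clock, tau_cap=tau_cap)
    inst._advance()
    return inst


_STATUS_TO_REPORT = {
    "completed": "complete",
    "repeated": "repeat",
    "test_canceled": "cancel",
    "test_finished": "finish",
}


def replay(definition_name: str,
           registry: ProcessRegistry,
           events: Sequence[ExecutionEvent],
           rules: Optional[Dict[str, Callable]] = None,
           functions: Optional[Dict[str, Callable]] = None,
           instance_id: Optional[str] = None) -> ProcessInstance:
    """Rebuild an instance by replaying its event log from scratch.

    Only user-initiated events are re-applied; system events (releases,
    terminal completion) are regenerated by the deterministic engine, so a
    faithful log reproduces residual, facts and lifecycle exactly.
    """
    clock = ReplayClock([ev.timestamp for ev in events])
    inst = instantiate(definition_name, registry, rules=rules,
                       functions=functions, instance_id=instance_id,
                       clock=clock)
    for ev in events:
        if ev.status == "released":
            continue
        if ev.status == "completed" and ev.action == "END":
            continue  # terminal completions are system-generated
        status = _STATUS_TO_REPORT.get(ev.status)
        if status is None:
            raise EngineError(f"unknown event status {ev.status!r}")
        inst.report(ev.action, status, ev.outcome or "ok",
                    path=tuple(ev.path.split("/")) if (status == "complete" and ev.path) else None)
    return inst


def facts_from_events(events: Iterable[ExecutionEvent]) -> Dict[str, FactRecord]:
    """Derive the per-procedure facts implied by an event log."""
    facts: Dict[str, FactRecord] = {}
    for ev in events:
        if ev.status in ("completed", "repeated") and ev.action != "END":
            rec = facts.setdefault(ev.action, FactRecord())
            rec.times_executed += 1
            rec.last_outcome = ev.outcome or "ok"
    return facts
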