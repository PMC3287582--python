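"""Process-expression algebra: AST, operational semantics, trace oracle, rewriting.

The control-flow language is an ACP-style process algebra extended with the
workflow operators used by process-aware laboratory systems:

=========  =============================  ====================================
notation   node kind                      meaning
=========  =============================  ====================================
``a``      atom                           one atomic action (lab procedure)
``X``      name_ref                       call of a named (possibly recursive)
                                          process definition
``P . Q``  seq                            sequential composition
``P + Q``  alt                            alternative composition (choice)
``P || Q`` par                            free merge (pure interleaving)
``P |* Q`` ipar                           interleaved parallel routing: the
                                          branches run one at a time, in
                                          either order, never overlapped
``P & Q``  mmerge                         multi-merge: each branch completion
                                          independently fires the sequential
                                          continuation once
``P ^ Q``  disc                           discriminator: the first branch to
                                          complete fires the continuation
                                          once; the other branch still runs,
                                          its completion is absorbed
``P ?*``   rep_star                       one-or-more repetition
``P ?n``   rep_n                          exactly-n repetition (n >= 1)
``P ?f``   rep_f                          f-limited repetition; f yields a
                                          positive integer at instantiation,
                                          statically analysed as ``?*``
``P % r``  guard                          conditional execution: P may start
                                          only while Boolean rule r holds
``P %! r`` guard (negated)                as above with r negated
=========  =============================  ====================================

Two action names are reserved: ``GO`` is the unique silent action (fired by
the system, elided from traces) and ``END`` the unique terminal action (its
release marks completion of a test).  The observational equivalence used
throughout is weak trace equivalence: equality of the sets of complete runs
with silent actions removed.

Semantics is given in derivative style: :func:`moves` returns the enabled
initial actions of an expression together with the residual expression left
after each of them, and :func:`terminated` says whether an expression may
successfully terminate right away.  :func:`traces` is the brute-force bounded
oracle built on top of this; :func:`rewrite_extended` eliminates the extended
operators in favour of ``.``, ``+``, ``||`` and guarded recursion and is
checked against the oracle.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Dict, FrozenSet, Iterator, List, Mapping, Optional, Sequence, Set, Tuple

__all__ = [
    "ActionSymbol",
    "RuleRef",
    "ProcessExpr",
    "ProcessRegistry",
    "Move",
    "Trace",
    "NpdlError",
    "ArityError",
    "GuardednessError",
    "StateCapExceeded",
    "UnknownNameError",
    "atom",
    "symbol",
    "make",
    "seq",
    "alt",
    "par",
    "ipar",
    "mmerge",
    "disc",
    "rep_star",
    "rep_n",
    "rep_f",
    "guard",
    "name_ref",
    "SKIP",
    "GO",
    "END",
    "moves",
    "enabled",
    "step",
    "terminated",
    "traces",
    "is_trace",
    "trace_equivalent",
    "rewrite_extended",
    "validate_expression",
    "validate_terminal_tail",
    "iter_nodes",
    "DEFAULT_LOOP_BOUND",
    "DEFAULT_STATE_CAP",
]

IDENT_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*\Z")

SILENT_NAME = "GO"
TERMINAL_NAME = "END"

DEFAULT_LOOP_BOUND = 2
DEFAULT_STATE_CAP = 100_000


class NpdlError(Exception):
    """Base class for all library errors."""


class ArityError(NpdlError, ValueError):
    """A node was built with the wrong operands or parameters."""


class GuardednessError(NpdlError):
    """A recursive definition performs no action before calling itself."""


class StateCapExceeded(NpdlError):
    """Bounded enumeration visited more residual states than allowed."""


class UnknownNameError(NpdlError, KeyError):
    """A process name, rule or function did not resolve."""


# ---------------------------------------------------------------------------
# symbols and rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ActionSymbol:
    """A named atomic action; regular, silent (GO) or terminal (END)."""

    name: str
    kind: str = "regular"

    def __post_init__(self) -> None:
        if not IDENT_RE.match(self.name):
            raise ArityError(f"invalid action name {self.name!r}")
        if self.kind not in ("regular", "silent", "terminal"):
            raise ArityError(f"invalid symbol kind {self.kind!r}")
        # GO and END are the only silent/terminal symbols, and vice versa.
        if (self.name == SILENT_NAME) != (self.kind == "silent"):
            raise ArityError("the silent symbol must be named GO and GO must be silent")
        if (self.name == TERMINAL_NAME) != (self.kind == "terminal"):
            raise ArityError("the terminal symbol must be named END and END must be terminal")


def symbol(name: str) -> ActionSymbol:
    """Build the symbol for *name*, assigning the reserved kinds for GO/END."""
    if name == SILENT_NAME:
        return ActionSymbol(name, "silent")
    if name == TERMINAL_NAME:
        return ActionSymbol(name, "terminal")
    return ActionSymbol(name, "regular")


@dataclass(frozen=True)
class RuleRef:
    """Reference to a Boolean rule, possibly negated (``% r`` / ``%! r``)."""

    name: str
    negated: bool = False

    def __post_init__(self) -> None:
        if not IDENT_RE.match(self.name):
            raise ArityError(f"invalid rule name {self.name!r}")


# ---------------------------------------------------------------------------
# the AST
# ---------------------------------------------------------------------------

#: public node kinds (the surface language)
PUBLIC_KINDS = (
    "atom", "name_ref", "seq", "alt", "par", "ipar", "mmerge", "disc",
    "rep_star", "rep_n", "rep_f", "guard",
)
#: internal node kinds used by the semantics only
INTERNAL_KINDS = (
    "skip",       # the successfully terminated process (unit)
    "dead",       # bounded-unfolding cut-off: no moves, cannot terminate
    "star0",      # zero-or-more repetition (residual of ?*)
    "disc_race",  # running discriminator: (left residual, right residual, continuation)
)

BINARY_KINDS = frozenset({"seq", "alt", "par", "ipar", "mmerge", "disc"})
UNARY_KINDS = frozenset({"rep_star", "rep_n", "rep_f", "guard", "star0"})
LEAF_KINDS = frozenset({"atom", "name_ref", "skip", "dead"})


@dataclass(frozen=True)
class ProcessExpr:
    """One node of a process expression.  Use :func:`make` or the helper
    constructors; the dataclass itself performs no validation."""

    kind: str
    left: Optional["ProcessExpr"] = None
    right: Optional["ProcessExpr"] = None
    symbol: Optional[ActionSymbol] = None
    ref_name: Optional[str] = None
    n: Optional[int] = None
    func_name: Optional[str] = None
    rule: Optional[RuleRef] = None
    cont: Optional["ProcessExpr"] = None  # disc_race only

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        from .text import serialize_expression
        try:
            return f"ProcessExpr<{serialize_expression(self)}>"
        except Exception:
            return f"ProcessExpr(kind={self.kind!r})"


_EXPR_FIELDS = ("kind", "left", "right", "symbol", "ref_name", "n",
                "func_name", "rule", "cont")


def _expr_hash(self: ProcessExpr) -> int:
    h = self.__dict__.get("_hash")
    if h is None:
        h = hash(tuple(getattr(self, f) for f in _EXPR_FIELDS))
        object.__setattr__(self, "_hash", h)
    return h


def _expr_eq(self: ProcessExpr, other) -> bool:
    if self is other:
        return True
    if not isinstance(other, ProcessExpr):
        return NotImplemented
    if _expr_hash(self) != _expr_hash(other):
        return False
    return all(getattr(self, f) == getattr(other, f) for f in _EXPR_FIELDS)


# expressions are compared and hashed constantly (memo tables, subset
# construction); cache the structural hash per node
ProcessExpr.__hash__ = _expr_hash  # type: ignore[assignment]
ProcessExpr.__eq__ = _expr_eq      # type: ignore[assignment]


_NODE_CACHE: Dict[Tuple, ProcessExpr] = {}
_NODE_CACHE_MAX = 2_000_000


def _mk_node(kind: str,
             left: Optional[ProcessExpr] = None,
             right: Optional[ProcessExpr] = None,
             symbol: Optional[ActionSymbol] = None,
             ref_name: Optional[str] = None,
             n: Optional[int] = None,
             func_name: Optional[str] = None,
             rule: Optional[RuleRef] = None,
             cont: Optional[ProcessExpr] = None) -> ProcessExpr:
    """Hash-consing constructor: structurally equal nodes are one object,
    so the equality fast path (identity) almost always fires."""
    key = (kind, left, right, symbol, ref_name, n, func_name, rule, cont)
    hit = _NODE_CACHE.get(key)
    if hit is None:
        if len(_NODE_CACHE) >= _NODE_CACHE_MAX:
            _NODE_CACHE.clear()
        hit = ProcessExpr(kind, left, right, symbol, ref_name, n,
                          func_name, rule, cont)
        _NODE_CACHE[key] = hit
    return hit


SKIP = _mk_node("skip")
DEAD = _mk_node("dead")
GO = _mk_node("atom", symbol=ActionSymbol(SILENT_NAME, "silent"))
END = _mk_node("atom", symbol=ActionSymbol(TERMINAL_NAME, "terminal"))


def make(kind: str, *operands: ProcessExpr, **params) -> ProcessExpr:
    """Checked node constructor.

    Raises :class:`ArityError` on wrong arity, ``n < 1``, or unknown kind.
    """
    if kind == "atom":
        if operands or set(params) - {"symbol", "name"}:
            raise ArityError("atom takes no operands")
        sym = params.get("symbol")
        if sym is None:
            sym = symbol(params["name"])
        return _mk_node("atom", symbol=sym)
    if kind == "name_ref":
        if operands:
            raise ArityError("name_ref takes no operands")
        name = params["name"]
        if not IDENT_RE.match(name):
            raise ArityError(f"invalid process name {name!r}")
        return _mk_node("name_ref", ref_name=name)
    if kind in BINARY_KINDS:
        if len(operands) != 2:
            raise ArityError(f"{kind} takes exactly two operands, got {len(operands)}")
        return _mk_node(kind, left=operands[0], right=operands[1])
    if kind in ("rep_star", "star0"):
        if len(operands) != 1:
            raise ArityError(f"{kind} takes exactly one operand")
        return _mk_node(kind, left=operands[0])
    if kind == "rep_n":
        if len(operands) != 1:
            raise ArityError("rep_n takes exactly one operand")
        n = params.get("n")
        if not isinstance(n, int) or n < 1:
            raise ArityError(f"rep_n requires integer n >= 1, got {n!r}")
        return _mk_node("rep_n", left=operands[0], n=n)
    if kind == "rep_f":
        if len(operands) != 1:
            raise ArityError("rep_f takes exactly one operand")
        fname = params.get("func_name")
        if not fname or not IDENT_RE.match(fname):
            raise ArityError(f"rep_f requires a valid func_name, got {fname!r}")
        return _mk_node("rep_f", left=operands[0], func_name=fname)
    if kind == "guard":
        if len(operands) != 1:
            raise ArityError("guard takes exactly one operand")
        rule = params.get("rule")
        if not isinstance(rule, RuleRef):
            raise ArityError("guard requires rule=RuleRef(...)")
        return _mk_node("guard", left=operands[0], rule=rule)
    raise ArityError(f"unknown node kind {kind!r}")


# convenience constructors -------------------------------------------------

def atom(name: str) -> ProcessExpr:
    return make("atom", name=name)


def name_ref(name: str) -> ProcessExpr:
    return make("name_ref", name=name)


def seq(left: ProcessExpr, right: ProcessExpr) -> ProcessExpr:
    return make("seq", left, right)


def alt(left: ProcessExpr, right: ProcessExpr) -> ProcessExpr:
    return make("alt", left, right)


def par(left: ProcessExpr, right: ProcessExpr) -> ProcessExpr:
    return make("par", left, right)


def ipar(left: ProcessExpr, right: ProcessExpr) -> ProcessExpr:
    return make("ipar", left, right)


def mmerge(left: ProcessExpr, right: ProcessExpr) -> ProcessExpr:
    return make("mmerge", left, right)


def disc(left: ProcessExpr, right: ProcessExpr) -> ProcessExpr:
    return make("disc", left, right)


def rep_star(operand: ProcessExpr) -> ProcessExpr:
    return make("rep_star", operand)


def rep_n(operand: ProcessExpr, n: int) -> ProcessExpr:
    return make("rep_n", operand, n=n)


def rep_f(operand: ProcessExpr, func_name: str) -> ProcessExpr:
    return make("rep_f", operand, func_name=func_name)


def guard(operand: ProcessExpr, rule: RuleRef) -> ProcessExpr:
    return make("guard", operand, rule=rule)


def seq_chain(exprs: Sequence[ProcessExpr]) -> ProcessExpr:
    """Left-associated sequential chain of one or more expressions."""
    if not exprs:
        raise ArityError("seq_chain needs at least one expression")
    out = exprs[0]
    for e in exprs[1:]:
        out = seq(out, e)
    return out


def par_chain(exprs: Sequence[ProcessExpr]) -> ProcessExpr:
    if not exprs:
        raise ArityError("par_chain needs at least one expression")
    out = exprs[0]
    for e in exprs[1:]:
        out = par(out, e)
    return out


def iter_nodes(expr: ProcessExpr) -> Iterator[ProcessExpr]:
    """Depth-first pre-order traversal of the AST (does not expand
    name_refs).  Shared subterms (the AST may be a DAG) are yielded once."""
    stack = [expr]
    seen: Set[int] = set()
    while stack:
        node = stack.pop()
        if id(node) in seen:
            continue
        seen.add(id(node))
        yield node
        if node.cont is not None:
            stack.append(node.cont)
        if node.right is not None:
            stack.append(node.right)
        if node.left is not None:
            stack.append(node.left)


# smart constructors used by the semantics: absorb the unit / dead process

def _seq_mk(left: ProcessExpr, right: ProcessExpr) -> ProcessExpr:
    if left.kind == "skip":
        return right
    if right.kind == "skip":
        return left
    if left.kind == "dead" or right.kind == "dead":
        return DEAD
    return _mk_node("seq", left=left, right=right)


def _par_mk(left: ProcessExpr, right: ProcessExpr) -> ProcessExpr:
    if left.kind == "skip":
        return right
    if right.kind == "skip":
        return left
    if left.kind == "dead" or right.kind == "dead":
        return DEAD
    return _mk_node("par", left=left, right=right)


# ---------------------------------------------------------------------------
# process registry
# ---------------------------------------------------------------------------

class ProcessRegistry:
    """Named process definitions with per-name versions.

    The registry is the in-memory form of the common process repository:
    definitions may reference each other (and themselves) by name, provided
    every recursive cycle performs at least one atomic action before the
    recursive call (guardedness).
    """

    def __init__(self) -> None:
        self._defs: Dict[str, ProcessExpr] = {}
        self._versions: Dict[str, int] = {}
        self._norm_cache: Dict[Tuple[str, int], ProcessExpr] = {}

    def define(self, name: str, expr: ProcessExpr) -> int:
        """Store (or overwrite) a definition; returns the new version number."""
        if not IDENT_RE.match(name):
            raise ArityError(f"invalid process name {name!r}")
        self._defs[name] = expr
        self._versions[name] = self._versions.get(name, 0) + 1
        return self._versions[name]

    def resolve(self, name: str) -> ProcessExpr:
        try:
            return self._defs[name]
        except KeyError:
            raise UnknownNameError(f"undefined process {name!r}") from None

    def resolve_normalized(self, name: str) -> ProcessExpr:
        """Resolve *name* with multi-merge/discriminator continuations
        statically resolved (cached per definition version)."""
        body = self.resolve(name)
        key = (name, self._versions[name])
        cached = self._norm_cache.get(key)
        if cached is None:
            cached = resolve_patterns(body, self)
            self._norm_cache[key] = cached
        return cached

    def version(self, name: str) -> int:
        if name not in self._versions:
            raise UnknownNameError(f"undefined process {name!r}")
        return self._versions[name]

    def __contains__(self, name: str) -> bool:
        return name in self._defs

    def names(self) -> List[str]:
        return sorted(self._defs)

    def items(self) -> Iterator[Tuple[str, ProcessExpr]]:
        return iter(sorted(self._defs.items()))

    def copy(self) -> "ProcessRegistry":
        out = ProcessRegistry()
        out._defs = dict(self._defs)
        out._versions = dict(self._versions)
        out._norm_cache = dict(self._norm_cache)
        return out

    def fresh_name(self, prefix: str) -> str:
        i = 1
        while f"{prefix}_{i}" in self._defs:
            i += 1
        return f"{prefix}_{i}"

    # -- validation --------------------------------------------------------

    def validate(self, extra: Optional[ProcessExpr] = None) -> None:
        """Check resolvability of every name_ref and guardedness of recursion.

        Raises :class:`UnknownNameError` or :class:`GuardednessError`.
        """
        for _, body in self.items():
            for node in iter_nodes(body):
                if node.kind == "name_ref" and node.ref_name not in self:
                    raise UnknownNameError(f"undefined process {node.ref_name!r}")
        if extra is not None:
            for node in iter_nodes(extra):
                if node.kind == "name_ref" and node.ref_name not in self:
                    raise UnknownNameError(f"undefined process {node.ref_name!r}")
        # guardedness: build the "unguarded call" graph and reject cycles
        graph = {name: self._unguarded_refs(body) for name, body in self.items()}
        state: Dict[str, int] = {}  # 0 visiting, 1 done

        def visit(name: str, path: Tuple[str, ...]) -> None:
            if state.get(name) == 1:
                return
            if state.get(name) == 0:
                cyc = path[path.index(name):] + (name,)
                raise GuardednessError(
                    "unguarded recursion through " + " -> ".join(cyc))
            state[name] = 0
            for callee in graph.get(name, ()):
                visit(callee, path + (name,))
            state[name] = 1

        for name in graph:
            visit(name, ())

    def _nullable(self, expr: ProcessExpr, seen: FrozenSet[str] = frozenset()) -> bool:
        """Can *expr* terminate without performing any atomic action?"""
        k = expr.kind
        if k in ("skip", "star0"):
            return True
        if k in ("atom", "dead"):
            return False
        if k == "name_ref":
            if expr.ref_name in seen:
                return False  # cycle: treated as non-nullable; guardedness flags it
            return self._nullable(self.resolve(expr.ref_name), seen | {expr.ref_name})
        if k == "alt":
            return self._nullable(expr.left, seen) or self._nullable(expr.right, seen)
        if k in ("seq", "par", "ipar", "mmerge", "disc"):
            return self._nullable(expr.left, seen) and self._nullable(expr.right, seen)
        if k in ("rep_star", "rep_n", "rep_f", "guard"):
            return self._nullable(expr.left, seen)
        if k == "disc_race":
            return False
        raise ArityError(f"unknown node kind {k!r}")

    def _unguarded_refs(self, expr: ProcessExpr) -> Set[str]:
        """Names referenced before any atomic action has necessarily occurred."""
        k = expr.kind
        if k == "name_ref":
            return {expr.ref_name}
        if k in ("atom", "skip", "dead"):
            return set()
        if k == "seq":
            out = self._unguarded_refs(expr.left)
            if self._nullable(expr.left):
                out |= self._unguarded_refs(expr.right)
            return out
        if k in ("alt", "par", "ipar", "mmerge", "disc"):
            return self._unguarded_refs(expr.left) | self._unguarded_refs(expr.right)
        if k in ("rep_star", "rep_n", "rep_f", "guard", "star0"):
            return self._unguarded_refs(expr.left)
        return set()


# ---------------------------------------------------------------------------
# static validation of a single expression
# ---------------------------------------------------------------------------

def validate_expression(expr: ProcessExpr,
                        registry: Optional[ProcessRegistry] = None) -> None:
    """Structural validation: arities, n >= 1, resolvable name_refs, END in
    tail position only.  Raises on the first violation."""
    for node in iter_nodes(expr):
        k = node.kind
        if k in BINARY_KINDS:
            if node.left is None or node.right is None:
                raise ArityError(f"{k} node missing an operand")
        elif k in UNARY_KINDS:
            if node.left is None or node.right is not None:
                raise ArityError(f"{k} node has wrong arity")
            if k == "rep_n" and (node.n is None or node.n < 1):
                raise ArityError("rep_n requires n >= 1")
            if k == "guard" and node.rule is None:
                raise ArityError("guard node missing its rule")
        elif k == "atom":
            if node.symbol is None:
                raise ArityError("atom node missing its symbol")
        elif k == "name_ref":
            if node.ref_name is None:
                raise ArityError("name_ref node missing its name")
            if registry is not None and node.ref_name not in registry:
                raise UnknownNameError(f"undefined process {node.ref_name!r}")
    validate_terminal_tail(expr, registry)


def _contains_terminal(expr: ProcessExpr, registry: Optional[ProcessRegistry],
                       seen: FrozenSet[str]) -> bool:
    for node in iter_nodes(expr):
        if node.kind == "atom" and node.symbol.kind == "terminal":
            return True
        if node.kind == "name_ref" and registry is not None and node.ref_name in registry:
            if node.ref_name not in seen:
                if _contains_terminal(registry.resolve(node.ref_name), registry,
                                      seen | {node.ref_name}):
                    return True
    return False


def validate_terminal_tail(expr: ProcessExpr,
                           registry: Optional[ProcessRegistry] = None,
                           _seen: FrozenSet[str] = frozenset()) -> None:
    """Static check that the terminal END can only occur last in any trace.

    Conservative: END is allowed as the whole expression, at the tail of a
    sequential spine, in either branch of a choice, or behind a guard; it is
    rejected inside parallel/merge/repetition constructs and on the left of
    a sequence.
    """
    k = expr.kind
    if k == "atom" or k in ("skip", "dead"):
        return
    if k == "name_ref":
        if registry is not None and expr.ref_name in registry and expr.ref_name not in _seen:
            validate_terminal_tail(registry.resolve(expr.ref_name), registry,
                                   _seen | {expr.ref_name})
        return
    if k == "seq":
        if _contains_terminal(expr.left, registry, _seen):
            raise ArityError("terminal END may only appear in tail position")
        validate_terminal_tail(expr.right, registry, _seen)
        return
    if k == "alt":
        validate_terminal_tail(expr.left, registry, _seen)
        validate_terminal_tail(expr.right, registry, _seen)
        return
    if k == "guard":
        validate_terminal_tail(expr.left, registry, _seen)
        return
    # par/ipar/mmerge/disc/rep_*: END may not occur inside at all
    if _contains_terminal(expr, registry, _seen):
        raise ArityError(f"terminal END may not occur inside a {k!r} construct")


# ---------------------------------------------------------------------------
# operational semantics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Move:
    """One enabled initial action of an expression.

    ``path`` identifies the occurrence (stable across repeated calls of
    :func:`moves` on the same expression); ``residual`` is what remains after
    consuming it; ``guards`` lists the rule references that gate it (already
    filtered when a rule context is supplied, recorded either way).
    """

    symbol: ActionSymbol
    path: Tuple[str, ...]
    residual: ProcessExpr
    guards: Tuple[RuleRef, ...] = ()


#: a rule context maps evaluation onto Boolean rules; ``None`` means static
#: analysis (every guard passes, but is recorded on the move).
RuleContext = Callable[[RuleRef], bool]

_MAX_REF_DEPTH = 512


def _disc_race_mk(left: ProcessExpr, right: ProcessExpr, cont: ProcessExpr,
                  registry: Optional[ProcessRegistry],
                  ctx: Optional[RuleContext]) -> ProcessExpr:
    """Build a running discriminator, resolving the race eagerly: the moment
    one branch can successfully terminate it is deemed complete, the
    continuation starts, and the other branch keeps running (its completion
    is absorbed by the surrounding merge)."""
    if _term(left, registry, ctx, frozenset()):
        return _par_mk(cont, right)
    if _term(right, registry, ctx, frozenset()):
        return _par_mk(cont, left)
    return _mk_node("disc_race", left=left, right=right, cont=cont)


_PATTERN_CACHE: Dict[ProcessExpr, bool] = {}


def _contains_pattern(expr: ProcessExpr) -> bool:
    hit = _PATTERN_CACHE.get(expr)
    if hit is not None:
        return hit
    if expr.kind in ("mmerge", "disc"):
        out = True
    else:
        out = any(_contains_pattern(c)
                  for c in (expr.left, expr.right, expr.cont) if c is not None)
    if len(_PATTERN_CACHE) >= _NODE_CACHE_MAX:
        _PATTERN_CACHE.clear()
    _PATTERN_CACHE[expr] = out
    return out


def resolve_patterns(expr: ProcessExpr,
                     registry: Optional[ProcessRegistry] = None) -> ProcessExpr:
    """Statically resolve multi-merge and discriminator continuations.

    The workflow readings of ``&`` and ``^`` are context-sensitive: both fire
    (part of) what *follows them sequentially*.  This pass fixes that context
    once, at expression load: every ``&``/``^`` captures its enclosing
    sequential continuation statically, and the continuation never crosses a
    repetition body, a guard, a parallel branch or a process-name boundary
    (those scopes are sealed).  The result contains no mmerge/disc nodes —
    multi-merge becomes a parallel composition with the continuation copied
    into each branch, and a discriminator becomes a race node stepped by the
    operational semantics.  All semantic entry points apply this pass, so
    callers normally never need to.
    """

    def norm(e: ProcessExpr, cont: ProcessExpr) -> ProcessExpr:
        k = e.kind
        if k in ("atom", "name_ref", "skip", "dead"):
            return _seq_mk(e, cont)
        if k == "seq":
            return norm(e.left, norm(e.right, cont))
        if k == "alt":
            if _contains_pattern(e):
                # push the continuation into the branches (right distribution
                # of "." over "+" is trace-valid) so patterns can capture it
                return _mk_node("alt", left=norm(e.left, cont),
                                   right=norm(e.right, cont))
            branch = _mk_node("alt", left=norm(e.left, SKIP),
                                 right=norm(e.right, SKIP))
            return _seq_mk(branch, cont)
        if k == "par":
            return _seq_mk(_par_mk(norm(e.left, SKIP), norm(e.right, SKIP)), cont)
        if k == "ipar":
            l0, r0 = norm(e.left, SKIP), norm(e.right, SKIP)
            if _contains_pattern(e):
                expanded = _mk_node("alt", left=_seq_mk(l0, r0),
                                       right=_seq_mk(r0, l0))
                return _seq_mk(expanded, cont)
            return _seq_mk(_mk_node("ipar", left=l0, right=r0), cont)
        if k == "mmerge":
            return _par_mk(norm(e.left, cont), norm(e.right, cont))
        if k == "disc":
            return _disc_race_mk(norm(e.left, SKIP), norm(e.right, SKIP),
                                 cont, registry, None)
        if k in ("rep_star", "rep_f", "rep_n", "star0"):
            node = _mk_node(k, left=norm(e.left, SKIP), n=e.n,
                               func_name=e.func_name)
            return _seq_mk(node, cont)
        if k == "guard":
            node = _mk_node("guard", left=norm(e.left, SKIP), rule=e.rule)
            return _seq_mk(node, cont)
        if k == "disc_race":
            node = _mk_node("disc_race", left=norm(e.left, SKIP),
                               right=norm(e.right, SKIP),
                               cont=norm(e.cont, SKIP))
            return _seq_mk(node, cont)
        raise ArityError(f"unknown node kind {k!r}")

    return norm(expr, SKIP)


def moves(expr: ProcessExpr,
          registry: Optional[ProcessRegistry] = None,
          ctx: Optional[RuleContext] = None,
          _depth: int = 0,
          _memo: Optional[Dict[ProcessExpr, List[Move]]] = None) -> List[Move]:
    """Enabled initial actions of *expr* with their residuals.

    With a rule context, guarded subterms whose rule evaluates false
    contribute no moves; without one, guards pass and are recorded.
    Multi-merge/discriminator continuations are resolved on entry (see
    :func:`resolve_patterns`).
    """
    if _memo is None:
        _memo = {}  # shared across the recursion: the AST may be a DAG
    hit = _memo.get(expr)
    if hit is not None:
        return hit
    out = _moves_uncached(expr, registry, ctx, _depth, _memo)
    _memo[expr] = out
    return out


def _moves_uncached(expr: ProcessExpr,
                    registry: Optional[ProcessRegistry],
                    ctx: Optional[RuleContext],
                    _depth: int,
                    _memo: Dict[ProcessExpr, List[Move]]) -> List[Move]:
    if _depth > _MAX_REF_DEPTH:
        raise GuardednessError("recursion depth exceeded while computing moves "
                               "(unguarded definition?)")
    if _contains_pattern(expr):
        expr = resolve_patterns(expr, registry)
    k = expr.kind
    if k in ("skip", "dead"):
        return []
    if k == "atom":
        return [Move(expr.symbol, (), SKIP)]
    if k == "name_ref":
        if registry is None:
            raise UnknownNameError(f"name {expr.ref_name!r} used without a registry")
        body = registry.resolve_normalized(expr.ref_name)
        return [Move(m.symbol, ("r",) + m.path, m.residual, m.guards)
                for m in moves(body, registry, ctx, _depth + 1, _memo)]
    if k == "seq":
        head, tail = expr.left, expr.right
        while head.kind == "seq":  # normalized forms are right-nested already
            head, tail = head.left, _mk_node("seq", left=head.right, right=tail)
        out = [Move(m.symbol, ("L",) + m.path, _seq_mk(m.residual, tail), m.guards)
               for m in moves(head, registry, ctx, _depth + 1, _memo)]
        if _term(head, registry, ctx, frozenset()):
            out += [Move(m.symbol, ("R",) + m.path, m.residual, m.guards)
                    for m in moves(tail, registry, ctx, _depth + 1, _memo)]
        return out
    if k == "alt":
        return ([Move(m.symbol, ("L",) + m.path, m.residual, m.guards)
                 for m in moves(expr.left, registry, ctx, _depth + 1, _memo)]
                + [Move(m.symbol, ("R",) + m.path, m.residual, m.guards)
                   for m in moves(expr.right, registry, ctx, _depth + 1, _memo)])
    if k == "par":
        return ([Move(m.symbol, ("L",) + m.path, _par_mk(m.residual, expr.right), m.guards)
                 for m in moves(expr.left, registry, ctx, _depth + 1, _memo)]
                + [Move(m.symbol, ("R",) + m.path, _par_mk(expr.left, m.residual), m.guards)
                   for m in moves(expr.right, registry, ctx, _depth + 1, _memo)])
    if k == "ipar":
        # branches run one at a time, in either order, never overlapped
        expanded = alt(seq(expr.left, expr.right), seq(expr.right, expr.left))
        return moves(expanded, registry, ctx, _depth + 1, _memo)
    if k == "disc_race":
        out: List[Move] = []
        for m in moves(expr.left, registry, ctx, _depth + 1, _memo):
            res = _disc_race_mk(m.residual, expr.right, expr.cont, registry, ctx)
            out.append(Move(m.symbol, ("L",) + m.path, res, m.guards))
        for m in moves(expr.right, registry, ctx, _depth + 1, _memo):
            res = _disc_race_mk(expr.left, m.residual, expr.cont, registry, ctx)
            out.append(Move(m.symbol, ("R",) + m.path, res, m.guards))
        return out
    if k in ("rep_star", "star0"):
        # unfold one body copy; the zero-more residual keeps the option open
        rest = _mk_node("star0", left=expr.left)
        return [Move(m.symbol, ("L",) + m.path, _seq_mk(m.residual, rest), m.guards)
                for m in moves(expr.left, registry, ctx, _depth + 1, _memo)]
    if k == "rep_n":
        rest = SKIP if expr.n == 1 else rep_n(expr.left, expr.n - 1)
        return moves(_seq_mk_unrolled(expr.left, rest), registry, ctx, _depth + 1, _memo)
    if k == "rep_f":
        # statically, f-limited repetition behaves as one-or-more repetition
        return moves(rep_star(expr.left), registry, ctx, _depth + 1, _memo)
    if k == "guard":
        if ctx is not None:
            held = ctx(expr.rule)
            if not held:
                return []
        return [Move(m.symbol, ("g",) + m.path, m.residual, (expr.rule,) + m.guards)
                for m in moves(expr.left, registry, ctx, _depth + 1, _memo)]
    raise ArityError(f"unknown node kind {k!r}")


def _seq_mk_unrolled(body: ProcessExpr, rest: ProcessExpr) -> ProcessExpr:
    if rest.kind == "skip":
        return body
    return _mk_node("seq", left=body, right=rest)


def _term(expr: ProcessExpr,
          registry: Optional[ProcessRegistry],
          ctx: Optional[RuleContext],
          seen: FrozenSet[str],
          _memo: Optional[Dict] = None) -> bool:
    if _memo is None:
        _memo = {}
    key = (expr, seen)
    hit = _memo.get(key)
    if hit is not None:
        return hit
    out = _term_uncached(expr, registry, ctx, seen, _memo)
    _memo[key] = out
    return out


def _term_uncached(expr: ProcessExpr,
                   registry: Optional[ProcessRegistry],
                   ctx: Optional[RuleContext],
                   seen: FrozenSet[str],
                   _memo: Dict) -> bool:
    k = expr.kind
    if k in ("skip", "star0"):
        return True
    if k in ("atom", "dead", "disc_race"):
        return False
    if k == "name_ref":
        if expr.ref_name in seen:
            return False
        if registry is None:
            raise UnknownNameError(f"name {expr.ref_name!r} used without a registry")
        return _term(registry.resolve(expr.ref_name), registry, ctx, seen | {expr.ref_name}, _memo)
    if k == "alt":
        return (_term(expr.left, registry, ctx, seen, _memo)
                or _term(expr.right, registry, ctx, seen, _memo))
    if k in ("seq", "par", "ipar", "mmerge", "disc"):
        # for seq this is correct regardless of association or of a
        # multi-merge/discriminator head: both expansions terminate iff all
        # components can
        return (_term(expr.left, registry, ctx, seen, _memo)
                and _term(expr.right, registry, ctx, seen, _memo))
    if k in ("rep_star", "rep_n", "rep_f"):
        return _term(expr.left, registry, ctx, seen, _memo)
    if k == "guard":
        if ctx is not None and not ctx(expr.rule):
            return False
        return _term(expr.left, registry, ctx, seen, _memo)
    raise ArityError(f"unknown node kind {k!r}")


def terminated(expr: ProcessExpr,
               registry: Optional[ProcessRegistry] = None,
               ctx: Optional[RuleContext] = None) -> bool:
    """True iff *expr* may successfully terminate now, with no obligatory
    work remaining."""
    return _term(expr, registry, ctx, frozenset())


def enabled(expr: ProcessExpr,
            registry: Optional[ProcessRegistry] = None,
            ctx: Optional[RuleContext] = None) -> Set[Tuple[str, Tuple[str, ...]]]:
    """The initial actions executable now, as (action name, occurrence path)."""
    return {(m.symbol.name, m.path) for m in moves(expr, registry, ctx)}


def step(expr: ProcessExpr,
         path: Tuple[str, ...],
         registry: Optional[ProcessRegistry] = None,
         ctx: Optional[RuleContext] = None) -> ProcessExpr:
    """Consume the enabled occurrence at *path*, returning the residual."""
    for m in moves(expr, registry, ctx):
        if m.path == tuple(path):
            return m.residual
    raise NpdlError(f"occurrence {path!r} is not currently enabled")


# ---------------------------------------------------------------------------
# bounded unfolding and the trace oracle
# ---------------------------------------------------------------------------

#: rules with fixed built-in truth values (usable anywhere a rule is expected)
BUILTIN_RULES = {"always": True, "never": False}


def _static_ctx(rule_values: Optional[Mapping[str, bool]]) -> Optional[RuleContext]:
    if rule_values is None:
        return None

    def ctx(ref: RuleRef) -> bool:
        if ref.name in BUILTIN_RULES:
            v = BUILTIN_RULES[ref.name]
        else:
            v = rule_values.get(ref.name, True)
        return (not v) if ref.negated else v

    return ctx


def inline_bounded(expr: ProcessExpr,
                   registry: Optional[ProcessRegistry],
                   loop_bound: int) -> ProcessExpr:
    """Close *expr* by inlining name_refs and bounding every repetition.

    Every recursive call chain is unrolled at most *loop_bound* times per
    name, and every ``?*``/``?f`` is expanded to between one and *loop_bound*
    body copies; exhausted budgets become a dead end that contributes no
    complete traces.
    """
    if loop_bound < 1:
        raise ArityError("loop_bound must be >= 1")
    expr = resolve_patterns(expr, registry)

    def bounded_star(body: ProcessExpr, k: int) -> ProcessExpr:
        out = body
        for _ in range(k - 1):
            out = _mk_node("seq", left=body,
                              right=_mk_node("alt", left=SKIP, right=out))
        return out

    memo: Dict[Tuple[ProcessExpr, FrozenSet[Tuple[str, int]]], ProcessExpr] = {}
    names_memo: Dict[ProcessExpr, FrozenSet[str]] = {}

    def reachable_names(direct: Set[str]) -> FrozenSet[str]:
        # reachability over the name-reference graph (cycles welcome)
        out: Set[str] = set()
        stack = list(direct)
        while stack:
            name = stack.pop()
            if name in out or registry is None or name not in registry:
                out.add(name)
                continue
            out.add(name)
            body = registry.resolve_normalized(name)
            stack.extend(n.ref_name for n in iter_nodes(body)
                         if n.kind == "name_ref" and n.ref_name not in out)
        return frozenset(out)

    def relevant_names(e: ProcessExpr) -> FrozenSet[str]:
        got = names_memo.get(e)
        if got is None:
            direct = {n.ref_name for n in iter_nodes(e) if n.kind == "name_ref"}
            got = reachable_names(direct)
            names_memo[e] = got
        return got

    def go(e: ProcessExpr, budgets: Mapping[str, int]) -> ProcessExpr:
        # memoized so equal (subterm, budget) expansions are one shared
        # object: residuals of different unfolding paths then coincide;
        # budgets are keyed only on the names the subterm can reach
        rel = relevant_names(e)
        key = (e, frozenset((n, b) for n, b in budgets.items() if n in rel))
        hit = memo.get(key)
        if hit is not None:
            return hit
        out = _go(e, budgets)
        memo[key] = out
        return out

    def _go(e: ProcessExpr, budgets: Mapping[str, int]) -> ProcessExpr:
        k = e.kind
        if k in ("atom", "skip", "dead"):
            return e
        if k == "name_ref":
            remaining = budgets.get(e.ref_name, loop_bound)
            if remaining <= 0:
                return DEAD
            if registry is None:
                raise UnknownNameError(f"name {e.ref_name!r} used without a registry")
            body = registry.resolve_normalized(e.ref_name)
            return go(body, {**budgets, e.ref_name: remaining - 1})
        if k in BINARY_KINDS:
            return _mk_node(k, left=go(e.left, budgets), right=go(e.right, budgets))
        if k in ("rep_star", "rep_f", "star0"):
            inner = go(e.left, budgets)
            b = bounded_star(inner, loop_bound)
            if k == "star0":
                return _mk_node("alt", left=SKIP, right=b)
            return b
        if k == "rep_n":
            inner = go(e.left, budgets)
            return seq_chain([inner] * e.n)
        if k == "guard":
            return _mk_node("guard", left=go(e.left, budgets), rule=e.rule)
        if k == "disc_race":
            return _mk_node("disc_race", left=go(e.left, budgets),
                               right=go(e.right, budgets), cont=go(e.cont, budgets))
        raise ArityError(f"unknown node kind {k!r}")

    return go(expr, {})


Trace = Tuple[str, ...]


def traces(expr: ProcessExpr,
           registry: Optional[ProcessRegistry] = None,
           loop_bound: int = DEFAULT_LOOP_BOUND,
           rule_values: Optional[Mapping[str, bool]] = None,
           state_cap: int = DEFAULT_STATE_CAP) -> FrozenSet[Trace]:
    """Brute-force bounded trace enumeration (the oracle).

    Enumerates every complete run reachable with each repetition/recursion
    unrolled at most *loop_bound* times, eliding silent actions.  ``rule_values``
    fixes the guards statically (unlisted rules hold); by default every guard
    passes.  Raises :class:`StateCapExceeded` past *state_cap* distinct
    residuals.
    """
    if registry is not None:
        registry.validate(extra=expr)
    closed = inline_bounded(expr, registry, loop_bound)
    ctx = _static_ctx(rule_values or {})
    memo: Dict[ProcessExpr, FrozenSet[Trace]] = {}
    visiting: Set[ProcessExpr] = set()

    def enum(e: ProcessExpr) -> FrozenSet[Trace]:
        if e in memo:
            return memo[e]
        if e in visiting:
            raise GuardednessError("cyclic residual during bounded enumeration")
        if len(memo) + len(visiting) > state_cap:
            raise StateCapExceeded(f"more than {state_cap} residual states visited")
        visiting.add(e)
        out: Set[Trace] = set()
        if _term(e, None, ctx, frozenset()):
            out.add(())
        for m in moves(e, None, ctx):
            tail = enum(m.residual)
            if m.symbol.kind == "silent":
                out |= tail
            else:
                out |= {(m.symbol.name,) + t for t in tail}
        visiting.discard(e)
        memo[e] = frozenset(out)
        return memo[e]

    return enum(closed)


def is_trace(expr: ProcessExpr,
             observed: Sequence[str],
             registry: Optional[ProcessRegistry] = None,
             loop_bound: int = DEFAULT_LOOP_BOUND,
             rule_values: Optional[Mapping[str, bool]] = None,
             state_cap: int = DEFAULT_STATE_CAP) -> bool:
    """Membership check: is *observed* (silent-elided) a complete bounded
    trace of *expr*?  Equivalent to ``tuple(observed) in traces(...)`` but
    avoids enumerating the full set."""
    closed = inline_bounded(expr, registry, loop_bound)
    ctx = _static_ctx(rule_values or {})
    target = tuple(observed)
    seen: Set[Tuple[ProcessExpr, int]] = set()
    budget = [state_cap]

    def match(e: ProcessExpr, i: int) -> bool:
        key = (e, i)
        if key in seen:
            return False
        seen.add(key)
        budget[0] -= 1
        if budget[0] < 0:
            raise StateCapExceeded(f"more than {state_cap} states visited")
        if i == len(target) and _term(e, None, ctx, frozenset()):
            return True
        for m in moves(e, None, ctx):
            if m.symbol.kind == "silent":
                if match(m.residual, i):
                    return True
            elif i < len(target) and m.symbol.name == target[i]:
                if match(m.residual, i + 1):
                    return True
        return False

    return match(closed, 0)


class _WeakDFA:
    """Determinized view (subset construction over the silent closure) of
    the bounded transition system, with memoized moves and transitions."""

    def __init__(self, ctx: Optional[RuleContext], state_cap: int) -> None:
        self.ctx = ctx
        self.state_cap = state_cap
        self._moves: Dict[ProcessExpr, List[Move]] = {}
        self._term: Dict[ProcessExpr, bool] = {}
        self._trans: Dict[FrozenSet[ProcessExpr], Dict[str, FrozenSet[ProcessExpr]]] = {}
        self._accept: Dict[FrozenSet[ProcessExpr], bool] = {}
        self._nonempty: Dict[FrozenSet[ProcessExpr], bool] = {}

    def moves_of(self, e: ProcessExpr) -> List[Move]:
        if len(self._moves) > self.state_cap:
            raise StateCapExceeded(
                f"more than {self.state_cap} residual states visited")
        return moves(e, None, self.ctx, _memo=self._moves)

    def term_of(self, e: ProcessExpr) -> bool:
        return _term(e, None, self.ctx, frozenset(), _memo=self._term)

    def start(self, expr: ProcessExpr) -> FrozenSet[ProcessExpr]:
        return self.closure(frozenset([expr]))

    def closure(self, states: FrozenSet[ProcessExpr]) -> FrozenSet[ProcessExpr]:
        out = set(states)
        stack = list(states)
        while stack:
            e = stack.pop()
            for m in self.moves_of(e):
                if m.symbol.kind == "silent" and m.residual not in out:
                    out.add(m.residual)
                    stack.append(m.residual)
        return frozenset(out)

    def transitions(self, states: FrozenSet[ProcessExpr]
                    ) -> Dict[str, FrozenSet[ProcessExpr]]:
        out = self._trans.get(states)
        if out is None:
            by_label: Dict[str, Set[ProcessExpr]] = {}
            for e in states:
                for m in self.moves_of(e):
                    if m.symbol.kind != "silent":
                        by_label.setdefault(m.symbol.name, set()).add(m.residual)
            out = {a: self.closure(frozenset(s)) for a, s in sorted(by_label.items())}
            self._trans[states] = out
        return out

    def accepting(self, states: FrozenSet[ProcessExpr]) -> bool:
        out = self._accept.get(states)
        if out is None:
            out = any(self.term_of(e) for e in states)
            self._accept[states] = out
        return out

    def nonempty(self, states: FrozenSet[ProcessExpr]) -> bool:
        """Does any complete trace start from this determinized state?"""
        cached = self._nonempty.get(states)
        if cached is not None:
            return cached
        seen: Set[FrozenSet[ProcessExpr]] = set()
        stack = [states]
        found = False
        while stack:
            s = stack.pop()
            if s in seen:
                continue
            if len(seen) > self.state_cap:
                raise StateCapExceeded("emptiness check exceeded the state cap")
            seen.add(s)
            if self.accepting(s):
                found = True
                break
            stack.extend(self.transitions(s).values())
        self._nonempty[states] = found
        return found


def trace_equivalent(e1: ProcessExpr,
                     e2: ProcessExpr,
                     registry: Optional[ProcessRegistry] = None,
                     loop_bound: int = DEFAULT_LOOP_BOUND,
                     rule_values: Optional[Mapping[str, bool]] = None,
                     state_cap: int = DEFAULT_STATE_CAP) -> bool:
    """Weak trace equivalence at the given loop bound: the complete-trace
    sets of the two expressions coincide (``traces(e1) == traces(e2)``).

    Decided by walking the two determinized bounded transition systems in
    lockstep (subset construction over the silent closure), which avoids
    materializing the trace sets themselves; a transition only one side can
    take is tolerated exactly when no complete trace goes through it."""
    ctx = _static_ctx(rule_values or {})
    dfa = _WeakDFA(ctx, state_cap)
    s1 = dfa.start(inline_bounded(e1, registry, loop_bound))
    s2 = dfa.start(inline_bounded(e2, registry, loop_bound))
    intern: Dict[Tuple, int] = {}
    memo: Dict[FrozenSet[ProcessExpr], int] = {}
    return (_canonical_signature(dfa, s1, intern, memo)
            == _canonical_signature(dfa, s2, intern, memo))


def _canonical_signature(dfa: "_WeakDFA", start: FrozenSet[ProcessExpr],
                         intern: Dict[Tuple, int],
                         memo: Dict[FrozenSet[ProcessExpr], int]) -> int:
    """Canonical id of the complete-trace set reachable from *start*.

    The bounded system is acyclic, so the minimal acyclic DFA has a unique
    bottom-up signature: states whose language is empty collapse to a dead
    id (their incoming transitions yield no complete trace), and states with
    equal languages share one id.  The intern/memo tables must be shared
    between the two sides of a comparison.
    """
    EMPTY = -1

    def sig(state: FrozenSet[ProcessExpr]) -> int:
        got = memo.get(state)
        if got is not None:
            return got
        if len(memo) > dfa.state_cap:
            raise StateCapExceeded(
                f"more than {dfa.state_cap} determinized states visited")
        memo[state] = EMPTY  # cycle guard; bounded systems are acyclic
        parts = []
        for label, target in dfa.transitions(state).items():
            t = sig(target)
            if t != EMPTY:
                parts.append((label, t))
        accepting = dfa.accepting(state)
        if not parts and not accepting:
            memo[state] = EMPTY
            return EMPTY
        key = (accepting, tuple(sorted(parts)))
        got = intern.get(key)
        if got is None:
            got = len(intern)
            intern[key] = got
        memo[state] = got
        return got

    import sys
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 100_000))
    try:
        return sig(start)
    finally:
        sys.setrecursionlimit(old)


# ---------------------------------------------------------------------------
# rewriting the extended operators to . + || and guarded recursion
# ---------------------------------------------------------------------------

_REWRITE_STATE_CAP = 20_000

#: the distinguished constant-false rule used to express a dead end in basic
#: operators (a guarded silent action that can never fire)
NEVER = RuleRef("never")


def _has_unbounded_loops(expr: ProcessExpr) -> bool:
    return any(n.kind in ("rep_star", "rep_f", "star0", "name_ref")
               for n in iter_nodes(expr))


def rewrite_extended(expr: ProcessExpr,
                     registry: Optional[ProcessRegistry] = None,
                     strip_guards: bool = False,
                     loop_bound: int = DEFAULT_LOOP_BOUND) -> Tuple[ProcessExpr, ProcessRegistry]:
    """Eliminate the extended operators from *expr* (and from every stored
    definition), returning an equivalent expression over atoms, name_refs,
    ``.``, ``+``, ``||`` and (unless *strip_guards*) guards, together with the
    registry extended by the fresh recursive definitions the rewrite needs.

    * ``?n`` unrolls to n sequential copies.
    * ``?*`` and ``?f`` become a fresh guarded recursive definition
      ``X ::= E + E . X``.
    * ``|*`` becomes ``(L . R) + (R . L)``.
    * ``&`` distributes its sequential continuation over both branches:
      ``(L & R) . C  ->  (L . C) || (R . C)``.
    * ``^`` is compiled by enumerating the reachable states of its race phase
      (both branches running, neither yet complete) into fresh recursive
      definitions; on the move that first completes a branch the emitted
      transition continues compositionally with ``continuation || rest of the
      other branch``.  The silent GO encodes a termination option, so
      equality holds under the weak (GO-elided) trace semantics.

    The result preserves the bounded trace set at any loop bound, with one
    exception: when a discriminator *branch* itself contains unbounded
    repetition or a process reference, its race phase is compiled at the
    analysis depth *loop_bound*, and equality is guaranteed at that bound.
    """
    out_reg = registry.copy() if registry is not None else ProcessRegistry()
    in_reg = registry
    expr = resolve_patterns(expr, registry)

    def rw(e: ProcessExpr) -> ProcessExpr:
        k = e.kind
        if k in ("atom", "name_ref"):
            return e
        if k == "skip":
            return GO  # weakly-silent unit (only survives where not absorbed)
        if k == "dead":
            return _mk_node("guard", left=GO, rule=NEVER)
        if k == "seq":
            return _seq_mk(rw(e.left), rw(e.right))
        if k == "alt":
            return _mk_node("alt", left=rw(e.left), right=rw(e.right))
        if k == "par":
            return _par_mk(rw(e.left), rw(e.right))
        if k == "ipar":
            l, r = rw(e.left), rw(e.right)
            return alt(_seq_mk(l, r), _seq_mk(r, l))
        if k == "disc_race":
            cont = SKIP if e.cont.kind == "skip" else rw(e.cont)
            return _compile_disc(e.left, e.right, cont,
                                 out_reg, in_reg, rw, strip_guards, loop_bound)
        if k in ("rep_star", "rep_f"):
            body = rw(e.left)
            name = out_reg.fresh_name("_star")
            out_reg.define(name, alt(body, _seq_mk(body, name_ref(name))))
            return name_ref(name)
        if k == "star0":
            return alt(GO, rw(rep_star(e.left)))  # GO encodes the empty option
        if k == "rep_n":
            body = rw(e.left)
            return seq_chain([body] * e.n)
        if k == "guard":
            inner = rw(e.left)
            return inner if strip_guards else _mk_node("guard", left=inner, rule=e.rule)
        raise ArityError(f"unknown node kind {k!r}")

    for name, body in list(out_reg.items()):
        out_reg.define(name, rw(resolve_patterns(body, registry)))
        # define() bumps the version; acceptable for a rewrite product
    result = rw(expr)
    return result, out_reg


def _compile_disc(left: ProcessExpr, right: ProcessExpr, cont_rw: ProcessExpr,
                  out_reg: ProcessRegistry,
                  in_reg: Optional[ProcessRegistry],
                  rw: Callable[[ProcessExpr], ProcessExpr],
                  strip_guards: bool,
                  loop_bound: int) -> ProcessExpr:
    """Compile ``(left ^ right) . cont`` into basic operators.

    Enumerates the race phase (pairs of branch residuals, neither yet able to
    terminate) as fresh recursive definitions; a move after which a branch can
    terminate resolves the race and continues with ``cont || other-residual``,
    emitted compositionally through *rw*.  *cont_rw* is already rewritten.
    """
    # branch-internal unbounded loops would desynchronise bound counting
    # between the race graph and the original expression: unroll them first.
    if _has_unbounded_loops(left):
        left = inline_bounded(left, in_reg, loop_bound)
    if _has_unbounded_loops(right):
        right = inline_bounded(right, in_reg, loop_bound)

    def resolved(other: ProcessExpr) -> ProcessExpr:
        return _par_mk(cont_rw, rw(other))

    if _term(left, in_reg, None, frozenset()):
        return resolved(right)
    if _term(right, in_reg, None, frozenset()):
        return resolved(left)

    states: Dict[Tuple[ProcessExpr, ProcessExpr], str] = {}
    pending: List[Tuple[ProcessExpr, ProcessExpr]] = []

    def state_name(l: ProcessExpr, r: ProcessExpr) -> str:
        key = (l, r)
        if key not in states:
            if len(states) >= _REWRITE_STATE_CAP:
                raise StateCapExceeded("discriminator rewrite exceeded the state cap")
            name = out_reg.fresh_name("_disc")
            out_reg.define(name, GO)  # placeholder reserves the name
            states[key] = name
            pending.append(key)
        return states[key]

    start = state_name(left, right)
    while pending:
        l, r = key = pending.pop(0)
        branches: List[ProcessExpr] = []

        def emit(m: Move, l_res: ProcessExpr, r_res: ProcessExpr,
                 completed: ProcessExpr, other: ProcessExpr) -> None:
            act = _mk_node("atom", symbol=m.symbol)
            if _term(completed, in_reg, None, frozenset()):
                rest = resolved(other)
                body = act if rest.kind == "skip" else _seq_mk(act, rest)
            else:
                body = _seq_mk(act, name_ref(state_name(l_res, r_res)))
            if not strip_guards:
                for ref in reversed(m.guards):
                    body = _mk_node("guard", left=body, rule=ref)
            branches.append(body)

        for m in moves(l, in_reg, None):
            emit(m, m.residual, r, m.residual, r)
        for m in moves(r, in_reg, None):
            emit(m, l, m.residual, m.residual, l)
        if not branches:
            # a dead end introduced by bounded unrolling: no moves, no exit
            body = _mk_node("guard", left=GO, rule=NEVER)
        else:
            body = branches[0]
            for b in branches[1:]:
                body = _mk_node("alt", left=body, right=b)
        out_reg.define(states[key], body)
    return name_ref(start)
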