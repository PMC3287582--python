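"""Concrete textual syntax for process expressions and named definitions.

Grammar (this package's dialect; whitespace insignificant, ``#`` starts a
line comment, files use UTF-8 and the ``.npdl`` extension)::

    program    :=  { "define" NAME "=" expression ";" }
    expression :=  choice
    choice     :=  merge { "+" merge }                    # loosest
    merge      :=  sequence { ("||" | "|*" | "&" | "^") sequence }
    sequence   :=  postfix { "." postfix }
    postfix    :=  primary { "?*" | "?" INT | "?f(" NAME ")"
                           | "%" NAME | "%!" NAME }       # tightest
    primary    :=  NAME | "0" | "1" | "(" expression ")"

``NAME`` is ``[A-Za-z_][A-Za-z0-9_]*``.  The binary merge-level operators
share one precedence level and associate to the left; mixing them is
allowed.  ``1`` is the empty (successfully terminated) process and ``0`` the
deadlock — they mainly occur in serialized residuals of running instances.

``parse(serialize(E))`` is structurally equal to ``E`` for every valid
expression; the serializer emits minimal parentheses.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import List, Optional, Tuple

from .algebra import (
    _mk_node,
    DEAD,
    SKIP,
    ArityError,
    NpdlError,
    ProcessExpr,
    ProcessRegistry,
    RuleRef,
    alt,
    atom,
    disc,
    guard,
    ipar,
    mmerge,
    name_ref,
    par,
    rep_f,
    rep_n,
    rep_star,
    seq,
)

__all__ = [
    "NpdlSyntaxError",
    "parse_expression",
    "parse_program",
    "serialize_expression",
    "serialize_program",
    "serialize",
]


class NpdlSyntaxError(NpdlError):
    """Syntax error with 1-based line/column position."""

    def __init__(self, message: str, line: int, column: int) -> None:
        super().__init__(f"{message} (line {line}, column {column})")
        self.line = line
        self.column = column


# ---------------------------------------------------------------------------
# tokenizer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Token:
    kind: str          # NAME INT OP EOF
    text: str
    line: int
    column: int


_TOKEN_RE = re.compile(
    r"""
      (?P<ws>\s+|\#[^\n]*)
    | (?P<name>[A-Za-z_][A-Za-z0-9_]*)
    | (?P<int>[0-9]+)
    | (?P<op>\?\*|\|\||\|\*|%!|\?|%|\.|\+|&|\^|\(|\)|=|;)
    """,
    re.VERBOSE,
)


def _tokenize(text: str) -> List[_Token]:
    tokens: List[_Token] = []
    pos = 0
    line = 1
    line_start = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise NpdlSyntaxError(f"unexpected character {text[pos]!r}",
                                  line, pos - line_start + 1)
        col = m.start() - line_start + 1
        if m.lastgroup == "name":
            tokens.append(_Token("NAME", m.group(), line, col))
        elif m.lastgroup == "int":
            tokens.append(_Token("INT", m.group(), line, col))
        elif m.lastgroup == "op":
            tokens.append(_Token("OP", m.group(), line, col))
        # whitespace/comment: track line numbers
        nl = m.group().count("\n")
        if nl:
            line += nl
            line_start = m.start() + m.group().rindex("\n") + 1
        pos = m.end()
    tokens.append(_Token("EOF", "", line, len(text) - line_start + 1))
    return tokens


# ---------------------------------------------------------------------------
# parser
# ---------------------------------------------------------------------------

_MERGE_OPS = {"||": par, "|*": ipar, "&": mmerge, "^": disc}


class _Parser:
    def __init__(self, text: str) -> None:
        self.tokens = _tokenize(text)
        self.i = 0

    @property
    def tok(self) -> _Token:
        return self.tokens[self.i]

    def advance(self) -> _Token:
        t = self.tok
        self.i += 1
        return t

    def error(self, expected: str) -> "NpdlSyntaxError":
        t = self.tok
        got = repr(t.text) if t.kind != "EOF" else "end of input"
        return NpdlSyntaxError(f"expected {expected}, found {got}", t.line, t.column)

    def accept_op(self, op: str) -> bool:
        if self.tok.kind == "OP" and self.tok.text == op:
            self.advance()
            return True
        return False

    def expect_op(self, op: str) -> None:
        if not self.accept_op(op):
            raise self.error(f"{op!r}")

    def expect_name(self) -> str:
        if self.tok.kind != "NAME":
            raise self.error("an identifier")
        return self.advance().text

    # grammar ---------------------------------------------------------------

    def expression(self) -> ProcessExpr:
        e = self.merge()
        while self.accept_op("+"):
            e = alt(e, self.merge())
        return e

    def merge(self) -> ProcessExpr:
        e = self.sequence()
        while self.tok.kind == "OP" and self.tok.text in _MERGE_OPS:
            op = self.advance().text
            e = _MERGE_OPS[op](e, self.sequence())
        return e

    def sequence(self) -> ProcessExpr:
        e = self.postfix()
        while self.accept_op("."):
            e = seq(e, self.postfix())
        return e

    def postfix(self) -> ProcessExpr:
        e = self.primary()
        while True:
            if self.accept_op("?*"):
                e = rep_star(e)
            elif self.tok.kind == "OP" and self.tok.text == "?":
                self.advance()
                if self.tok.kind == "INT":
                    n = int(self.advance().text)
                    if n < 1:
                        raise NpdlSyntaxError("repetition count must be >= 1",
                                              self.tok.line, self.tok.column)
                    e = rep_n(e, n)
                elif self.tok.kind == "NAME":
                    fname = self.advance().text
                    if fname == "f" and self.accept_op("("):
                        fname = self.expect_name()
                        self.expect_op(")")
                    e = rep_f(e, fname)
                else:
                    raise self.error("a repetition count or function name after '?'")
            elif self.tok.kind == "OP" and self.tok.text in ("%", "%!"):
                negated = self.advance().text == "%!"
                e = guard(e, RuleRef(self.expect_name(), negated))
            else:
                return e

    def primary(self) -> ProcessExpr:
        if self.tok.kind == "NAME":
            name = self.advance().text
            if name == "define":
                raise NpdlSyntaxError("'define' is a reserved word",
                                      self.tok.line, self.tok.column)
            # references to defined processes are resolved by the caller;
            # bare names parse as atoms and are upgraded by parse_program
            return atom(name)
        if self.tok.kind == "INT" and self.tok.text in ("0", "1"):
            t = self.advance()
            return DEAD if t.text == "0" else SKIP
        if self.accept_op("("):
            e = self.expression()
            self.expect_op(")")
            return e
        raise self.error("an action name, '0', '1' or '('")


def parse_expression(text: str,
                     known_names: Optional[set] = None) -> ProcessExpr:
    """Parse one expression.  Identifiers in *known_names* become process
    references (name_ref); all other identifiers are atomic actions."""
    p = _Parser(text)
    e = p.expression()
    if p.tok.kind != "EOF":
        raise p.error("end of input")
    if known_names:
        e = _promote_refs(e, known_names)
    return e


def _promote_refs(expr: ProcessExpr, names: set) -> ProcessExpr:
    if expr.kind == "atom" and expr.symbol.kind == "regular" and expr.symbol.name in names:
        return name_ref(expr.symbol.name)
    kw = {}
    for f in ("left", "right", "cont"):
        child = getattr(expr, f)
        if child is not None:
            kw[f] = _promote_refs(child, names)
    if not kw:
        return expr
    return _mk_node(expr.kind, symbol=expr.symbol, ref_name=expr.ref_name,
                       n=expr.n, func_name=expr.func_name, rule=expr.rule,
                       **{**{"left": expr.left, "right": expr.right, "cont": expr.cont},
                          **kw})


def parse_program(text: str,
                  registry: Optional[ProcessRegistry] = None) -> ProcessRegistry:
    """Parse a program of ``define Name = <expr> ;`` statements.

    Returns the registry (a fresh one unless given).  Redefining a name is a
    versioning event: the definition is replaced and its version incremented.
    Every name referenced must be defined somewhere in the file (or already
    in *registry*); references may be forward.
    """
    reg = registry if registry is not None else ProcessRegistry()
    p = _Parser(text)
    raw: List[Tuple[str, ProcessExpr]] = []
    while p.tok.kind != "EOF":
        if not (p.tok.kind == "NAME" and p.tok.text == "define"):
            raise p.error("'define'")
        p.advance()
        name = p.expect_name()
        p.expect_op("=")
        body = p.expression()
        p.expect_op(";")
        raw.append((name, body))
    names = set(reg.names()) | {n for n, _ in raw}
    for name, body in raw:
        reg.define(name, _promote_refs(body, names))
    # every reference must now resolve; guardedness is checked as well
    reg.validate()
    return reg


# ---------------------------------------------------------------------------
# serializer
# ---------------------------------------------------------------------------

_PREC_ALT = 1
_PREC_MERGE = 2
_PREC_SEQ = 3
_PREC_POSTFIX = 4
_PREC_PRIMARY = 5

_BIN_TOKEN = {"alt": "+", "par": "||", "ipar": "|*", "mmerge": "&", "disc": "^", "seq": "."}
_BIN_PREC = {"alt": _PREC_ALT, "par": _PREC_MERGE, "ipar": _PREC_MERGE,
             "mmerge": _PREC_MERGE, "disc": _PREC_MERGE, "seq": _PREC_SEQ}


def _desugar_internal(expr: ProcessExpr) -> ProcessExpr:
    """Map internal residual nodes onto surface syntax: ``star0(E)`` is
    ``1 + E ?*`` and a running discriminator is ``(L ^ R) . C``."""
    k = expr.kind
    if k == "star0":
        return alt(SKIP, rep_star(_desugar_internal(expr.left)))
    if k == "disc_race":
        race = disc(_desugar_internal(expr.left), _desugar_internal(expr.right))
        cont = _desugar_internal(expr.cont)
        return race if cont.kind == "skip" else seq(race, cont)
    kw = {}
    for f in ("left", "right", "cont"):
        child = getattr(expr, f)
        if child is not None:
            kw[f] = _desugar_internal(child)
    if not kw:
        return expr
    return _mk_node(k, symbol=expr.symbol, ref_name=expr.ref_name,
                       n=expr.n, func_name=expr.func_name, rule=expr.rule,
                       **{**{"left": expr.left, "right": expr.right, "cont": expr.cont},
                          **kw})


def serialize_expression(expr: ProcessExpr) -> str:
    """Canonical text with minimal parentheses; round-trips structurally
    (internal residual nodes are mapped to surface syntax first)."""
    expr = _desugar_internal(expr)

    def go(e: ProcessExpr, prec: int) -> str:
        k = e.kind
        if k == "atom":
            s, p = e.symbol.name, _PREC_PRIMARY
        elif k == "name_ref":
            s, p = e.ref_name, _PREC_PRIMARY
        elif k == "skip":
            s, p = "1", _PREC_PRIMARY
        elif k == "dead":
            s, p = "0", _PREC_PRIMARY
        elif k in _BIN_TOKEN:
            p = _BIN_PREC[k]
            # left-associative: the right operand needs parens at equal level
            s = f"{go(e.left, p)} {_BIN_TOKEN[k]} {go(e.right, p + 1)}"
        elif k == "rep_star":
            s, p = f"{go(e.left, _PREC_POSTFIX)} ?*", _PREC_POSTFIX
        elif k == "rep_n":
            s, p = f"{go(e.left, _PREC_POSTFIX)} ?{e.n}", _PREC_POSTFIX
        elif k == "rep_f":
            s, p = f"{go(e.left, _PREC_POSTFIX)} ?f({e.func_name})", _PREC_POSTFIX
        elif k == "guard":
            op = "%!" if e.rule.negated else "%"
            s, p = f"{go(e.left, _PREC_POSTFIX)} {op} {e.rule.name}", _PREC_POSTFIX
        else:
            raise ArityError(f"cannot serialize node kind {k!r}")
        return f"( {s} )" if p < prec else s

    return go(expr, 0)


def serialize_program(registry: ProcessRegistry) -> str:
    lines = [f"define {name} = {serialize_expression(body)} ;"
             for name, body in registry.items()]
    return "\n".join(lines) + ("\n" if lines else "")


def serialize(obj) -> str:
    """Serialize an expression or a registry."""
    if isinstance(obj, ProcessRegistry):
        return serialize_program(obj)
    return serialize_expression(obj)
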