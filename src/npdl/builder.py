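"""Compile end-user test definitions into canonical process expressions.

A genetic test is defined by a laboratory user as a list of procedures with
execution-order integers plus metadata (name, description, duration in
days, cost).  No process-algebra knowledge is required of the user: the
compiler applies the mapping used by the test-definition interface —

* procedures sharing an execution order form a group that runs in parallel
  (``||``);
* groups are linked in ascending order of the execution-order integer with
  sequential composition (``.``);
* each procedure may be repeated as needed (``?*``) and its completion gate
  is a silent ``GO`` guarded by the built-in success rule ``ok_<procedure>``
  (``%``), so the flow only proceeds past a procedure once it has last
  completed with outcome ok;
* the terminal ``END`` closes the expression; its release marks test
  completion.

For the SMA example (PCR of SMN1 exons 7 and 8 at the same order) the
compiled form is::

    ((PCR_exon7 ?* . (GO % ok_PCR_exon7)) || (PCR_exon8 ?* . (GO % ok_PCR_exon8))) . END
"""

from __future__ import annotations

import csv
import io
import json
import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

from .algebra import (
    END,
    GO,
    IDENT_RE,
    ArityError,
    ProcessExpr,
    ProcessRegistry,
    RuleRef,
    atom,
    guard,
    par_chain,
    rep_star,
    seq,
    seq_chain,
)
from .engine import OK_RULE_PREFIX

__all__ = [
    "ProcedureDef",
    "TestDefinition",
    "TestItem",
    "ProcedureCatalog",
    "validate",
    "build_expression",
    "ok_rule_name",
    "test_from_json",
    "test_from_csv",
    "catalog_from_json",
]


def ok_rule_name(procedure: str) -> str:
    """The generated success rule for a procedure (``ok_<procedure>``)."""
    return OK_RULE_PREFIX + procedure


@dataclass(frozen=True)
class ProcedureDef:
    """A reusable laboratory procedure (one atomic test step)."""

    name: str
    description: str = ""
    technique: str = ""
    reagents: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not IDENT_RE.match(self.name):
            raise ArityError(f"invalid procedure name {self.name!r}")


class ProcedureCatalog:
    """The set of pre-defined procedures tests are composed from."""

    def __init__(self, procedures: Iterable[ProcedureDef] = ()) -> None:
        self._procs: Dict[str, ProcedureDef] = {}
        for p in procedures:
            self.add(p)

    def add(self, proc: ProcedureDef) -> None:
        if proc.name in self._procs:
            raise ArityError(f"duplicate procedure {proc.name!r} in catalog")
        self._procs[proc.name] = proc

    def __contains__(self, name: str) -> bool:
        return name in self._procs

    def get(self, name: str) -> ProcedureDef:
        return self._procs[name]

    def names(self) -> List[str]:
        return sorted(self._procs)

    def __iter__(self):
        return iter(self._procs.values())

    def __len__(self) -> int:
        return len(self._procs)


@dataclass(frozen=True)
class TestItem:
    __test__ = False  # domain class, not a pytest suite

    procedure: str
    order: int


@dataclass(frozen=True)
class TestDefinition:
    """The end-user artifact: which procedures, in which order groups."""

    __test__ = False  # domain class, not a pytest suite

    name: str
    description: str = ""
    attachment: Optional[str] = None
    duration_days: float = 0.0
    cost: float = 0.0
    items: Tuple[TestItem, ...] = ()

    @property
    def process_name(self) -> str:
        """The (sanitised) registry name the compiled expression is stored
        under; non-identifier characters become underscores."""
        name = re.sub(r"\W", "_", self.name)
        if not re.match(r"[A-Za-z_]", name):
            name = "_" + name
        return name


def validate(test_def: TestDefinition, catalog: ProcedureCatalog) -> List[str]:
    """Check a test definition against the catalog; returns violation
    messages (empty list = valid)."""
    violations: List[str] = []
    if not test_def.name.strip():
        violations.append("test name must not be empty")
    if not test_def.items:
        violations.append("a test needs at least one procedure")
    if test_def.duration_days < 0:
        violations.append("duration_days must be non-negative")
    if test_def.cost < 0:
        violations.append("cost must be non-negative")
    seen = set()
    for item in test_def.items:
        if item.procedure in seen:
            violations.append(f"duplicate procedure {item.procedure!r} in test")
        seen.add(item.procedure)
        if item.procedure not in catalog:
            violations.append(f"procedure {item.procedure!r} not in catalog")
        if item.order < 1:
            violations.append(
                f"execution order of {item.procedure!r} must be >= 1")
    return violations


def _wrap_procedure(name: str) -> ProcessExpr:
    """``(p ?*) . (GO % ok_p)``: repeatable execution, then a silent gate
    that opens once the procedure last completed ok."""
    return seq(rep_star(atom(name)), guard(GO, RuleRef(ok_rule_name(name))))


def build_expression(test_def: TestDefinition,
                     catalog: ProcedureCatalog,
                     registry: Optional[ProcessRegistry] = None
                     ) -> Tuple[ProcessExpr, str]:
    """Compile a valid test definition to its canonical expression.

    Groups items by ascending execution order; same order -> parallel,
    different orders -> sequential; appends the terminal END.  Registers the
    expression under the test's (sanitised) name when a registry is given.
    Returns (expression, process name).
    """
    violations = validate(test_def, catalog)
    if violations:
        raise ArityError("invalid test definition: " + "; ".join(violations))
    groups: Dict[int, List[str]] = {}
    for item in test_def.items:
        groups.setdefault(item.order, []).append(item.procedure)
    group_exprs = [par_chain([_wrap_procedure(p) for p in groups[order]])
                   for order in sorted(groups)]
    expr = seq_chain(group_exprs + [END])
    name = test_def.process_name
    if registry is not None:
        registry.define(name, expr)
    return expr, name


# ---------------------------------------------------------------------------
# interchange formats
# ---------------------------------------------------------------------------

def test_from_json(text: str) -> TestDefinition:
    """Load a test definition from JSON:
    ``{"name":…, "description":…, "duration_days":…, "cost":…,
    "procedures":[{"name":…, "order":…}, …]}``."""
    data = json.loads(text)
    items = tuple(TestItem(p["name"], int(p["order"]))
                  for p in data.get("procedures", []))
    return TestDefinition(
        name=data["name"], description=data.get("description", ""),
        attachment=data.get("attachment"),
        duration_days=float(data.get("duration_days", 0)),
        cost=float(data.get("cost", 0)), items=items)


def test_from_csv(text: str, name: str, **metadata) -> TestDefinition:
    """Load the item list from CSV with columns ``procedure,order``."""
    items = []
    for row in csv.DictReader(io.StringIO(text)):
        items.append(TestItem(row["procedure"].strip(), int(row["order"])))
    return TestDefinition(name=name, items=tuple(items), **metadata)


def catalog_from_json(text: str) -> ProcedureCatalog:
    """Load a procedure catalog from a JSON list of objects with ``name``
    and optional ``description``/``technique``/``reagents``."""
    data = json.loads(text)
    return ProcedureCatalog(
        ProcedureDef(name=p["name"], description=p.get("description", ""),
                     technique=p.get("technique", ""),
                     reagents=tuple(p.get("reagents", ())))
        for p in data)
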