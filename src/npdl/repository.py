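"""Relational persistence: process repository, lab records, work queues.

An embedded SQLite database (file or in-memory) holds the common process
repository — versioned process definitions as NPDL text — together with the
procedure catalog, test definitions, patients, samples, test orders,
running instances and their event logs.  The schema ships as a plain SQL
migration file, so the store stays portable across relational engines.

The two work-queue views mirror the procedure-execution interface: filter
by *procedure* (all released occurrences of matching procedures across all
tests, e.g. every pending ``PCR*`` regardless of disease) or by *disease*
(only the released steps of orders for that test).
"""

from __future__ import annotations

import csv
import io
import json
import sqlite3
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Dict, List, Optional, Tuple

from .algebra import NpdlError, ProcessRegistry, UnknownNameError
from .builder import ProcedureCatalog, ProcedureDef, TestDefinition, TestItem
from .engine import (
    EvaluationContext,
    ExecutionEvent,
    ProcessInstance,
    ReplayClock,
    facts_from_events,
)
from .text import parse_expression, serialize_expression

__all__ = [
    "Repository",
    "WorkQueueItem",
    "WORK_QUEUE_COLUMNS",
    "Patient",
    "Sample",
    "TestOrder",
]

#: the seven work-queue columns, in interface order
WORK_QUEUE_COLUMNS = (
    "procedure name", "patient number", "patient name", "DNA number",
    "date of test request", "test name", "execution status",
)


@dataclass(frozen=True)
class Patient:
    number: int
    name: str


@dataclass(frozen=True)
class Sample:
    dna_number: str
    patient: int


@dataclass(frozen=True)
class TestOrder:
    __test__ = False  # domain class, not a pytest suite

    id: int
    sample: str
    test: str
    request_date: str  # ISO-8601


@dataclass(frozen=True)
class WorkQueueItem:
    """One released procedure occurrence awaiting a user status report."""

    procedure: str
    patient_number: int
    patient_name: str
    dna_number: str
    request_date: str
    test_name: str
    execution_status: str
    instance_id: str = ""
    available_actions: Tuple[str, ...] = ("complete", "repeat", "cancel", "finish")

    def row(self) -> Tuple:
        return (self.procedure, self.patient_number, self.patient_name,
                self.dna_number, self.request_date, self.test_name,
                self.execution_status)


class Repository:
    """Embedded relational store for the whole laboratory state."""

    def __init__(self, path: str = ":memory:") -> None:
        self.conn = sqlite3.connect(path)
        self.conn.execute("PRAGMA foreign_keys = ON")
        ddl = resources.files("npdl.migrations").joinpath("001_init.sql").read_text()
        self.conn.executescript(ddl)
        self.conn.commit()

    def close(self) -> None:
        self.conn.close()

    # -- process definitions ----------------------------------------------

    def save_definition(self, name: str, version: int, npdl_text: str) -> None:
        with self.conn:
            self.conn.execute(
                "INSERT OR REPLACE INTO process_definition VALUES (?,?,?)",
                (name, version, npdl_text))

    def save_registry(self, registry: ProcessRegistry) -> None:
        for name, body in registry.items():
            self.save_definition(name, registry.version(name),
                                 serialize_expression(body))

    def load_registry(self) -> ProcessRegistry:
        """Latest version of every stored definition, reparsed."""
        reg = ProcessRegistry()
        rows = self.conn.execute(
            "SELECT name, npdl_text FROM process_definition p "
            "WHERE version = (SELECT MAX(version) FROM process_definition "
            "                 WHERE name = p.name) ORDER BY name").fetchall()
        names = {name for name, _ in rows}
        for name, text in rows:
            reg.define(name, parse_expression(text, known_names=names))
        return reg

    # -- catalog and tests -------------------------------------------------

    def save_procedure(self, proc: ProcedureDef) -> None:
        with self.conn:
            self.conn.execute(
                "INSERT OR REPLACE INTO procedure_catalog VALUES (?,?,?,?)",
                (proc.name, proc.description, proc.technique,
                 json.dumps(list(proc.reagents))))

    def load_catalog(self) -> ProcedureCatalog:
        rows = self.conn.execute(
            "SELECT name, description, technique, reagents "
            "FROM procedure_catalog ORDER BY name").fetchall()
        return ProcedureCatalog(
            ProcedureDef(n, d, t, tuple(json.loads(r))) for n, d, t, r in rows)

    def save_test(self, test: TestDefinition, process_name: str) -> None:
        with self.conn:
            self.conn.execute(
                "INSERT OR REPLACE INTO test VALUES (?,?,?,?,?,?)",
                (test.name, test.description, test.attachment,
                 test.duration_days, test.cost, process_name))
            self.conn.execute("DELETE FROM test_item WHERE test = ?", (test.name,))
            for item in test.items:
                self.conn.execute("INSERT INTO test_item VALUES (?,?,?)",
                                  (test.name, item.procedure, item.order))

    def load_test(self, name: str) -> TestDefinition:
        row = self.conn.execute(
            "SELECT name, description, attachment, duration_days, cost "
            "FROM test WHERE name = ?", (name,)).fetchone()
        if row is None:
            raise UnknownNameError(f"unknown test {name!r}")
        items = tuple(TestItem(p, o) for p, o in self.conn.execute(
            "SELECT procedure, exec_order FROM test_item WHERE test = ? "
            "ORDER BY exec_order, procedure", (name,)))
        return TestDefinition(name=row[0], description=row[1], attachment=row[2],
                              duration_days=row[3], cost=row[4], items=items)

    def test_process_name(self, test_name: str) -> str:
        row = self.conn.execute("SELECT process_name FROM test WHERE name = ?",
                                (test_name,)).fetchone()
        if row is None:
            raise UnknownNameError(f"unknown test {test_name!r}")
        return row[0]

    def list_tests(self) -> List[str]:
        return [r[0] for r in self.conn.execute(
            "SELECT name FROM test ORDER BY name")]

    def test_procedures(self, test_name: str) -> List[str]:
        return [r[0] for r in self.conn.execute(
            "SELECT procedure FROM test_item WHERE test = ? ORDER BY procedure",
            (test_name,))]

    # -- patients, samples, orders ------------------------------------------

    def save_patient(self, patient: Patient) -> None:
        with self.conn:
            self.conn.execute("INSERT OR REPLACE INTO patient VALUES (?,?)",
                              (patient.number, patient.name))

    def save_sample(self, sample: Sample) -> None:
        with self.conn:
            self.conn.execute("INSERT OR REPLACE INTO sample VALUES (?,?)",
                              (sample.dna_number, sample.patient))

    def save_order(self, order: TestOrder) -> None:
        with self.conn:
            self.conn.execute("INSERT OR REPLACE INTO test_order VALUES (?,?,?,?)",
                              (order.id, order.sample, order.test,
                               order.request_date))

    def next_order_id(self) -> int:
        row = self.conn.execute("SELECT COALESCE(MAX(id), 0) + 1 FROM test_order").fetchone()
        return row[0]

    # -- instances and events ------------------------------------------------

    def persist_instance(self, instance: ProcessInstance,
                         order_id: Optional[int] = None) -> None:
        """Save residual, lifecycle and the full event log."""
        with self.conn:
            self.conn.execute(
                "INSERT OR REPLACE INTO instance VALUES (?,?,?,?,?,?)",
                (instance.id, order_id, instance.definition_name,
                 instance.definition_version,
                 serialize_expression(instance.residual), instance.lifecycle))
            self.conn.execute("DELETE FROM event WHERE instance = ?",
                              (instance.id,))
            for ev in instance.log:
                self.conn.execute("INSERT INTO event VALUES (?,?,?,?,?,?,?)",
                                  (instance.id, ev.seq, ev.action, ev.status,
                                   ev.outcome, ev.timestamp, ev.path))

    def load_events(self, instance_id: str) -> List[ExecutionEvent]:
        rows = self.conn.execute(
            "SELECT seq, action, status, outcome, timestamp, path "
            "FROM event WHERE instance = ? ORDER BY seq", (instance_id,))
        return [ExecutionEvent(*r) for r in rows]

    def load_instance(self, instance_id: str,
                      registry: Optional[ProcessRegistry] = None,
                      rules: Optional[Dict[str, Callable]] = None,
                      functions: Optional[Dict[str, Callable]] = None) -> ProcessInstance:
        """Rebuild a live instance from its stored residual and event log.

        The residual is reparsed; the facts are derived from the log; the
        released set is recomputed, so it matches the in-memory state the
        instance was saved with.
        """
        row = self.conn.execute(
            "SELECT order_id, definition_name, definition_version, "
            "residual_npdl, lifecycle FROM instance WHERE id = ?",
            (instance_id,)).fetchone()
        if row is None:
            raise UnknownNameError(f"unknown instance {instance_id!r}")
        _, def_name, def_version, residual_text, lifecycle = row
        reg = registry if registry is not None else self.load_registry()
        events = self.load_events(instance_id)
        residual = parse_expression(residual_text, known_names=set(reg.names()))
        ctx = EvaluationContext(rules=dict(rules or {}),
                                functions=dict(functions or {}))
        ctx.facts = facts_from_events(events)
        inst = ProcessInstance(
            instance_id=instance_id, definition_name=def_name,
            definition_version=def_version, registry=reg, residual=residual,
            ctx=ctx, clock=ReplayClock([ev.timestamp for ev in events]))
        inst.log = list(events)
        inst.lifecycle = lifecycle
        if lifecycle == "running":
            inst._released_logged = {ev.action for ev in events
                                     if ev.status == "released"}
            inst._advance()
        return inst

    def instance_order(self, instance_id: str) -> Optional[int]:
        row = self.conn.execute("SELECT order_id FROM instance WHERE id = ?",
                                (instance_id,)).fetchone()
        return row[0] if row else None

    def running_instances(self) -> List[str]:
        return [r[0] for r in self.conn.execute(
            "SELECT id FROM instance WHERE lifecycle = 'running' ORDER BY id")]

    # -- work queues ---------------------------------------------------------

    def work_queue(self, filter_kind: str, value: str = "",
                   registry: Optional[ProcessRegistry] = None,
                   rules: Optional[Dict[str, Callable]] = None) -> List[WorkQueueItem]:
        """The released steps of all running instances, joined to patient,
        sample and test metadata.

        ``filter_kind`` is ``"procedure"`` (exact name, or a prefix with a
        trailing ``*``, across all tests), ``"disease"`` (one test's orders
        only) or ``"all"``.  Unknown values yield an empty list.
        """
        if filter_kind not in ("procedure", "disease", "all"):
            raise NpdlError(f"unknown work-queue filter {filter_kind!r}")
        reg = registry if registry is not None else self.load_registry()
        items: List[WorkQueueItem] = []
        for inst_id in self.running_instances():
            meta = self.conn.execute(
                "SELECT o.test, o.request_date, s.dna_number, p.number, p.name "
                "FROM instance i JOIN test_order o ON i.order_id = o.id "
                "JOIN sample s ON o.sample = s.dna_number "
                "JOIN patient p ON s.patient = p.number "
                "WHERE i.id = ?", (inst_id,)).fetchone()
            if meta is None:
                continue  # instance not attached to an order
            test_name, request_date, dna, pat_no, pat_name = meta
            if filter_kind == "disease" and test_name != value:
                continue
            inst = self.load_instance(inst_id, registry=reg, rules=rules)
            if inst.lifecycle != "running":
                continue
            last_status: Dict[str, str] = {}
            for ev in inst.log:
                last_status[ev.action] = ev.status
            for step in inst.released():
                if filter_kind == "procedure" and not _match(step.action, value):
                    continue
                items.append(WorkQueueItem(
                    procedure=step.action, patient_number=pat_no,
                    patient_name=pat_name, dna_number=dna,
                    request_date=request_date, test_name=test_name,
                    execution_status=last_status.get(step.action, "released"),
                    instance_id=inst_id))
        items.sort(key=lambda it: (it.procedure, it.dna_number, it.instance_id))
        return items

    def work_queue_csv(self, filter_kind: str = "all", value: str = "",
                       registry: Optional[ProcessRegistry] = None) -> str:
        buf = io.StringIO()
        w = csv.writer(buf)
        w.writerow(WORK_QUEUE_COLUMNS)
        for item in self.work_queue(filter_kind, value, registry):
            w.writerow(item.row())
        return buf.getvalue()

    # -- CSV import/export -----------------------------------------------------

    def export_csv(self, table: str) -> str:
        if table not in ("patient", "sample", "test_order"):
            raise NpdlError(f"no CSV export for table {table!r}")
        cur = self.conn.execute(f"SELECT * FROM {table} ORDER BY 1")
        buf = io.StringIO()
        w = csv.writer(buf)
        w.writerow([c[0] for c in cur.description])
        w.writerows(cur.fetchall())
        return buf.getvalue()

    def import_patients_csv(self, text: str) -> int:
        n = 0
        for row in csv.DictReader(io.StringIO(text)):
            self.save_patient(Patient(int(row["number"]), row["name"]))
            n += 1
        return n

    def import_samples_csv(self, text: str) -> int:
        n = 0
        for row in csv.DictReader(io.StringIO(text)):
            self.save_sample(Sample(row["dna_number"], int(row["patient"])))
            n += 1
        return n

    def import_orders_csv(self, text: str) -> int:
        n = 0
        for row in csv.DictReader(io.StringIO(text)):
            self.save_order(TestOrder(int(row["id"]), row["sample"],
                                      row["test"], row["request_date"]))
            n += 1
        return n


def _match(name: str, pattern: str) -> bool:
    if pattern.endswith("*"):
        return name.startswith(pattern[:-1])
    return name == pattern
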