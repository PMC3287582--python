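"""Relational store: round-trips, integrity, work-queue views."""

import sqlite3

import pytest

from npdl.algebra import ProcessRegistry, UnknownNameError
from npdl.builder import build_expression
from npdl.engine import instantiate
from npdl.fixtures import WorkloadSpec, generate_workload
from npdl.repository import (
    Patient,
    Repository,
    Sample,
    TestOrder,
    WORK_QUEUE_COLUMNS,
)
from npdl.text import serialize_expression as S


@pytest.fixture
def repo():
    r = Repository(":memory:")
    yield r
    r.close()


@pytest.fixture
def lab(repo, sma_catalog, sma_test):
    """Repository loaded with the SMA test and one ordered sample."""
    registry = ProcessRegistry()
    for proc in sma_catalog:
        repo.save_procedure(proc)
    expr, name = build_expression(sma_test, sma_catalog, registry)
    repo.save_test(sma_test, name)
    repo.save_definition(name, registry.version(name), S(expr))
    repo.save_patient(Patient(1001, "Maria Souza"))
    repo.save_sample(Sample("DNA1001a", 1001))
    repo.save_order(TestOrder(1, "DNA1001a", "SMA", "2020-01-06"))
    inst = instantiate(name, registry, instance_id="inst-000001")
    repo.persist_instance(inst, order_id=1)
    return repo, registry, inst


class TestRoundTrips:
    def test_registry_reparse(self, lab):
        repo, registry, _ = lab
        again = repo.load_registry()
        for name in registry.names():
            assert again.resolve(name) == registry.resolve(name)

    def test_catalog_and_test(self, lab, sma_test):
        repo, _, _ = lab
        assert repo.load_catalog().get("PCR_exon7").name == "PCR_exon7"
        assert repo.load_test("SMA") == sma_test

    def test_mid_execution_instance(self, lab):
        repo, registry, inst = lab
        inst.report("PCR_exon7", "complete", "ok")
        repo.persist_instance(inst, order_id=1)
        twin = repo.load_instance(inst.id, registry=registry)
        assert twin.lifecycle == "running"
        assert sorted(s.action for s in twin.released()) \
            == sorted(s.action for s in inst.released()) \
            == ["PCR_exon7", "PCR_exon8"]
        assert twin.log == inst.log
        # the reloaded instance keeps working identically: exon7 already
        # completed ok before the save, so completing exon8 fires END
        twin.report("PCR_exon8", "complete", "ok")
        assert twin.lifecycle == "finished"

    def test_unknown_instance(self, repo):
        with pytest.raises(UnknownNameError):
            repo.load_instance("nope")

    def test_duplicate_event_sequence_is_integrity_error(self, lab):
        repo, _, inst = lab
        with pytest.raises(sqlite3.IntegrityError):
            repo.conn.execute(
                "INSERT INTO event VALUES (?,?,?,?,?,?,?)",
                (inst.id, 1, "x", "released", "", "t", ""))

    def test_csv_export_import(self, lab):
        repo, _, _ = lab
        text = repo.export_csv("patient")
        fresh = Repository(":memory:")
        assert fresh.import_patients_csv(text) == 1
        assert fresh.export_csv("patient") == text


class TestWorkQueue:
    def setup_lab(self, n_patients=4, n_tests=3, seed=11):
        wl = generate_workload(WorkloadSpec(seed=seed, n_patients=n_patients,
                                            n_tests=n_tests))
        repo = Repository(":memory:")
        registry = ProcessRegistry()
        for proc in wl.catalog:
            repo.save_procedure(proc)
        for test in wl.tests:
            expr, name = build_expression(test, wl.catalog, registry)
            repo.save_test(test, name)
            repo.save_definition(name, registry.version(name), S(expr))
        for p in wl.patients:
            repo.save_patient(p)
        for s in wl.samples:
            repo.save_sample(s)
        for o in wl.orders:
            repo.save_order(o)
            inst = instantiate(repo.test_process_name(o.test), registry,
                               instance_id=f"inst-{o.id:06d}")
            repo.persist_instance(inst, order_id=o.id)
        return repo, registry

    def test_disease_filter_partitions_the_queue(self):
        repo, registry = self.setup_lab()
        full = [i.row() for i in repo.work_queue("all", registry=registry)]
        union = []
        for t in repo.list_tests():
            union += [i.row() for i in
                      repo.work_queue("disease", t, registry=registry)]
        assert sorted(full) == sorted(union)
        assert full  # sanity: the queue is not empty

    def test_procedure_prefix_filter(self):
        repo, registry = self.setup_lab()
        pcr = repo.work_queue("procedure", "PCR*", registry=registry)
        assert pcr
        assert all(i.procedure.startswith("PCR") for i in pcr)
        exact = repo.work_queue("procedure", "PCR_exon7", registry=registry)
        assert all(i.procedure == "PCR_exon7" for i in exact)

    def test_disease_filter_shows_only_that_test(self):
        repo, registry = self.setup_lab()
        sma_only = repo.work_queue("disease", "SMA", registry=registry)
        assert sma_only and all(i.test_name == "SMA" for i in sma_only)
        assert {i.procedure for i in sma_only} <= {"PCR_exon7", "PCR_exon8"}

    def test_unknown_value_gives_empty_list(self):
        repo, registry = self.setup_lab()
        assert repo.work_queue("disease", "unknown", registry=registry) == []
        assert repo.work_queue("procedure", "teleport", registry=registry) == []

    def test_empty_database(self, repo):
        assert repo.work_queue("all") == []

    def test_queue_recomputed_from_persisted_state(self):
        repo, registry = self.setup_lab(n_patients=2, n_tests=1)
        before = [i.row() for i in repo.work_queue("all", registry=registry)]
        # a fresh Repository object over the same connection state
        after = [i.row() for i in repo.work_queue("all")]  # reloads registry
        assert sorted(before) == sorted(after)

    def test_csv_has_the_seven_interface_columns(self, lab):
        repo, _, _ = lab
        header = repo.work_queue_csv("all").splitlines()[0]
        assert header == ",".join(WORK_QUEUE_COLUMNS)
        rows = repo.work_queue_csv("disease", "SMA").splitlines()
        assert len(rows) == 3  # header + the two released PCRs
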