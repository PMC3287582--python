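"""Test-definition compiler: validation, canonical form, trace properties."""

import itertools
import json

import pytest

from npdl.algebra import traces
from npdl.builder import (
    ProcedureCatalog,
    ProcedureDef,
    TestDefinition,
    TestItem,
    build_expression,
    catalog_from_json,
    ok_rule_name,
    validate,
)
from npdl.builder import test_from_csv as load_test_csv
from npdl.builder import test_from_json as load_test_json
from npdl.text import parse_expression as P


class TestValidate:
    def test_sma_is_valid(self, sma_test, sma_catalog):
        assert validate(sma_test, sma_catalog) == []

    def test_empty_items(self, sma_catalog):
        bad = TestDefinition(name="X", items=())
        assert len(validate(bad, sma_catalog)) == 1

    def test_duplicate_procedure(self, sma_catalog):
        bad = TestDefinition(name="X", items=(
            TestItem("PCR_exon7", 1), TestItem("PCR_exon7", 2)))
        assert any("duplicate" in v for v in validate(bad, sma_catalog))

    def test_unknown_procedure_and_bad_order(self, sma_catalog):
        bad = TestDefinition(name="X", items=(TestItem("teleportation", 0),))
        msgs = validate(bad, sma_catalog)
        assert any("not in catalog" in v for v in msgs)
        assert any("order" in v for v in msgs)

    def test_negative_metadata(self, sma_catalog):
        bad = TestDefinition(name="X", duration_days=-1, cost=-5,
                             items=(TestItem("analysis", 1),))
        assert len(validate(bad, sma_catalog)) == 2


class TestBuildExpression:
    def test_sma_canonical_form(self, sma_test, sma_catalog):
        expr, name = build_expression(sma_test, sma_catalog)
        assert name == "SMA"
        assert expr == P(
            "((PCR_exon7 ?* . (GO % ok_PCR_exon7)) || "
            "(PCR_exon8 ?* . (GO % ok_PCR_exon8))) . END")
        assert traces(expr, loop_bound=1) == frozenset({
            ("PCR_exon7", "PCR_exon8", "END"),
            ("PCR_exon8", "PCR_exon7", "END"),
        })

    def test_ascending_order_is_sequential(self, sma_catalog):
        t = TestDefinition(name="chain", items=(
            TestItem("DNA_extraction", 1), TestItem("PCR_exon7", 2),
            TestItem("analysis", 3)))
        expr, _ = build_expression(t, sma_catalog)
        assert traces(expr, loop_bound=1) == frozenset({
            ("DNA_extraction", "PCR_exon7", "analysis", "END")})

    def test_single_procedure_degenerate_group(self, sma_catalog):
        t = TestDefinition(name="solo", items=(TestItem("analysis", 5),))
        expr, _ = build_expression(t, sma_catalog)
        assert expr == P("(analysis ?* . (GO % ok_analysis)) . END")

    def test_orders_need_not_be_consecutive(self, sma_catalog):
        a = TestDefinition(name="t", items=(
            TestItem("DNA_extraction", 2), TestItem("analysis", 9)))
        b = TestDefinition(name="t", items=(
            TestItem("DNA_extraction", 1), TestItem("analysis", 2)))
        ea, _ = build_expression(a, sma_catalog)
        eb, _ = build_expression(b, sma_catalog)
        assert ea == eb

    def test_invalid_definition_rejected(self, sma_catalog):
        with pytest.raises(Exception):
            build_expression(TestDefinition(name="X", items=()), sma_catalog)

    def test_registration(self, sma_test, sma_catalog):
        from npdl.algebra import ProcessRegistry
        reg = ProcessRegistry()
        _, name = build_expression(sma_test, sma_catalog, reg)
        assert name in reg


class TestTraceProperties:
    def catalog(self, names):
        return ProcedureCatalog(ProcedureDef(n) for n in names)

    def test_group_ordering_respected(self):
        names = ["p1", "p2", "p3", "p4"]
        t = TestDefinition(name="t", items=(
            TestItem("p1", 1), TestItem("p2", 1),
            TestItem("p3", 2), TestItem("p4", 3)))
        expr, _ = build_expression(t, self.catalog(names))
        for tr in traces(expr, loop_bound=1):
            assert tr.index("p3") > max(tr.index("p1"), tr.index("p2"))
            assert tr.index("p4") > tr.index("p3")

    @pytest.mark.parametrize("m", [1, 2, 3, 4])
    def test_parallel_group_contributes_m_factorial_orderings(self, m):
        names = [f"p{i}" for i in range(m)]
        t = TestDefinition(name="t",
                           items=tuple(TestItem(n, 1) for n in names))
        expr, _ = build_expression(t, self.catalog(names))
        ts = traces(expr, loop_bound=1)
        assert len(ts) == len(list(itertools.permutations(names)))
        for tr in ts:
            assert tr[-1] == "END" and tr.count("END") == 1

    def test_gate_blocks_end_when_ok_false(self, sma_test, sma_catalog):
        expr, _ = build_expression(sma_test, sma_catalog)
        blocked = traces(expr, loop_bound=1,
                         rule_values={ok_rule_name("PCR_exon7"): False})
        assert blocked == frozenset()  # no complete run reaches END


class TestInterchange:
    def test_json_round_understood(self):
        text = json.dumps({
            "name": "SMA", "description": "d", "duration_days": 7,
            "cost": 120.0,
            "procedures": [{"name": "PCR_exon7", "order": 1},
                           {"name": "PCR_exon8", "order": 1}]})
        t = load_test_json(text)
        assert t.duration_days == 7 and len(t.items) == 2

    def test_csv_items(self):
        t = load_test_csv("procedure,order\nDNA_extraction,1\nanalysis,2\n",
                          name="chain")
        assert t.items == (TestItem("DNA_extraction", 1), TestItem("analysis", 2))

    def test_catalog_json(self):
        cat = catalog_from_json(json.dumps(
            [{"name": "PCR_exon7", "reagents": ["primer mix", "Taq"]}]))
        assert "PCR_exon7" in cat
        assert cat.get("PCR_exon7").reagents == ("primer mix", "Taq")

    def test_process_name_sanitised(self):
        t = TestDefinition(name="Cystic Fibrosis (CFTR)",
                           items=(TestItem("analysis", 1),))
        assert t.process_name == "Cystic_Fibrosis__CFTR_"
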