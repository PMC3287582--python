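"""Engine: instance lifecycle, releases, status reports, replay."""

import pytest

from npdl.algebra import ProcessRegistry, UnknownNameError
from npdl.engine import (
    EngineError,
    InstanceNotRunning,
    NotReleasedError,
    TickClock,
    instantiate,
    replay,
)
from npdl.text import parse_expression as P


def released_set(inst):
    return sorted({s.action for s in inst.released()})


@pytest.fixture
def sma(sma_registry):
    registry, name = sma_registry
    return instantiate(name, registry, instance_id="sma-1")


class TestInstantiate:
    def test_sma_releases_both_pcrs(self, sma):
        assert released_set(sma) == ["PCR_exon7", "PCR_exon8"]

    def test_function_repetition_fixed_at_instantiation(self):
        reg = ProcessRegistry()
        reg.define("T", P("a ?f(three) . b"))
        inst = instantiate("T", reg, functions={"three": lambda facts: 3})
        # behaves exactly like a ?3: three completions of a required before b
        for _ in range(3):
            assert released_set(inst) == ["a"]
            inst.report("a", "complete", "ok")
        assert released_set(inst) == ["b"]

    def test_missing_rule_is_named_in_the_error(self, sma_registry):
        reg = ProcessRegistry()
        reg.define("T", P("a % mystery"))
        with pytest.raises(UnknownNameError, match="mystery"):
            instantiate("T", reg)

    def test_missing_function_is_an_error(self):
        reg = ProcessRegistry()
        reg.define("T", P("a ?f(absent)"))
        with pytest.raises(UnknownNameError, match="absent"):
            instantiate("T", reg)

    def test_unknown_definition(self):
        with pytest.raises(UnknownNameError):
            instantiate("nope", ProcessRegistry())


class TestReleased:
    def test_completed_procedure_stays_repeatable_until_gate_commits(self, sma):
        sma.report("PCR_exon7", "complete", "ok")
        # the other PCR is released and the completed one can still repeat
        assert released_set(sma) == ["PCR_exon7", "PCR_exon8"]

    def test_both_ok_fires_gates_and_end(self, sma):
        sma.report("PCR_exon7", "complete", "ok")
        sma.report("PCR_exon8", "complete", "ok")
        assert sma.lifecycle == "finished"
        assert sma.released() == []
        assert [e.action for e in sma.log if e.status == "completed"] == [
            "PCR_exon7", "PCR_exon8", "END"]

    def test_guard_blocked_instance_is_stuck(self):
        reg = ProcessRegistry()
        reg.define("T", P("a % never"))
        inst = instantiate("T", reg)
        assert inst.lifecycle == "stuck"
        assert inst.released() == []


class TestReport:
    def test_parallel_completion_order_independent(self, sma_registry):
        registry, name = sma_registry
        one = instantiate(name, registry, instance_id="x")
        two = instantiate(name, registry, instance_id="y")
        one.report("PCR_exon7", "complete", "ok")
        one.report("PCR_exon8", "complete", "ok")
        two.report("PCR_exon8", "complete", "ok")
        two.report("PCR_exon7", "complete", "ok")
        assert one.residual == two.residual
        assert one.lifecycle == two.lifecycle == "finished"

    def test_repeat_keeps_action_released(self, sma):
        sma.report("PCR_exon7", "repeat")
        assert "PCR_exon7" in released_set(sma)
        assert sma.ctx.facts["PCR_exon7"].times_executed == 1

    def test_cancel_stops_everything(self, sma):
        sma.report("PCR_exon7", "cancel")
        assert sma.lifecycle == "canceled"
        with pytest.raises(InstanceNotRunning):
            sma.released()
        with pytest.raises(InstanceNotRunning):
            sma.report("PCR_exon8", "complete")

    def test_finish_before_completion_is_forced(self, sma):
        sma.report("PCR_exon7", "finish")
        assert sma.lifecycle == "forced_finished"

    def test_unreleased_action_rejected(self, sma):
        with pytest.raises(NotReleasedError):
            sma.report("DNA_extraction", "complete")

    def test_failed_outcome_blocks_the_gate(self, sma):
        sma.report("PCR_exon7", "complete", "failed")
        sma.report("PCR_exon8", "complete", "ok")
        assert sma.lifecycle == "running"  # END has not fired
        assert "PCR_exon7" in released_set(sma)
        sma.report("PCR_exon7", "complete", "ok")
        assert sma.lifecycle == "finished"

    def test_bad_status_and_outcome(self, sma):
        with pytest.raises(EngineError):
            sma.report("PCR_exon7", "postpone")
        with pytest.raises(EngineError):
            sma.report("PCR_exon7", "complete", "maybe")


class TestPatternExecution:
    def drive(self, text, order=None):
        reg = ProcessRegistry()
        reg.define("T", P(text))
        inst = instantiate("T", reg)
        while inst.lifecycle == "running":
            rel = released_set(inst)
            if not rel:
                break
            pick = rel[0] if order is None else next(a for a in order if a in rel)
            inst.report(pick, "complete", "ok")
        return inst

    def test_multi_merge_continuation_fires_twice(self):
        for order in (("a", "b", "c"), ("b", "a", "c")):
            inst = self.drive("(a & b) . c", order=order)
            assert [e.action for e in inst.log if e.status == "completed"].count("c") == 2
            assert inst.lifecycle == "finished"

    def test_discriminator_continuation_fires_once(self):
        for order in (("a", "b", "c"), ("b", "a", "c")):
            inst = self.drive("(a ^ b) . c", order=order)
            assert [e.action for e in inst.log if e.status == "completed"].count("c") == 1
            assert inst.lifecycle == "finished"

    def test_interleaved_parallel_one_branch_at_a_time(self):
        reg = ProcessRegistry()
        reg.define("T", P("(a . b) |* (c . d)"))
        inst = instantiate("T", reg)
        assert released_set(inst) == ["a", "c"]
        inst.report("a", "complete", "ok")
        # committed to the left branch: c only reappears after b
        assert released_set(inst) == ["b"]
        inst.report("b", "complete", "ok")
        assert released_set(inst) == ["c"]


class TestEventSourcing:
    def test_sequence_numbers_gapless(self, sma):
        sma.report("PCR_exon7", "complete", "ok")
        sma.report("PCR_exon7", "repeat")
        assert [e.seq for e in sma.log] == list(range(1, len(sma.log) + 1))

    def test_replay_reproduces_state(self, sma_registry):
        registry, name = sma_registry
        inst = instantiate(name, registry, instance_id="r1")
        inst.report("PCR_exon7", "complete", "failed")
        inst.report("PCR_exon7", "repeat")
        inst.report("PCR_exon7", "complete", "ok")
        inst.report("PCR_exon8", "complete", "ok")
        twin = replay(name, registry, inst.log, instance_id="r1")
        assert twin.residual == inst.residual
        assert twin.lifecycle == inst.lifecycle
        assert twin.log == inst.log
        assert {k: (v.times_executed, v.last_outcome) for k, v in twin.ctx.facts.items()} \
            == {k: (v.times_executed, v.last_outcome) for k, v in inst.ctx.facts.items()}

    def test_no_events_after_terminal_lifecycle(self, sma):
        sma.report("PCR_exon7", "cancel")
        n = len(sma.log)
        with pytest.raises(InstanceNotRunning):
            sma.report("PCR_exon8", "complete")
        assert len(sma.log) == n

    def test_deterministic_clock(self, sma_registry):
        registry, name = sma_registry
        a = instantiate(name, registry, clock=TickClock())
        b = instantiate(name, registry, clock=TickClock())
        assert [e.timestamp for e in a.log] == [e.timestamp for e in b.log]
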