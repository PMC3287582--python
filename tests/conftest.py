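import pytest

from npdl.algebra import ProcessRegistry
from npdl.builder import (
    ProcedureCatalog,
    ProcedureDef,
    TestDefinition,
    TestItem,
    build_expression,
)


@pytest.fixture
def sma_catalog():
    return ProcedureCatalog([
        ProcedureDef("PCR_exon7", "PCR of SMN1 exon 7"),
        ProcedureDef("PCR_exon8", "PCR of SMN1 exon 8"),
        ProcedureDef("DNA_extraction"),
        ProcedureDef("analysis"),
    ])


@pytest.fixture
def sma_test():
    """The SMA test: two PCRs at the same execution order (parallel)."""
    return TestDefinition(
        name="SMA", description="SMN1 exon 7/8 deletion", duration_days=7,
        cost=120.0, items=(TestItem("PCR_exon7", 1), TestItem("PCR_exon8", 1)))


@pytest.fixture
def sma_registry(sma_catalog, sma_test):
    """Registry holding the compiled SMA process; returns (registry, name)."""
    registry = ProcessRegistry()
    _, name = build_expression(sma_test, sma_catalog, registry)
    return registry, name
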