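"""A desk-scale laboratory: synthetic workload, relational store, queues.

Generates a small consistent dataset (procedure catalog, tests, patients,
samples, orders), starts one process instance per order, persists
everything to an embedded relational store, and shows the two work-queue
views a technician uses: by procedure (all pending PCRs regardless of
test, e.g. to batch one thermal cycler) and by disease (follow one test).
"""

from npdl import ProcessRegistry, build_expression, instantiate
from npdl.fixtures import WorkloadSpec, generate_workload
from npdl.repository import Repository
from npdl.text import serialize_expression

wl = generate_workload(WorkloadSpec(seed=42, n_patients=4, n_tests=3))
print(f"workload: {len(wl.patients)} patients, {len(wl.samples)} samples, "
      f"{len(wl.tests)} tests, {len(wl.orders)} orders")

repo = Repository(":memory:")      # pass a path for a persistent store
registry = ProcessRegistry()
for proc in wl.catalog:
    repo.save_procedure(proc)
for test in wl.tests:
    expr, name = build_expression(test, wl.catalog, registry)
    repo.save_test(test, name)
    repo.save_definition(name, registry.version(name),
                         serialize_expression(expr))
for p in wl.patients:
    repo.save_patient(p)
for s in wl.samples:
    repo.save_sample(s)
for order in wl.orders:
    repo.save_order(order)
    inst = instantiate(repo.test_process_name(order.test), registry,
                       instance_id=f"inst-{order.id:06d}")
    repo.persist_instance(inst, order_id=order.id)

print("\nall pending PCR steps (one thermal-cycler batch):")
print(repo.work_queue_csv("procedure", "PCR*", registry=registry))
# the seven columns mirror the procedure-execution interface

print("pending steps of the SMA test only:")
print(repo.work_queue_csv("disease", "SMA", registry=registry))

inst_id = repo.running_instances()[0]
inst = repo.load_instance(inst_id, registry=registry)
step = sorted({s.action for s in inst.released()})[0]
inst.report(step, "complete", "ok")
repo.persist_instance(inst, order_id=repo.instance_order(inst_id))
print(f"completed {step} on {inst_id}; queue recomputed from the store:")
print(repo.work_queue_csv("disease", "SMA", registry=registry))
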