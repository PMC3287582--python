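-- Relational process repository: process definitions, the procedure
-- catalog, tests, patients/samples/orders, running instances and their
-- event logs.  Plain portable SQL; dates are ISO-8601 text.

CREATE TABLE IF NOT EXISTS process_definition (
    name       TEXT NOT NULL,
    version    INTEGER NOT NULL,
    npdl_text  TEXT NOT NULL,
    PRIMARY KEY (name, version)
);

CREATE TABLE IF NOT EXISTS procedure_catalog (
    name        TEXT PRIMARY KEY,
    description TEXT NOT NULL DEFAULT '',
    technique   TEXT NOT NULL DEFAULT '',
    reagents    TEXT NOT NULL DEFAULT '[]'   -- JSON list of free-text items
);

CREATE TABLE IF NOT EXISTS test (
    name          TEXT PRIMARY KEY,
    description   TEXT NOT NULL DEFAULT '',
    attachment    TEXT,
    duration_days REAL NOT NULL DEFAULT 0 CHECK (duration_days >= 0),
    cost          REAL NOT NULL DEFAULT 0 CHECK (cost >= 0),
    process_name  TEXT NOT NULL
);

CREATE TABLE IF NOT EXISTS test_item (
    test       TEXT NOT NULL REFERENCES test(name),
    procedure  TEXT NOT NULL REFERENCES procedure_catalog(name),
    exec_order INTEGER NOT NULL CHECK (exec_order >= 1),
    PRIMARY KEY (test, procedure)
);

CREATE TABLE IF NOT EXISTS patient (
    number INTEGER PRIMARY KEY,
    name   TEXT NOT NULL
);

CREATE TABLE IF NOT EXISTS sample (
    dna_number TEXT PRIMARY KEY,
    patient    INTEGER NOT NULL REFERENCES patient(number)
);

CREATE TABLE IF NOT EXISTS test_order (
    id           INTEGER PRIMARY KEY,
    sample       TEXT NOT NULL REFERENCES sample(dna_number),
    test         TEXT NOT NULL REFERENCES test(name),
    request_date TEXT NOT NULL
);

CREATE TABLE IF NOT EXISTS instance (
    id                 TEXT PRIMARY KEY,
    order_id           INTEGER REFERENCES test_order(id),
    definition_name    TEXT NOT NULL,
    definition_version INTEGER NOT NULL,
    residual_npdl      TEXT NOT NULL,
    lifecycle          TEXT NOT NULL
);

CREATE TABLE IF NOT EXISTS event (
    instance  TEXT NOT NULL REFERENCES instance(id),
    seq       INTEGER NOT NULL,
    action    TEXT NOT NULL,
    status    TEXT NOT NULL,
    outcome   TEXT NOT NULL DEFAULT '',
    timestamp TEXT NOT NULL,
    path      TEXT NOT NULL DEFAULT '',
    PRIMARY KEY (instance, seq)
);
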