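"""Metadata store: records, manifests, subscriptions, messages, triples."""

import random

import pytest

from tcgasync.metadata import (
    ChangeMessage,
    FileMetadataRecord,
    ManifestQuery,
    MetadataError,
    MetadataStore,
)

DISEASES = ["BRCA", "GBM", "OV"]
DATATYPES = ["Somatic_Mutations", "RNASeqV2", "DNA_Methylation"]
LEVELS = ["1", "2", "3"]
CENTERS = ["broad_mit_edu", "unc_edu"]


def make_record(i, rng=None, **overrides):
    rng = rng or random.Random(i)
    base = dict(
        logical_id=f"lid-{i}",
        repo_version=1,
        status="current",
        barcode=f"TCGA-A1-{i:04d}-01A-11D-A141-01",
        access=rng.choice(["public", "controlled"]),
        disease=rng.choice(DISEASES),
        center_code="01",
        center_name=rng.choice(CENTERS),
        platform="IlluminaGA_DNASeq",
        level=rng.choice(LEVELS),
        experiment_id=f"exp{i}",
        analysis_revision=1,
        tcga_revision=1,
        datatype=rng.choice(DATATYPES),
        extension="txt",
        md5=f"md5-{i}",
        local_path=f"BRCA/p/s/d/L/f{i}.txt",
        ingest_ts=f"2015-01-01T00:{i % 60:02d}:00",
    )
    base.update(overrides)
    return FileMetadataRecord(**base)


@pytest.fixture
def store():
    return MetadataStore()


def test_upserted_record_is_retrievable_with_descriptions(store):
    store.upsert_record(make_record(1, disease="BRCA"))
    rec = store.get_record("lid-1", 1)
    assert rec is not None
    assert rec.disease_desc == "Breast invasive carcinoma"
    assert rec.tss_desc == "Albert Einstein Medical Center"
    assert rec.sample_type_desc == "Primary Solid Tumor"
    assert rec.analyte_desc == "DNA"


def test_double_upsert_keeps_one_record(store):
    store.upsert_record(make_record(1))
    store.upsert_record(make_record(1))
    assert len(store.all_records()) == 1


def test_unknown_vocabulary_code_is_an_error_naming_table_and_code(store):
    with pytest.raises(KeyError, match="disease_study.*XXXX"):
        store.upsert_record(make_record(1, disease="XXXX"))


def test_empty_query_returns_all_current_records(store):
    for i in range(5):
        store.upsert_record(make_record(i))
    store.upsert_record(make_record(99, status="archived"))
    assert len(store.query_manifest(ManifestQuery())) == 5


def test_query_matching_nothing_is_empty_not_an_error(store):
    store.upsert_record(make_record(1, disease="BRCA"))
    assert store.query_manifest(ManifestQuery(disease="OV")) == []


def test_malformed_date_range_is_an_error():
    with pytest.raises(MetadataError, match="date_from"):
        ManifestQuery(date_from="not-a-date")
    with pytest.raises(MetadataError, match="range"):
        ManifestQuery(date_from="2015-02-01", date_to="2015-01-01")


def brute_force_scan(records, q: ManifestQuery):
    out = [r for r in records if r.status == "current" and q.matches(r)]
    return sorted(out, key=lambda r: (r.logical_id, r.repo_version))


def test_randomized_queries_agree_with_linear_scan(store):
    rng = random.Random(42)
    records = [make_record(i, rng=rng) for i in range(60)]
    for r in records:
        store.upsert_record(r)
    stored = store.all_records()
    for _ in range(40):
        q = ManifestQuery(
            disease=rng.choice([None] + DISEASES),
            datatype=rng.choice([None] + DATATYPES),
            level=rng.choice([None] + LEVELS),
            center=rng.choice([None] + CENTERS),
            access=rng.choice([None, "public", "controlled"]),
            barcode_prefix=rng.choice([None, "TCGA-A1-00", "TCGA-A1-0001"]),
            date_from=rng.choice([None, "2015-01-01T00:10:00"]),
            date_to=rng.choice([None, "2015-01-01T00:40:00"]),
        )
        got = [(r.logical_id, r.repo_version) for r in store.query_manifest(q)]
        want = [(r.logical_id, r.repo_version) for r in brute_force_scan(stored, q)]
        assert got == want, q


def test_duplicate_subscription_is_idempotent_and_unsubscribe_removes_one(store):
    q = ManifestQuery(disease="BRCA")
    store.subscribe("alice", q)
    store.subscribe("alice", q)
    assert len(store.subscriptions()) == 1
    assert store.unsubscribe("alice", q) == 1
    assert store.subscriptions() == []
    assert store.unsubscribe("alice", q) == 0


def test_empty_filter_subscription_matches_every_change(store):
    store.subscribe("bob", ManifestQuery())
    changes = [("added", make_record(i)) for i in range(3)]
    events = store.emit_notifications(changes, "run-1")
    assert len(events) == 3
    assert {e.subscriber for e in events} == {"bob"}


def test_no_subscriptions_no_events(store):
    assert store.emit_notifications([("added", make_record(1))], "r") == []


def test_subscription_filter_selects_matching_changes_only(store):
    store.subscribe("alice", ManifestQuery(disease="BRCA"))
    changes = [
        ("added", make_record(1, disease="BRCA")),
        ("modified", make_record(2, disease="BRCA")),
        ("deleted", make_record(3, disease="GBM")),
    ]
    events = store.emit_notifications(changes, "run-2")
    assert len(events) == 2
    assert {e.change for e in events} == {"added", "modified"}


def test_event_count_is_sum_over_subscriptions_of_matching_changes(store):
    rng = random.Random(9)
    store.subscribe("a", ManifestQuery(disease="BRCA"))
    store.subscribe("b", ManifestQuery(datatype="RNASeqV2"))
    store.subscribe("c", ManifestQuery())
    changes = [(rng.choice(["added", "modified", "deleted"]), make_record(i, rng=rng))
               for i in range(20)]
    events = store.emit_notifications(changes, "run-3")
    expected = sum(
        1
        for sub in store.subscriptions()
        for _, rec in changes
        if sub.query.matches(rec)
    )
    assert len(events) == expected
    assert len(set(events)) == len(events)  # no duplicates


def test_change_messages_count_and_lossless_round_trip(store):
    assert store.build_change_messages("r", []) == []
    changes = [
        ("added", make_record(1)),
        ("added", make_record(2)),
        ("modified", make_record(3)),
        ("deleted", make_record(4)),
    ]
    msgs = store.build_change_messages("run-9", changes)
    assert len(msgs) == 4
    text = store.serialize_messages(msgs)
    assert store.parse_messages(text) == msgs


def test_change_message_schema_rejects_unknown_action():
    with pytest.raises(ValueError, match="unknown action"):
        ChangeMessage(run_id="r", action="renamed", logical_id="x", repo_version=1,
                      local_path="p", md5="m", timestamp="t")


def test_empty_store_exports_empty_triple_dump(store):
    assert store.export_triples().strip() == ""


def test_triple_count_is_records_times_populated_fields(store):
    for i in range(4):
        store.upsert_record(make_record(i))
    dump = store.export_triples()
    lines = [l for l in dump.splitlines() if l.strip()]
    assert len(lines) == store.triple_count()


def test_triple_reimport_reproduces_manifest_results(store):
    for i in range(10):
        store.upsert_record(make_record(i))
    rebuilt = MetadataStore.import_triples(store.export_triples())
    for q in (ManifestQuery(), ManifestQuery(disease="BRCA"), ManifestQuery(level="2")):
        a = [(r.logical_id, r.repo_version, r.md5) for r in store.query_manifest(q)]
        b = [(r.logical_id, r.repo_version, r.md5) for r in rebuilt.query_manifest(q)]
        assert a == b
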