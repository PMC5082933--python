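"""Provenance metadata store: records, vocabularies, manifests,
subscriptions, notifications, change messages and a triple export.

One embedded relational store (SQLite) is the system of record; the
RDF form is an export.  Each file-metadata record is keyed by
(logical id, repository version) and carries the full naming metadata,
description fields materialized from the controlled vocabularies,
reference-genome and algorithm annotations, and pointers to both the
local and the original file.

Notifications are *events*, not emails: a sync run matches its change
set against stored subscriptions and appends matching events to an
outbox.  Metadata-only serial bumps (content unchanged at the source)
emit nothing — "meaningful difference" means the checksum changed.

Change messages are JSON documents (schema enforced with pydantic) so
downstream loaders can consume each sync's additions, modifications
and deletions without touching the store.
"""

from __future__ import annotations

import json
import sqlite3
from dataclasses import dataclass, field, fields as dc_fields, asdict
from datetime import datetime
from pathlib import Path
from typing import Dict, Iterable, List, Optional
from urllib.parse import quote

from pydantic import BaseModel, field_validator
from rdflib import Graph, Literal, URIRef

from .vocab import Vocabulary

ADDED, MODIFIED, DELETED = "added", "modified", "deleted"

_NS_FILE = "urn:x-tcgarepo:file:"
_NS_FIELD = "urn:x-tcgarepo:field:"


class MetadataError(ValueError):
    pass


@dataclass
class FileMetadataRecord:
    """Full provenance for one (logical id, repository version)."""

    logical_id: str
    repo_version: int
    status: str
    barcode: str
    access: str
    disease: str
    center_code: Optional[str]
    center_name: str
    platform: str
    level: str
    experiment_id: str
    analysis_revision: int
    tcga_revision: int
    datatype: str
    extension: str
    md5: str
    local_path: str
    ingest_ts: str
    ref_genome: Optional[str] = None
    ref_genome_source: Optional[str] = None
    algorithm_name: Optional[str] = None
    algorithm_version: Optional[str] = None
    portion_name: Optional[str] = None
    portion_number: int = 1
    disease_desc: Optional[str] = None
    tss_desc: Optional[str] = None
    center_desc: Optional[str] = None
    sample_type_desc: Optional[str] = None
    analyte_desc: Optional[str] = None
    archive_name: Optional[str] = None
    archive_serial: Optional[int] = None
    source_md5: Optional[str] = None
    original_path: Optional[str] = None
    original_name: Optional[str] = None

    def to_dict(self) -> dict:
        return asdict(self)


_FIELD_NAMES = [f.name for f in dc_fields(FileMetadataRecord)]
_INT_FIELDS = {
    f.name
    for f in dc_fields(FileMetadataRecord)
    if f.type in ("int", "Optional[int]")
}


@dataclass(frozen=True)
class ManifestQuery:
    """Conjunctive filters; an absent filter matches everything."""

    disease: Optional[str] = None
    datatype: Optional[str] = None
    level: Optional[str] = None
    platform: Optional[str] = None
    center: Optional[str] = None
    access: Optional[str] = None
    barcode_prefix: Optional[str] = None
    date_from: Optional[str] = None
    date_to: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("date_from", "date_to"):
            value = getattr(self, name)
            if value is not None:
                try:
                    datetime.fromisoformat(value)
                except ValueError:
                    raise MetadataError(f"malformed {name}: {value!r}") from None
        if self.date_from and self.date_to and self.date_from > self.date_to:
            raise MetadataError("malformed date range: date_from > date_to")

    def matches(self, rec: FileMetadataRecord) -> bool:
        if self.disease is not None and rec.disease != self.disease:
            return False
        if self.datatype is not None and rec.datatype != self.datatype:
            return False
        if self.level is not None and rec.level != self.level:
            return False
        if self.platform is not None and rec.platform != self.platform:
            return False
        if self.center is not None and rec.center_name != self.center:
            return False
        if self.access is not None and rec.access != self.access:
            return False
        if self.barcode_prefix is not None and not rec.barcode.startswith(self.barcode_prefix):
            return False
        if self.date_from is not None and rec.ingest_ts < self.date_from:
            return False
        if self.date_to is not None and rec.ingest_ts > self.date_to:
            return False
        return True

    def to_json(self) -> str:
        return json.dumps(
            {k: v for k, v in asdict(self).items() if v is not None}, sort_keys=True
        )

    @classmethod
    def from_json(cls, text: str) -> "ManifestQuery":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class Subscription:
    subscriber: str
    query: ManifestQuery
    created: str


@dataclass(frozen=True)
class NotificationEvent:
    subscriber: str
    change: str  # added | modified | deleted
    logical_id: str
    repo_version: int
    run_id: str


class ChangeMessage(BaseModel):
    """One JSON change message for downstream loaders."""

    run_id: str
    action: str
    logical_id: str
    repo_version: int
    local_path: str
    md5: str
    timestamp: str

    @field_validator("action")
    @classmethod
    def _action_known(cls, v: str) -> str:
        if v not in (ADDED, MODIFIED, DELETED):
            raise ValueError(f"unknown action {v!r}")
        return v


class MetadataStore:
    """SQLite-backed provenance store with an N-Triples export."""

    def __init__(self, path: "Path | str" = ":memory:", vocabulary: Optional[Vocabulary] = None):
        self.path = str(path)
        self._db = sqlite3.connect(self.path)
        self.vocabulary = vocabulary or Vocabulary.load_default()
        self._db.executescript(
            f"""
            CREATE TABLE IF NOT EXISTS file_metadata (
                {", ".join(f'"{n}"' for n in _FIELD_NAMES)},
                PRIMARY KEY (logical_id, repo_version)
            );
            CREATE TABLE IF NOT EXISTS subscriptions (
                subscriber TEXT NOT NULL,
                query_json TEXT NOT NULL,
                created TEXT NOT NULL,
                UNIQUE (subscriber, query_json)
            );
            CREATE TABLE IF NOT EXISTS sync_state (
                store TEXT PRIMARY KEY,
                serial INTEGER,
                last_date TEXT
            );
            CREATE TABLE IF NOT EXISTS meta (key TEXT PRIMARY KEY, value TEXT);
            """
        )
        self._db.commit()

    def close(self) -> None:
        self._db.close()

    # -- records ----------------------------------------------------------

    def _materialize_descriptions(self, rec: FileMetadataRecord) -> None:
        from .barcode import parse_barcode

        v = self.vocabulary
        rec.disease_desc = v.resolve("disease_study", rec.disease)
        b = parse_barcode(rec.barcode)
        rec.tss_desc = v.resolve("tissue_source_site", b.tss)
        if rec.center_code is not None:
            rec.center_desc = v.resolve("center", rec.center_code)
        if b.sample_type is not None:
            rec.sample_type_desc = v.resolve("sample_type", b.sample_type)
        if b.analyte is not None:
            rec.analyte_desc = v.resolve("portion_analyte", b.analyte)

    def upsert_record(self, rec: FileMetadataRecord) -> FileMetadataRecord:
        """Insert or replace by (logical id, version); resolves vocabularies."""
        self._materialize_descriptions(rec)
        values = [getattr(rec, n) for n in _FIELD_NAMES]
        placeholders = ", ".join("?" for _ in _FIELD_NAMES)
        self._db.execute(
            f"INSERT OR REPLACE INTO file_metadata VALUES ({placeholders})", values
        )
        self._db.commit()
        return rec

    def get_record(self, logical_id: str, repo_version: int) -> Optional[FileMetadataRecord]:
        row = self._db.execute(
            "SELECT * FROM file_metadata WHERE logical_id=? AND repo_version=?",
            (logical_id, repo_version),
        ).fetchone()
        return self._row_to_record(row) if row else None

    def _row_to_record(self, row: tuple) -> FileMetadataRecord:
        data = dict(zip(_FIELD_NAMES, row))
        return FileMetadataRecord(**data)

    def all_records(self) -> List[FileMetadataRecord]:
        rows = self._db.execute(
            "SELECT * FROM file_metadata ORDER BY logical_id, repo_version"
        ).fetchall()
        return [self._row_to_record(r) for r in rows]

    def set_status(self, logical_id: str, repo_version: int, status: str) -> None:
        self._db.execute(
            "UPDATE file_metadata SET status=? WHERE logical_id=? AND repo_version=?",
            (status, logical_id, repo_version),
        )
        self._db.commit()

    # -- sync bookkeeping --------------------------------------------------

    def get_sync_state(self, store: str) -> tuple[Optional[int], Optional[str]]:
        row = self._db.execute(
            "SELECT serial, last_date FROM sync_state WHERE store=?", (store,)
        ).fetchone()
        return (row[0], row[1]) if row else (None, None)

    def set_sync_state(self, store: str, serial: Optional[int], last_date: Optional[str]) -> None:
        self._db.execute(
            "INSERT INTO sync_state (store, serial, last_date) VALUES (?,?,?) "
            "ON CONFLICT(store) DO UPDATE SET serial=excluded.serial, last_date=excluded.last_date",
            (store, serial, last_date),
        )
        self._db.commit()

    def next_run_id(self) -> str:
        row = self._db.execute("SELECT value FROM meta WHERE key='run_counter'").fetchone()
        n = int(row[0]) + 1 if row else 1
        self._db.execute(
            "INSERT INTO meta (key, value) VALUES ('run_counter', ?) "
            "ON CONFLICT(key) DO UPDATE SET value=excluded.value",
            (str(n),),
        )
        self._db.commit()
        return f"sync-{n:04d}"

    def current_paths(self) -> Dict[str, tuple[str, str]]:
        """original remote path -> (logical_id, source_md5) for current records."""
        rows = self._db.execute(
            "SELECT original_path, logical_id, source_md5 FROM file_metadata "
            "WHERE status='current' AND original_path IS NOT NULL"
        ).fetchall()
        return {r[0]: (r[1], r[2]) for r in rows}

    # -- manifest ----------------------------------------------------------

    def query_manifest(self, q: ManifestQuery) -> List[FileMetadataRecord]:
        """Current records satisfying all filters, ordered by (id, version)."""
        clauses, params = ["status = 'current'"], []
        for column, value in (
            ("disease", q.disease),
            ("datatype", q.datatype),
            ("level", q.level),
            ("platform", q.platform),
            ("center_name", q.center),
            ("access", q.access),
        ):
            if value is not None:
                clauses.append(f'"{column}" = ?')
                params.append(value)
        if q.barcode_prefix is not None:
            clauses.append("substr(barcode, 1, ?) = ?")
            params.extend([len(q.barcode_prefix), q.barcode_prefix])
        if q.date_from is not None:
            clauses.append("ingest_ts >= ?")
            params.append(q.date_from)
        if q.date_to is not None:
            clauses.append("ingest_ts <= ?")
            params.append(q.date_to)
        sql = (
            "SELECT * FROM file_metadata WHERE "
            + " AND ".join(clauses)
            + " ORDER BY logical_id, repo_version"
        )
        rows = self._db.execute(sql, params).fetchall()
        return [self._row_to_record(r) for r in rows]

    def write_manifest(self, path: "Path | str", records: Iterable[FileMetadataRecord]) -> None:
        lines = ["logical_id\tversion\tlocal_path\tmd5\tdisease\tdatatype\tlevel"]
        for r in records:
            lines.append(
                f"{r.logical_id}\t{r.repo_version}\t{r.local_path}\t{r.md5}\t"
                f"{r.disease}\t{r.datatype}\t{r.level}"
            )
        Path(path).write_text("\n".join(lines) + "\n")

    # -- subscriptions & notifications ------------------------------------

    def subscribe(self, subscriber: str, query: ManifestQuery, created: str = "") -> Subscription:
        if not subscriber:
            raise MetadataError("subscriber id must be non-empty")
        self._db.execute(
            "INSERT OR IGNORE INTO subscriptions (subscriber, query_json, created) VALUES (?,?,?)",
            (subscriber, query.to_json(), created),
        )
        self._db.commit()
        return Subscription(subscriber, query, created)

    def unsubscribe(self, subscriber: str, query: ManifestQuery) -> int:
        cur = self._db.execute(
            "DELETE FROM subscriptions WHERE subscriber=? AND query_json=?",
            (subscriber, query.to_json()),
        )
        self._db.commit()
        return cur.rowcount

    def subscriptions(self) -> List[Subscription]:
        rows = self._db.execute(
            "SELECT subscriber, query_json, created FROM subscriptions "
            "ORDER BY subscriber, query_json"
        ).fetchall()
        return [Subscription(r[0], ManifestQuery.from_json(r[1]), r[2]) for r in rows]

    def emit_notifications(
        self,
        changes: List[tuple[str, FileMetadataRecord]],
        run_id: str,
        outbox: "Path | str | None" = None,
    ) -> List[NotificationEvent]:
        """One event per (matching subscription x change).

        ``changes`` carries (action, record) pairs for content changes
        only — metadata-only serial bumps must not be passed in.
        """
        events: List[NotificationEvent] = []
        for sub in self.subscriptions():
            for action, rec in changes:
                if action not in (ADDED, MODIFIED, DELETED):
                    raise MetadataError(f"unknown change kind {action!r}")
                if sub.query.matches(rec):
                    events.append(
                        NotificationEvent(
                            subscriber=sub.subscriber,
                            change=action,
                            logical_id=rec.logical_id,
                            repo_version=rec.repo_version,
                            run_id=run_id,
                        )
                    )
        if outbox is not None and events:
            with open(outbox, "a", encoding="utf-8") as fh:
                for ev in events:
                    fh.write(json.dumps(asdict(ev), sort_keys=True) + "\n")
        return events

    # -- change messages ---------------------------------------------------

    @staticmethod
    def build_change_messages(
        run_id: str, changes: List[tuple[str, FileMetadataRecord]]
    ) -> List[ChangeMessage]:
        """One schema-validated JSON message per add/modify/delete."""
        return [
            ChangeMessage(
                run_id=run_id,
                action=action,
                logical_id=rec.logical_id,
                repo_version=rec.repo_version,
                local_path=rec.local_path,
                md5=rec.md5,
                timestamp=rec.ingest_ts,
            )
            for action, rec in changes
        ]

    @staticmethod
    def serialize_messages(messages: List[ChangeMessage]) -> str:
        return json.dumps([m.model_dump() for m in messages], indent=1, sort_keys=True)

    @staticmethod
    def parse_messages(text: str) -> List[ChangeMessage]:
        return [ChangeMessage.model_validate(obj) for obj in json.loads(text)]

    # -- triples -----------------------------------------------------------

    def export_triples(self) -> str:
        """N-Triples dump: subject = file id, predicate = field, object = value."""
        g = Graph()
        for rec in self.all_records():
            subject = URIRef(f"{_NS_FILE}{quote(rec.logical_id, safe='')}:{rec.repo_version}")
            for name in _FIELD_NAMES:
                value = getattr(rec, name)
                if value is None:
                    continue
                g.add((subject, URIRef(_NS_FIELD + name), Literal(value)))
        return g.serialize(format="nt")

    @classmethod
    def import_triples(cls, nt_text: str, vocabulary: Optional[Vocabulary] = None) -> "MetadataStore":
        """Rebuild a store from an N-Triples dump (round-trip inverse)."""
        g = Graph()
        g.parse(data=nt_text, format="nt")
        by_subject: Dict[str, dict] = {}
        for s, p, o in g:
            field_name = str(p)[len(_NS_FIELD):]
            if field_name not in _FIELD_NAMES:
                raise MetadataError(f"unknown predicate in triple dump: {p}")
            values = by_subject.setdefault(str(s), {})
            value = o.toPython()
            if field_name in _INT_FIELDS:
                value = int(value)
            values[field_name] = value
        store = cls(vocabulary=vocabulary)
        for values in by_subject.values():
            store.upsert_record(FileMetadataRecord(**values))
        return store

    def triple_count(self) -> int:
        return sum(
            1
            for rec in self.all_records()
            for name in _FIELD_NAMES
            if getattr(rec, name) is not None
        )
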