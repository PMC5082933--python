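"""Versioned, participant/sample-oriented local file store.

Each logical file (the identity under which successive content
revisions version: datatype, barcode, level, experiment id, portion
name, portion number) holds versions ``1..k`` with no gaps and at most
one *current* version.  Ingesting changed content archives the previous
version under a parallel ``archive/`` subtree and bumps the version;
re-ingesting identical content only refreshes provenance (the source
archive serial), exactly as a serial bump without a content change
should.  Removal is policy-driven: ``archive`` retains the bytes under
``archive/``, ``delete`` removes them and leaves a tombstone record.

The catalog is an embedded SQLite database inside the repository root.
Every state change is timestamped by an injectable clock (strictly
monotonized), which is what makes ``snapshot(as_of)`` — the
date-freeze/provenance query — deterministic and testable.
"""

from __future__ import annotations

import hashlib
import json
import shutil
import sqlite3
from dataclasses import dataclass, asdict
from datetime import datetime, timedelta
from pathlib import Path
from typing import Callable, List, Optional

from .naming import FileNameFields, build_directory_path, build_file_name

CURRENT, ARCHIVED, DELETED = "current", "archived", "deleted"
ARCHIVE_POLICY, DELETE_POLICY = "archive", "delete"

CATALOG_NAME = "catalog.db"
ARCHIVE_DIR = "archive"


class RepositoryError(ValueError):
    pass


@dataclass(frozen=True)
class Provenance:
    """Where a stored file came from."""

    archive_name: str
    serial: Optional[int]
    original_name: str
    original_location: str
    source_md5: Optional[str] = None


@dataclass(frozen=True)
class StoredFile:
    """One versioned repository entry."""

    logical_id: str
    repo_version: int
    status: str
    local_path: str  # relative to the repository root
    md5: str
    source_md5: Optional[str]
    ingest_timestamp: str
    provenance: Provenance
    fields: Optional[FileNameFields] = None


def logical_id_for(fields: FileNameFields) -> str:
    return "|".join(str(part) for part in fields.logical_key)


_SCHEMA = """
CREATE TABLE IF NOT EXISTS stored_files (
    logical_id   TEXT NOT NULL,
    repo_version INTEGER NOT NULL,
    status       TEXT NOT NULL,
    local_path   TEXT NOT NULL,
    md5          TEXT NOT NULL,
    source_md5   TEXT,
    ingest_ts    TEXT NOT NULL,
    superseded_ts TEXT,
    removed_ts   TEXT,
    archive_name TEXT,
    serial       INTEGER,
    original_name TEXT,
    original_location TEXT,
    fields_json  TEXT,
    naming       TEXT NOT NULL,
    PRIMARY KEY (logical_id, repo_version)
);
CREATE TABLE IF NOT EXISTS repo_meta (key TEXT PRIMARY KEY, value TEXT);
"""


def _fields_to_json(fields: Optional[FileNameFields]) -> Optional[str]:
    if fields is None:
        return None
    d = asdict(fields)
    d["barcode"] = fields.barcode.render()
    return json.dumps(d, sort_keys=True)


def _fields_from_json(text: Optional[str]) -> Optional[FileNameFields]:
    if not text:
        return None
    from .barcode import parse_barcode

    d = json.loads(text)
    d["barcode"] = parse_barcode(d["barcode"])
    return FileNameFields(**d)


class Repository:
    """The versioned local file store rooted at a directory."""

    #: file-naming policies for ingested files
    GRAMMAR = "grammar"  # repository naming grammar (DCC datatypes)
    ORIGINAL = "original"  # keep the original (or date-prefixed) name

    def __init__(self, root: "Path | str", clock: Optional[Callable[[], datetime]] = None):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)
        self._clock = clock or datetime.now
        self._db = sqlite3.connect(self.root / CATALOG_NAME)
        self._db.executescript(_SCHEMA)
        self._db.commit()

    def close(self) -> None:
        self._db.close()

    # -- time -------------------------------------------------------------

    def _now(self) -> str:
        """Strictly monotone event timestamp (ties bumped by 1 microsecond)."""
        now = self._clock().isoformat()
        row = self._db.execute(
            "SELECT value FROM repo_meta WHERE key='last_ts'"
        ).fetchone()
        if row and now <= row[0]:
            now = (datetime.fromisoformat(row[0]) + timedelta(microseconds=1)).isoformat()
        self._db.execute(
            "INSERT INTO repo_meta (key, value) VALUES ('last_ts', ?) "
            "ON CONFLICT(key) DO UPDATE SET value=excluded.value",
            (now,),
        )
        return now

    # -- row mapping ------------------------------------------------------

    _COLS = (
        "logical_id, repo_version, status, local_path, md5, source_md5, ingest_ts, "
        "superseded_ts, removed_ts, archive_name, serial, original_name, "
        "original_location, fields_json, naming"
    )

    def _to_stored(self, row: tuple) -> StoredFile:
        return StoredFile(
            logical_id=row[0],
            repo_version=row[1],
            status=row[2],
            local_path=row[3],
            md5=row[4],
            source_md5=row[5],
            ingest_timestamp=row[6],
            provenance=Provenance(
                archive_name=row[9],
                serial=row[10],
                original_name=row[11],
                original_location=row[12],
                source_md5=row[5],
            ),
            fields=_fields_from_json(row[13]),
        )

    # -- ingest -----------------------------------------------------------

    def _target_name(self, fields: FileNameFields, naming: str, original_name: str, version: int) -> str:
        if naming == self.GRAMMAR:
            return build_file_name(fields.with_version(version))
        return original_name

    def _archive_path(self, rel_path: str, version: int, naming: str) -> str:
        if naming == self.GRAMMAR:
            return str(Path(ARCHIVE_DIR) / rel_path)  # version is in the name
        return str(Path(ARCHIVE_DIR) / f"{rel_path}.v{version}")

    def ingest_file(
        self,
        staged: "Path | str",
        fields: FileNameFields,
        provenance: Provenance,
        naming: str = "grammar",
    ) -> StoredFile:
        """Move a verified staged file into the store, versioning as needed.

        New logical id -> version 1.  Same id with changed content ->
        previous version archived, new current at version+1.  Same id
        with identical content -> provenance refresh only (no new
        version).  The staged file's checksum must match the
        provenance's source checksum when one is given upstream of
        harmonization-free datatypes; the caller stages only verified
        bytes, so here the guard is existence + readability.
        """
        staged = Path(staged)
        if not staged.exists():
            raise RepositoryError(f"staged file missing: {staged}")
        if naming not in (self.GRAMMAR, self.ORIGINAL):
            raise RepositoryError(f"unknown naming policy: {naming!r}")
        data = staged.read_bytes()
        digest = hashlib.md5(data).hexdigest()
        logical_id = logical_id_for(fields)

        cur = self._db.execute(
            f"SELECT {self._COLS} FROM stored_files WHERE logical_id=? AND status=?",
            (logical_id, CURRENT),
        ).fetchone()

        if cur is not None and cur[4] == digest:
            # unchanged content: refresh the referenced archive serial only
            self._db.execute(
                "UPDATE stored_files SET archive_name=?, serial=?, original_location=? "
                "WHERE logical_id=? AND repo_version=?",
                (
                    provenance.archive_name,
                    provenance.serial,
                    provenance.original_location,
                    logical_id,
                    cur[1],
                ),
            )
            self._db.commit()
            return self.get(logical_id, cur[1])

        max_row = self._db.execute(
            "SELECT MAX(repo_version) FROM stored_files WHERE logical_id=?", (logical_id,)
        ).fetchone()
        version = (max_row[0] or 0) + 1

        ts = self._now()
        if cur is not None:
            # supersede at the same instant the replacement lands, so no
            # snapshot time sees zero current versions for this id
            self._supersede(cur, when=ts)

        rel_dir = build_directory_path(fields).relative
        name = self._target_name(fields, naming, provenance.original_name, version)
        rel_path = str(Path(rel_dir) / name)
        target = self.root / rel_path
        target.parent.mkdir(parents=True, exist_ok=True)
        tmp = target.with_name(target.name + ".part")
        tmp.write_bytes(data)
        tmp.replace(target)  # atomic move: no half-written current files
        staged.unlink()
        self._db.execute(
            "INSERT INTO stored_files VALUES (?,?,?,?,?,?,?,?,?,?,?,?,?,?,?)",
            (
                logical_id,
                version,
                CURRENT,
                rel_path,
                digest,
                provenance.source_md5,
                ts,
                None,
                None,
                provenance.archive_name,
                provenance.serial,
                provenance.original_name,
                provenance.original_location,
                _fields_to_json(fields.with_version(version)),
                naming,
            ),
        )
        self._db.commit()
        return self.get(logical_id, version)

    def _supersede(self, cur_row: tuple, when: Optional[str]) -> None:
        """Archive the current version (bytes move under ``archive/``)."""
        logical_id, version, rel_path, naming = cur_row[0], cur_row[1], cur_row[3], cur_row[14]
        archived_rel = self._archive_path(rel_path, version, naming)
        src, dst = self.root / rel_path, self.root / archived_rel
        dst.parent.mkdir(parents=True, exist_ok=True)
        shutil.move(src, dst)
        ts = when or self._now()
        self._db.execute(
            "UPDATE stored_files SET status=?, superseded_ts=?, local_path=? "
            "WHERE logical_id=? AND repo_version=?",
            (ARCHIVED, ts, archived_rel, logical_id, version),
        )

    # -- removal ----------------------------------------------------------

    def remove_file(self, logical_id: str, policy: str = ARCHIVE_POLICY) -> StoredFile:
        """Remove the current version per policy (archive bytes, or delete)."""
        if policy not in (ARCHIVE_POLICY, DELETE_POLICY):
            raise RepositoryError(f"unknown delete policy: {policy!r}")
        cur = self._db.execute(
            f"SELECT {self._COLS} FROM stored_files WHERE logical_id=? AND status=?",
            (logical_id, CURRENT),
        ).fetchone()
        if cur is None:
            raise RepositoryError(f"no current version for logical id {logical_id!r}")
        version, rel_path, naming = cur[1], cur[3], cur[14]
        ts = self._now()
        if policy == ARCHIVE_POLICY:
            archived_rel = self._archive_path(rel_path, version, naming)
            dst = self.root / archived_rel
            dst.parent.mkdir(parents=True, exist_ok=True)
            shutil.move(self.root / rel_path, dst)
            new_path = archived_rel
        else:
            (self.root / rel_path).unlink()
            new_path = rel_path  # tombstone keeps the last known location
        self._db.execute(
            "UPDATE stored_files SET status=?, removed_ts=?, local_path=? "
            "WHERE logical_id=? AND repo_version=?",
            (DELETED, ts, new_path, logical_id, version),
        )
        self._db.commit()
        return self.get(logical_id, version)

    # -- queries ----------------------------------------------------------

    def get(self, logical_id: str, version: int) -> StoredFile:
        row = self._db.execute(
            f"SELECT {self._COLS} FROM stored_files WHERE logical_id=? AND repo_version=?",
            (logical_id, version),
        ).fetchone()
        if row is None:
            raise RepositoryError(f"no such stored file: {logical_id!r} v{version}")
        return self._to_stored(row)

    def versions(self, logical_id: str) -> List[StoredFile]:
        rows = self._db.execute(
            f"SELECT {self._COLS} FROM stored_files WHERE logical_id=? ORDER BY repo_version",
            (logical_id,),
        ).fetchall()
        return [self._to_stored(r) for r in rows]

    def current_version_by_fields(self, fields: FileNameFields) -> Optional[StoredFile]:
        return self.current_version(logical_id_for(fields))

    def current_version(self, logical_id: str) -> Optional[StoredFile]:
        row = self._db.execute(
            f"SELECT {self._COLS} FROM stored_files WHERE logical_id=? AND status=?",
            (logical_id, CURRENT),
        ).fetchone()
        return self._to_stored(row) if row else None

    def get_current(self, where: Optional[Callable[[StoredFile], bool]] = None) -> List[StoredFile]:
        rows = self._db.execute(
            f"SELECT {self._COLS} FROM stored_files WHERE status=? "
            "ORDER BY logical_id, repo_version",
            (CURRENT,),
        ).fetchall()
        out = [self._to_stored(r) for r in rows]
        if where is not None:
            out = [s for s in out if where(s)]
        return out

    def snapshot(self, as_of: "datetime | str") -> List[tuple[str, int, str]]:
        """Manifest of (logical_id, repo_version, local_path) as of an instant.

        A version is in the snapshot iff it was ingested at or before
        ``as_of`` and neither superseded nor removed by then.
        """
        if isinstance(as_of, datetime):
            as_of = as_of.isoformat()
        rows = self._db.execute(
            f"SELECT logical_id, repo_version, local_path FROM stored_files "
            "WHERE ingest_ts <= ? "
            "AND (superseded_ts IS NULL OR superseded_ts > ?) "
            "AND (removed_ts IS NULL OR removed_ts > ?) "
            "ORDER BY logical_id, repo_version",
            (as_of, as_of, as_of),
        ).fetchall()
        return [(r[0], r[1], r[2]) for r in rows]

    def write_manifest(self, path: "Path | str", entries: Optional[List[StoredFile]] = None) -> None:
        """Tab-delimited manifest: logical_id, version, path, md5."""
        entries = entries if entries is not None else self.get_current()
        lines = ["logical_id\tversion\tpath\tmd5"]
        lines += [f"{s.logical_id}\t{s.repo_version}\t{s.local_path}\t{s.md5}" for s in entries]
        Path(path).write_text("\n".join(lines) + "\n")
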