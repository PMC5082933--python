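"""Versioned store: ingest semantics, archival, snapshots, immutability."""

import hashlib
import random

import pytest

from tcgasync.barcode import parse_barcode
from tcgasync.naming import FileNameFields
from tcgasync.repository import Provenance, Repository, RepositoryError, logical_id_for

from conftest import TickingClock


def fields(participant="A0SB", portion_number=1, platform="IlluminaGA_DNASeq", level="2"):
    return FileNameFields(
        barcode=parse_barcode(f"TCGA-A1-{participant}-01A-11D-A141-01"),
        access="public",
        disease="BRCA",
        center_name="broad_mit_edu",
        platform=platform,
        level=level,
        experiment_id="exp1",
        analysis_revision=1,
        tcga_revision=1,
        portion_number=portion_number,
        extension="maf",
    )


def stage(tmp_path, content: bytes, name="staged.bin"):
    p = tmp_path / name
    p.write_bytes(content)
    return p


def test_first_ingest_is_version_one_current(make_repo, tmp_path):
    repo = make_repo()
    s = repo.ingest_file(stage(tmp_path, b"v1"), fields(),
                         Provenance("arch", 1, "orig.maf", "dcc/a/orig.maf", "m"))
    assert (s.repo_version, s.status) == (1, "current")
    assert (repo.root / s.local_path).read_bytes() == b"v1"
    assert s.local_path.startswith("BRCA/TCGA-A1-A0SB/TCGA-A1-A0SB-01A/")


def test_identical_reingest_refreshes_provenance_without_new_version(make_repo, tmp_path):
    repo = make_repo()
    f = fields()
    repo.ingest_file(stage(tmp_path, b"same"), f, Provenance("arch", 1, "o", "dcc/a/o", "m"))
    s = repo.ingest_file(stage(tmp_path, b"same"), f, Provenance("arch", 3, "o", "dcc/a/o", "m"))
    assert s.repo_version == 1
    assert s.provenance.serial == 3  # referenced archive number updated
    assert len(repo.versions(s.logical_id)) == 1


def test_changed_content_archives_previous_and_bumps_version(make_repo, tmp_path):
    repo = make_repo()
    f = fields()
    s1 = repo.ingest_file(stage(tmp_path, b"one"), f, Provenance("arch", 1, "o", "l", "m1"))
    s2 = repo.ingest_file(stage(tmp_path, b"two"), f, Provenance("arch", 2, "o", "l", "m2"))
    assert (s2.repo_version, s2.status) == (2, "current")
    v1 = repo.get(s1.logical_id, 1)
    assert v1.status == "archived"
    assert v1.local_path.startswith("archive/")
    assert (repo.root / v1.local_path).read_bytes() == b"one"
    assert (repo.root / s2.local_path).read_bytes() == b"two"


def test_archived_bytes_are_immutable_across_later_operations(make_repo, tmp_path):
    repo = make_repo()
    f = fields()
    repo.ingest_file(stage(tmp_path, b"one"), f, Provenance("a", 1, "o", "l", None))
    lid = logical_id_for(f)
    for k, content in enumerate([b"two", b"three", b"four"], start=2):
        repo.ingest_file(stage(tmp_path, content), f, Provenance("a", k, "o", "l", None))
        v1 = repo.get(lid, 1)
        assert hashlib.md5((repo.root / v1.local_path).read_bytes()).hexdigest() == v1.md5
    versions = [s.repo_version for s in repo.versions(lid)]
    assert versions == [1, 2, 3, 4]  # gapless, strictly increasing


def test_remove_with_archive_policy_keeps_retrievable_bytes(make_repo, tmp_path):
    repo = make_repo()
    f = fields()
    repo.ingest_file(stage(tmp_path, b"data"), f, Provenance("a", 1, "o", "l", None))
    s = repo.remove_file(logical_id_for(f), "archive")
    assert s.status == "deleted"
    assert (repo.root / s.local_path).read_bytes() == b"data"
    assert s.local_path.startswith("archive/")


def test_remove_with_delete_policy_leaves_tombstone_only(make_repo, tmp_path):
    repo = make_repo()
    f = fields()
    s0 = repo.ingest_file(stage(tmp_path, b"data"), f, Provenance("a", 1, "o", "l", None))
    s = repo.remove_file(logical_id_for(f), "delete")
    assert s.status == "deleted"
    assert not (repo.root / s0.local_path).exists()
    assert repo.get(s.logical_id, s.repo_version) is not None
    with pytest.raises(RepositoryError):
        repo.remove_file(logical_id_for(f), "delete")


def test_unknown_logical_id_removal_is_an_error(make_repo):
    with pytest.raises(RepositoryError, match="ghost"):
        make_repo().remove_file("ghost", "archive")


def test_snapshot_now_equals_current_and_prehistory_is_empty(make_repo, tmp_path):
    clock = TickingClock()
    repo = make_repo(clock=clock)
    for i in range(3):
        repo.ingest_file(stage(tmp_path, f"c{i}".encode()), fields(portion_number=i + 1),
                         Provenance("a", 1, "o", "l", None))
    now = clock.now.isoformat()
    snap = repo.snapshot(now)
    current = repo.get_current()
    assert [(s.logical_id, s.repo_version, s.local_path) for s in current] == snap
    assert repo.snapshot("2000-01-01T00:00:00") == []


def test_snapshot_before_removal_still_lists_the_file(make_repo, tmp_path):
    clock = TickingClock()
    repo = make_repo(clock=clock)
    f = fields()
    repo.ingest_file(stage(tmp_path, b"x"), f, Provenance("a", 1, "o", "l", None))
    before_removal = clock.now.isoformat()
    repo.remove_file(logical_id_for(f), "archive")
    assert len(repo.snapshot(before_removal)) == 1
    assert repo.snapshot(clock.now.isoformat()) == []


def test_random_history_snapshots_match_brute_force_replay(make_repo, tmp_path):
    """snapshot(t) == replay of the recorded event history truncated at t."""
    rng = random.Random(23)
    clock = TickingClock()
    repo = make_repo(clock=clock)
    field_pool = [fields(portion_number=i + 1) for i in range(4)]
    events = []  # (ts, kind, logical_id, version, path)

    for step in range(20):
        f = rng.choice(field_pool)
        lid = logical_id_for(f)
        cur = repo.current_version(lid)
        if cur is not None and rng.random() < 0.25:
            s = repo.remove_file(lid, "archive")
            # the ticking clock advances exactly once per state change, so
            # clock.now is the removal instant
            events.append((clock.now.isoformat(), "remove", lid, s.repo_version, None))
        else:
            content = f"c{step}-{rng.randint(0, 2)}".encode()
            s = repo.ingest_file(stage(tmp_path, content), f, Provenance("a", step, "o", "l", None))
            if cur is None or s.repo_version != cur.repo_version:
                events.append((s.ingest_timestamp, "ingest", lid, s.repo_version, s.local_path))

    def replay(upto):
        state = {}
        for ts, kind, lid, version, path in events:
            if ts > upto:
                break
            if kind == "ingest":
                state[lid] = (version, path)
            else:
                state.pop(lid, None)
        return sorted((lid, v) for lid, (v, _) in state.items())

    from datetime import timedelta

    start = TickingClock().now
    for _ in range(100):
        t = (start + timedelta(seconds=rng.randint(0, 25 * 60))).isoformat()
        got = sorted((lid, v) for lid, v, _ in repo.snapshot(t))
        assert got == replay(t), t


def test_get_current_filter_and_snapshot_consistency(make_repo, tmp_path):
    clock = TickingClock()
    repo = make_repo(clock=clock)
    assert repo.get_current() == []
    repo.ingest_file(stage(tmp_path, b"a"), fields(), Provenance("a", 1, "o", "l", None))
    repo.ingest_file(stage(tmp_path, b"b"), fields(portion_number=2),
                     Provenance("a", 1, "o", "l", None))
    brca = repo.get_current(lambda s: s.fields.disease == "BRCA")
    assert len(brca) == 2
    assert repo.get_current(lambda s: s.fields.disease == "GBM") == []
    snap = repo.snapshot(clock.now.isoformat())
    assert [(s.logical_id, s.repo_version, s.local_path) for s in repo.get_current()] == snap
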