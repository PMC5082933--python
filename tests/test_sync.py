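"""Sync engine: change planning, verified fetch, full-run semantics."""


import pytest

from tcgasync.metadata import MetadataStore
from tcgasync.mock_remote import (
    MutationSpec,
    advance_release,
    inject_fault,
    replay_ledger,
)
from tcgasync.repository import Repository
from tcgasync.sync import (
    SyncConfig,
    SyncError,
    default_adapters,
    fetch_file,
    parse_changes_file,
    plan_sync,
    run_sync,
)
from tcgasync.validation import audit_download_log


@pytest.fixture
def workspace(tmp_path):
    def _make(name="ws"):
        ws = tmp_path / name
        return Repository(ws / "repository"), MetadataStore(ws / "metadata.db"), ws / "work"

    return _make


def config_for(remote, **kw):
    return SyncConfig(uuid_map=str(remote.root / "uuid_map.tsv"), **kw)


# -- change-list parsing -----------------------------------------------------


def test_header_only_changes_file_is_empty():
    cs = parse_changes_file("# serial=2\n")
    assert (cs.added, cs.modified, cs.deleted) == ([], [], [])


def test_changes_file_routes_verbs_by_line_count():
    text = "# serial=2\nADDED\ta/x\nADDED\ta/y\nDELETED\ta/z\n"
    cs = parse_changes_file(text)
    assert (len(cs.added), len(cs.modified), len(cs.deleted)) == (2, 0, 1)
    # oracle: raw line count by verb
    lines = [l for l in text.splitlines() if "\t" in l]
    assert len(lines) == len(cs.added) + len(cs.modified) + len(cs.deleted)


def test_duplicate_path_under_two_verbs_is_rejected():
    with pytest.raises(SyncError, match="two change lists"):
        parse_changes_file("ADDED\ta/x\nDELETED\ta/x\n")


@pytest.mark.parametrize("line,match", [("RENAMED\ta/x", "unknown verb"),
                                        ("ADDED a/x", "expected")])
def test_malformed_changes_lines_report_line_number(line, match):
    with pytest.raises(SyncError, match=f"line 1.*{match}|{match}"):
        parse_changes_file(line + "\n")


# -- adapters ----------------------------------------------------------------


def test_default_registry_has_one_adapter_per_remote_datastore():
    adapters = default_adapters()
    assert len(adapters) == 4
    assert {a.store for a in adapters} == {"dcc", "bamstore", "level4store", "msstore"}


def test_plan_on_fresh_workspace_adds_everything(make_remote, workspace):
    remote = make_remote()
    _, store, _ = workspace()
    cs = plan_sync(remote, store, config_for(remote))
    assert sorted(cs.added) == sorted(remote.manifest)
    assert cs.modified == [] and cs.deleted == []


def test_plan_against_unchanged_remote_is_empty(make_remote, workspace):
    remote = make_remote()
    repo, store, work = workspace()
    run_sync(remote, config_for(remote), repo, store, work)
    cs = plan_sync(remote, store, config_for(remote))
    assert cs.is_empty() and cs.serial_bumped_unchanged == []


def test_plan_sizes_match_fixture_mutation(make_remote, workspace):
    remote = make_remote(n_participants=3, datatypes=("Somatic_Mutations",))
    repo, store, work = workspace()
    run_sync(remote, config_for(remote), repo, store, work)
    advance_release(remote, MutationSpec(adds={"Somatic_Mutations": 2},
                                         modifies={"Somatic_Mutations": 1},
                                         deletes={"Somatic_Mutations": 1}, seed=8))
    cs = plan_sync(remote, store, config_for(remote))
    assert (len(cs.added), len(cs.modified), len(cs.deleted)) == (2, 1, 1)
    # ledger oracle: events of the new serial
    latest = {ev.path: ev.action for ev in remote.ledger if ev.serial == 2}
    assert {p: a for p, a in latest.items() if a == "added"}.keys() == set(cs.added)
    assert {p: a for p, a in latest.items() if a == "modified"}.keys() == set(cs.modified)
    assert {p: a for p, a in latest.items() if a == "deleted"}.keys() == set(cs.deleted)


def test_empty_release_routes_all_dcc_paths_to_serial_bumped(make_remote, workspace):
    remote = make_remote(datatypes=("Somatic_Mutations", "Protected_Mutations"))
    repo, store, work = workspace()
    run_sync(remote, config_for(remote), repo, store, work)
    advance_release(remote, MutationSpec())
    cs = plan_sync(remote, store, config_for(remote))
    dcc_paths = {p for p in remote.manifest if p.startswith("dcc/")}
    assert set(cs.serial_bumped_unchanged) == dcc_paths
    assert cs.is_empty()
    report = run_sync(remote, config_for(remote), repo, store, work)
    assert report.downloads == 0 and report.messages == 0


def test_remote_serial_regression_is_an_error(make_remote, workspace):
    remote = make_remote(datatypes=("Somatic_Mutations",))
    repo, store, work = workspace()
    run_sync(remote, config_for(remote), repo, store, work)
    store.set_sync_state("dcc", 99, None)
    with pytest.raises(SyncError, match="regression"):
        plan_sync(remote, store, config_for(remote))


# -- fetch -------------------------------------------------------------------


def test_clean_fetch_verifies_first_try(make_remote, tmp_path):
    remote = make_remote(datatypes=("Somatic_Mutations",))
    path = sorted(remote.manifest)[0]
    r = fetch_file(remote, path, remote.manifest[path], 3, tmp_path / "s", tmp_path / "log")
    assert (r.attempts, r.verified) == (1, True)
    assert r.staged.read_bytes() == (remote.root / path).read_bytes()


def test_fetch_retries_through_injected_faults(make_remote, tmp_path):
    remote = make_remote(datatypes=("Somatic_Mutations",))
    path = sorted(remote.manifest)[0]
    inject_fault(remote, path, 2)
    r = fetch_file(remote, path, remote.manifest[path], 3, tmp_path / "s", tmp_path / "log")
    assert (r.attempts, r.verified) == (3, True)


def test_fetch_exhaustion_is_a_failed_result_recoverable_from_log(make_remote, tmp_path):
    remote = make_remote(datatypes=("Somatic_Mutations",))
    path = sorted(remote.manifest)[0]
    inject_fault(remote, path, 3)
    log = tmp_path / "log"
    r = fetch_file(remote, path, remote.manifest[path], 3, tmp_path / "s", log)
    assert (r.attempts, r.verified) == (3, False)
    assert audit_download_log(log.read_text()) == [path]


# -- full runs ---------------------------------------------------------------


def test_repeated_run_is_a_no_op_fixpoint(make_remote, workspace):
    remote = make_remote()
    repo, store, work = workspace()
    first = run_sync(remote, config_for(remote), repo, store, work)
    assert first.downloads == len(remote.manifest)
    second = run_sync(remote, config_for(remote), repo, store, work)
    assert second.downloads == 0
    assert second.messages == 0 and second.events == 0
    assert second.outcomes == {}


def test_post_sync_repository_equals_ledger_replay(make_remote, workspace):
    remote = make_remote(n_participants=2)
    repo, store, work = workspace()
    cfg = config_for(remote)
    run_sync(remote, cfg, repo, store, work)
    for k in range(3):
        advance_release(remote, MutationSpec(
            adds={"Somatic_Mutations": 1, "WGS_cgHub": 1},
            modifies={"Protected_Mutations": 1, "Mass_Spectrometry": 1},
            deletes={"Somatic_Mutations": 1}, seed=k))
        run_sync(remote, cfg, repo, store, work)
    current = {s.provenance.original_location: s.source_md5 for s in repo.get_current()}
    assert current == replay_ledger(remote.ledger)


def test_modified_file_version_increments_by_exactly_one(make_remote, workspace):
    remote = make_remote(datatypes=("Somatic_Mutations",))
    repo, store, work = workspace()
    cfg = config_for(remote)
    run_sync(remote, cfg, repo, store, work)
    advance_release(remote, MutationSpec(modifies={"Somatic_Mutations": 1}, seed=2))
    path = [ev.path for ev in remote.ledger if ev.serial == 2][0]
    lid = store.current_paths()[path][0]
    before = repo.current_version(lid).repo_version
    run_sync(remote, cfg, repo, store, work)
    after = repo.current_version(lid).repo_version
    assert after == before + 1
    assert repo.get(lid, before).status == "archived"


def test_failed_download_is_contained_and_retried_next_run(make_remote, workspace):
    remote = make_remote(datatypes=("Somatic_Mutations",))
    repo, store, work = workspace()
    cfg = config_for(remote, retry_limit=2)
    victim = sorted(p for p in remote.manifest if p.startswith("dcc/"))[0]
    inject_fault(remote, victim, 2)
    report = run_sync(remote, cfg, repo, store, work)
    assert victim in report.failed
    assert "failed" in report.outcomes[victim]
    assert len(report.failed) == 1  # one bad file never aborts the others
    log_text = (work / "logs" / "downloads.log").read_text()
    assert victim in audit_download_log(log_text)
    # faults consumed: the next run picks the file up cleanly
    report2 = run_sync(remote, cfg, repo, store, work)
    assert report2.failed == []
    assert victim in report2.outcomes
    assert {s.provenance.original_location for s in repo.get_current()} == set(remote.manifest)


def test_delete_policy_archive_keeps_bytes_delete_removes_them(make_remote, workspace, tmp_path):
    for policy in ("archive", "delete"):
        remote = make_remote(n_participants=2, datatypes=("Somatic_Mutations",), seed=hash(policy) % 100)
        repo, store, work = workspace(name=f"ws-{policy}")
        cfg = config_for(remote, delete_policy=policy)
        run_sync(remote, cfg, repo, store, work)
        advance_release(remote, MutationSpec(deletes={"Somatic_Mutations": 1}, seed=1))
        path = [ev.path for ev in remote.ledger if ev.serial == 2][0]
        lid = store.current_paths()[path][0]
        run_sync(remote, cfg, repo, store, work)
        tomb = repo.versions(lid)[-1]
        assert tomb.status == "deleted"
        exists = (repo.root / tomb.local_path).exists()
        assert exists == (policy == "archive")


def test_vcf_files_are_harmonized_and_sorted_at_ingest(make_remote, workspace):
    from tcgasync.validation import check_vcf_sorted
    from tcgasync.vcf import REQUIRED_KEYS

    remote = make_remote(n_participants=2, datatypes=("Protected_Mutations",))
    repo, store, work = workspace()
    run_sync(remote, config_for(remote), repo, store, work)
    vcfs = [s for s in repo.get_current() if s.local_path.endswith(".vcf")]
    assert vcfs
    for s in vcfs:
        text = (repo.root / s.local_path).read_text()
        keys = [l[2:].split("=", 1)[0] for l in text.splitlines() if l.startswith("##")]
        assert keys[:8] == list(REQUIRED_KEYS)
        assert check_vcf_sorted(text).severity == "ok"


def test_sync_config_yaml_round_trip_and_validation(tmp_path):
    cfg = SyncConfig(datatypes=["Somatic_Mutations"], retry_limit=5, delete_policy="delete")
    p = tmp_path / "cfg.yaml"
    cfg.to_yaml(p)
    assert SyncConfig.from_yaml(p) == cfg
    with pytest.raises(SyncError, match="retry_limit"):
        SyncConfig(retry_limit=0)
    with pytest.raises(SyncError, match="delete_policy"):
        SyncConfig(delete_policy="shred")
    with pytest.raises(SyncError, match="Banana"):
        SyncConfig(datatypes=["Banana_Seq"])


def test_datatype_selection_restricts_the_plan(make_remote, workspace):
    remote = make_remote(datatypes=("Somatic_Mutations", "WGS_cgHub"))
    _, store, _ = workspace()
    cfg = SyncConfig(datatypes=["Somatic_Mutations"])
    cs = plan_sync(remote, store, cfg)
    assert cs.added and all(p.startswith("dcc/") for p in cs.added)
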