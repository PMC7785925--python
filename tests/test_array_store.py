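"""Transactional store semantics: atomicity, versioning, reads, deletes."""

import json

import pytest

import sccommons as sc
from conftest import build_toy_store


def manifest_text(store):
    return (store.path / "manifest.json").read_text()


class TestTransactions:
    def test_abort_is_a_byte_level_noop(self, tmp_path):
        store, ids = build_toy_store(tmp_path / "s")
        before = manifest_text(store)
        txn = store.begin_load(ids["project"])
        store.abort_load(txn)
        assert manifest_text(store) == before
        assert store.version == json.loads(before)["version"]

    def test_rollback_discards_written_entries(self, tmp_path):
        store, ids = build_toy_store(tmp_path / "s")
        n_before = store.n_entries()
        txn = store.begin_load(ids["project"])
        sid = txn.register_sample("S2")
        cells = [txn.register_cell(sid, f"x{i}") for i in range(10)]
        mid = txn.register_measurementset(sid, 0, "normalized")
        assert store.write_entries(txn, [(c, ids["ACE2"], 1.0) for c in cells],
                                   mid) == 10
        store.abort_load(txn)
        assert store.n_entries() == n_before
        assert "S2" not in [s.name for s in store.catalog.samples.values()]

    def test_two_load_commits_bump_version_by_two(self, tmp_path):
        store, ids = build_toy_store(tmp_path / "s")
        v0 = store.version
        for name in ("A", "B"):
            txn = store.begin_load(ids["project"])
            sid = txn.register_sample(name)
            c = txn.register_cell(sid, "bc0")
            mid = txn.register_measurementset(sid, 0, "normalized")
            store.write_entries(txn, [(c, ids["ACE2"], 1.0)], mid)
            store.commit_load(txn)
        assert store.version == v0 + 2

    def test_empty_commit_bumps_version_adds_nothing(self, tmp_path):
        store, ids = build_toy_store(tmp_path / "s")
        v0, n0 = store.version, store.n_entries()
        txn = store.begin_load(ids["project"])
        assert store.commit_load(txn) == v0 + 1
        assert store.n_entries() == n0

    def test_write_entries_counts_and_rejects(self, tmp_path):
        store, ids = build_toy_store(tmp_path / "s")
        txn = store.begin_load(ids["project"])
        sid = txn.register_sample("S2")
        c = txn.register_cell(sid, "bc")
        mid = txn.register_measurementset(sid, 0, "normalized")
        assert store.write_entries(txn, [], mid) == 0
        store.write_entries(txn, [(c, ids["ACE2"], 2.0)], mid)
        with pytest.raises(sc.IntegrityError, match=str(ids["ACE2"])):
            store.write_entries(txn, [(c, ids["ACE2"], 2.0)], mid)
        with pytest.raises(sc.ValidationError):
            store.write_entries(txn, [(c, ids["TMPRSS2"], float("nan"))], mid)
        with pytest.raises(sc.ReferentialError):
            store.write_entries(txn, [(9999, ids["ACE2"], 1.0)], mid)
        store.abort_load(txn)

    def test_negative_raw_rejected_at_commit_store_unchanged(self, tmp_path):
        store, ids = build_toy_store(tmp_path / "s")
        before = manifest_text(store)
        txn = store.begin_load(ids["project"])
        sid = txn.register_sample("S2")
        c = txn.register_cell(sid, "bc")
        mid = txn.register_measurementset(sid, 0, "raw")
        store.write_entries(txn, [(c, ids["ACE2"], -1.0)], mid)
        with pytest.raises(sc.ValidationError):
            store.commit_load(txn)
        assert manifest_text(store) == before

    def test_concurrent_open_load_on_same_project_conflicts(self, tmp_path):
        store, ids = build_toy_store(tmp_path / "s")
        txn = store.begin_load(ids["project"])
        with pytest.raises(sc.ConflictError):
            store.begin_load(ids["project"])
        store.abort_load(txn)
        store.begin_load(ids["project"])  # released after abort

    def test_no_dirty_reads_before_commit(self, tmp_path):
        store, ids = build_toy_store(tmp_path / "s")
        n0 = store.n_entries()
        rows0 = list(store.read_submatrix(matrix_kind="normalized"))
        txn = store.begin_load(ids["project"])
        sid = txn.register_sample("S2")
        c = txn.register_cell(sid, "bc")
        mid = txn.register_measurementset(sid, 0, "normalized")
        store.write_entries(txn, [(c, ids["ACE2"], 9.0)], mid)
        # interleaved reader sees the committed state only
        assert store.n_entries() == n0
        assert list(store.read_submatrix(matrix_kind="normalized")) == rows0
        store.commit_load(txn)
        assert store.n_entries() == n0 + 1


class TestFaultInjection:
    @pytest.mark.parametrize("stage", ["validate", "write_chunks",
                                       "write_catalog", "swap_manifest"])
    def test_crash_before_manifest_swap_preserves_old_version(self, tmp_path, stage):
        store, ids = build_toy_store(tmp_path / "s")
        before = manifest_text(store)
        rows_before = list(store.read_submatrix(matrix_kind="normalized"))

        class Boom(RuntimeError):
            pass

        def hook(s):
            if s == stage:
                raise Boom(s)

        store.fault_hook = hook
        txn = store.begin_load(ids["project"])
        sid = txn.register_sample("S2")
        c = txn.register_cell(sid, "bc")
        mid = txn.register_measurementset(sid, 0, "normalized")
        store.write_entries(txn, [(c, ids["ACE2"], 1.0)], mid)
        with pytest.raises(Boom):
            store.commit_load(txn)
        assert txn.state == "aborted"
        # the surviving manifest is the old one: a reopened store is intact
        assert manifest_text(store) == before
        reopened = sc.Store.open(store.path)
        assert reopened.version == json.loads(before)["version"]
        assert list(reopened.read_submatrix(matrix_kind="normalized")) == rows_before


class TestReads:
    def test_gene_slice_enumeration_on_toy(self, toy_store):
        store, ids = toy_store
        c1, c2, c3 = ids["cells"]
        rows = list(store.read_submatrix(None, {ids["ACE2"]}, "normalized", None))
        assert [(r[2], r[4]) for r in rows] == [(c1, 2.0), (c2, 1.0)]
        assert list(store.read_submatrix({c3}, None, "normalized", None)) == []
        with pytest.raises(sc.NotFoundError):
            store.read_submatrix({999}, None, "normalized", None)

    def test_rows_sorted_and_deterministic(self, small_atlas):
        store = small_atlas["store"]
        rows = list(store.read_submatrix(matrix_kind="normalized"))
        assert rows == sorted(rows, key=lambda r: (r[0], r[1], r[2], r[3]))
        assert rows == list(store.read_submatrix(matrix_kind="normalized"))

    def test_conservation_of_entries(self, small_atlas):
        store = small_atlas["store"]
        for kind in ("raw", "normalized"):
            rows = list(store.read_submatrix(matrix_kind=kind))
            assert len(rows) == store.n_entries(kind)
            assert sum(r[4] for r in rows) == pytest.approx(
                store.value_sum(kind), rel=1e-12)

    def test_project_restricted_reads_touch_only_that_projects_chunks(
            self, small_atlas):
        store = small_atlas["store"]
        pid = store.catalog.project_id_by_name("wang20_rectum")
        own = {m["path"] for m in store.chunk_meta.values()
               if m["project_id"] == pid}
        store.io_log.clear()
        list(store.read_submatrix(matrix_kind="normalized", project_ids=[pid]))
        assert store.io_log and set(store.io_log) <= own


class TestDelete:
    def _two_project_store(self, tmp_path):
        store = sc.Store.create(tmp_path / "s")
        cfg = sc.AtlasConfig(n_projects=2, samples_per_project=1,
                             cells_per_sample=50, n_genes=30, seed=3)
        manifest = sc.generate_atlas(cfg, tmp_path / "atlas")
        sc.load_atlas(store, tmp_path / "atlas")
        return store, manifest, tmp_path / "atlas"

    def test_delete_removes_everything_of_the_project(self, tmp_path):
        store, manifest, _ = self._two_project_store(tmp_path)
        p0, p1 = (p["name"] for p in manifest["projects"])
        pid = store.catalog.project_id_by_name(p0)
        victim_cell = store.catalog.cells_of_project(pid)[0]
        removed = store.delete_project_data(pid)
        expected = sum(manifest["projects"][0]["n_entries"].values())
        assert removed == expected
        assert victim_cell not in store.catalog.cells
        with pytest.raises(sc.NotFoundError):
            store.catalog.project_id_by_name(p0)
        surviving = manifest["projects"][1]["n_entries"]
        assert store.n_entries("normalized") == surviving["normalized"]
        assert store.n_entries("raw") == surviving["raw"]
        store.catalog.check_referential()

    def test_delete_then_reload_restores_planted_counts(self, tmp_path):
        store, manifest, atlas_dir = self._two_project_store(tmp_path)
        p0 = manifest["projects"][0]
        pid = store.catalog.project_id_by_name(p0["name"])
        store.delete_project_data(pid)
        # reload just that project from the atlas files
        new_pid = store.register_project(p0["name"])
        for s in p0["samples"]:
            bundle = sc.read_10x_dir(atlas_dir / s["dir"] / "normalized")
            sc.load_bundle(store, new_pid, s["name"], bundle, "normalized",
                           cell_tags_tsv=atlas_dir / s["tags_tsv"],
                           sample_tags=s["sample_tags"])
        assert store.n_entries("normalized", new_pid) == p0["n_entries"]["normalized"]

    def test_delete_unknown_project(self, tmp_path):
        store = sc.Store.create(tmp_path / "s")
        with pytest.raises(sc.NotFoundError):
            store.delete_project_data(4)
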