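"""On-disc sparse expression array with atomic, versioned loads.

The quantification data form a sparse 4-D array addressed by
``(sample_id, measurementset_id, cell_id, feature_id)``; an absent
coordinate means value 0.  Physically the array is partitioned into one
MatrixMarket chunk file per measurement set (i.e. per project/sample/kind
slice), which keeps gene- and project-sliced reads local, plus a JSON
manifest naming the committed version.  Commits are manifest swaps: chunk
and catalog files for the new version are written under fresh names and a
single atomic ``os.replace`` of ``manifest.json`` publishes them, so a
crash at any earlier point leaves the prior version intact and readers
never observe a half-applied load.

Writer concurrency is deliberately simple — one open load per project,
linear version history — which matches a curated-commons workload of bulk
loads and many readers.
"""

from __future__ import annotations

import copy
import hashlib
import json
import math
import os
import shutil
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping, Optional, Sequence, Union

import numpy as np
import scipy.io
import scipy.sparse as sp

from .core_model import (
    Catalog,
    ConflictError,
    IntegrityError,
    NotFoundError,
    ReferentialError,
    TagValue,
    ValidationError,
)

__all__ = ["Store", "LoadTransaction"]

MANIFEST_NAME = "manifest.json"

#: Commit stages, in order; the fault-injection hook fires before each.
COMMIT_STAGES = ("validate", "write_chunks", "write_catalog", "swap_manifest")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


class _Chunk:
    """In-memory image of one measurement set's entries, with lazy indexes."""

    def __init__(self, cells: np.ndarray, feats: np.ndarray, vals: np.ndarray):
        self.cells = cells
        self.feats = feats
        self.vals = vals
        self._by_feature: Optional[dict[int, list[tuple[int, float]]]] = None

    def by_feature(self) -> dict[int, list[tuple[int, float]]]:
        """Secondary index: feature -> posting list of (cell, value)."""
        if self._by_feature is None:
            idx: dict[int, list[tuple[int, float]]] = {}
            for c, f, v in zip(self.cells.tolist(), self.feats.tolist(), self.vals.tolist()):
                idx.setdefault(f, []).append((c, v))
            self._by_feature = idx
        return self._by_feature

    def __len__(self) -> int:
        return len(self.vals)


class LoadTransaction:
    """Staging area for one project load.

    Entity registrations go to a shadow copy of the catalog and expression
    entries to per-measurement-set staging dicts; nothing is visible to
    readers until :meth:`Store.commit_load` swaps the manifest.
    """

    def __init__(self, store: "Store", project_id: int):
        self.store = store
        self.project_id = project_id
        self.catalog: Catalog = copy.deepcopy(store.catalog)
        self.staged: dict[int, dict[tuple[int, int], float]] = {}
        self.state = "open"

    def _require_open(self) -> None:
        if self.state != "open":
            raise ValidationError(f"transaction is {self.state}, not open")

    # registrations against the shadow catalog ------------------------------

    def register_sample(self, name: str, description: str = "",
                        tags: Optional[Mapping] = None) -> int:
        self._require_open()
        return self.catalog.register_sample(self.project_id, name, description, tags)

    def register_cell(self, sample_id: int, barcode: str,
                      tags: Optional[Mapping] = None) -> int:
        self._require_open()
        return self.catalog.register_cell(sample_id, barcode, tags)

    def register_featureset(self, genome_build: str = "GRCh38",
                            reference_model: str = "", table_hash: str = "") -> int:
        self._require_open()
        return self.catalog.register_featureset(genome_build, reference_model, table_hash)

    def register_feature(self, featureset_id: int, ensembl_id: str, gene_symbol: str,
                         **kw) -> int:
        self._require_open()
        return self.catalog.register_feature(featureset_id, ensembl_id, gene_symbol, **kw)

    def register_measurementset(self, sample_id: int, featureset_id: int,
                                matrix_kind: str, name: str = "",
                                description: str = "") -> int:
        self._require_open()
        mid = self.catalog.register_measurementset(sample_id, featureset_id,
                                                   matrix_kind, name, description)
        self.staged[mid] = {}
        return mid

    def upsert_tags(self, kind: str, entity_id: int, tags: Mapping[str, TagValue]) -> None:
        self._require_open()
        self.catalog.upsert_tags(kind, entity_id, tags)


class Store:
    """A commons store rooted at one directory.

    Use :meth:`create` for a fresh store and :meth:`open` to attach to an
    existing one.  All catalog mutations are durable: each public mutating
    operation commits a new version by manifest swap.
    """

    def __init__(self, path: Union[str, Path], catalog: Catalog, version: int,
                 chunks: dict[int, dict]):
        self.path = Path(path)
        self.catalog = catalog
        self.version = version
        self.chunk_meta = chunks          # mid -> {path, checksum, n_entries, value_sum, ...}
        self._chunk_cache: dict[int, _Chunk] = {}
        self._open_txn_projects: set[int] = set()
        #: fault-injection hook, called with the commit stage name; a raise
        #: aborts the commit at that stage (used by atomicity tests).
        self.fault_hook: Optional[Callable[[str], None]] = None
        #: log of chunk files touched by reads, for I/O locality auditing.
        self.io_log: list[str] = []

    # -- lifecycle ----------------------------------------------------------

    @classmethod
    def create(cls, path: Union[str, Path]) -> "Store":
        path = Path(path)
        if (path / MANIFEST_NAME).exists():
            raise ValidationError(f"store already exists at {path}")
        path.mkdir(parents=True, exist_ok=True)
        (path / "chunks").mkdir(exist_ok=True)
        store = cls(path, Catalog(), version=0, chunks={})
        store._write_catalog_dir(0)
        store._swap_manifest(0, "catalog-v0")
        return store

    @classmethod
    def open(cls, path: Union[str, Path]) -> "Store":
        path = Path(path)
        mpath = path / MANIFEST_NAME
        if not mpath.exists():
            raise NotFoundError(f"no store manifest at {mpath}")
        manifest = json.loads(mpath.read_text())
        catalog = Catalog.from_dir(path / manifest["catalog_dir"])
        chunks = {int(k): v for k, v in manifest["chunks"].items()}
        return cls(path, catalog, manifest["version"], chunks)

    # -- manifest machinery -------------------------------------------------

    def _write_catalog_dir(self, version: int) -> str:
        name = f"catalog-v{version}"
        self.catalog.to_dir(self.path / name)
        return name

    def _swap_manifest(self, version: int, catalog_dir: str) -> None:
        manifest = {
            "version": version,
            "catalog_dir": catalog_dir,
            "chunks": {str(k): v for k, v in sorted(self.chunk_meta.items())},
        }
        tmp = self.path / (MANIFEST_NAME + ".tmp")
        tmp.write_text(json.dumps(manifest, indent=1, sort_keys=True))
        os.replace(tmp, self.path / MANIFEST_NAME)
        self.version = version
        # prune superseded catalog directories
        for d in self.path.glob("catalog-v*"):
            if d.name != catalog_dir and d.is_dir():
                shutil.rmtree(d, ignore_errors=True)

    def _commit_catalog(self) -> int:
        """Publish a catalog-only change as a new version."""
        newv = self.version + 1
        catalog_dir = self._write_catalog_dir(newv)
        self._swap_manifest(newv, catalog_dir)
        return newv

    # -- catalog pass-throughs (durable) ------------------------------------

    def register_entity(self, kind: str, parent_id: Optional[int], name: str,
                        tags: Optional[Mapping] = None) -> int:
        eid = self.catalog.register_entity(kind, parent_id, name, tags)
        self._commit_catalog()
        return eid

    def register_project(self, name: str, description: str = "",
                         public: bool = True, tags: Optional[Mapping] = None) -> int:
        pid = self.catalog.register_project(name, description, public, tags)
        self._commit_catalog()
        return pid

    def upsert_tags(self, kind: str, entity_id: int, tags: Mapping[str, TagValue]) -> dict:
        out = self.catalog.upsert_tags(kind, entity_id, tags)
        self._commit_catalog()
        return out

    def bulk_upsert_tags(self, kind: str,
                         updates: Iterable[tuple[int, Mapping[str, TagValue]]]) -> int:
        """Apply many tag merges in one durable commit; returns entities touched.

        Validates every update before mutating anything, so a bad row leaves
        the store unchanged."""
        updates = list(updates)
        for eid, _ in updates:
            self.catalog.get(kind, eid)
        n = 0
        for eid, tags in updates:
            self.catalog.upsert_tags(kind, eid, tags)
            n += 1
        self._commit_catalog()
        return n

    def list_tag_keys(self, kind: str, project_id: Optional[int] = None):
        return self.catalog.list_tag_keys(kind, project_id)

    # -- transactions -------------------------------------------------------

    def begin_load(self, project_id: int) -> LoadTransaction:
        if project_id not in self.catalog.projects:
            raise NotFoundError(f"unknown project id {project_id}")
        if project_id in self._open_txn_projects:
            raise ConflictError(f"project {project_id} already has an open load")
        self._open_txn_projects.add(project_id)
        return LoadTransaction(self, project_id)

    def write_entries(self, txn: LoadTransaction,
                      triples: Iterable[tuple[int, int, float]],
                      measurementset_id: int) -> int:
        txn._require_open()
        if measurementset_id not in txn.staged:
            raise NotFoundError(
                f"measurementset {measurementset_id} is not part of this transaction")
        mset = txn.catalog.measurementsets[measurementset_id]
        fs_features = set(txn.catalog.features_by_set[mset.featureset_id])
        sample_cells = set(txn.catalog.cells_by_sample[mset.sample_id])
        staged = txn.staged[measurementset_id]
        n = 0
        for cell_id, feature_id, value in triples:
            if not math.isfinite(value):
                raise ValidationError(
                    f"non-finite value at (cell {cell_id}, feature {feature_id})")
            if cell_id not in sample_cells:
                raise ReferentialError(
                    f"cell {cell_id} is not registered on sample {mset.sample_id}")
            if feature_id not in fs_features:
                raise ReferentialError(
                    f"feature {feature_id} is not in featureset {mset.featureset_id}")
            key = (cell_id, feature_id)
            if key in staged:
                raise IntegrityError(
                    f"duplicate coordinate (cell {cell_id}, feature {feature_id}) in load")
            staged[key] = float(value)
            n += 1
        return n

    def abort_load(self, txn: LoadTransaction) -> None:
        if txn.state == "open":
            txn.state = "aborted"
            self._open_txn_projects.discard(txn.project_id)

    def _fault(self, stage: str) -> None:
        if self.fault_hook is not None:
            self.fault_hook(stage)

    def commit_load(self, txn: LoadTransaction) -> int:
        """Validate, persist and atomically publish a load; returns the new
        version.  Any failure (including an injected fault) aborts the
        transaction and leaves the committed store untouched."""
        txn._require_open()
        newv = self.version + 1
        new_meta: dict[int, dict] = {}
        try:
            self._fault("validate")
            txn.catalog.check_referential()
            for mid, staged in txn.staged.items():
                mset = txn.catalog.measurementsets[mid]
                if mset.matrix_kind == "raw":
                    for (c, f), v in staged.items():
                        if v < 0:
                            raise ValidationError(
                                f"negative raw value at (cell {c}, feature {f})")

            self._fault("write_chunks")
            (self.path / "chunks").mkdir(exist_ok=True)
            for mid, staged in txn.staged.items():
                mset = txn.catalog.measurementsets[mid]
                relpath = f"chunks/ms{mid}-v{newv}.mtx"
                self._write_chunk(self.path / relpath, staged)
                new_meta[mid] = {
                    "path": relpath,
                    "checksum": _sha256(self.path / relpath),
                    "n_entries": len(staged),
                    "value_sum": float(sum(staged.values())),
                    "matrix_kind": mset.matrix_kind,
                    "project_id": txn.project_id,
                    "sample_id": mset.sample_id,
                }

            self._fault("write_catalog")
            # write the shadow catalog under the new version's directory
            old_catalog = self.catalog
            self.catalog = txn.catalog
            try:
                catalog_dir = self._write_catalog_dir(newv)
            finally:
                self.catalog = old_catalog

            self._fault("swap_manifest")
            self.catalog = txn.catalog
            self.chunk_meta.update(new_meta)
            self._swap_manifest(newv, catalog_dir)
        except BaseException:
            txn.state = "aborted"
            self._open_txn_projects.discard(txn.project_id)
            raise
        txn.state = "committed"
        self._open_txn_projects.discard(txn.project_id)
        for mid, staged in txn.staged.items():
            if staged:
                keys = np.array(sorted(staged), dtype=np.int64)
                vals = np.array([staged[tuple(k)] for k in keys], dtype=np.float64)
                self._chunk_cache[mid] = _Chunk(keys[:, 0], keys[:, 1], vals)
            else:
                empty = np.array([], dtype=np.int64)
                self._chunk_cache[mid] = _Chunk(empty, empty, np.array([], dtype=np.float64))
        return newv

    @staticmethod
    def _write_chunk(path: Path, staged: Mapping[tuple[int, int], float]) -> None:
        if staged:
            keys = sorted(staged)
            rows = np.array([k[0] for k in keys], dtype=np.int64)
            cols = np.array([k[1] for k in keys], dtype=np.int64)
            vals = np.array([staged[k] for k in keys], dtype=np.float64)
            shape = (int(rows.max()) + 1, int(cols.max()) + 1)
        else:
            rows = cols = np.array([], dtype=np.int64)
            vals = np.array([], dtype=np.float64)
            shape = (1, 1)
        mat = sp.coo_matrix((vals, (rows, cols)), shape=shape)
        scipy.io.mmwrite(str(path), mat, field="real", precision=17)

    # -- chunk access -------------------------------------------------------

    def _chunk(self, mid: int) -> _Chunk:
        meta = self.chunk_meta[mid]
        self.io_log.append(meta["path"])
        if mid not in self._chunk_cache:
            fpath = self.path / meta["path"]
            if _sha256(fpath) != meta["checksum"]:
                raise IntegrityError(f"checksum mismatch for chunk {meta['path']}")
            mat = scipy.io.mmread(str(fpath)).tocoo()
            order = np.lexsort((mat.col, mat.row))
            self._chunk_cache[mid] = _Chunk(
                mat.row.astype(np.int64)[order], mat.col.astype(np.int64)[order],
                mat.data.astype(np.float64)[order])
        return self._chunk_cache[mid]

    def measurementsets_for(self, matrix_kind: Optional[str] = None,
                            project_ids: Optional[Sequence[int]] = None) -> list[int]:
        """Committed measurement-set ids, optionally restricted by kind/projects."""
        out = []
        for mid, meta in sorted(self.chunk_meta.items()):
            if matrix_kind is not None and meta["matrix_kind"] != matrix_kind:
                continue
            if project_ids is not None and meta["project_id"] not in project_ids:
                continue
            out.append(mid)
        return out

    # -- reads --------------------------------------------------------------

    def read_submatrix(self, cell_ids: Optional[Iterable[int]] = None,
                       feature_ids: Optional[Iterable[int]] = None,
                       matrix_kind: str = "normalized",
                       project_ids: Optional[Iterable[int]] = None,
                       ) -> Iterator[tuple[int, int, int, int, float]]:
        """Stream the stored nonzero entries in the coordinate intersection.

        ``None`` for a coordinate set means "all".  Rows come out in
        deterministic ascending (project, sample, cell, feature) order.
        Only chunks of measurement sets inside the project scope are
        touched, which is what keeps project-restricted reads local.
        """
        cset = None if cell_ids is None else set(cell_ids)
        fset = None if feature_ids is None else set(feature_ids)
        pset = None if project_ids is None else set(project_ids)
        if pset is not None:
            for pid in pset:
                if pid not in self.catalog.projects:
                    raise NotFoundError(f"unknown project id {pid}")
        if cset is not None:
            for cid in cset:
                if cid not in self.catalog.cells:
                    raise NotFoundError(f"unknown cell id {cid}")
        if fset is not None:
            for fid in fset:
                if fid not in self.catalog.features:
                    raise NotFoundError(f"unknown feature id {fid}")
        return self._iter_submatrix(cset, fset, matrix_kind, pset)

    def _iter_submatrix(self, cset, fset, matrix_kind, pset):
        mids = self.measurementsets_for(matrix_kind,
                                        None if pset is None else sorted(pset))
        # group measurement sets by (project, sample) and emit sample groups
        # in ascending order; within a group entries are merge-sorted.
        groups: dict[tuple[int, int], list[int]] = {}
        for mid in mids:
            meta = self.chunk_meta[mid]
            groups.setdefault((meta["project_id"], meta["sample_id"]), []).append(mid)
        for (pid, sid) in sorted(groups):
            rows: list[tuple[int, int, float]] = []
            for mid in groups[(pid, sid)]:
                ch = self._chunk(mid)
                for c, f, v in zip(ch.cells.tolist(), ch.feats.tolist(), ch.vals.tolist()):
                    if cset is not None and c not in cset:
                        continue
                    if fset is not None and f not in fset:
                        continue
                    rows.append((c, f, v))
            rows.sort(key=lambda r: (r[0], r[1]))
            for c, f, v in rows:
                yield (pid, sid, c, f, v)

    def n_entries(self, matrix_kind: Optional[str] = None,
                  project_id: Optional[int] = None) -> int:
        total = 0
        for mid, meta in self.chunk_meta.items():
            if matrix_kind is not None and meta["matrix_kind"] != matrix_kind:
                continue
            if project_id is not None and meta["project_id"] != project_id:
                continue
            total += meta["n_entries"]
        return total

    def value_sum(self, matrix_kind: Optional[str] = None,
                  project_id: Optional[int] = None) -> float:
        total = 0.0
        for mid, meta in self.chunk_meta.items():
            if matrix_kind is not None and meta["matrix_kind"] != matrix_kind:
                continue
            if project_id is not None and meta["project_id"] != project_id:
                continue
            total += meta["value_sum"]
        return total

    # -- housekeeping -------------------------------------------------------

    def delete_project_data(self, project_id: int) -> int:
        """Atomically remove a project and all its samples, cells,
        measurement sets and entries; returns the number of entries removed.
        Feature sets are shared across projects and are retained."""
        if project_id not in self.catalog.projects:
            raise NotFoundError(f"unknown project id {project_id}")
        if project_id in self._open_txn_projects:
            raise ConflictError(f"project {project_id} has an open load")
        cat = self.catalog
        removed_entries = 0
        doomed_mids = [mid for mid, meta in self.chunk_meta.items()
                       if meta["project_id"] == project_id]
        for mid in doomed_mids:
            removed_entries += self.chunk_meta[mid]["n_entries"]
        for sid in list(cat.samples_by_project[project_id]):
            for cid in cat.cells_by_sample[sid]:
                cell = cat.cells.pop(cid)
                del cat.cell_by_key[(sid, cell.name)]
            del cat.cells_by_sample[sid]
            for mid in cat.msets_by_sample[sid]:
                cat.measurementsets.pop(mid, None)
            del cat.msets_by_sample[sid]
            sample = cat.samples.pop(sid)
            del cat.sample_by_key[(project_id, sample.name)]
        del cat.samples_by_project[project_id]
        proj = cat.projects.pop(project_id)
        del cat.project_by_name[proj.name]
        for mid in doomed_mids:
            del self.chunk_meta[mid]
            self._chunk_cache.pop(mid, None)
        self._commit_catalog()
        return removed_entries
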