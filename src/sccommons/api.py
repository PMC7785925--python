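"""REST surface over the commons: a plain WSGI application.

The service exposes the GET/PUT/POST/DELETE verbs needed to query, upload
and update data, versioned under ``/v1``:

========  =====================================  ==================================
method    route                                  action
========  =====================================  ==================================
GET       /v1/projects                           list projects
GET       /v1/projects/{name}                    one project with samples
POST      /v1/projects                           create a project
POST      /v1/projects/{name}/samples            upload a 10x bundle (JSON body
                                                 carrying the three files as text)
PUT       /v1/cells/tags                         bulk tag TSV update
POST      /v1/query/cells                        resolve a CellQuery, returns a
                                                 server-side cell-set id
GET       /v1/query/cells/{id}/expression        paged expression rows
GET       /v1/summary/celltypes                  prevalence table for a cell set
DELETE    /v1/projects/{name}                    remove a project and its data
========  =====================================  ==================================

Cell sets created by ``POST /v1/query/cells`` are named server-side
resources with a TTL so later requests can refine or fetch them.  Errors
are structured JSON ``{code, message, location}``; validation problems are
4xx, store faults 5xx.  No authentication; bind to localhost.
"""

from __future__ import annotations

import io
import json
import tempfile
import time
import urllib.parse
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from .array_store import Store
from .core_model import (CommonsError, ConflictError, FormatError,
                         IntegrityError, NotFoundError, ReferentialError,
                         UniquenessError, ValidationError)
from .ingest_10x import apply_cell_tag_tsv, load_bundle, read_10x_dir
from .ontology import load_packaged
from .query_engine import CellSet, QueryEngine, query_from_json
from .summarize import celltype_prevalence

__all__ = ["ApiConfig", "CommonsApp", "make_app", "call_app", "serve"]

_STATUS = {
    ValidationError: 400, FormatError: 400, UniquenessError: 409,
    ReferentialError: 400, NotFoundError: 404, ConflictError: 409,
    IntegrityError: 500,
}

_REASONS = {200: "OK", 201: "Created", 400: "Bad Request", 404: "Not Found",
            405: "Method Not Allowed", 409: "Conflict", 500: "Internal Server Error"}


@dataclass
class ApiConfig:
    store_path: str = "store"
    host: str = "127.0.0.1"
    port: int = 8050
    page_size: int = 10000            # max result rows per expression page
    default_matrix_kind: str = "normalized"
    ontology_paths: dict = field(default_factory=dict)  # prefix -> OBO path
    cellset_ttl_seconds: float = 3600.0

    def __post_init__(self):
        if self.page_size < 1:
            raise ValidationError("page_size must be >= 1")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "ApiConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


class CommonsApp:
    """WSGI application bound to one open store."""

    def __init__(self, store: Store, config: Optional[ApiConfig] = None):
        self.store = store
        self.config = config or ApiConfig(store_path=str(store.path))
        ontologies = {}
        for prefix, path in self.config.ontology_paths.items():
            from .ontology import load_obo
            ontologies[prefix] = load_obo(path)
        if not ontologies:
            ontologies = {p: load_packaged(n) for p, n in
                          (("CL", "cl"), ("UBERON", "uberon"), ("DOID", "doid"))}
        self.engine = QueryEngine(store, ontologies)
        self._cellsets: dict[str, tuple[CellSet, float]] = {}
        self._cellset_seq = 0

    # -- WSGI ---------------------------------------------------------------

    def __call__(self, environ, start_response):
        method = environ["REQUEST_METHOD"]
        path = environ.get("PATH_INFO", "/")
        query = urllib.parse.parse_qs(environ.get("QUERY_STRING", ""))
        try:
            body = None
            if method in ("POST", "PUT"):
                length = int(environ.get("CONTENT_LENGTH") or 0)
                raw = environ["wsgi.input"].read(length) if length else b""
                if raw:
                    try:
                        body = json.loads(raw)
                    except json.JSONDecodeError as e:
                        raise ValidationError(f"request body is not valid JSON: {e}")
            status, payload = self._route(method, path, query, body)
        except CommonsError as e:
            status = _STATUS.get(type(e), 400)
            payload = {"code": type(e).__name__, "message": str(e), "location": path}
        except Exception as e:  # store faults and bugs -> 5xx
            status = 500
            payload = {"code": "InternalError", "message": str(e), "location": path}
        data = json.dumps(payload).encode()
        start_response(f"{status} {_REASONS.get(status, 'Error')}",
                       [("Content-Type", "application/json"),
                        ("Content-Length", str(len(data)))])
        return [data]

    # -- routing ------------------------------------------------------------

    def _route(self, method: str, path: str, query: dict, body):
        parts = [p for p in path.split("/") if p]
        if not parts or parts[0] != "v1":
            raise NotFoundError(f"unknown route {path}")
        parts = parts[1:]

        if parts == ["projects"]:
            if method == "GET":
                return 200, self._list_projects()
            if method == "POST":
                return 201, self._create_project(body or {})
        if len(parts) == 2 and parts[0] == "projects":
            name = urllib.parse.unquote(parts[1])
            if method == "GET":
                return 200, self._get_project(name)
            if method == "DELETE":
                pid = self.store.catalog.project_id_by_name(name)
                removed = self.store.delete_project_data(pid)
                return 200, {"entries_removed": removed}
        if len(parts) == 3 and parts[0] == "projects" and parts[2] == "samples" \
                and method == "POST":
            return 201, self._upload_sample(urllib.parse.unquote(parts[1]), body or {})
        if parts == ["cells", "tags"] and method == "PUT":
            return 200, self._put_tags(body or {})
        if parts == ["query", "cells"] and method == "POST":
            return 201, self._post_query(body or {})
        if len(parts) == 4 and parts[:2] == ["query", "cells"] \
                and parts[3] == "expression" and method == "GET":
            return 200, self._get_expression(parts[2], query)
        if parts == ["summary", "celltypes"] and method == "GET":
            return 200, self._get_summary(query)
        raise NotFoundError(f"unknown route {method} {path}")

    # -- handlers -----------------------------------------------------------

    def _list_projects(self):
        cat = self.store.catalog
        out = []
        for pid in sorted(cat.projects):
            p = cat.projects[pid]
            out.append({"project_id": pid, "name": p.name,
                        "description": p.description,
                        "n_samples": len(cat.samples_by_project[pid]),
                        "n_cells": len(cat.cells_of_project(pid))})
        return out

    def _get_project(self, name: str):
        cat = self.store.catalog
        pid = cat.project_id_by_name(name)
        p = cat.projects[pid]
        samples = []
        for sid in cat.samples_by_project[pid]:
            s = cat.samples[sid]
            samples.append({"sample_id": sid, "name": s.name, "tags": s.tags,
                            "n_cells": len(cat.cells_by_sample[sid])})
        return {"project_id": pid, "name": p.name, "description": p.description,
                "tags": p.tags, "n_cells": len(cat.cells_of_project(pid)),
                "samples": samples}

    def _create_project(self, body: dict):
        if "name" not in body:
            raise ValidationError("project creation needs a 'name'")
        pid = self.store.register_project(body["name"],
                                          body.get("description", ""),
                                          tags=body.get("tags"))
        return {"project_id": pid, "name": body["name"]}

    def _upload_sample(self, project_name: str, body: dict):
        for k in ("sample_name", "matrix_mtx", "features_tsv", "barcodes_tsv"):
            if k not in body:
                raise ValidationError(f"sample upload needs field {k!r}")
        pid = self.store.catalog.project_id_by_name(project_name)
        kind = body.get("matrix_kind", self.config.default_matrix_kind)
        with tempfile.TemporaryDirectory() as tmp:
            tmpdir = Path(tmp)
            (tmpdir / "matrix.mtx").write_text(body["matrix_mtx"])
            (tmpdir / "features.tsv").write_text(body["features_tsv"])
            (tmpdir / "barcodes.tsv").write_text(body["barcodes_tsv"])
            tags_path = None
            if body.get("tags_tsv"):
                tags_path = tmpdir / "tags.tsv"
                tags_path.write_text(body["tags_tsv"])
            bundle = read_10x_dir(tmpdir)
            sid, mid, n_cells, n_entries = load_bundle(
                self.store, pid, body["sample_name"], bundle, kind,
                cell_tags_tsv=tags_path, sample_tags=body.get("sample_tags"))
        return {"sample_id": sid, "measurementset_id": mid,
                "n_cells": n_cells, "n_entries": n_entries}

    def _put_tags(self, body: dict):
        for k in ("project", "sample", "tags_tsv"):
            if k not in body:
                raise ValidationError(f"tag update needs field {k!r}")
        cat = self.store.catalog
        pid = cat.project_id_by_name(body["project"])
        key = (pid, body["sample"])
        if key not in cat.sample_by_key:
            raise NotFoundError(f"unknown sample {body['sample']!r}")
        with tempfile.NamedTemporaryFile("wt", suffix=".tsv", delete=False) as fh:
            fh.write(body["tags_tsv"])
            tmp = fh.name
        try:
            n = apply_cell_tag_tsv(self.store, cat.sample_by_key[key], tmp)
        finally:
            Path(tmp).unlink(missing_ok=True)
        return {"n_updated": n}

    def _purge_cellsets(self) -> None:
        now = time.monotonic()
        for cid in [k for k, (_, exp) in self._cellsets.items() if exp < now]:
            del self._cellsets[cid]

    def _post_query(self, body: dict):
        self._purge_cellsets()
        q = query_from_json(body)
        base_id = body.get("base")
        if base_id is not None:
            if base_id not in self._cellsets:
                raise NotFoundError(f"unknown or expired cell set {base_id!r}")
            import dataclasses
            q = dataclasses.replace(q, base=self._cellsets[base_id][0])
        cs = self.engine.select_cells(q)
        self._cellset_seq += 1
        cs_id = f"cs-{self._cellset_seq}"
        self._cellsets[cs_id] = (cs, time.monotonic() + self.config.cellset_ttl_seconds)
        return {"cellset_id": cs_id, "n_cells": len(cs),
                "n_projects_with_data": cs.n_projects_with_data}

    def _cellset(self, cs_id: str) -> CellSet:
        self._purge_cellsets()
        if cs_id not in self._cellsets:
            raise NotFoundError(f"unknown or expired cell set {cs_id!r}")
        return self._cellsets[cs_id][0]

    def _get_expression(self, cs_id: str, query: dict):
        cs = self._cellset(cs_id)
        kind = query.get("kind", [self.config.default_matrix_kind])[0]
        genes_param = query.get("genes", ["all"])[0]
        genes = None if genes_param == "all" else genes_param.split(",")
        page = int(query.get("page", ["0"])[0])
        page_size = min(int(query.get("page_size", [str(self.config.page_size)])[0]),
                        self.config.page_size)
        if page < 0 or page_size < 1:
            raise ValidationError("page must be >= 0 and page_size >= 1")
        start, stop = page * page_size, (page + 1) * page_size
        rows = []
        has_more = False
        for i, row in enumerate(self.engine.fetch_expression(cs, genes, kind)):
            if i >= stop:
                has_more = True
                break
            if i >= start:
                rows.append(list(row))
        return {"rows": rows, "page": page, "page_size": page_size,
                "has_more": has_more}

    def _get_summary(self, query: dict):
        if "cellset" not in query:
            raise ValidationError("summary needs a 'cellset' parameter")
        cs = self._cellset(query["cellset"][0])
        key = query.get("key", ["CellType.select"])[0]
        min_pct = float(query.get("min_pct", ["1.0"])[0])
        table = celltype_prevalence(self.store, cs, key, min_pct)
        return json.loads(table.to_json())


def make_app(config: ApiConfig) -> CommonsApp:
    path = Path(config.store_path)
    store = Store.open(path) if (path / "manifest.json").exists() else Store.create(path)
    return CommonsApp(store, config)


def call_app(app: CommonsApp, method: str, path: str, body=None):
    """Drive the WSGI app in-process; returns (status_code, parsed JSON).

    Used by the test-suite and anywhere library/REST parity matters."""
    path, _, qs = path.partition("?")
    raw = json.dumps(body).encode() if body is not None else b""
    environ = {
        "REQUEST_METHOD": method, "PATH_INFO": path, "QUERY_STRING": qs,
        "CONTENT_LENGTH": str(len(raw)), "wsgi.input": io.BytesIO(raw),
        "SERVER_NAME": "localhost", "SERVER_PORT": "0",
        "wsgi.url_scheme": "http",
    }
    captured = {}

    def start_response(status, headers):
        captured["status"] = int(status.split()[0])

    chunks = app(environ, start_response)
    data = b"".join(chunks)
    return captured["status"], json.loads(data) if data else None


def serve(config: ApiConfig):  # pragma: no cover - manual entry point
    """Run the service with wsgiref until interrupted."""
    from wsgiref.simple_server import make_server
    app = make_app(config)
    with make_server(config.host, config.port, app) as httpd:
        print(f"serving on http://{config.host}:{config.port}/v1/projects")
        httpd.serve_forever()
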