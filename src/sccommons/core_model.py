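"""Entity hierarchy, tag model and the registry of stable integer ids.

The commons organises data as project -> sample -> cell, with features
grouped into feature sets and each loaded matrix bound to a sample by a
measurement set.  Every entity carries an open key-value tag map
(:class:`TagSet`) holding whatever metadata the source study shipped
(``DOID``, ``UBERONID``, ``CL ID``, ``percent.mt``, cell-type labels under
heterogeneous key names, ...).  Surrogate ids are 0-based, dense and
assigned in insertion order so they double as array coordinates.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pandas as pd

__all__ = [
    "CommonsError",
    "NotFoundError",
    "UniquenessError",
    "ReferentialError",
    "ValidationError",
    "FormatError",
    "IntegrityError",
    "ConflictError",
    "TagValue",
    "TagSet",
    "Project",
    "Sample",
    "Cell",
    "Feature",
    "FeatureSet",
    "MeasurementSet",
    "MATRIX_KINDS",
    "Catalog",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class CommonsError(Exception):
    """Base class for all errors raised by the commons."""


class NotFoundError(CommonsError):
    """A referenced entity, term or resource does not exist."""


class UniquenessError(CommonsError):
    """A name or key collides with an existing entity."""


class ReferentialError(CommonsError):
    """A parent/foreign reference does not resolve."""


class ValidationError(CommonsError):
    """Input violates a contract (bad value, malformed query, ...)."""


class FormatError(CommonsError):
    """A file does not conform to its declared format."""


class IntegrityError(CommonsError):
    """A store-level consistency rule would be violated."""


class ConflictError(CommonsError):
    """A concurrent operation holds a resource (e.g. an open load)."""


# ---------------------------------------------------------------------------
# Tags
# ---------------------------------------------------------------------------

TagValue = Union[str, int, float]
#: Open key->value metadata map; keys are case-sensitive and stored verbatim.
TagSet = dict

_NUMBER_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def coerce_tag_value(text: str) -> TagValue:
    """Parse a TSV cell into a tag value: numeric-looking text becomes a
    float (so QC tags like ``percent.mt`` support range filters), everything
    else stays a verbatim string."""
    if _NUMBER_RE.match(text):
        return float(text)
    return text


def _check_tags(tags: Mapping[str, TagValue]) -> dict:
    out = {}
    for k, v in tags.items():
        if not isinstance(k, str) or not k:
            raise ValidationError(f"tag keys must be non-empty strings, got {k!r}")
        if not isinstance(v, (str, int, float)) or isinstance(v, bool):
            raise ValidationError(f"tag value for {k!r} must be string or number, got {type(v).__name__}")
        out[k] = v
    return out


# ---------------------------------------------------------------------------
# Entities
# ---------------------------------------------------------------------------

@dataclass
class Project:
    project_id: int
    name: str
    description: str = ""
    public: bool = True
    tags: TagSet = field(default_factory=dict)


@dataclass
class Sample:
    sample_id: int
    project_id: int
    name: str
    description: str = ""
    tags: TagSet = field(default_factory=dict)


@dataclass
class Cell:
    cell_id: int
    sample_id: int
    name: str  # barcode
    tags: TagSet = field(default_factory=dict)


@dataclass
class FeatureSet:
    featureset_id: int
    genome_build: str = "GRCh38"
    reference_model: str = ""
    table_hash: str = ""  # content hash of the feature table, for reuse on load


@dataclass
class Feature:
    feature_id: int
    featureset_id: int
    ensembl_id: str
    gene_symbol: str
    chromosome: str = ""
    start: str = ""
    end: str = ""
    feature_type: str = "Gene Expression"
    source: str = ""


MATRIX_KINDS = ("raw", "normalized")


@dataclass
class MeasurementSet:
    measurementset_id: int
    sample_id: int
    featureset_id: int
    name: str = ""
    description: str = ""
    matrix_kind: str = "normalized"


_ENTITY_KINDS = ("project", "sample", "cell", "feature", "featureset", "measurementset")


# ---------------------------------------------------------------------------
# Catalog
# ---------------------------------------------------------------------------

class Catalog:
    """In-memory registry of all entities plus the id counters.

    The catalog is the source of truth for identity and metadata; expression
    values live in the array store.  It is cheap to deep-copy, which the
    store exploits to give load transactions a shadow catalog.
    """

    def __init__(self) -> None:
        self.projects: dict[int, Project] = {}
        self.samples: dict[int, Sample] = {}
        self.cells: dict[int, Cell] = {}
        self.features: dict[int, Feature] = {}
        self.featuresets: dict[int, FeatureSet] = {}
        self.measurementsets: dict[int, MeasurementSet] = {}
        self._counters: dict[str, int] = {k: 0 for k in _ENTITY_KINDS}
        # secondary indexes (ids only, rebuilt on load)
        self.project_by_name: dict[str, int] = {}
        self.sample_by_key: dict[tuple[int, str], int] = {}
        self.cell_by_key: dict[tuple[int, str], int] = {}
        self.featureset_by_hash: dict[str, int] = {}
        self.samples_by_project: dict[int, list[int]] = {}
        self.cells_by_sample: dict[int, list[int]] = {}
        self.msets_by_sample: dict[int, list[int]] = {}
        self.features_by_set: dict[int, list[int]] = {}

    # -- id assignment ------------------------------------------------------

    def _next_id(self, kind: str) -> int:
        i = self._counters[kind]
        self._counters[kind] = i + 1
        return i

    # -- registration -------------------------------------------------------

    def register_project(self, name: str, description: str = "",
                         public: bool = True, tags: Optional[Mapping] = None) -> int:
        if not name:
            raise ValidationError("project name must be non-empty")
        if name in self.project_by_name:
            raise UniquenessError(f"project name {name!r} already exists")
        pid = self._next_id("project")
        self.projects[pid] = Project(pid, name, description, public, _check_tags(tags or {}))
        self.project_by_name[name] = pid
        self.samples_by_project[pid] = []
        return pid

    def register_sample(self, project_id: int, name: str, description: str = "",
                        tags: Optional[Mapping] = None) -> int:
        if project_id not in self.projects:
            raise ReferentialError(f"unknown project id {project_id}")
        key = (project_id, name)
        if key in self.sample_by_key:
            raise UniquenessError(f"sample {name!r} already exists in project {project_id}")
        sid = self._next_id("sample")
        self.samples[sid] = Sample(sid, project_id, name, description, _check_tags(tags or {}))
        self.sample_by_key[key] = sid
        self.samples_by_project[project_id].append(sid)
        self.cells_by_sample[sid] = []
        self.msets_by_sample[sid] = []
        return sid

    def register_cell(self, sample_id: int, name: str,
                      tags: Optional[Mapping] = None) -> int:
        if sample_id not in self.samples:
            raise ReferentialError(f"unknown sample id {sample_id}")
        key = (sample_id, name)
        if key in self.cell_by_key:
            raise UniquenessError(f"cell barcode {name!r} already exists in sample {sample_id}")
        cid = self._next_id("cell")
        self.cells[cid] = Cell(cid, sample_id, name, _check_tags(tags or {}))
        self.cell_by_key[key] = cid
        self.cells_by_sample[sample_id].append(cid)
        return cid

    def register_featureset(self, genome_build: str = "GRCh38",
                            reference_model: str = "", table_hash: str = "") -> int:
        fsid = self._next_id("featureset")
        self.featuresets[fsid] = FeatureSet(fsid, genome_build, reference_model, table_hash)
        if table_hash:
            self.featureset_by_hash[table_hash] = fsid
        self.features_by_set[fsid] = []
        return fsid

    def register_feature(self, featureset_id: int, ensembl_id: str, gene_symbol: str,
                         chromosome: str = "", start: str = "", end: str = "",
                         feature_type: str = "Gene Expression", source: str = "") -> int:
        if featureset_id not in self.featuresets:
            raise ReferentialError(f"unknown featureset id {featureset_id}")
        for fid in self.features_by_set[featureset_id]:
            if self.features[fid].ensembl_id == ensembl_id:
                raise UniquenessError(
                    f"ensembl id {ensembl_id!r} already in featureset {featureset_id}")
        fid = self._next_id("feature")
        self.features[fid] = Feature(fid, featureset_id, ensembl_id, gene_symbol,
                                     chromosome, start, end, feature_type, source)
        self.features_by_set[featureset_id].append(fid)
        return fid

    def register_measurementset(self, sample_id: int, featureset_id: int,
                                matrix_kind: str, name: str = "",
                                description: str = "") -> int:
        if sample_id not in self.samples:
            raise ReferentialError(f"unknown sample id {sample_id}")
        if featureset_id not in self.featuresets:
            raise ReferentialError(f"unknown featureset id {featureset_id}")
        if matrix_kind not in MATRIX_KINDS:
            raise ValidationError(f"matrix_kind must be one of {MATRIX_KINDS}, got {matrix_kind!r}")
        mid = self._next_id("measurementset")
        self.measurementsets[mid] = MeasurementSet(mid, sample_id, featureset_id,
                                                   name, description, matrix_kind)
        self.msets_by_sample[sample_id].append(mid)
        return mid

    def register_entity(self, kind: str, parent_id: Optional[int], name: str,
                        tags: Optional[Mapping] = None) -> int:
        """Generic registration for the hierarchy kinds (project/sample/cell)."""
        if kind == "project":
            return self.register_project(name, tags=tags)
        if kind == "sample":
            if parent_id is None:
                raise ReferentialError("sample requires a parent project id")
            return self.register_sample(parent_id, name, tags=tags)
        if kind == "cell":
            if parent_id is None:
                raise ReferentialError("cell requires a parent sample id")
            return self.register_cell(parent_id, name, tags=tags)
        raise ValidationError(f"register_entity supports project/sample/cell, got {kind!r}")

    # -- lookup -------------------------------------------------------------

    def _table(self, kind: str) -> dict:
        return {"project": self.projects, "sample": self.samples, "cell": self.cells,
                "feature": self.features, "featureset": self.featuresets,
                "measurementset": self.measurementsets}[kind]

    def get(self, kind: str, entity_id: int):
        table = self._table(kind)
        if entity_id not in table:
            raise NotFoundError(f"unknown {kind} id {entity_id}")
        return table[entity_id]

    def project_id_by_name(self, name: str) -> int:
        if name not in self.project_by_name:
            raise NotFoundError(f"unknown project {name!r}")
        return self.project_by_name[name]

    def project_of_cell(self, cell_id: int) -> int:
        return self.samples[self.cells[cell_id].sample_id].project_id

    def cells_of_project(self, project_id: int) -> list[int]:
        if project_id not in self.projects:
            raise NotFoundError(f"unknown project id {project_id}")
        out: list[int] = []
        for sid in self.samples_by_project[project_id]:
            out.extend(self.cells_by_sample[sid])
        return out

    def features_by_symbol(self, symbol: str) -> list[int]:
        return [fid for fid, f in self.features.items() if f.gene_symbol == symbol]

    def features_by_ensembl(self, ensembl_id: str) -> list[int]:
        return [fid for fid, f in self.features.items() if f.ensembl_id == ensembl_id]

    # -- tags ---------------------------------------------------------------

    def upsert_tags(self, kind: str, entity_id: int, tags: Mapping[str, TagValue]) -> TagSet:
        """Merge ``tags`` into the entity's tag map (new keys added, existing
        overwritten, others untouched).  Validates before mutating so the
        update is atomic per entity.  Idempotent."""
        entity = self.get(kind, entity_id)
        if not hasattr(entity, "tags"):
            raise ValidationError(f"{kind} entities do not carry tags")
        checked = _check_tags(tags)
        entity.tags.update(checked)
        return dict(entity.tags)

    def list_tag_keys(self, kind: str, project_id: Optional[int] = None) -> pd.DataFrame:
        """Table of (key, n_entities) over all entities of ``kind``,
        optionally restricted to one project."""
        if project_id is not None and project_id not in self.projects:
            raise NotFoundError(f"unknown project id {project_id}")
        if kind == "project":
            entities = self.projects.values()
            if project_id is not None:
                entities = [self.projects[project_id]]
        elif kind == "sample":
            entities = self.samples.values()
            if project_id is not None:
                entities = [self.samples[s] for s in self.samples_by_project[project_id]]
        elif kind == "cell":
            entities = self.cells.values()
            if project_id is not None:
                entities = [self.cells[c] for c in self.cells_of_project(project_id)]
        else:
            raise ValidationError(f"list_tag_keys supports project/sample/cell, got {kind!r}")
        counts: dict[str, int] = {}
        for e in entities:
            for k in e.tags:
                counts[k] = counts.get(k, 0) + 1
        df = pd.DataFrame(sorted(counts.items()), columns=["key", "n_entities"])
        return df

    # -- integrity ----------------------------------------------------------

    def check_referential(self) -> None:
        """Full-scan referential integrity check; raises on the first hole."""
        for s in self.samples.values():
            if s.project_id not in self.projects:
                raise IntegrityError(f"sample {s.sample_id} references missing project {s.project_id}")
        for c in self.cells.values():
            if c.sample_id not in self.samples:
                raise IntegrityError(f"cell {c.cell_id} references missing sample {c.sample_id}")
        for f in self.features.values():
            if f.featureset_id not in self.featuresets:
                raise IntegrityError(f"feature {f.feature_id} references missing featureset {f.featureset_id}")
        for m in self.measurementsets.values():
            if m.sample_id not in self.samples:
                raise IntegrityError(f"measurementset {m.measurementset_id} references missing sample {m.sample_id}")
            if m.featureset_id not in self.featuresets:
                raise IntegrityError(f"measurementset {m.measurementset_id} references missing featureset {m.featureset_id}")

    # -- persistence --------------------------------------------------------
    #
    # Plain-text TSV tables plus a JSON counters file.  Tags live in one long
    # table (kind, entity_id, key, value, vtype) so arbitrary keys survive
    # round-trips bit-exactly: numbers are written with repr() and re-parsed
    # as floats/ints, strings verbatim.

    _ENTITY_COLUMNS = {
        "projects": ["project_id", "name", "description", "public"],
        "samples": ["sample_id", "project_id", "name", "description"],
        "cells": ["cell_id", "sample_id", "name"],
        "featuresets": ["featureset_id", "genome_build", "reference_model", "table_hash"],
        "features": ["feature_id", "featureset_id", "ensembl_id", "gene_symbol",
                     "chromosome", "start", "end", "feature_type", "source"],
        "measurementsets": ["measurementset_id", "sample_id", "featureset_id",
                            "name", "description", "matrix_kind"],
    }

    def to_dir(self, path: Union[str, Path]) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)

        def dump(fname: str, rows: Iterable, cols: list[str]) -> None:
            df = pd.DataFrame([{c: getattr(r, c) for c in cols} for r in rows], columns=cols)
            df = df.sort_values(cols[0]) if len(df) else df
            df.to_csv(path / fname, sep="\t", index=False)

        dump("projects.tsv", self.projects.values(), self._ENTITY_COLUMNS["projects"])
        dump("samples.tsv", self.samples.values(), self._ENTITY_COLUMNS["samples"])
        dump("cells.tsv", self.cells.values(), self._ENTITY_COLUMNS["cells"])
        dump("featuresets.tsv", self.featuresets.values(), self._ENTITY_COLUMNS["featuresets"])
        dump("features.tsv", self.features.values(), self._ENTITY_COLUMNS["features"])
        dump("measurementsets.tsv", self.measurementsets.values(),
             self._ENTITY_COLUMNS["measurementsets"])

        tag_rows = []
        for kind in ("project", "sample", "cell"):
            table = self._table(kind)
            id_attr = f"{kind}_id"
            for eid in sorted(table):
                for k, v in table[eid].tags.items():
                    if isinstance(v, bool):  # excluded at _check_tags; belt and braces
                        v = str(v)
                    vtype = "number" if isinstance(v, (int, float)) else "string"
                    text = repr(v) if vtype == "number" else v
                    tag_rows.append((kind, eid, k, text, vtype))
            del id_attr
        pd.DataFrame(tag_rows, columns=["kind", "entity_id", "key", "value", "vtype"]) \
            .to_csv(path / "tags.tsv", sep="\t", index=False)

        (path / "counters.json").write_text(json.dumps(self._counters, sort_keys=True))

    @classmethod
    def from_dir(cls, path: Union[str, Path]) -> "Catalog":
        path = Path(path)
        cat = cls()

        def read(fname: str) -> pd.DataFrame:
            return pd.read_csv(path / fname, sep="\t", dtype=str, keep_default_na=False)

        for _, r in read("projects.tsv").iterrows():
            pid = int(r.project_id)
            cat.projects[pid] = Project(pid, r["name"], r.description, r.public == "True")
            cat.project_by_name[r["name"]] = pid
            cat.samples_by_project[pid] = []
        for _, r in read("samples.tsv").iterrows():
            sid = int(r.sample_id)
            pid = int(r.project_id)
            cat.samples[sid] = Sample(sid, pid, r["name"], r.description)
            cat.sample_by_key[(pid, r["name"])] = sid
            cat.samples_by_project[pid].append(sid)
            cat.cells_by_sample[sid] = []
            cat.msets_by_sample[sid] = []
        for _, r in read("cells.tsv").iterrows():
            cid = int(r.cell_id)
            sid = int(r.sample_id)
            cat.cells[cid] = Cell(cid, sid, r["name"])
            cat.cell_by_key[(sid, r["name"])] = cid
            cat.cells_by_sample[sid].append(cid)
        for _, r in read("featuresets.tsv").iterrows():
            fsid = int(r.featureset_id)
            cat.featuresets[fsid] = FeatureSet(fsid, r.genome_build, r.reference_model, r.table_hash)
            if r.table_hash:
                cat.featureset_by_hash[r.table_hash] = fsid
            cat.features_by_set[fsid] = []
        for _, r in read("features.tsv").iterrows():
            fid = int(r.feature_id)
            fsid = int(r.featureset_id)
            cat.features[fid] = Feature(fid, fsid, r.ensembl_id, r.gene_symbol,
                                        r.chromosome, r.start, r.end, r.feature_type, r.source)
            cat.features_by_set[fsid].append(fid)
        for _, r in read("measurementsets.tsv").iterrows():
            mid = int(r.measurementset_id)
            sid = int(r.sample_id)
            cat.measurementsets[mid] = MeasurementSet(mid, sid, int(r.featureset_id),
                                                      r["name"], r.description, r.matrix_kind)
            cat.msets_by_sample[sid].append(mid)

        for _, r in read("tags.tsv").iterrows():
            table = cat._table(r.kind)
            eid = int(r.entity_id)
            if r.vtype == "number":
                v: TagValue = float(r.value)
                if v.is_integer() and "." not in r.value and "e" not in r.value.lower():
                    v = int(v)
            else:
                v = r.value
            table[eid].tags[r.key] = v

        cat._counters = json.loads((path / "counters.json").read_text())
        return cat

    def __deepcopy__(self, memo):
        import copy
        new = Catalog.__new__(Catalog)
        for k, v in self.__dict__.items():
            new.__dict__[k] = copy.deepcopy(v, memo)
        return new
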