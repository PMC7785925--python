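"""Composable cell-selection queries and expression retrieval.

A :class:`CellQuery` is a conjunction of filters over the project ->
sample -> cell hierarchy:

* :class:`TagFilter` — key/value metadata at project, sample or cell level,
  either an any-of value set or a numeric range (for QC tags such as
  ``percent.mt``);
* :class:`OntologyFilter` — a controlled-vocabulary term expanded through
  the loaded ontology to its descendants or ancestors, then applied as an
  any-of tag filter;
* :class:`ExpressionFilter` — a per-gene predicate (>= t, > t, <= t, < t,
  within [a, b]) on raw or normalized values, where a coordinate absent
  from the sparse store counts as 0.

Disjunction is expressed through any-of value sets; co-expression of a gene
list is the conjunction of per-gene threshold filters and therefore equals
the intersection of the single-gene results.  A query may refine a previous
result (``base``), which restricts the search universe — the composition
used to search expression on a previously selected cell population.

Gene symbols may map to several features; a cell passes a gene predicate if
any matching feature does (public data are mostly symbol-annotated, and
symbol duplication is real).  A cell lacking a filtered tag key fails that
filter: absence is not a wildcard.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, NamedTuple, Optional, Sequence, Union

from .array_store import Store
from .core_model import NotFoundError, ValidationError
from .ontology import Ontology, ancestors, descendants

__all__ = [
    "NumericRange",
    "TagFilter",
    "OntologyFilter",
    "ExpressionFilter",
    "CellQuery",
    "CellSet",
    "ExpressionRow",
    "QueryEngine",
    "query_to_json",
    "query_from_json",
]


# ---------------------------------------------------------------------------
# Filter types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NumericRange:
    low: float
    high: float
    incl_low: bool = True
    incl_high: bool = True

    def __post_init__(self):
        if self.low > self.high:
            raise ValidationError(f"numeric range low {self.low} > high {self.high}")

    def contains(self, v: float) -> bool:
        lo = v >= self.low if self.incl_low else v > self.low
        hi = v <= self.high if self.incl_high else v < self.high
        return lo and hi


@dataclass(frozen=True)
class TagFilter:
    entity_level: str                      # project | sample | cell
    key: str
    values: Optional[frozenset] = None     # any-of set of strings
    numeric_range: Optional[NumericRange] = None

    def __post_init__(self):
        if self.entity_level not in ("project", "sample", "cell"):
            raise ValidationError(f"bad entity_level {self.entity_level!r}")
        if (self.values is None) == (self.numeric_range is None):
            raise ValidationError("exactly one of values / numeric_range must be set")
        if self.values is not None:
            if not self.values:
                raise ValidationError("any-of value set must be non-empty")
            object.__setattr__(self, "values", frozenset(str(v) for v in self.values))

    def matches(self, tags: dict) -> bool:
        if self.key not in tags:
            return False
        v = tags[self.key]
        if self.values is not None:
            return str(v) in self.values
        try:
            return self.numeric_range.contains(float(v))
        except (TypeError, ValueError):
            return False


@dataclass(frozen=True)
class OntologyFilter:
    entity_level: str                      # sample | cell
    key: str                               # e.g. "CL ID", "UBERONID", "DOID"
    term: str                              # CURIE
    expand: str = "none"                   # none | descendants | ancestors

    def __post_init__(self):
        if self.entity_level not in ("sample", "cell"):
            raise ValidationError(f"bad entity_level {self.entity_level!r}")
        if self.expand not in ("none", "descendants", "ancestors"):
            raise ValidationError(f"bad expand mode {self.expand!r}")


_PRED_OPS = ("ge", "gt", "le", "lt", "within")


@dataclass(frozen=True)
class ExpressionFilter:
    gene: Union[str, dict]                 # symbol, or {"gene_symbol"|"ensembl_id": ...}
    matrix_kind: str = "normalized"
    op: str = "ge"
    threshold: Optional[float] = None      # for ge/gt/le/lt
    low: Optional[float] = None            # for within
    high: Optional[float] = None

    def __post_init__(self):
        if self.op not in _PRED_OPS:
            raise ValidationError(f"bad predicate op {self.op!r}")
        if self.op == "within":
            if self.low is None or self.high is None:
                raise ValidationError("within predicate needs low and high")
            if not (math.isfinite(self.low) and math.isfinite(self.high)):
                raise ValidationError("thresholds must be finite")
            if self.low > self.high:
                raise ValidationError("within range requires low <= high")
        else:
            if self.threshold is None or not math.isfinite(self.threshold):
                raise ValidationError("threshold must be a finite number")

    def predicate(self, v: float) -> bool:
        if self.op == "ge":
            return v >= self.threshold
        if self.op == "gt":
            return v > self.threshold
        if self.op == "le":
            return v <= self.threshold
        if self.op == "lt":
            return v < self.threshold
        return self.low <= v <= self.high


Filter = Union[TagFilter, OntologyFilter, ExpressionFilter]


@dataclass(frozen=True)
class CellQuery:
    filters: tuple = ()
    project_scope: Optional[frozenset] = None      # project names or ids; None = all
    base: Optional["CellSet"] = None               # restricts the search universe
    fetch_genes: Optional[Union[str, tuple]] = None  # "all" or gene list; used by
    # workload replay to fetch expression for the selected cells

    def __post_init__(self):
        object.__setattr__(self, "filters", tuple(self.filters))
        if self.project_scope is not None:
            object.__setattr__(self, "project_scope", frozenset(self.project_scope))
        if isinstance(self.fetch_genes, (list, tuple)):
            object.__setattr__(self, "fetch_genes", tuple(self.fetch_genes))


@dataclass(frozen=True)
class CellSet:
    """A resolved selection: cell ids plus provenance and the number of
    distinct projects contributing members."""
    cell_ids: frozenset
    provenance: dict = field(compare=False, default_factory=dict)
    n_projects_with_data: int = 0

    def __len__(self) -> int:
        return len(self.cell_ids)

    def __iter__(self):
        return iter(self.cell_ids)


class ExpressionRow(NamedTuple):
    project_id: int
    sample_id: int
    cell_id: int
    feature_id: int
    gene_symbol: str
    value: float


# ---------------------------------------------------------------------------
# JSON (de)serialisation of queries
# ---------------------------------------------------------------------------

def query_to_json(q: CellQuery) -> dict:
    filters = []
    for f in q.filters:
        if isinstance(f, TagFilter):
            d = {"type": "tag", "level": f.entity_level, "key": f.key}
            if f.values is not None:
                d["any_of"] = sorted(f.values)
            else:
                d["range"] = {"low": f.numeric_range.low, "high": f.numeric_range.high,
                              "incl": [f.numeric_range.incl_low, f.numeric_range.incl_high]}
            filters.append(d)
        elif isinstance(f, OntologyFilter):
            filters.append({"type": "ontology", "level": f.entity_level, "key": f.key,
                            "term": f.term, "expand": f.expand})
        elif isinstance(f, ExpressionFilter):
            d = {"type": "expression", "gene": f.gene, "kind": f.matrix_kind, "op": f.op}
            if f.op == "within":
                d["low"], d["high"] = f.low, f.high
            else:
                d["value"] = f.threshold
            filters.append(d)
        else:  # pragma: no cover - guarded by CellQuery construction
            raise ValidationError(f"unknown filter type {type(f).__name__}")
    out: dict = {"filters": filters}
    if q.project_scope is not None:
        out["project_scope"] = sorted(q.project_scope, key=str)
    if q.fetch_genes is not None:
        out["fetch_genes"] = (q.fetch_genes if q.fetch_genes == "all"
                              else list(q.fetch_genes))
    return out


def query_from_json(d: dict) -> CellQuery:
    if not isinstance(d, dict) or "filters" not in d:
        raise ValidationError("query JSON must be an object with a 'filters' array")
    filters: list[Filter] = []
    for fd in d["filters"]:
        t = fd.get("type")
        if t == "tag":
            rng = None
            vals = None
            if "range" in fd:
                r = fd["range"]
                incl = r.get("incl", [True, True])
                rng = NumericRange(float(r["low"]), float(r["high"]), incl[0], incl[1])
            else:
                vals = frozenset(fd["any_of"])
            filters.append(TagFilter(fd["level"], fd["key"], vals, rng))
        elif t == "ontology":
            filters.append(OntologyFilter(fd["level"], fd["key"], fd["term"],
                                          fd.get("expand", "none")))
        elif t == "expression":
            op = fd.get("op", "ge")
            if op == "within":
                filters.append(ExpressionFilter(fd["gene"], fd.get("kind", "normalized"),
                                                op, low=float(fd["low"]),
                                                high=float(fd["high"])))
            else:
                filters.append(ExpressionFilter(fd["gene"], fd.get("kind", "normalized"),
                                                op, threshold=float(fd["value"])))
        else:
            raise ValidationError(f"unknown filter type {t!r}")
    scope = d.get("project_scope")
    fetch = d.get("fetch_genes")
    if isinstance(fetch, list):
        fetch = tuple(fetch)
    return CellQuery(filters=tuple(filters),
                     project_scope=None if scope is None else frozenset(scope),
                     fetch_genes=fetch)


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------

class QueryEngine:
    """Evaluates queries against one store, with optional ontologies keyed
    by CURIE prefix (``{"CL": ..., "UBERON": ..., "DOID": ...}``)."""

    def __init__(self, store: Store, ontologies: Optional[dict] = None):
        self.store = store
        self.ontologies: dict[str, Ontology] = ontologies or {}

    # -- gene resolution ----------------------------------------------------

    def resolve_gene(self, selector: Union[str, dict]) -> list[int]:
        """Feature ids matching a gene selector; symbol lookup first, then
        ENSEMBL id for plain strings.  Empty list if nothing matches."""
        cat = self.store.catalog
        if isinstance(selector, dict):
            if "gene_symbol" in selector:
                return sorted(cat.features_by_symbol(selector["gene_symbol"]))
            if "ensembl_id" in selector:
                return sorted(cat.features_by_ensembl(selector["ensembl_id"]))
            raise ValidationError("gene selector dict needs gene_symbol or ensembl_id")
        fids = cat.features_by_symbol(selector)
        if not fids:
            fids = cat.features_by_ensembl(selector)
        return sorted(fids)

    # -- ontology expansion -------------------------------------------------

    def expand_ontology_filter(self, f: OntologyFilter) -> TagFilter:
        """Rewrite an ontology filter into an any-of tag filter over the
        requested closure of the term."""
        prefix = f.term.split(":", 1)[0]
        onto = self.ontologies.get(prefix)
        if onto is None:
            raise NotFoundError(f"no ontology loaded for prefix {prefix!r}")
        if f.term not in onto:
            raise NotFoundError(f"term {f.term!r} not in the {prefix} ontology")
        if f.expand == "none":
            terms = {f.term}
        elif f.expand == "descendants":
            terms = descendants(onto, f.term)
        else:
            terms = ancestors(onto, f.term)
        return TagFilter(f.entity_level, f.key, frozenset(terms))

    # -- scope and universe -------------------------------------------------

    def _resolve_scope(self, scope: Optional[Iterable]) -> list[int]:
        cat = self.store.catalog
        if scope is None:
            return sorted(cat.projects)
        pids = []
        for p in scope:
            if isinstance(p, str):
                pids.append(cat.project_id_by_name(p))
            else:
                if p not in cat.projects:
                    raise NotFoundError(f"unknown project id {p}")
                pids.append(int(p))
        return sorted(set(pids))

    # -- filter application -------------------------------------------------

    def _apply_tag_filter(self, universe: set, flt: TagFilter) -> set:
        cat = self.store.catalog
        if flt.entity_level == "cell":
            return {c for c in universe if flt.matches(cat.cells[c].tags)}
        if flt.entity_level == "sample":
            ok_samples = {sid for sid in {cat.cells[c].sample_id for c in universe}
                          if flt.matches(cat.samples[sid].tags)}
            return {c for c in universe if cat.cells[c].sample_id in ok_samples}
        pids = {cat.project_of_cell(c) for c in universe}
        ok_projects = {pid for pid in pids if flt.matches(cat.projects[pid].tags)}
        return {c for c in universe if cat.project_of_cell(c) in ok_projects}

    def _apply_expression_filter(self, universe: set, flt: ExpressionFilter,
                                 project_ids: Sequence[int],
                                 warnings: list[str]) -> set:
        fids = self.resolve_gene(flt.gene)
        if not fids:
            warnings.append(f"gene selector {flt.gene!r} matched no features")
            return set()
        pred = flt.predicate
        # gather stored values for the matching features; when the same
        # sample carries several measurement sets of one kind the latest wins
        vals: dict[tuple[int, int], float] = {}
        fidset = set(fids)
        for mid in self.store.measurementsets_for(flt.matrix_kind, list(project_ids)):
            index = self.store._chunk(mid).by_feature()
            for f in fidset:
                for c, v in index.get(f, ()):
                    vals[(c, f)] = v
        if pred(0.0):
            # implicit zeros pass: a cell fails only if every matching
            # feature has a stored, failing value
            nf = len(fidset)
            failing_count: dict[int, int] = {}
            passes_stored: set[int] = set()
            for (c, f), v in vals.items():
                if pred(v):
                    passes_stored.add(c)
                else:
                    failing_count[c] = failing_count.get(c, 0) + 1
            doomed = {c for c, n in failing_count.items()
                      if n == nf}
            return {c for c in universe if c not in doomed or c in passes_stored}
        passing = {c for (c, f), v in vals.items() if pred(v)}
        return universe & passing

    # -- main entry points --------------------------------------------------

    def select_cells(self, q: CellQuery) -> CellSet:
        """Resolve a query to the exact set of cells satisfying all filters.

        Membership is deterministic and independent of filter evaluation
        order (the query is a conjunction over a fixed universe)."""
        if not isinstance(q, CellQuery):
            raise ValidationError("select_cells expects a CellQuery")
        cat = self.store.catalog
        pids = self._resolve_scope(q.project_scope)
        universe: set[int] = set()
        for pid in pids:
            universe.update(cat.cells_of_project(pid))
        if q.base is not None:
            if not isinstance(q.base, CellSet):
                raise ValidationError("base must be a resolved CellSet")
            universe &= set(q.base.cell_ids)

        warnings: list[str] = []
        for flt in q.filters:
            if not universe:
                break
            if isinstance(flt, OntologyFilter):
                flt = self.expand_ontology_filter(flt)
            if isinstance(flt, TagFilter):
                universe = self._apply_tag_filter(universe, flt)
            elif isinstance(flt, ExpressionFilter):
                universe = self._apply_expression_filter(universe, flt, pids, warnings)
            else:
                raise ValidationError(f"unknown filter type {type(flt).__name__}")

        n_projects = len({cat.project_of_cell(c) for c in universe})
        prov = dict(query_to_json(replace(q, base=None)))
        if q.base is not None:
            prov["base_size"] = len(q.base)
        if warnings:
            prov["warnings"] = warnings
        return CellSet(frozenset(universe), prov, n_projects)

    def coexpression_cells(self, genes: Sequence[Union[str, dict]], threshold: float,
                           matrix_kind: str = "normalized",
                           scope: Optional[Iterable] = None) -> CellSet:
        """Cells in which every listed gene is at or above ``threshold``.

        Equals the intersection of the single-gene results; a single gene
        degenerates to a plain threshold filter."""
        if not genes:
            raise ValidationError("co-expression needs at least one gene")
        filters = tuple(ExpressionFilter(g, matrix_kind, "ge", threshold) for g in genes)
        return self.select_cells(CellQuery(filters=filters,
                                           project_scope=None if scope is None
                                           else frozenset(scope)))

    def fetch_expression(self, cells: Optional[Union[CellSet, Iterable[int]]] = None,
                         genes: Optional[Sequence[Union[str, dict]]] = None,
                         matrix_kind: str = "normalized",
                         warnings: Optional[list] = None) -> Iterator[ExpressionRow]:
        """Stream stored entries at the intersection of a cell set and a gene
        list (``None`` means all).  Unknown gene selectors are omitted with a
        warning."""
        cat = self.store.catalog
        cell_ids = None
        project_ids = None
        if cells is not None:
            cell_ids = set(cells.cell_ids) if isinstance(cells, CellSet) else set(cells)
            project_ids = sorted({cat.project_of_cell(c) for c in cell_ids})
            if not cell_ids:
                return
        feature_ids = None
        if genes is not None:
            feature_ids = set()
            for g in genes:
                fids = self.resolve_gene(g)
                if not fids and warnings is not None:
                    warnings.append(f"gene selector {g!r} matched no features; omitted")
                feature_ids.update(fids)
            if not feature_ids:
                return
        for pid, sid, cid, fid, v in self.store.read_submatrix(
                cell_ids, feature_ids, matrix_kind, project_ids):
            yield ExpressionRow(pid, sid, cid, fid, cat.features[fid].gene_symbol, v)

    def fetch_project_matrix(self, project_name: str,
                             matrix_kind: str = "normalized",
                             warnings: Optional[list] = None) -> Iterator[ExpressionRow]:
        """All entries of one project and matrix kind."""
        pid = self.store.catalog.project_id_by_name(project_name)
        if not self.store.measurementsets_for(matrix_kind, [pid]):
            if warnings is not None:
                warnings.append(
                    f"project {project_name!r} has no {matrix_kind} data")
            return
        cat = self.store.catalog
        for p, s, c, f, v in self.store.read_submatrix(None, None, matrix_kind, [pid]):
            yield ExpressionRow(p, s, c, f, cat.features[f].gene_symbol, v)
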