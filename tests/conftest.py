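"""Shared fixtures: toy store, synthetic atlases, and an independent
dense brute-force query oracle."""

from __future__ import annotations

import random

import pytest
from hypothesis import settings

import sccommons as sc
from sccommons.query_engine import (CellQuery, ExpressionFilter, NumericRange,
                                    OntologyFilter, TagFilter)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


ONTOLOGIES = {p: sc.load_packaged(n) for p, n in
              (("CL", "cl"), ("UBERON", "uberon"), ("DOID", "doid"))}


@pytest.fixture(scope="session")
def ontologies():
    return ONTOLOGIES


# ---------------------------------------------------------------------------
# Toy store: 1 project, 1 sample, 3 cells (c1, c2, c3), genes ACE2/TMPRSS2,
# normalized values c1:ACE2=2.0; c2:ACE2=1.0, TMPRSS2=1.5; c3: nothing.
# ---------------------------------------------------------------------------

def build_toy_store(path):
    store = sc.Store.create(path)
    pid = store.register_project("toy")
    txn = store.begin_load(pid)
    sid = txn.register_sample("S1")
    cells = [txn.register_cell(sid, bc) for bc in ("c1", "c2", "c3")]
    fsid = txn.register_featureset(table_hash="toyfs")
    ace2 = txn.register_feature(fsid, "ENSG00000130234", "ACE2")
    tmprss2 = txn.register_feature(fsid, "ENSG00000184012", "TMPRSS2")
    mid = txn.register_measurementset(sid, fsid, "normalized")
    store.write_entries(txn, [(cells[0], ace2, 2.0), (cells[1], ace2, 1.0),
                              (cells[1], tmprss2, 1.5)], mid)
    store.commit_load(txn)
    ids = {"project": pid, "sample": sid, "cells": cells,
           "ACE2": ace2, "TMPRSS2": tmprss2, "mset": mid}
    return store, ids


@pytest.fixture
def toy_store(tmp_path):
    return build_toy_store(tmp_path / "toy")


# ---------------------------------------------------------------------------
# Small atlas (2 projects x 1 sample x 200 cells, 60 genes), session-scoped
# and treated as read-only by tests that use it.
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_atlas(tmp_path_factory):
    root = tmp_path_factory.mktemp("small_atlas")
    cfg = sc.small_config(seed=7)
    manifest = sc.generate_atlas(cfg, root / "atlas")
    store = sc.Store.create(root / "store")
    sc.load_atlas(store, root / "atlas")
    engine = sc.QueryEngine(store, ONTOLOGIES)
    return {"store": store, "engine": engine, "manifest": manifest,
            "atlas_dir": root / "atlas", "config": cfg}


# ---------------------------------------------------------------------------
# Brute-force oracle: densify the matrix and scan every cell, evaluating
# each filter from first principles.  Shares nothing with QueryEngine's
# evaluation strategy.
# ---------------------------------------------------------------------------

def dense_values(store, matrix_kind):
    """(cell, feature) -> value for one kind, later measurement set wins."""
    dense = {}
    for mid in store.measurementsets_for(matrix_kind):
        ch = store._chunk(mid)
        for c, f, v in zip(ch.cells.tolist(), ch.feats.tolist(), ch.vals.tolist()):
            dense[(c, f)] = v
    return dense


def _oracle_pred(flt, v):
    if flt.op == "ge":
        return v >= flt.threshold
    if flt.op == "gt":
        return v > flt.threshold
    if flt.op == "le":
        return v <= flt.threshold
    if flt.op == "lt":
        return v < flt.threshold
    return flt.low <= v <= flt.high


def oracle_select(store, ontologies, q, dense_cache=None):
    """Reference implementation of select_cells by exhaustive scan."""
    cat = store.catalog
    if q.project_scope is None:
        pids = sorted(cat.projects)
    else:
        pids = sorted(cat.project_by_name[p] if isinstance(p, str) else p
                      for p in q.project_scope)
    cells = [c for pid in pids for c in cat.cells_of_project(pid)]
    if q.base is not None:
        cells = [c for c in cells if c in q.base.cell_ids]

    dense_cache = dense_cache if dense_cache is not None else {}

    def dense(kind):
        if kind not in dense_cache:
            dense_cache[kind] = dense_values(store, kind)
        return dense_cache[kind]

    keep = []
    for c in cells:
        cell = cat.cells[c]
        sample = cat.samples[cell.sample_id]
        project = cat.projects[sample.project_id]
        ok = True
        for flt in q.filters:
            if isinstance(flt, OntologyFilter):
                onto = ontologies[flt.term.split(":")[0]]
                if flt.expand == "none":
                    terms = {flt.term}
                elif flt.expand == "descendants":
                    terms = sc.descendants(onto, flt.term)
                else:
                    terms = sc.ancestors(onto, flt.term)
                flt = TagFilter(flt.entity_level, flt.key, frozenset(terms))
            if isinstance(flt, TagFilter):
                tags = {"cell": cell.tags, "sample": sample.tags,
                        "project": project.tags}[flt.entity_level]
                if flt.key not in tags:
                    ok = False
                elif flt.values is not None:
                    ok = str(tags[flt.key]) in flt.values
                else:
                    try:
                        x = float(tags[flt.key])
                    except (TypeError, ValueError):
                        ok = False
                    else:
                        r = flt.numeric_range
                        lo = x >= r.low if r.incl_low else x > r.low
                        hi = x <= r.high if r.incl_high else x < r.high
                        ok = lo and hi
            elif isinstance(flt, ExpressionFilter):
                sym = flt.gene if isinstance(flt.gene, str) else None
                if isinstance(flt.gene, dict):
                    if "gene_symbol" in flt.gene:
                        fids = [f for f, ft in cat.features.items()
                                if ft.gene_symbol == flt.gene["gene_symbol"]]
                    else:
                        fids = [f for f, ft in cat.features.items()
                                if ft.ensembl_id == flt.gene["ensembl_id"]]
                else:
                    fids = [f for f, ft in cat.features.items()
                            if ft.gene_symbol == sym]
                    if not fids:
                        fids = [f for f, ft in cat.features.items()
                                if ft.ensembl_id == sym]
                vals = dense(flt.matrix_kind)
                ok = any(_oracle_pred(flt, vals.get((c, f), 0.0)) for f in fids)
            if not ok:
                break
        if ok:
            keep.append(c)
    return set(keep)


@pytest.fixture(scope="session")
def oracle():
    return oracle_select


# ---------------------------------------------------------------------------
# Seeded random query generator over an atlas store.
# ---------------------------------------------------------------------------

def random_queries(store, cfg, rng: random.Random, n: int, prior_results=None):
    """Yield n random well-formed CellQueries mixing every filter family."""
    labels = sorted(cfg.label_proportions)
    genes = [sym for _, sym, _ in cfg.gene_table()]
    cl_terms = sorted({t for t in cfg.cl_map.values()})
    locations = list(cfg.locations)
    project_names = list(cfg.project_names)
    keys = list(cfg.celltype_keys) + ["CellType.select"]
    out = []
    for _ in range(n):
        filters = []
        for _ in range(rng.randint(1, 3)):
            kind = rng.choice(["tag", "tag", "onto", "expr", "expr", "mt", "loc"])
            if kind == "tag":
                filters.append(TagFilter(
                    "cell", rng.choice(keys),
                    frozenset(rng.sample(labels, rng.randint(1, 5)))))
            elif kind == "loc":
                filters.append(TagFilter(
                    "sample", "Location",
                    frozenset(rng.sample(locations, rng.randint(1, 3)))))
            elif kind == "mt":
                lo = round(rng.uniform(0, 8), 2)
                hi = round(lo + rng.uniform(0, 5), 2)
                filters.append(TagFilter(
                    "cell", "percent.mt", None,
                    NumericRange(lo, hi, rng.random() < 0.5, rng.random() < 0.5)))
            elif kind == "onto":
                filters.append(OntologyFilter(
                    "cell", "CL ID", rng.choice(cl_terms),
                    rng.choice(["none", "descendants", "ancestors"])))
            else:
                gene = rng.choice(genes)
                op = rng.choice(["ge", "gt", "le", "lt", "within"])
                mkind = rng.choice(["normalized", "normalized", "raw"])
                if op == "within":
                    a = round(rng.uniform(0, 3), 2)
                    filters.append(ExpressionFilter(
                        gene, mkind, op, low=a, high=round(a + rng.uniform(0, 4), 2)))
                else:
                    filters.append(ExpressionFilter(
                        gene, mkind, op,
                        threshold=rng.choice([0.5, 1.0, 1.5, 2.0, 5.0])))
        scope = None
        if rng.random() < 0.3:
            scope = frozenset(rng.sample(project_names,
                                         rng.randint(1, len(project_names))))
        base = None
        if prior_results and rng.random() < 0.2:
            base = rng.choice(prior_results)
        out.append(CellQuery(filters=tuple(filters), project_scope=scope, base=base))
    return out
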