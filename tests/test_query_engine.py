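"""Selection semantics: predicates, implicit zeros, composition laws."""

import random

import pytest

import sccommons as sc
from sccommons.query_engine import (CellQuery, ExpressionFilter, NumericRange,
                                    OntologyFilter, TagFilter, query_from_json,
                                    query_to_json)
from conftest import ONTOLOGIES, oracle_select, random_queries


@pytest.fixture
def toy_engine(toy_store):
    store, ids = toy_store
    return sc.QueryEngine(store, ONTOLOGIES), store, ids


class TestToyEnumerations:
    def test_two_gene_conjunction(self, toy_engine):
        engine, _, ids = toy_engine
        cs = engine.select_cells(CellQuery(filters=(
            ExpressionFilter("ACE2", "normalized", "ge", 1.0),
            ExpressionFilter("TMPRSS2", "normalized", "ge", 1.0))))
        assert set(cs.cell_ids) == {ids["cells"][1]}

    def test_implicit_zero_satisfies_upper_bound(self, toy_engine):
        engine, _, ids = toy_engine
        cs = engine.select_cells(CellQuery(filters=(
            ExpressionFilter("ACE2", "normalized", "lt", 7.0),)))
        assert set(cs.cell_ids) == set(ids["cells"])

    def test_within_range(self, toy_engine):
        engine, _, ids = toy_engine
        cs = engine.select_cells(CellQuery(filters=(
            ExpressionFilter("ACE2", "normalized", "within", low=0.5, high=1.5),)))
        assert set(cs.cell_ids) == {ids["cells"][1]}

    def test_coexpression_single_gene_degeneracy(self, toy_engine):
        engine, _, ids = toy_engine
        cs = engine.coexpression_cells(["ACE2"], 1.0, "normalized")
        assert set(cs.cell_ids) == {ids["cells"][0], ids["cells"][1]}

    def test_coexpression_intersection(self, toy_engine):
        engine, _, ids = toy_engine
        cs = engine.coexpression_cells(["ACE2", "TMPRSS2"], 1.0, "normalized")
        assert set(cs.cell_ids) == {ids["cells"][1]}

    def test_empty_gene_list_rejected(self, toy_engine):
        engine, _, _ = toy_engine
        with pytest.raises(sc.ValidationError):
            engine.coexpression_cells([], 1.0)

    def test_unknown_gene_contributes_empty_with_warning(self, toy_engine):
        engine, _, _ = toy_engine
        cs = engine.select_cells(CellQuery(filters=(
            ExpressionFilter("NOSUCHGENE", "normalized", "ge", 1.0),)))
        assert len(cs) == 0
        assert any("NOSUCHGENE" in w for w in cs.provenance["warnings"])

    def test_unknown_tag_key_is_empty_not_error(self, toy_engine):
        engine, _, _ = toy_engine
        cs = engine.select_cells(CellQuery(filters=(
            TagFilter("cell", "no_such_key", frozenset({"x"})),)))
        assert len(cs) == 0


class TestFetch:
    def test_fetch_by_cells_and_genes(self, toy_engine):
        engine, _, ids = toy_engine
        rows = list(engine.fetch_expression({ids["cells"][1]},
                                            ["ACE2", "TMPRSS2"], "normalized"))
        assert len(rows) == 2
        assert {r.gene_symbol for r in rows} == {"ACE2", "TMPRSS2"}

    def test_fetch_empty_cellset(self, toy_engine):
        engine, _, _ = toy_engine
        assert list(engine.fetch_expression(set(), None, "normalized")) == []

    def test_fetch_unknown_gene_omitted_with_warning(self, toy_engine):
        engine, _, ids = toy_engine
        warnings = []
        rows = list(engine.fetch_expression(None, ["ACE2", "NOPE"],
                                            "normalized", warnings=warnings))
        assert {r.gene_symbol for r in rows} == {"ACE2"}
        assert warnings and "NOPE" in warnings[0]

    def test_project_matrix_counts(self, small_atlas):
        engine, manifest = small_atlas["engine"], small_atlas["manifest"]
        for p in manifest["projects"]:
            rows = list(engine.fetch_project_matrix(p["name"], "normalized"))
            assert len(rows) == p["n_entries"]["normalized"]
        with pytest.raises(sc.NotFoundError):
            list(engine.fetch_project_matrix("nope", "normalized"))

    def test_project_matrix_missing_kind_warns_empty(self, toy_engine):
        engine, _, _ = toy_engine
        warnings = []
        rows = list(engine.fetch_project_matrix("toy", "raw", warnings=warnings))
        assert rows == [] and warnings

    def test_partition_additivity(self, small_atlas):
        engine, manifest = small_atlas["engine"], small_atlas["manifest"]
        total = sum(1 for _ in engine.fetch_expression(None, None, "normalized"))
        per_project = sum(
            sum(1 for _ in engine.fetch_project_matrix(p["name"], "normalized"))
            for p in manifest["projects"])
        assert total == per_project


class TestOntologyExpansion:
    def test_none_is_singleton(self, small_atlas):
        engine = small_atlas["engine"]
        tf = engine.expand_ontology_filter(
            OntologyFilter("cell", "CL ID", "CL:0000584", "none"))
        assert tf.values == frozenset({"CL:0000584"})

    def test_descendants_of_parent_contains_enterocyte(self, small_atlas):
        engine = small_atlas["engine"]
        tf = engine.expand_ontology_filter(
            OntologyFilter("cell", "CL ID", "CL:0000212", "descendants"))
        assert "CL:0000584" in tf.values

    def test_expansion_is_monotone(self, small_atlas):
        engine = small_atlas["engine"]
        plain = engine.select_cells(CellQuery(filters=(
            OntologyFilter("cell", "CL ID", "CL:0000584", "none"),)))
        expanded = engine.select_cells(CellQuery(filters=(
            OntologyFilter("cell", "CL ID", "CL:0000584", "descendants"),)))
        assert set(plain.cell_ids) <= set(expanded.cell_ids)

    def test_missing_term_not_found(self, small_atlas):
        engine = small_atlas["engine"]
        with pytest.raises(sc.NotFoundError):
            engine.expand_ontology_filter(
                OntologyFilter("cell", "CL ID", "CL:9999999", "descendants"))


class TestCompositionLaws:
    def test_refinement_law(self, small_atlas):
        engine = small_atlas["engine"]
        q1 = CellQuery(filters=(TagFilter("cell", "CellType.select",
                                          frozenset({"Enterocyte", "Goblet"})),))
        base = engine.select_cells(q1)
        q2 = CellQuery(filters=(ExpressionFilter("ACE2", "normalized", "ge", 1.0),))
        refined = engine.select_cells(
            CellQuery(filters=q2.filters, base=base))
        unbased = engine.select_cells(q2)
        assert set(refined.cell_ids) == set(unbased.cell_ids) & set(base.cell_ids)

    def test_threshold_monotonicity(self, small_atlas):
        engine = small_atlas["engine"]
        sizes = [len(engine.coexpression_cells(["ACE2", "TMPRSS2"], t))
                 for t in (0.5, 1.0, 1.5, 2.0, 4.0)]
        assert sizes == sorted(sizes, reverse=True)

    def test_anyof_widening_monotonicity(self, small_atlas):
        engine = small_atlas["engine"]
        small = engine.select_cells(CellQuery(filters=(
            TagFilter("cell", "CellType.select", frozenset({"Enterocyte"})),)))
        wide = engine.select_cells(CellQuery(filters=(
            TagFilter("cell", "CellType.select",
                      frozenset({"Enterocyte", "Enterocytes", "Goblet"})),)))
        assert set(small.cell_ids) <= set(wide.cell_ids)

    def test_scope_law(self, small_atlas):
        engine = small_atlas["engine"]
        store = small_atlas["store"]
        cs = engine.coexpression_cells(["ACE2"], 1.0)
        contributing = {store.catalog.project_of_cell(c) for c in cs.cell_ids}
        assert len(contributing) == cs.n_projects_with_data
        rescoped = engine.coexpression_cells(["ACE2"], 1.0,
                                             scope=frozenset(contributing))
        assert set(rescoped.cell_ids) == set(cs.cell_ids)

    def test_intersection_law(self, small_atlas):
        engine = small_atlas["engine"]
        joint = engine.coexpression_cells(["ACE2", "TMPRSS2", "DPP4"], 1.0)
        single = [engine.coexpression_cells([g], 1.0)
                  for g in ("ACE2", "TMPRSS2", "DPP4")]
        expect = set(single[0].cell_ids)
        for s in single[1:]:
            expect &= set(s.cell_ids)
        assert set(joint.cell_ids) == expect


class TestSymbolDuplication:
    def test_cell_passes_if_any_matching_feature_passes(self, tmp_path):
        store = sc.Store.create(tmp_path / "s")
        pid = store.register_project("P")
        txn = store.begin_load(pid)
        sid = txn.register_sample("S")
        c1 = txn.register_cell(sid, "b1")
        c2 = txn.register_cell(sid, "b2")
        fs = txn.register_featureset(table_hash="h")
        fa = txn.register_feature(fs, "ENSG_A", "DUPGENE")
        fb = txn.register_feature(fs, "ENSG_B", "DUPGENE")
        mid = txn.register_measurementset(sid, fs, "normalized")
        # c1 expresses only the first copy, c2 only the second
        store.write_entries(txn, [(c1, fa, 5.0), (c2, fb, 5.0)], mid)
        store.commit_load(txn)
        engine = sc.QueryEngine(store)
        cs = engine.select_cells(CellQuery(filters=(
            ExpressionFilter("DUPGENE", "normalized", "ge", 1.0),)))
        assert set(cs.cell_ids) == {c1, c2}
        # ensembl selector narrows to one feature
        cs_a = engine.select_cells(CellQuery(filters=(
            ExpressionFilter({"ensembl_id": "ENSG_A"}, "normalized", "ge", 1.0),)))
        assert set(cs_a.cell_ids) == {c1}


class TestNumericTagFilters:
    def test_percent_mt_range(self, small_atlas):
        engine, store = small_atlas["engine"], small_atlas["store"]
        flt = TagFilter("cell", "percent.mt", None, NumericRange(0.0, 2.0))
        cs = engine.select_cells(CellQuery(filters=(flt,)))
        expect = {c for c, cell in store.catalog.cells.items()
                  if "percent.mt" in cell.tags and 0.0 <= cell.tags["percent.mt"] <= 2.0}
        assert set(cs.cell_ids) == expect

    def test_exactly_one_of_values_or_range(self):
        with pytest.raises(sc.ValidationError):
            TagFilter("cell", "k", frozenset({"a"}), NumericRange(0, 1))
        with pytest.raises(sc.ValidationError):
            TagFilter("cell", "k", None, None)


class TestSerialization:
    def test_query_json_round_trip(self):
        q = CellQuery(
            filters=(TagFilter("cell", "CellType.select",
                               frozenset({"Enterocyte", "Goblet"})),
                     TagFilter("cell", "percent.mt", None,
                               NumericRange(0, 5, True, False)),
                     OntologyFilter("cell", "CL ID", "CL:0000584", "descendants"),
                     ExpressionFilter("ACE2", "normalized", "within",
                                      low=1.0, high=3.0)),
            project_scope=frozenset({"wang20_rectum"}),
            fetch_genes=("ACE2",))
        assert query_from_json(query_to_json(q)) == q

    def test_bad_json_rejected(self):
        with pytest.raises(sc.ValidationError):
            query_from_json({"filters": [{"type": "nonsense"}]})
        with pytest.raises(sc.ValidationError):
            query_from_json([])


def test_engine_agrees_with_dense_oracle_on_small_atlas(small_atlas):
    """Spot-check: 40 random mixed queries vs the exhaustive scanner (the
    full 200-query run lives in the acceptance suite)."""
    store, engine, cfg = (small_atlas["store"], small_atlas["engine"],
                          small_atlas["config"])
    rng = random.Random(424242)
    cache = {}
    prior = []
    for q in random_queries(store, cfg, rng, 40, prior):
        got = engine.select_cells(q)
        expect = oracle_select(store, ONTOLOGIES, q, dense_cache=cache)
        assert set(got.cell_ids) == expect, query_to_json(q)
        prior.append(got)
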