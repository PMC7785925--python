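"""10x bundle I/O: round trips, validation codes, atomic loading."""

import math

import pytest
import scipy.io
from hypothesis import given, settings
from hypothesis import strategies as st

import sccommons as sc
from sccommons.ingest_10x import TenXBundle, read_tag_tsv
from conftest import build_toy_store


def toy_bundle():
    return TenXBundle(
        features=[("ENSG00000130234", "ACE2", "Gene Expression"),
                  ("ENSG00000184012", "TMPRSS2", "Gene Expression")],
        barcodes=["AAAC-1", "AAAG-1", "AAAT-1"],
        triples=[(1, 1, 2.0), (1, 2, 1.0), (2, 2, 1.5)])


# -- hypothesis strategy for random valid bundles ---------------------------

@st.composite
def bundles(draw):
    n_feat = draw(st.integers(1, 8))
    n_bc = draw(st.integers(1, 8))
    features = [(f"ENSG{i:011d}", f"G{i}", "Gene Expression") for i in range(n_feat)]
    barcodes = [f"BC{i:04d}-1" for i in range(n_bc)]
    coords = draw(st.sets(st.tuples(st.integers(1, n_feat), st.integers(1, n_bc)),
                          max_size=n_feat * n_bc))
    vals = draw(st.lists(
        st.one_of(st.integers(1, 1000).map(float),
                  st.floats(1e-3, 1e4, allow_nan=False, allow_infinity=False)),
        min_size=len(coords), max_size=len(coords)))
    triples = [(r, c, v) for (r, c), v in zip(sorted(coords), vals)]
    return TenXBundle(features, barcodes, triples)


class TestRoundTrip:
    @pytest.mark.parametrize("compress", [False, True])
    def test_toy_write_read_identity(self, tmp_path, compress):
        b = toy_bundle()
        sc.write_10x_dir(b, tmp_path / "d", compress=compress)
        assert sc.read_10x_dir(tmp_path / "d") == b

    @given(bundle=bundles(), compress=st.booleans())
    @settings(max_examples=40)
    def test_random_bundles_round_trip(self, tmp_path_factory, bundle, compress):
        d = tmp_path_factory.mktemp("rt")
        sc.write_10x_dir(bundle, d, compress=compress)
        back = sc.read_10x_dir(d)
        assert back == bundle

    @given(bundle=bundles())
    @settings(max_examples=20)
    def test_matrix_agrees_with_scipy_mmread(self, tmp_path_factory, bundle):
        """Independent cross-check of the line-based matrix reader."""
        d = tmp_path_factory.mktemp("sp")
        sc.write_10x_dir(bundle, d)
        mat = scipy.io.mmread(str(d / "matrix.mtx")).tocoo()
        ours = {(r, c): v for r, c, v in bundle.triples}
        theirs = {(int(r) + 1, int(c) + 1): float(v)
                  for r, c, v in zip(mat.row, mat.col, mat.data)}
        assert ours == theirs
        assert mat.shape == (bundle.n_features, bundle.n_barcodes)


class TestReadErrors:
    def test_missing_file_is_named(self, tmp_path):
        sc.write_10x_dir(toy_bundle(), tmp_path / "d")
        (tmp_path / "d" / "barcodes.tsv").unlink()
        with pytest.raises(sc.FormatError, match="barcodes.tsv"):
            sc.read_10x_dir(tmp_path / "d")

    def test_out_of_range_index_reports_line(self, tmp_path):
        d = tmp_path / "d"
        sc.write_10x_dir(toy_bundle(), d)
        (d / "matrix.mtx").write_text(
            "%%MatrixMarket matrix coordinate real general\n"
            "2 3 1\n"
            "3 1 5.0\n")
        with pytest.raises(sc.FormatError, match=r"matrix.mtx:3.*row index 3"):
            sc.read_10x_dir(d)

    def test_header_count_mismatch(self, tmp_path):
        d = tmp_path / "d"
        sc.write_10x_dir(toy_bundle(), d)
        (d / "matrix.mtx").write_text(
            "%%MatrixMarket matrix coordinate real general\n"
            "2 3 5\n"
            "1 1 1.0\n")
        with pytest.raises(sc.FormatError, match="declares 5 entries"):
            sc.read_10x_dir(d)

    def test_two_column_features_get_default_type(self, tmp_path):
        d = tmp_path / "d"
        sc.write_10x_dir(toy_bundle(), d)
        (d / "features.tsv").write_text("ENSG1\tACE2\nENSG2\tTMPRSS2\n")
        b = sc.read_10x_dir(d)
        assert b.features[0] == ("ENSG1", "ACE2", "Gene Expression")


class TestValidation:
    def test_clean_bundle_ok(self):
        rep = sc.validate_bundle(toy_bundle())
        assert rep.ok and not rep.errors

    def test_duplicate_barcode(self):
        b = toy_bundle()
        b.barcodes[2] = "AAAC-1"
        rep = sc.validate_bundle(b)
        assert not rep.ok
        assert {e[0] for e in rep.errors} == {"DUP_BARCODE"}

    def test_nan_value_reports_coordinate(self):
        b = toy_bundle()
        b.triples[1] = (1, 2, math.nan)
        rep = sc.validate_bundle(b)
        codes = {e[0]: e[2] for e in rep.errors}
        assert codes == {"NON_FINITE": "matrix.mtx (1,2)"}

    def test_duplicate_coordinate_and_empty_symbol(self):
        b = toy_bundle()
        b.triples.append((1, 1, 3.0))
        b.features[1] = ("ENSGX", "", "Gene Expression")
        rep = sc.validate_bundle(b)
        assert {"DUP_COORD", "EMPTY_SYMBOL"} <= {e[0] for e in rep.errors}

    def test_negative_raw_error_but_normalized_warning(self):
        b = toy_bundle()
        b.triples[0] = (1, 1, -0.5)
        raw = sc.validate_bundle(b, "raw")
        norm = sc.validate_bundle(b, "normalized")
        assert "NEGATIVE_VALUE" in {e[0] for e in raw.errors}
        assert norm.ok and "NEGATIVE_VALUE" in {w[0] for w in norm.warnings}


class TestLoadBundle:
    def test_toy_load_counts(self, tmp_path):
        store, ids = build_toy_store(tmp_path / "s")
        sid, mid, n_cells, n_entries = sc.load_bundle(
            store, ids["project"], "S2", toy_bundle(), "normalized")
        assert (n_cells, n_entries) == (3, 3)
        assert store.catalog.measurementsets[mid].matrix_kind == "normalized"

    def test_mass_conservation(self, tmp_path):
        store, ids = build_toy_store(tmp_path / "s")
        b = toy_bundle()
        before = store.value_sum("normalized")
        sc.load_bundle(store, ids["project"], "S2", b, "normalized")
        assert store.value_sum("normalized") - before == pytest.approx(
            b.value_sum(), rel=1e-9)

    def test_tag_tsv_partial_coverage(self, tmp_path):
        store, ids = build_toy_store(tmp_path / "s")
        tsv = tmp_path / "tags.tsv"
        tsv.write_text("barcode\tCellType\tpercent.mt\n"
                       "AAAC-1\tEnterocyte\t3.5\n"
                       "AAAG-1\tGoblet\t\n")
        sid, _, _, _ = sc.load_bundle(store, ids["project"], "S2", toy_bundle(),
                                      "normalized", cell_tags_tsv=tsv)
        cells = [store.catalog.cells[c] for c in store.catalog.cells_by_sample[sid]]
        tagged = [c for c in cells if "CellType" in c.tags]
        assert len(tagged) == 2 and len(cells) == 3
        by_name = {c.name: c.tags for c in cells}
        assert by_name["AAAC-1"]["percent.mt"] == 3.5      # numeric coercion
        assert "percent.mt" not in by_name["AAAG-1"]       # empty cell -> no tag

    def test_unknown_barcode_in_tsv_rejects_load_atomically(self, tmp_path):
        store, ids = build_toy_store(tmp_path / "s")
        v0, n0 = store.version, store.n_entries()
        tsv = tmp_path / "tags.tsv"
        tsv.write_text("barcode\tCellType\nZZZZ-9\tEnterocyte\n")
        with pytest.raises(sc.ValidationError, match="ZZZZ-9"):
            sc.load_bundle(store, ids["project"], "S2", toy_bundle(),
                           "normalized", cell_tags_tsv=tsv)
        assert (store.version, store.n_entries()) == (v0, n0)
        assert (ids["project"], "S2") not in store.catalog.sample_by_key

    def test_invalid_bundle_rejected(self, tmp_path):
        store, ids = build_toy_store(tmp_path / "s")
        b = toy_bundle()
        b.barcodes[1] = "AAAC-1"
        with pytest.raises(sc.ValidationError, match="DUP_BARCODE"):
            sc.load_bundle(store, ids["project"], "S2", b, "normalized")

    def test_two_kinds_share_one_sample_and_cells(self, tmp_path):
        store, ids = build_toy_store(tmp_path / "s")
        b = toy_bundle()
        sid1, mid1, _, _ = sc.load_bundle(store, ids["project"], "S2", b, "raw")
        sid2, mid2, _, _ = sc.load_bundle(store, ids["project"], "S2", b, "normalized")
        assert sid1 == sid2 and mid1 != mid2
        assert len(store.catalog.cells_by_sample[sid1]) == 3
        kinds = {store.catalog.measurementsets[m].matrix_kind
                 for m in store.catalog.msets_by_sample[sid1]}
        assert kinds == {"raw", "normalized"}
        # kind-scoped reads see only their own entries
        assert store.n_entries("raw", ids["project"]) == 3

    def test_featureset_reused_by_table_hash(self, tmp_path):
        store, ids = build_toy_store(tmp_path / "s")
        b = toy_bundle()
        sc.load_bundle(store, ids["project"], "S2", b, "normalized")
        n_fs = len(store.catalog.featuresets)
        sc.load_bundle(store, ids["project"], "S3", b, "normalized")
        assert len(store.catalog.featuresets) == n_fs


class TestGeneratedAtlasDensity:
    def test_planted_nonzero_count_from_density(self, tmp_path):
        # no markers: every cell gets round(density * n_genes) background genes
        cfg = sc.AtlasConfig(n_projects=1, samples_per_project=1,
                             cells_per_sample=500, n_genes=200,
                             background_density=0.05, seed=5, markers=(),
                             label_proportions={"Enterocyte": 1.0})
        sc.generate_atlas(cfg, tmp_path / "a")
        b = sc.read_10x_dir(tmp_path / "a" / "projects" / "wang20_rectum"
                            / "S1" / "normalized")
        assert len(b.triples) == 500 * round(0.05 * 200)


def test_read_tag_tsv_shape_errors(tmp_path):
    p = tmp_path / "t.tsv"
    p.write_text("barcode\tk1\tk2\nbc1\tv1\n")
    with pytest.raises(sc.FormatError, match="t.tsv:2"):
        read_tag_tsv(p)
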