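"""10x CellRanger v3-style directory I/O and the bundle loader.

A bundle is the classic triple ``matrix.mtx`` / ``features.tsv`` /
``barcodes.tsv``, each optionally gzipped.  The matrix is MatrixMarket
coordinate format with 1-based indices (features are rows, barcodes are
columns); internal ids are 0-based and the conversion happens exactly once,
here.  The matrix file is read line-by-line rather than through
``scipy.io.mmread`` because the validation contract needs line-numbered
bounds errors and must see duplicate coordinates, which mmread sums away;
a cross-check against mmread on clean bundles lives in the test suite.
"""

from __future__ import annotations

import gzip
import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Optional, Union

from .array_store import Store
from .core_model import FormatError, NotFoundError, ValidationError, coerce_tag_value

__all__ = [
    "TenXBundle",
    "ValidationReport",
    "read_10x_dir",
    "validate_bundle",
    "write_10x_dir",
    "load_bundle",
    "read_tag_tsv",
    "apply_cell_tag_tsv",
]

_FILES = ("matrix.mtx", "features.tsv", "barcodes.tsv")


@dataclass
class TenXBundle:
    """In-memory image of one 10x directory.

    ``features`` rows are (ensembl_id, gene_symbol, feature_type); ``triples``
    keep the MatrixMarket 1-based (row=feature, col=barcode, value) indices
    verbatim so that write∘read is the identity.
    """
    features: list[tuple[str, str, str]]
    barcodes: list[str]
    triples: list[tuple[int, int, float]]

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_barcodes(self) -> int:
        return len(self.barcodes)

    def value_sum(self) -> float:
        return sum(v for _, _, v in self.triples)

    def feature_table_hash(self) -> str:
        h = hashlib.sha256()
        for row in self.features:
            h.update(("\t".join(row) + "\n").encode())
        return h.hexdigest()


@dataclass
class ValidationReport:
    errors: list[tuple[str, str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def add_error(self, code: str, message: str, location: str = "") -> None:
        self.errors.append((code, message, location))

    def add_warning(self, code: str, message: str, location: str = "") -> None:
        self.warnings.append((code, message, location))


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _open_maybe_gz(base: Path) -> tuple[IO[str], str]:
    """Open ``base`` or ``base.gz``, whichever exists (plain wins)."""
    if base.exists():
        return open(base, "rt", encoding="utf-8"), base.name
    gz = base.with_name(base.name + ".gz")
    if gz.exists():
        return gzip.open(gz, "rt", encoding="utf-8"), gz.name
    raise FormatError(f"missing file: {base.name}[.gz] in {base.parent}")


def _read_matrix(fh: IO[str], fname: str) -> tuple[int, int, list[tuple[int, int, float]]]:
    header = fh.readline()
    if not header.startswith("%%MatrixMarket"):
        raise FormatError(f"{fname}:1: missing MatrixMarket banner")
    parts = header.split()
    if len(parts) < 4 or parts[1] != "matrix" or parts[2] != "coordinate":
        raise FormatError(f"{fname}:1: only 'matrix coordinate' files are supported")
    if parts[3] not in ("real", "integer"):
        raise FormatError(f"{fname}:1: unsupported value field {parts[3]!r}")
    lineno = 1
    dims = None
    for line in fh:
        lineno += 1
        if line.startswith("%") or not line.strip():
            continue
        toks = line.split()
        if len(toks) != 3:
            raise FormatError(f"{fname}:{lineno}: expected 3 dimension tokens")
        try:
            dims = (int(toks[0]), int(toks[1]), int(toks[2]))
        except ValueError as e:
            raise FormatError(f"{fname}:{lineno}: bad dimension line: {e}") from None
        break
    if dims is None:
        raise FormatError(f"{fname}: missing dimension line")
    n_rows, n_cols, n_nnz = dims
    triples: list[tuple[int, int, float]] = []
    for line in fh:
        lineno += 1
        if line.startswith("%") or not line.strip():
            continue
        toks = line.split()
        if len(toks) != 3:
            raise FormatError(f"{fname}:{lineno}: expected 'row col value'")
        try:
            r, c, v = int(toks[0]), int(toks[1]), float(toks[2])
        except ValueError as e:
            raise FormatError(f"{fname}:{lineno}: bad entry: {e}") from None
        if not 1 <= r <= n_rows:
            raise FormatError(
                f"{fname}:{lineno}: row index {r} out of range 1..{n_rows}")
        if not 1 <= c <= n_cols:
            raise FormatError(
                f"{fname}:{lineno}: column index {c} out of range 1..{n_cols}")
        triples.append((r, c, v))
    if len(triples) != n_nnz:
        raise FormatError(
            f"{fname}: header declares {n_nnz} entries but {len(triples)} found")
    return n_rows, n_cols, triples


def read_10x_dir(path: Union[str, Path]) -> TenXBundle:
    """Read a 10x directory (plain or gzipped files) into a bundle.

    The feature count and barcode count must match the matrix header
    dimensions; 2-column feature tables (pre-v3 CellRanger) are accepted
    with ``feature_type`` defaulted to ``"Gene Expression"``.
    """
    path = Path(path)
    fh, fname = _open_maybe_gz(path / "features.tsv")
    with fh:
        features = []
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) == 2:
                cols = cols + ["Gene Expression"]
            if len(cols) < 3:
                raise FormatError(f"{fname}:{i}: expected >=2 tab-separated columns")
            features.append((cols[0], cols[1], cols[2]))
    fh, bname = _open_maybe_gz(path / "barcodes.tsv")
    with fh:
        barcodes = [line.strip() for line in fh if line.strip()]
    fh, mname = _open_maybe_gz(path / "matrix.mtx")
    with fh:
        n_rows, n_cols, triples = _read_matrix(fh, mname)
    if n_rows != len(features):
        raise FormatError(
            f"{mname}: header declares {n_rows} features but {fname} has {len(features)}")
    if n_cols != len(barcodes):
        raise FormatError(
            f"{mname}: header declares {n_cols} barcodes but {bname} has {len(barcodes)}")
    return TenXBundle(features, barcodes, triples)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_bundle(bundle: TenXBundle, matrix_kind: Optional[str] = None) -> ValidationReport:
    """Deterministic consistency report.

    Checks duplicate barcodes, duplicate matrix coordinates, empty gene
    symbols, non-finite values and negative values.  Negative values are an
    error for raw counts and a warning otherwise (variance-stabilised
    normalisations may legitimately go below zero).
    """
    rep = ValidationReport()
    seen_bc: dict[str, int] = {}
    for i, bc in enumerate(bundle.barcodes, start=1):
        if bc in seen_bc:
            rep.add_error("DUP_BARCODE",
                          f"barcode {bc!r} listed at positions {seen_bc[bc]} and {i}",
                          f"barcodes.tsv:{i}")
        else:
            seen_bc[bc] = i
    for i, (ens, sym, _ftype) in enumerate(bundle.features, start=1):
        if not sym:
            rep.add_error("EMPTY_SYMBOL", f"feature {ens!r} has an empty gene symbol",
                          f"features.tsv:{i}")
    seen_coord: set[tuple[int, int]] = set()
    for r, c, v in bundle.triples:
        if (r, c) in seen_coord:
            rep.add_error("DUP_COORD", f"duplicate coordinate ({r}, {c})",
                          f"matrix.mtx ({r},{c})")
        seen_coord.add((r, c))
        if math.isnan(v) or math.isinf(v):
            rep.add_error("NON_FINITE", f"non-finite value at ({r}, {c})",
                          f"matrix.mtx ({r},{c})")
        elif v < 0:
            msg = f"negative value {v} at ({r}, {c})"
            if matrix_kind == "raw":
                rep.add_error("NEGATIVE_VALUE", msg, f"matrix.mtx ({r},{c})")
            else:
                rep.add_warning("NEGATIVE_VALUE", msg, f"matrix.mtx ({r},{c})")
        if not 1 <= r <= bundle.n_features or not 1 <= c <= bundle.n_barcodes:
            rep.add_error("INDEX_RANGE", f"coordinate ({r}, {c}) out of range",
                          f"matrix.mtx ({r},{c})")
    return rep


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _fmt_value(v: float) -> str:
    # integers bit-exact, floats via shortest round-tripping repr
    if float(v).is_integer() and abs(v) < 2 ** 53:
        return str(int(v))
    return repr(float(v))


def write_10x_dir(bundle: TenXBundle, path: Union[str, Path],
                  compress: bool = False) -> None:
    """Write a bundle as a 10x directory; with ``compress`` the three files
    get a ``.gz`` suffix.  Reading the result yields an equal bundle."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if compress else ""
    opener = (lambda p: gzip.open(p, "wt", encoding="utf-8")) if compress \
        else (lambda p: open(p, "wt", encoding="utf-8"))
    with opener(path / ("features.tsv" + suffix)) as fh:
        for ens, sym, ftype in bundle.features:
            fh.write(f"{ens}\t{sym}\t{ftype}\n")
    with opener(path / ("barcodes.tsv" + suffix)) as fh:
        for bc in bundle.barcodes:
            fh.write(bc + "\n")
    with opener(path / ("matrix.mtx" + suffix)) as fh:
        fh.write("%%MatrixMarket matrix coordinate real general\n")
        fh.write(f"{bundle.n_features} {bundle.n_barcodes} {len(bundle.triples)}\n")
        for r, c, v in bundle.triples:
            fh.write(f"{r} {c} {_fmt_value(v)}\n")


# ---------------------------------------------------------------------------
# Tag TSVs
# ---------------------------------------------------------------------------

def read_tag_tsv(path: Union[str, Path]) -> list[tuple[str, dict]]:
    """Parse a tag TSV (header row; first column is the entity name/barcode,
    remaining columns are tag keys).  Numeric-looking cells become numbers;
    empty cells mean "no tag"."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise FormatError(f"{path.name}: empty tag TSV")
        keys = header.split("\t")[1:]
        rows = []
        for i, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != len(keys) + 1:
                raise FormatError(
                    f"{path.name}:{i}: expected {len(keys) + 1} columns, got {len(cols)}")
            tags = {k: coerce_tag_value(c) for k, c in zip(keys, cols[1:]) if c != ""}
            rows.append((cols[0], tags))
    return rows


def apply_cell_tag_tsv(store: Store, sample_id: int, path: Union[str, Path]) -> int:
    """Bulk tag update for the cells of one committed sample from a TSV keyed
    by barcode.  Unknown barcodes abort the whole update."""
    rows = read_tag_tsv(path)
    cat = store.catalog
    if sample_id not in cat.samples:
        raise NotFoundError(f"unknown sample id {sample_id}")
    unknown = [bc for bc, _ in rows if (sample_id, bc) not in cat.cell_by_key]
    if unknown:
        raise ValidationError(
            f"tag TSV references unknown barcodes: {', '.join(unknown[:10])}"
            + (" ..." if len(unknown) > 10 else ""))
    updates = [(cat.cell_by_key[(sample_id, bc)], tags) for bc, tags in rows]
    return store.bulk_upsert_tags("cell", updates)


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def load_bundle(store: Store, project_id: int, sample_name: str, bundle: TenXBundle,
                matrix_kind: str, cell_tags_tsv: Optional[Union[str, Path]] = None,
                sample_tags: Optional[dict] = None,
                ) -> tuple[int, int, int, int]:
    """Load one bundle as one sample + one measurement set, atomically.

    The feature table is content-hashed and an existing feature set with the
    same hash is reused, so repeated loads of data aligned to the same
    reference share one feature set.  If the sample already exists on the
    project (e.g. a second matrix kind for the same cells), its cells are
    reused and only a new measurement set is created.  Barcodes missing from
    the tag TSV are loaded untagged.  Returns
    ``(sample_id, measurementset_id, n_cells, n_entries)``.
    """
    report = validate_bundle(bundle, matrix_kind)
    if not report.ok:
        codes = ", ".join(sorted({e[0] for e in report.errors}))
        raise ValidationError(f"bundle failed validation ({codes}); load rejected")
    tag_rows = read_tag_tsv(cell_tags_tsv) if cell_tags_tsv is not None else []
    known = set(bundle.barcodes)
    unknown = [bc for bc, _ in tag_rows if bc not in known]
    if unknown:
        raise ValidationError(
            f"tag TSV references unknown barcodes: {', '.join(unknown[:10])}"
            + (" ..." if len(unknown) > 10 else ""))
    tag_by_bc = {bc: tags for bc, tags in tag_rows}

    txn = store.begin_load(project_id)
    try:
        fs_hash = bundle.feature_table_hash()
        fsid = txn.catalog.featureset_by_hash.get(fs_hash)
        if fsid is None:
            fsid = txn.register_featureset(table_hash=fs_hash)
            for ens, sym, ftype in bundle.features:
                txn.register_feature(fsid, ens, sym, feature_type=ftype)
        feature_ids = txn.catalog.features_by_set[fsid]

        existing_sid = txn.catalog.sample_by_key.get((project_id, sample_name))
        if existing_sid is not None:
            sid = existing_sid
            cells = txn.catalog.cells_by_sample[sid]
            by_name = {txn.catalog.cells[c].name: c for c in cells}
            if set(by_name) != known:
                raise ValidationError(
                    f"sample {sample_name!r} exists with a different barcode set")
            cell_ids = [by_name[bc] for bc in bundle.barcodes]
            for bc, tags in tag_by_bc.items():
                txn.upsert_tags("cell", by_name[bc], tags)
        else:
            sid = txn.register_sample(sample_name, tags=sample_tags)
            cell_ids = [txn.register_cell(sid, bc, tags=tag_by_bc.get(bc))
                        for bc in bundle.barcodes]

        mid = txn.register_measurementset(sid, fsid, matrix_kind,
                                          name=f"{sample_name}:{matrix_kind}")
        n = store.write_entries(
            txn,
            ((cell_ids[c - 1], feature_ids[r - 1], v) for r, c, v in bundle.triples),
            mid)
        store.commit_load(txn)
    except BaseException:
        store.abort_load(txn)
        raise
    return sid, mid, len(bundle.barcodes), n
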