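"""Seeded multi-project synthetic atlas generator with an exact truth manifest.

The generator emulates what makes a public cell-atlas corpus awkward:
several projects with heterogeneous cell-type tag keys (``cell_type``,
``CellType``, ``celltypes``, ``celltype1``, ...), sparse raw + normalized
matrices in 10x CellRanger v3 layout, ontology term annotations (``CL ID``)
and planted marker/co-expression structure.  Everything that queries can
measure is planted deterministically:

* cell-type labels get exact per-sample counts (largest-remainder
  apportionment of the configured proportions);
* marker positives for a gene are a prefix of a per-(sample, label)
  shuffled cell order shared across genes, so a k-gene co-expression count
  has the closed form ``min(k_g)`` per group — no sampling error;
* background expression only ever touches non-marker genes, drawn
  log-normal at a fixed per-cell count, so entry totals are exact too.

``generate_atlas`` writes the 10x directories, per-sample tag TSVs, an
identity harmonization map and a JSON truth manifest whose counts are
recomputed from the generated matrices and asserted against the planted
closed forms before anything is returned.  One RNG stream per project,
keyed by (seed, project index), keeps projects independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from .array_store import Store
from .core_model import ValidationError
from .harmonize import HARMONIZED_KEY, HarmonizationMap, apply_harmonization
from .ingest_10x import TenXBundle, load_bundle, read_10x_dir, write_10x_dir
from .query_engine import (CellQuery, CellSet, ExpressionFilter, QueryEngine,
                           TagFilter)

__all__ = [
    "MarkerSpec",
    "AtlasConfig",
    "default_config",
    "small_config",
    "generate_atlas",
    "load_atlas",
    "default_benchmark_workload",
    "run_workload",
    "QUERY1_LABELS",
    "QUERY2_LOCATIONS",
    "COEXPRESSION_GENES",
]

# The six cell-type labels and three locations of the benchmark tag queries,
# and the viral-entry gene panel used by the co-expression queries.
QUERY1_LABELS = ("Enterocyte", "Enterocytes", "Best4+ Enterocytes",
                 "Enterocyte Progenitors", "Immature Enterocytes 1",
                 "Immature Enterocytes 2")
QUERY2_LOCATIONS = ("Rectum", "Decidua", "Ileum")
COEXPRESSION_GENES = ("ACE2", "TMPRSS2", "DPP4")


@dataclass(frozen=True)
class MarkerSpec:
    """Plant ``gene = value`` (normalized) on a ``positive_fraction`` prefix
    of each sample's cells carrying ``label``."""
    label: str
    gene: str
    value: float
    positive_fraction: float


@dataclass
class AtlasConfig:
    n_projects: int = 5
    samples_per_project: int = 2
    cells_per_sample: int = 1000
    n_genes: int = 500
    background_density: float = 0.05     # fraction of non-marker genes per cell
    seed: int = 0
    project_names: Optional[list] = None
    celltype_keys: tuple = ("cell_type", "CellType", "celltypes", "celltype1",
                            HARMONIZED_KEY)
    label_proportions: dict = field(default_factory=lambda: {
        "Enterocyte": 0.12, "Enterocytes": 0.06, "Best4+ Enterocytes": 0.04,
        "Enterocyte Progenitors": 0.05, "Immature Enterocytes 1": 0.04,
        "Immature Enterocytes 2": 0.04, "Goblet": 0.10, "Ciliated": 0.08,
        "AT2": 0.10, "Gallbladder": 0.07, "Common Bile Duct": 0.05,
        "Proximal tubule": 0.05, "Monocyte": 0.10, "Endothelial": 0.10,
    })
    markers: tuple = (
        MarkerSpec("Enterocyte", "ACE2", 2.0, 0.5),
        MarkerSpec("Enterocyte", "TMPRSS2", 1.5, 0.3),
        MarkerSpec("Enterocyte", "DPP4", 1.2, 0.2),
        MarkerSpec("Enterocytes", "ACE2", 2.0, 0.4),
        MarkerSpec("Enterocytes", "TMPRSS2", 1.5, 0.2),
        MarkerSpec("Gallbladder", "ACE2", 2.5, 0.6),
        MarkerSpec("Gallbladder", "TMPRSS2", 2.0, 0.5),
        MarkerSpec("Gallbladder", "DPP4", 1.5, 0.3),
        MarkerSpec("AT2", "TMPRSS2", 2.0, 0.7),
        MarkerSpec("AT2", "ACE2", 1.1, 0.1),
        MarkerSpec("Ciliated", "TMPRSS2", 1.8, 0.4),
        MarkerSpec("Common Bile Duct", "ACE2", 2.0, 0.5),
        MarkerSpec("Common Bile Duct", "TMPRSS2", 1.6, 0.4),
        MarkerSpec("Common Bile Duct", "DPP4", 1.3, 0.2),
        MarkerSpec("Proximal tubule", "ACE2", 1.5, 0.3),
        MarkerSpec("Proximal tubule", "DPP4", 2.0, 0.4),
        MarkerSpec("Goblet", "TMPRSS2", 1.4, 0.2),
    )
    #: cell-type label -> CL term planted as the "CL ID" cell tag; labels
    #: absent from the map stay unannotated at the ontology level.
    cl_map: dict = field(default_factory=lambda: {
        "Enterocyte": "CL:0000584", "Enterocytes": "CL:0000584",
        "Best4+ Enterocytes": "CL:4030026",
        "Enterocyte Progenitors": "CL:1000335",
        "Immature Enterocytes 1": "CL:1000334",
        "Immature Enterocytes 2": "CL:1000334",
        "Goblet": "CL:0000160", "Ciliated": "CL:0000064",
        "AT2": "CL:0002063", "Monocyte": "CL:0000576",
        "Endothelial": "CL:0000115",
    })
    locations: tuple = ("Rectum", "Decidua", "Ileum", "Lung", "Liver",
                       "Heart", "Blood", "Kidney")
    location_uberon: dict = field(default_factory=lambda: {
        "Rectum": "UBERON:0001052", "Decidua": "UBERON:0002450",
        "Ileum": "UBERON:0002116", "Lung": "UBERON:0002048",
        "Liver": "UBERON:0002107", "Heart": "UBERON:0000948",
        "Blood": "UBERON:0000178", "Kidney": "UBERON:0002113",
    })
    background_lognorm: tuple = (0.0, 1.0)   # (mu, sigma) of ln(value)

    def __post_init__(self):
        # normalise sequence fields so YAML round trips compare equal
        self.markers = tuple(MarkerSpec(**m) if isinstance(m, dict) else m
                             for m in self.markers)
        self.celltype_keys = tuple(self.celltype_keys)
        self.locations = tuple(self.locations)
        self.background_lognorm = tuple(self.background_lognorm)
        total = sum(self.label_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"label proportions must sum to 1, got {total}")
        for m in self.markers:
            if not 0.0 <= m.positive_fraction <= 1.0:
                raise ValidationError(
                    f"positive_fraction for ({m.label}, {m.gene}) outside [0, 1]")
            if m.label not in self.label_proportions:
                raise ValidationError(f"marker label {m.label!r} not in proportions")
        if self.project_names is None:
            base = ["wang20_rectum", "hca_immune_census", "lung_atlas",
                    "liver_atlas", "kidney_atlas"]
            while len(base) < self.n_projects:
                base.append(f"project_{len(base):02d}")
            self.project_names = base[: self.n_projects]
        if len(self.project_names) != self.n_projects:
            raise ValidationError("project_names length must equal n_projects")
        marker_genes = {m.gene for m in self.markers}
        if self.n_genes < len(marker_genes) + 1:
            raise ValidationError("n_genes too small for the marker scheme")

    # -- YAML round trip ----------------------------------------------------

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "AtlasConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    # -- derived ------------------------------------------------------------

    def gene_table(self) -> list[tuple[str, str, str]]:
        """(ensembl_id, symbol, feature_type) rows; the viral-entry panel
        first, then filler genes."""
        named = [("ENSG00000130234", "ACE2"), ("ENSG00000184012", "TMPRSS2"),
                 ("ENSG00000197635", "DPP4")]
        extra_markers = sorted({m.gene for m in self.markers}
                               - {s for _, s in named})
        for i, sym in enumerate(extra_markers):
            named.append((f"ENSG99{900000 + i:06d}", sym))
        rows = [(e, s, "Gene Expression") for e, s in named]
        for i in range(len(rows), self.n_genes):
            rows.append((f"ENSG99{i:06d}", f"GENE{i:04d}", "Gene Expression"))
        return rows


def default_config(seed: int = 0) -> AtlasConfig:
    """The default study conditions: 5 projects x 2 samples x 1,000 cells,
    500 genes, 5% background density."""
    return AtlasConfig(seed=seed)


def small_config(seed: int = 0) -> AtlasConfig:
    """A scaled-down atlas (2 projects x 1 sample x 200 cells, 60 genes) for
    fast unit tests; same structure, same planted vocabulary."""
    return AtlasConfig(n_projects=2, samples_per_project=1, cells_per_sample=200,
                       n_genes=60, seed=seed)


# ---------------------------------------------------------------------------
# Apportionment and planting
# ---------------------------------------------------------------------------

def _apportion(proportions: dict, n: int) -> dict:
    """Largest-remainder apportionment of n cells over labels; exact."""
    labels = sorted(proportions)
    raw = {l: proportions[l] * n for l in labels}
    counts = {l: int(math.floor(raw[l])) for l in labels}
    short = n - sum(counts.values())
    order = sorted(labels, key=lambda l: (-(raw[l] - counts[l]), l))
    for l in order[:short]:
        counts[l] += 1
    return counts


def _sample_plant(cfg: AtlasConfig, rng: np.random.Generator):
    """Plant one sample: labels, marker positives and background entries.

    Returns (labels per cell, norm dict, raw dict, planted-k bookkeeping)
    with matrix coordinates (cell_index, gene_index), 0-based."""
    n = cfg.cells_per_sample
    genes = cfg.gene_table()
    gene_index = {sym: i for i, (_, sym, _) in enumerate(genes)}
    marker_genes = {m.gene for m in cfg.markers}
    bg_genes = np.array([i for i, (_, sym, _) in enumerate(genes)
                         if sym not in marker_genes])

    counts = _apportion(cfg.label_proportions, n)
    labels: list[str] = []
    for l in sorted(counts):
        labels.extend([l] * counts[l])
    perm = rng.permutation(n)
    labels = [labels[p] for p in perm]

    by_label: dict[str, list[int]] = {}
    for ci, l in enumerate(labels):
        by_label.setdefault(l, []).append(ci)
    # one shuffled order per (sample, label), shared across marker genes so
    # positives are nested prefixes
    for l in by_label:
        order = np.array(by_label[l])
        rng.shuffle(order)
        by_label[l] = order.tolist()

    norm: dict[tuple[int, int], float] = {}
    raw: dict[tuple[int, int], float] = {}
    planted_k: dict[tuple[str, str], int] = {}
    for m in cfg.markers:
        cells_l = by_label.get(m.label, [])
        k = int(round(m.positive_fraction * len(cells_l)))
        planted_k[(m.label, m.gene)] = k
        gi = gene_index[m.gene]
        for ci in cells_l[:k]:
            norm[(ci, gi)] = m.value
            raw[(ci, gi)] = float(max(1, int(round(m.value * 2))))

    n_bg = int(round(cfg.background_density * len(bg_genes)))
    mu, sigma = cfg.background_lognorm
    for ci in range(n):
        chosen = rng.choice(bg_genes, size=n_bg, replace=False)
        vals = np.exp(rng.normal(mu, sigma, size=n_bg))
        rawvals = rng.integers(1, 11, size=n_bg)
        for gi, v, rv in zip(chosen.tolist(), vals.tolist(), rawvals.tolist()):
            norm[(ci, gi)] = v
            raw[(ci, gi)] = float(rv)
    return labels, norm, raw, planted_k


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate_atlas(cfg: AtlasConfig, out_dir: Union[str, Path],
                   compress: bool = False) -> dict:
    """Write a synthetic atlas to ``out_dir`` and return its manifest.

    Layout: ``projects/<project>/<sample>/{raw,normalized}/`` 10x
    directories plus ``tags.tsv`` per sample, ``harmonization.tsv`` and
    ``manifest.json`` at the root.  Identical (config, seed) produce
    byte-identical output.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genes = cfg.gene_table()
    gene_index = {sym: i for i, (_, sym, _) in enumerate(genes)}

    manifest: dict = {"config": dataclasses.asdict(cfg), "projects": []}
    hmap_rows: list[tuple] = []

    # per-cell records for truth computation:
    # (project, sample, barcode, label, location, norm values for marker genes)
    cell_records: list[dict] = []
    sample_seq = 0
    for pi, pname in enumerate(cfg.project_names):
        rng = np.random.default_rng([cfg.seed, pi])
        ct_key = cfg.celltype_keys[pi % len(cfg.celltype_keys)]
        pentry = {"name": pname, "celltype_key": ct_key, "samples": [],
                  "n_entries": {"raw": 0, "normalized": 0},
                  "value_sum": {"raw": 0.0, "normalized": 0.0}}
        for si in range(cfg.samples_per_project):
            sname = f"S{si + 1}"
            location = cfg.locations[sample_seq % len(cfg.locations)]
            sample_seq += 1
            labels, norm, raw, planted_k = _sample_plant(cfg, rng)
            barcodes = [f"{pname}-{sname}-BC{i:05d}" for i in range(cfg.cells_per_sample)]

            sdir = out / "projects" / pname / sname
            for kind, entries in (("raw", raw), ("normalized", norm)):
                triples = [(gi + 1, ci + 1, v)
                           for (ci, gi), v in sorted(entries.items())]
                bundle = TenXBundle(genes, barcodes, triples)
                write_10x_dir(bundle, sdir / kind, compress=compress)
                pentry["n_entries"][kind] += len(triples)
                pentry["value_sum"][kind] += float(sum(v for _, _, v in triples))

            mt = np.round(rng.uniform(0, 10, size=cfg.cells_per_sample), 3)
            with open(sdir / "tags.tsv", "wt", encoding="utf-8") as fh:
                fh.write(f"barcode\t{ct_key}\tCL ID\tpercent.mt\n")
                for bc, l, m in zip(barcodes, labels, mt.tolist()):
                    cl = cfg.cl_map.get(l, "")
                    fh.write(f"{bc}\t{l}\t{cl}\t{m}\n")

            sample_tags = {"Location": location, "organ": location.lower()}
            if location in cfg.location_uberon:
                sample_tags["UBERONID"] = cfg.location_uberon[location]
            pentry["samples"].append({
                "name": sname, "dir": str(Path("projects") / pname / sname),
                "tags_tsv": str(Path("projects") / pname / sname / "tags.tsv"),
                "sample_tags": sample_tags, "n_cells": cfg.cells_per_sample,
            })

            marker_gis = {m.gene: gene_index[m.gene] for m in cfg.markers}
            for ci, (bc, l) in enumerate(zip(barcodes, labels)):
                mv = {g: norm.get((ci, gi), 0.0) for g, gi in marker_gis.items()}
                cell_records.append({"project": pname, "sample": sname,
                                     "barcode": bc, "label": l,
                                     "location": location, "norm": mv,
                                     "n_norm_entries": 0})
            # per-cell normalized entry counts, for fetch-row truths
            per_cell = {}
            for (ci, gi) in norm:
                per_cell[ci] = per_cell.get(ci, 0) + 1
            base = len(cell_records) - cfg.cells_per_sample
            for ci, cnt in per_cell.items():
                cell_records[base + ci]["n_norm_entries"] = cnt
            pentry.setdefault("_planted_k", []).append(
                {f"{l}|{g}": k for (l, g), k in planted_k.items()})

        for l in sorted(cfg.label_proportions):
            hmap_rows.append((pname, ct_key, l, l))
        manifest["projects"].append(pentry)

    HarmonizationMap(hmap_rows).to_tsv(out / "harmonization.tsv")
    manifest["harmonization_tsv"] = "harmonization.tsv"
    manifest["truth"] = _compute_truth(cfg, manifest, cell_records)
    for p in manifest["projects"]:
        p.pop("_planted_k", None)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _members(records) -> list:
    return [[r["project"], r["sample"], r["barcode"]] for r in records]


def _compute_truth(cfg: AtlasConfig, manifest: dict, records: list[dict]) -> dict:
    """Recompute every workload answer from the generated data and assert it
    against the planted closed forms."""
    thr = 1.0
    q1 = [r for r in records if r["label"] in QUERY1_LABELS]
    q2 = [r for r in q1 if r["location"] in QUERY2_LOCATIONS]
    q3 = [r for r in records
          if all(r["norm"].get(g, 0.0) >= thr for g in ("ACE2", "TMPRSS2"))]
    q4 = [r for r in q3 if r["norm"].get("DPP4", 0.0) >= thr]
    q6 = [r for r in q1 if r["norm"].get("ACE2", 0.0) >= thr]

    # closed-form cross-check of the co-expression counts: per (sample,
    # label) the positives of each marker gene are nested prefixes, so the
    # joint count is min(k_g) over labels carrying every queried gene.
    def closed_form(gene_set):
        total = 0
        for p in manifest["projects"]:
            for planted in p["_planted_k"]:
                for l in cfg.label_proportions:
                    ks = [planted.get(f"{l}|{g}") for g in gene_set]
                    if all(k is not None for k in ks):
                        total += min(ks)
        return total

    marker_vals = {(m.label, m.gene): m.value for m in cfg.markers}
    if all(v >= thr for v in marker_vals.values()):
        assert len(q3) == closed_form(("ACE2", "TMPRSS2")), "co-expression planting drifted"
        assert len(q4) == closed_form(("ACE2", "TMPRSS2", "DPP4")), \
            "triple co-expression planting drifted"

    def entry(name, recs, n_rows=None):
        d = {"name": name, "n_cells": len(recs),
             "n_projects": len({r["project"] for r in recs}),
             "members": _members(recs)}
        if n_rows is not None:
            d["n_rows"] = n_rows
        return d

    # expression-fetch row counts (normalized)
    marker_genes = {m.gene for m in cfg.markers}
    q5_genes = [g for g in COEXPRESSION_GENES]
    q5_rows = sum(1 for r in records for g in q5_genes if r["norm"].get(g, 0.0) != 0.0)
    q5_projects = len({r["project"] for r in records
                       if any(r["norm"].get(g, 0.0) != 0.0 for g in q5_genes)})
    q6_rows = sum(r["n_norm_entries"] for r in q6)
    q7_project = cfg.project_names[0]
    q7_rows = next(p["n_entries"]["normalized"] for p in manifest["projects"]
                   if p["name"] == q7_project)
    q7_cells = [r for r in records if r["project"] == q7_project]

    enterocyte_terms = {"CL:0000584", "CL:1000334", "CL:1000335", "CL:4030026"}
    cl_desc = [r for r in records if cfg.cl_map.get(r["label"]) in enterocyte_terms]

    per_project_pos: dict[str, dict[str, int]] = {}
    for r in records:
        d = per_project_pos.setdefault(r["project"], {g: 0 for g in sorted(marker_genes)})
        for g in marker_genes:
            if r["norm"].get(g, 0.0) >= thr:
                d[g] += 1

    workload = [
        entry("q1_celltype_anyof", q1),
        entry("q2_celltype_and_location", q2),
        entry("q3_coexpression_2gene", q3),
        entry("q4_coexpression_3gene", q4),
        {"name": "q5_expression_by_gene_list", "n_rows": q5_rows,
         "n_projects": q5_projects, "genes": q5_genes},
        entry("q6_refine_q1_then_fetch", q6, n_rows=q6_rows),
        {"name": "q7_project_dump", "project": q7_project, "n_rows": q7_rows,
         "n_cells": len(q7_cells), "n_projects": 1},
    ]
    return {
        "n_cells_total": len(records),
        "threshold": thr,
        "workload": workload,
        "cl_enterocyte_descendants": {"n_cells": len(cl_desc),
                                      "members": _members(cl_desc)},
        "marker_positive_per_project": per_project_pos,
    }


def atlas_checksum(out_dir: Union[str, Path]) -> str:
    """SHA-256 over every file of a generated atlas (sorted relative paths);
    used by determinism checks."""
    out = Path(out_dir)
    h = hashlib.sha256()
    for p in sorted(out.rglob("*")):
        if p.is_file():
            h.update(str(p.relative_to(out)).encode())
            h.update(p.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Loading a generated atlas into a store
# ---------------------------------------------------------------------------

def load_atlas(store: Store, atlas_dir: Union[str, Path],
               harmonize: bool = True) -> dict:
    """Load every project/sample (both matrix kinds) of a generated atlas,
    apply the cell tag TSVs and the shipped harmonization map, and return
    the atlas manifest."""
    atlas_dir = Path(atlas_dir)
    manifest = json.loads((atlas_dir / "manifest.json").read_text())
    for p in manifest["projects"]:
        pid = store.register_project(p["name"])
        for s in p["samples"]:
            sdir = atlas_dir / s["dir"]
            bundle_norm = read_10x_dir(sdir / "normalized")
            load_bundle(store, pid, s["name"], bundle_norm, "normalized",
                        cell_tags_tsv=atlas_dir / s["tags_tsv"],
                        sample_tags=s["sample_tags"])
            bundle_raw = read_10x_dir(sdir / "raw")
            load_bundle(store, pid, s["name"], bundle_raw, "raw")
    if harmonize:
        hmap = HarmonizationMap.from_tsv(atlas_dir / manifest["harmonization_tsv"])
        apply_harmonization(store, hmap)
    return manifest


def resolve_members(store: Store, members: list) -> frozenset:
    """Map manifest member triples (project, sample, barcode) to cell ids."""
    cat = store.catalog
    out = set()
    for pname, sname, bc in members:
        pid = cat.project_id_by_name(pname)
        sid = cat.sample_by_key[(pid, sname)]
        out.add(cat.cell_by_key[(sid, bc)])
    return frozenset(out)


# ---------------------------------------------------------------------------
# The seven-query benchmark workload
# ---------------------------------------------------------------------------

#: placeholder used by the workload for "the result of query 1".
BASE_QUERY_1 = "q1"


def default_benchmark_workload() -> list:
    """Seven queries mirroring the benchmark workload: any-of tag selection,
    tag + location, 2- and 3-gene co-expression at >= 1 on normalized data,
    expression fetch by gene list, refine-query-1-then-fetch, and a
    single-project dump."""
    tag_q1 = TagFilter("cell", HARMONIZED_KEY, frozenset(QUERY1_LABELS))
    loc = TagFilter("sample", "Location", frozenset(QUERY2_LOCATIONS))
    coex = [ExpressionFilter(g, "normalized", "ge", 1.0) for g in COEXPRESSION_GENES]
    q1 = CellQuery(filters=(tag_q1,))
    q2 = CellQuery(filters=(tag_q1, loc))
    q3 = CellQuery(filters=tuple(coex[:2]))
    q4 = CellQuery(filters=tuple(coex))
    q5 = CellQuery(fetch_genes=tuple(COEXPRESSION_GENES))
    q6 = CellQuery(filters=(coex[0],), base=BASE_QUERY_1, fetch_genes="all")
    q7 = CellQuery(project_scope=frozenset({"wang20_rectum"}), fetch_genes="all")
    return [q1, q2, q3, q4, q5, q6, q7]


def run_workload(engine: QueryEngine, queries: Optional[list] = None) -> list[dict]:
    """Execute the workload, resolving the query-6 base to the query-1
    result, and report n_cells / n_projects (and n_rows for the fetch
    queries) per query."""
    if queries is None:
        queries = default_benchmark_workload()
    results: list[dict] = []
    cellsets: list[Optional[CellSet]] = []
    for i, q in enumerate(queries):
        base = q.base
        if isinstance(base, str):
            ref = int(base.lstrip("q")) - 1
            q = dataclasses.replace(q, base=cellsets[ref])
        cs = engine.select_cells(q)
        cellsets.append(cs)
        rec = {"query": i + 1, "n_cells": len(cs),
               "n_projects": cs.n_projects_with_data}
        if q.fetch_genes is not None:
            genes = None if q.fetch_genes == "all" else list(q.fetch_genes)
            n_rows = 0
            row_projects = set()
            for row in engine.fetch_expression(cs, genes, "normalized"):
                n_rows += 1
                row_projects.add(row.project_id)
            rec["n_rows"] = n_rows
            # fetch queries report projects contributing rows
            rec["n_projects"] = len(row_projects)
        results.append(rec)
    return results
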