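# sccommons

An array-native, transactional **data commons for multi-project single-cell
RNA-seq expression data**: load many studies' sparse expression matrices and
heterogeneous metadata into one store, then select cells *across* studies by
metadata tags, ontology-expanded terms and gene-expression thresholds —
including multi-gene co-expression — in seconds, without merging everything
into one giant in-memory object.

It is written for computational biologists and data engineers who curate
collections of public single-cell datasets (cell atlases, disease cohorts)
and need to answer questions like *"which cell types co-express ACE2 and
TMPRSS2 at a normalized value ≥ 1, across every study we hold?"* without a
per-question bioinformatics project.

## The model

Quantification data are a sparse 4-dimensional array

```
RNAQUANTIFICATION[sample_id, measurementset_id, cell_id, feature_id] -> value
```

where an absent coordinate carries the value 0, and a *measurement set*
binds one matrix (`raw` or `normalized` counts) to a sample and a feature
set (genome build + gene table). Entities form the hierarchy
*project → sample → cell*, and every entity carries an open key-value tag
map: `DOID`/`UBERONID` at the sample level, `CL ID`, cell-type labels and
QC tags (`percent.mt`) at the cell level. Because public studies name their
cell-type key inconsistently (`cell_type`, `CellType`, `celltypes`,
`celltype1`, …), a curated mapping table writes a unified
`CellType.select` tag across projects; the source tags are never modified.

A cell selection is a conjunction of filters:

- **tag filters** — `key ∈ {v₁, …, vₖ}` (any-of) or a numeric range, at
  project, sample or cell level;
- **ontology filters** — a CL/UBERON/DOID term expanded through the `is_a`
  DAG to its descendants or ancestors (e.g. `CL:0000584` *enterocyte* and
  its children), then applied as an any-of tag filter;
- **expression filters** — per-gene predicates `≥ t`, `> t`, `≤ t`, `< t`
  or `within [a, b]` on raw or normalized values, with implicit zeros
  participating (a cell with no stored entry has value 0);
- co-expression of genes *G* at threshold *t* is the conjunction of
  per-gene `≥ t` filters, hence exactly `∩_{g∈G} select({g}, t)`.

A query may refine a previous result (*base*), the composition used to
fetch expression for a previously selected population. Selected cells can
be summarised as a **prevalence table**: per-label percentages with labels
under 1% pooled into an `Others` bucket.

Loads are ACID-style: a load stages entities and entries, and a single
atomic manifest swap publishes the new version — a crash at any earlier
point leaves the previous version intact, and readers never see a
half-applied load. On disc, entries are partitioned into one MatrixMarket
chunk per measurement set with a per-gene secondary index, so gene- and
project-sliced queries touch only the relevant chunks.

## Worked example

Everything is testable without downloads via the bundled synthetic-atlas
generator, which plants cell-type labels, ontology annotations and marker
co-expression with exact, machine-readable expected counts
(`manifest.json`):

```bash
$ sccommons synth --out atlas --seed 5 --small
wrote atlas with 400 cells to atlas

$ sccommons load atlas/projects/wang20_rectum/S1/normalized \
    --store store --project wang20_rectum --sample S1 \
    --kind normalized --tags atlas/projects/wang20_rectum/S1/tags.tsv
loaded sample S1 (id 0), measurementset 0: 200 cells, 694 entries

$ sccommons load atlas/projects/hca_immune_census/S1/normalized \
    --store store --project hca_immune_census --sample S1 \
    --kind normalized --tags atlas/projects/hca_immune_census/S1/tags.tsv
loaded sample S1 (id 1), measurementset 1: 200 cells, 694 entries

$ sccommons query --store store --coexpress ACE2,TMPRSS2 \
    --min 1 --kind normalized --out cells.tsv
44 cells (2 projects with data)

$ sccommons summarize --store store --cellset cells.tsv --key "CL ID"
label	percentage
Unannotated	50.00
CL:0000584	40.91
CL:0002063	9.09
Others	0.00
```

The query selected the 44 cells (out of 400) in which both ACE2 and
TMPRSS2 have normalized expression ≥ 1 — exactly the count planted by the
generator's manifest. The prevalence table groups those cells by their
Cell Ontology annotation: 40.91% are enterocytes (`CL:0000584`), 9.09%
type II pneumocytes (`CL:0002063`), and half carry cell-type labels with
no CL annotation (`Unannotated`); no label fell under the 1% cutoff, so
`Others` is 0.

The same operations are available as a library (`sccommons.Store`,
`QueryEngine`, `celltype_prevalence`, …) and over REST
(`sccommons serve`, endpoints under `/v1`: project CRUD, 10x upload, bulk
tag updates, query resolution with server-side cell sets, paged expression
download, prevalence summaries).

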