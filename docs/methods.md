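# Methods

## Data model and storage

The store models quantification data as a sparse 4-D array addressed by
`(sample_id, measurementset_id, cell_id, feature_id)`. All surrogate ids
are 0-based, dense and assigned in insertion order, so ids double as array
coordinates downstream. An absent coordinate is defined to carry value 0
("implicit zero"); zeros are never materialised. Values are stored as
64-bit floats for both raw and normalized matrices; `raw` values must be
finite and non-negative, `normalized` values finite (variance-stabilising
transforms can legitimately produce negatives, so they are only a warning
at validation time).

Physically, entries are partitioned into one MatrixMarket coordinate file
per measurement set — i.e. per (project, sample, matrix kind) slice —
under `chunks/`, with a JSON manifest naming the committed version, the
chunk list and SHA-256 checksums. The dominant query shapes are gene
slices within a project scope, so each chunk carries a lazily built
in-memory secondary index (feature → posting list of (cell, value));
project-restricted reads touch only that project's chunk files, which the
store makes observable through an I/O log. The catalog (entities + tags)
is persisted as plain TSV tables per version. Chunk files are immutable
once written; catalog directories are rewritten per version and old ones
pruned after the manifest swap.

### Transactions and crash safety

A load transaction stages entity registrations in a shadow copy of the
catalog and expression entries in per-measurement-set staging dicts;
readers of the store never see staged state. Commit proceeds in four
stages — validate, write chunks, write catalog, swap manifest — and only
the final `os.replace` of `manifest.json` publishes the new version.
Because every file written before the swap has a fresh, version-qualified
name, a crash at any stage leaves the previous manifest pointing at intact
files; reopening the store shows the old version. A fault-injection hook
fires before each stage so tests can kill a commit at every point.
Versioning is linear: one open load per project at a time, many readers;
full MVCC is deliberately not attempted — the workload is curated bulk
loads, not OLTP. Catalog-only mutations (tag upserts, harmonization,
deletes) also commit as full versions; bulk operations validate every row
before touching anything so a bad row leaves the store unchanged.

Deleting a project removes the project entity and all of its samples,
cells, measurement sets and entries in one commit; feature sets are shared
across projects and retained.

## 10x ingest

Bundles are the CellRanger v3 triple `matrix.mtx` / `features.tsv` /
`barcodes.tsv`, plain or gzipped; 2-column feature tables (pre-v3) are
accepted with the feature type defaulted. MatrixMarket indices are 1-based
per the standard and converted to internal 0-based ids exactly once, in
the ingest module. The matrix parser is line-based rather than
`scipy.io.mmread` because the validation contract needs line-numbered
bounds errors and must observe duplicate coordinates, which mmread sums
silently; a test cross-checks the parser against mmread on clean bundles.
Writing uses shortest round-tripping decimal representations (integers
bit-exact), giving read∘write identity on valid bundles.

Loading a bundle creates one sample, one cell per barcode, one measurement
set, and reuses an existing feature set when the feature table's content
hash matches. Loading a second matrix kind for an existing sample reuses
its cells. Cells present in `barcodes.tsv` but absent from the tag TSV are
loaded untagged — dropping them would violate conservation of mass, which
is checked (sum of loaded values equals the bundle sum, rel. 1e-9). A tag
TSV referencing unknown barcodes rejects the whole load.

## Ontologies

CL, UBERON and DOID are parsed from OBO with obonet; only `is_a` edges
define the hierarchy by default (`part_of` is opt-in, since only
parent/child semantics are part of the query contract), obsolete terms are
dropped, and ids that are not `PREFIX:digits` CURIEs (header artefacts)
are ignored. Descendant/ancestor expansion is the reflexive-transitive
closure on the DAG via networkx; a cyclic `is_a` graph is rejected with
one offending cycle named. The repo packages miniature (≤100-term)
synthetic subsets of the three vocabularies sufficient for tests; full
ontologies load through the same path but are never required.

## Query semantics

Queries are conjunctions; disjunction is expressed through any-of value
sets. Decisions that were genuinely open:

- Threshold `≥ 1` is inclusive; all five predicate forms (`≥ > ≤ <`,
  `within`) are exposed.
- A cell lacking a filtered tag key fails that filter — absence is not a
  wildcard. An unknown tag key therefore yields an empty result with a
  warning, not an error (the key may simply not occur in the loaded data).
- Gene symbols resolve to the union of matching features and a cell passes
  if *any* matching feature passes; public data are mostly symbol-annotated
  and symbol duplication is real. ENSEMBL selectors narrow to one feature.
  A selector matching nothing contributes an empty set to the conjunction
  (empty result) and a warning in the result's provenance.
- Predicates satisfied by 0 (e.g. `< 7`) are evaluated by complement:
  a cell fails only if every matching feature has a stored, failing value.
- If a sample carries several measurement sets of one kind, the latest
  wins per coordinate (deterministic, insertion-ordered).
- Sample- and project-level filters admit a cell iff its ancestors pass.

Prevalence tables list labels with percentage ≥ the cutoff (default 1%);
strictly-below goes to `Others`, so a label at exactly the cutoff is
listed. Cells missing the grouping key are pooled under the literal label
`Unannotated` and then subject to the same rule. Ranking ties break
lexicographically; display rounds to 2 decimals, internal values are
unrounded and listed + Others totals 100 to float precision.

## Harmonization

Cross-study cell-type harmonization is data, not code: a four-column TSV
(project, source key, source value, harmonized value) applied exactly
(no fuzzy matching, so curation stays auditable), additively (source tags
untouched) and idempotently. Conflicting or dangling rows are rejected
before any write. Candidate source keys are detected by the
case-insensitive patterns `celltype` / `cell_type`, ranked by coverage.

## Synthetic atlas generator

The generator emulates the features of a public multi-study corpus that
the query engine must cope with — heterogeneous per-project cell-type tag
keys, sparse raw + normalized matrices in 10x layout, ontology
annotations, planted marker/co-expression structure — while keeping every
queryable quantity exact:

- cell-type labels get exact per-sample counts by largest-remainder
  apportionment of the configured proportions;
- marker positives for each gene are a *prefix* of one per-(sample, label)
  shuffled cell order shared across genes, so a k-gene co-expression count
  is `min(k_g)` per group in closed form rather than a Bernoulli draw;
- background entries are drawn log-normal (μ=0, σ=1 of ln value) at a
  fixed per-cell count over non-marker genes only, so marker-gene truths
  and entry totals are unaffected by distributional choices;
- raw counts share the normalized sparsity pattern with integer values
  drawn independently (markers ≥ 1 by construction).

One RNG stream per project, keyed by (seed, project index), makes projects
independently reproducible; identical (config, seed) give byte-identical
output. The truth manifest is recomputed from the generated matrices and
asserted against the planted closed forms before generation returns, so
manifest counts are exact by construction, not by sampling.

Default conditions: 5 projects × 2 samples × 1,000 cells, 500 genes, 5%
background density, a 14-label vocabulary containing the six
enterocyte-family labels used by the benchmark tag query, sample locations
cycling through eight tissues (so the location filter genuinely shrinks
the tag query), and a marker scheme placing ACE2/TMPRSS2/DPP4 on
epithelial labels at fractions 0.1–0.7 with planted values 1.1–2.5. These
sizes exercise multi-project, multi-sample behaviour while keeping a full
generate + load + query cycle around ten seconds; a scaled-down
configuration (2 × 1 × 200 cells, 60 genes) backs the fast unit tests.
What the generator does *not* emulate: realistic dropout curves, doublets,
batch effects, library-size variation. Passing tests therefore demonstrate
the correctness of storage and query semantics on data with realistic
*structure*, not robustness to real scRNA-seq noise.

## Benchmark workload

`default_benchmark_workload()` returns seven queries spanning the supported
query classes: (1) a six-label `CellType.select` any-of; (2) the same plus
a sample-level `Location` any-of over {Rectum, Decidua, Ileum}; (3) 2-gene
and (4) 3-gene co-expression of ACE2/TMPRSS2(/DPP4) at ≥ 1 on normalized
data; (5) an expression fetch for the 3-gene panel across all projects;
(6) refining the query-1 result by an expression filter and fetching those
cells' expression; (7) a single-project matrix dump. Replaying the
workload against a loaded atlas must reproduce the truth manifest exactly,
including the refinement law `select(q6) = select(q6 unbased) ∩ select(q1)`.

## Interface

The REST service is a plain WSGI application (served with wsgiref),
versioned under `/v1`, with JSON request/response bodies; 10x uploads
carry the three files as text fields of a JSON body. Cell sets created by
`POST /v1/query/cells` are server-side resources with a TTL so follow-up
requests can page through expression or compose refinements. Every
endpoint result equals the corresponding library call on the same store
(enforced by parity tests), and concatenated expression pages equal the
unpaged stream. There is no authentication; the server binds to localhost
by default. The CLI (`sccommons`) is a thin veneer: each subcommand wraps
one library operation and exits nonzero with a diagnostic on failure.

## Verification strategy and limitations

The acceptance suite checks properties, not corpus-specific numbers:
engine/oracle set equality over 200 random mixed queries against an
exhaustive dense scanner, exact truth-manifest replay of the workload,
algebraic laws (intersection, refinement, monotonicity, duality),
conservation (prevalence percentages, entry counts, value sums), format
round trips, and crash atomicity at every commit stage. Known
limitations: single-writer-per-project concurrency only; no distributed
execution; chunk caches are unbounded in memory (fine at the tested
scales); numeric tag filtering coerces values through `float()` rather
than a typed schema; and the packaged ontologies are miniature synthetic
subsets, not the released CL/UBERON/DOID.
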