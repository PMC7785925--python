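"""Cross-project cell-type harmonization via the ``CellType.select`` tag.

Public studies annotate cell types under disparate key names (``cell_type``,
``CellType``, ``celltypes``, ``celltype1``, ...) and label vocabularies.
Harmonization is data, not code: a curated four-column mapping table
(project, source key, source value, harmonized value) is applied to write a
unified ``CellType.select`` tag on matching cells.  Source tags are never
touched, matching is exact (auditable curation, no fuzzy matching), and
re-application is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import pandas as pd

from .array_store import Store
from .core_model import FormatError, NotFoundError, ValidationError

__all__ = ["HARMONIZED_KEY", "HarmonizationMap", "detect_celltype_keys",
           "apply_harmonization"]

HARMONIZED_KEY = "CellType.select"

_COLUMNS = ["project_name", "source_key", "source_value", "harmonized_value"]


@dataclass
class HarmonizationMap:
    """Rows of (project_name, source_key, source_value, harmonized_value);
    the first three columns form a unique key."""
    rows: list

    def __post_init__(self):
        seen: dict[tuple, str] = {}
        for r in self.rows:
            if len(r) != 4:
                raise ValidationError(f"harmonization rows need 4 fields, got {r!r}")
            if not r[3]:
                raise ValidationError(f"empty harmonized value in row {r!r}")
            key = (r[0], r[1], r[2])
            if key in seen:
                if seen[key] != r[3]:
                    raise ValidationError(
                        f"conflicting harmonization targets for {key}: "
                        f"{seen[key]!r} vs {r[3]!r}")
                raise ValidationError(f"duplicate harmonization row for {key}")
            seen[key] = r[3]

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "HarmonizationMap":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"harmonization TSV missing columns: {missing}")
        return cls([tuple(r) for r in df[_COLUMNS].itertuples(index=False)])

    def to_tsv(self, path: Union[str, Path]) -> None:
        pd.DataFrame(self.rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)

    def __len__(self):
        return len(self.rows)


def detect_celltype_keys(store: Store, project_id: int) -> list[str]:
    """Candidate cell-type tag keys of one project: keys whose name contains
    ``celltype`` or ``cell_type`` case-insensitively, ranked by coverage
    (fraction of the project's cells carrying the key), ties alphabetical."""
    keys = store.list_tag_keys("cell", project_id)
    n_cells = len(store.catalog.cells_of_project(project_id))
    candidates = []
    for _, row in keys.iterrows():
        low = row["key"].lower()
        if "celltype" in low or "cell_type" in low:
            coverage = row["n_entities"] / n_cells if n_cells else 0.0
            candidates.append((-coverage, row["key"]))
    return [k for _, k in sorted(candidates)]


def apply_harmonization(store: Store, hmap: HarmonizationMap) -> dict:
    """Write ``CellType.select`` on every cell whose (project, key, value)
    matches a map row.  Validates the whole map before any write; returns a
    report ``{project_name: {"updated": n, "unmapped": {key: {value: n}}}}``
    where "unmapped" counts cells carrying a mapped source key with a value
    the map does not cover."""
    cat = store.catalog
    by_project: dict[str, dict[tuple[str, str], str]] = {}
    for pname, skey, sval, hval in hmap.rows:
        if pname not in cat.project_by_name:
            raise NotFoundError(f"harmonization map references unknown project {pname!r}")
        by_project.setdefault(pname, {})[(skey, sval)] = hval

    report: dict[str, dict] = {}
    updates: list[tuple[int, dict]] = []
    for pname, mapping in by_project.items():
        pid = cat.project_by_name[pname]
        source_keys = {k for k, _ in mapping}
        updated = 0
        unmapped: dict[str, dict[str, int]] = {}
        for cid in cat.cells_of_project(pid):
            tags = cat.cells[cid].tags
            for skey in source_keys:
                if skey not in tags:
                    continue
                sval = str(tags[skey])
                hval = mapping.get((skey, sval))
                if hval is None:
                    bucket = unmapped.setdefault(skey, {})
                    bucket[sval] = bucket.get(sval, 0) + 1
                else:
                    updates.append((cid, {HARMONIZED_KEY: hval}))
                    updated += 1
        report[pname] = {"updated": updated, "unmapped": unmapped}
    if updates:
        store.bulk_upsert_tags("cell", updates)
    return report
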