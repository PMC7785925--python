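"""Cell-type prevalence tables over a selected cell population.

Selected cells are grouped by a tag key (typically ``CellType.select``) and
reported as percentages of the selection; labels under a prevalence cutoff
(default 1%) are pooled into an "Others" bucket.  Cells missing the key are
grouped under the literal label ``"Unannotated"`` and then subject to the
same rule.  A label sitting exactly on the cutoff is listed, not bucketed
(only strictly-below goes to Others).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Union

import pandas as pd

from .array_store import Store
from .core_model import ValidationError
from .query_engine import CellSet

__all__ = ["UNANNOTATED_LABEL", "PrevalenceTable", "celltype_prevalence",
           "projects_with_data"]

UNANNOTATED_LABEL = "Unannotated"


@dataclass
class PrevalenceTable:
    """Rows of (label, percentage) sorted by descending percentage (ties
    alphabetical), plus the pooled Others percentage.  Listed + Others
    always totals 100 (up to float round-off); internal values are
    unrounded, rendering rounds to 2 decimals."""
    rows: list = field(default_factory=list)       # (label, pct 0..100)
    others_percentage: float = 0.0
    n_total: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["label", "percentage"])

    def to_tsv(self) -> str:
        lines = ["label\tpercentage"]
        for label, pct in self.rows:
            lines.append(f"{label}\t{pct:.2f}")
        lines.append(f"Others\t{self.others_percentage:.2f}")
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps({
            "rows": [{"label": l, "percentage": round(p, 2)} for l, p in self.rows],
            "others_percentage": round(self.others_percentage, 2),
            "n_total": self.n_total,
        })


def celltype_prevalence(store: Store, cells: Union[CellSet, set, frozenset],
                        tag_key: str, min_pct: float = 1.0) -> PrevalenceTable:
    """Per-label percentages of a cell set with the sub-threshold Others
    bucket.  ``min_pct = 0`` disables bucketing.  Raises on an empty cell
    set (percentages are undefined)."""
    ids = cells.cell_ids if isinstance(cells, CellSet) else cells
    if not ids:
        raise ValidationError("prevalence of an empty cell set is undefined")
    counts: dict[str, int] = {}
    cat = store.catalog
    for cid in ids:
        label = cat.cells[cid].tags.get(tag_key, UNANNOTATED_LABEL)
        label = str(label)
        counts[label] = counts.get(label, 0) + 1
    n_total = len(ids)
    listed = []
    others = 0.0
    for label in counts:
        pct = 100.0 * counts[label] / n_total
        if pct < min_pct:
            others += pct
        else:
            listed.append((label, pct))
    listed.sort(key=lambda r: (-r[1], r[0]))
    return PrevalenceTable(listed, others, n_total)


def projects_with_data(store: Store, cells: Union[CellSet, set, frozenset]) -> pd.DataFrame:
    """One row per project contributing at least one cell; counts sum to the
    size of the set."""
    ids = cells.cell_ids if isinstance(cells, CellSet) else cells
    cat = store.catalog
    counts: dict[int, int] = {}
    for cid in ids:
        pid = cat.project_of_cell(cid)
        counts[pid] = counts.get(pid, 0) + 1
    rows = [(pid, cat.projects[pid].name, n) for pid, n in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["project_id", "project", "n_cells"])
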