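"""Published cross-tabulations shipped as expandable fixtures.

Each fixture is one printed two-way table from the study, stored as JSON
package data and exposed as a :class:`ContingencyTable` together with its
row-major expansion into (row_label, col_label) observation pairs.  Complete
tables expand to exactly the 131 cohort records; a few printed panels are
internally incomplete (their cells do not sum to the cohort) and are flagged
``display_only`` — they render but are excluded from any statistical
reproduction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

from .cohort import ContingencyTable, expand_table

__all__ = ["ExpandedFixture", "fixture", "fixture_ids"]


@dataclass(frozen=True)
class ExpandedFixture:
    """A printed table plus its record-level expansion."""

    table_id: str
    table: ContingencyTable
    expansion: tuple[tuple[str, str], ...]
    display_only: bool = False

    @property
    def n(self) -> int:
        return self.table.n


@lru_cache(maxsize=1)
def _load_raw() -> dict:
    text = resources.files("exposurekit.data").joinpath("tables.json").read_text()
    return json.loads(text)


def fixture_ids(include_display_only: bool = True) -> tuple[str, ...]:
    """Stable ids of the shipped fixtures, in file order."""
    raw = _load_raw()
    return tuple(
        k for k, v in raw.items()
        if include_display_only or not v.get("display_only", False)
    )


def fixture(table_id: str) -> ExpandedFixture:
    """Return the printed table for ``table_id`` and its expansion."""
    raw = _load_raw()
    if table_id not in raw:
        raise KeyError(
            f"unknown fixture id {table_id!r}; known ids: {sorted(raw)}"
        )
    spec = raw[table_id]
    table = ContingencyTable.from_array(
        spec["counts"],
        spec["row_labels"],
        spec["col_labels"],
        row_var=spec["row_var"],
        col_var=spec["col_var"],
    )
    return ExpandedFixture(
        table_id=table_id,
        table=table,
        expansion=tuple(expand_table(table)),
        display_only=bool(spec.get("display_only", False)),
    )
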