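"""Packaged reference tables used for regression checks and examples.

Four TSV tables ship with the package: novel miRNA families with genomic
coordinates (T2), families conserved in other plant species (T3), isomiR
pattern summaries (T5), and predicted mRNA targets with pairing strings
(T6).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

_FILES = {
    "T2": "table2.tsv",
    "T3": "table3.tsv",
    "T5": "table5.tsv",
    "T6": "table6.tsv",
}

_INT_COLUMNS = {"size", "start", "end", "length", "n_isos"}


@dataclass(frozen=True)
class ReferenceTable:
    table_id: str
    columns: tuple[str, ...]
    rows: tuple[dict, ...]

    def __len__(self) -> int:
        return len(self.rows)

    def column(self, name: str) -> list:
        return [row[name] for row in self.rows]


def load_fixture(table_id: str) -> ReferenceTable:
    """Load one packaged table by id (T2, T3, T5 or T6)."""
    if table_id not in _FILES:
        raise ValueError(f"unknown table id {table_id!r}; choose from {sorted(_FILES)}")
    path = resources.files("mirloop").joinpath("data", _FILES[table_id])
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln]
    columns = tuple(lines[0].split("\t"))
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(columns):
            raise ValueError(
                f"{_FILES[table_id]}:{lineno}: expected {len(columns)} columns, "
                f"got {len(fields)}"
            )
        row = {}
        for col, value in zip(columns, fields):
            if col in _INT_COLUMNS:
                try:
                    row[col] = int(value)
                except ValueError as exc:
                    raise ValueError(
                        f"{_FILES[table_id]}:{lineno}: column {col!r} "
                        f"is not an integer: {value!r}"
                    ) from exc
            else:
                row[col] = value
        rows.append(row)
    return ReferenceTable(table_id=table_id, columns=columns, rows=tuple(rows))
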