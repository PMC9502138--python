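"""Tab-delimited readers/writers connecting the pipeline stages.

Dialect: UTF-8 TSV with a header row and no index column.  Entity tables use
an ``ID`` column, optional grouping columns, an optional query column, and
incrementally numbered ``PMID_1..PMID_n`` / ``ABSTRACT_1..ABSTRACT_n``
columns whose width is the table-wide maximum list length; empty cells
inside a run are skipped on read.  Matrices use ``ID`` plus one 0/1 column
per term.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd

from .data_model import BinaryTermMatrix, EntityRecord, EntityTable
from .errors import InputFormatError, ValidationError

__all__ = [
    "read_entity_table",
    "write_entity_table",
    "read_matrix",
    "write_matrix",
    "ID_COLUMN",
    "PMID_PREFIX",
    "TEXT_PREFIX",
]

ID_COLUMN = "ID"
PMID_PREFIX = "PMID_"
TEXT_PREFIX = "ABSTRACT_"


def _prefix_columns(columns, prefix: str) -> list[str]:
    """Columns matching ``<prefix><int>``, in their left-to-right file order."""
    pat = re.compile(re.escape(prefix) + r"\d+$")
    return [c for c in columns if pat.match(c)]


def read_entity_table(
    path,
    query_column: str | None = None,
    pmid_prefix: str = PMID_PREFIX,
    text_prefix: str = TEXT_PREFIX,
    grouping_columns: list[str] | None = None,
    id_column: str = ID_COLUMN,
) -> EntityTable:
    """Read an entity table from a TSV file.

    PMID and text columns are recognised by prefix and gathered
    left-to-right into ordered lists, skipping empty cells.
    """
    path = Path(path)
    grouping_columns = list(grouping_columns or [])
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if id_column not in frame.columns:
        raise InputFormatError(f"{path}: required column {id_column!r} missing")
    declared = grouping_columns + ([query_column] if query_column else [])
    missing = [c for c in declared if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: declared columns absent: {', '.join(missing)}")
    pmid_cols = _prefix_columns(frame.columns, pmid_prefix)
    text_cols = _prefix_columns(frame.columns, text_prefix)
    records = []
    for _, row in frame.iterrows():
        query = row[query_column].strip() if query_column else None
        records.append(
            EntityRecord(
                entity_id=row[id_column].strip(),
                grouping={c: row[c] for c in grouping_columns},
                query=query or None,
                pmids=[row[c].strip() for c in pmid_cols if row[c].strip()],
                texts=[row[c] for c in text_cols if row[c].strip()],
            )
        )
    return EntityTable(records, grouping_columns=grouping_columns)


def write_entity_table(
    table: EntityTable,
    path,
    query_column: str = "QUERY",
    pmid_prefix: str = PMID_PREFIX,
    text_prefix: str = TEXT_PREFIX,
    id_column: str = ID_COLUMN,
) -> None:
    """Write an entity table as TSV; re-reading yields an equal table."""
    n_pmids = max((len(r.pmids) for r in table.records), default=0)
    n_texts = max((len(r.texts) for r in table.records), default=0)
    has_query = any(r.query for r in table.records)
    columns = [id_column] + list(table.grouping_columns)
    if has_query:
        columns.append(query_column)
    columns += [f"{pmid_prefix}{i + 1}" for i in range(n_pmids)]
    columns += [f"{text_prefix}{i + 1}" for i in range(n_texts)]
    rows = []
    for rec in table.records:
        row = {id_column: rec.entity_id}
        row.update({c: rec.grouping.get(c, "") for c in table.grouping_columns})
        if has_query:
            row[query_column] = rec.query or ""
        for i in range(n_pmids):
            row[f"{pmid_prefix}{i + 1}"] = rec.pmids[i] if i < len(rec.pmids) else ""
        for i in range(n_texts):
            row[f"{text_prefix}{i + 1}"] = rec.texts[i] if i < len(rec.texts) else ""
        rows.append(row)
    frame = pd.DataFrame(rows, columns=columns)
    frame.to_csv(path, sep="\t", index=False)


def read_matrix(path, id_column: str = ID_COLUMN) -> BinaryTermMatrix:
    """Read a binary term matrix from TSV; cells must be 0 or 1."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if id_column not in frame.columns:
        raise InputFormatError(f"{path}: required column {id_column!r} missing")
    entity_ids = frame[id_column].tolist()
    terms = [c for c in frame.columns if c != id_column]
    cells = frame[terms]
    bad = cells[~cells.isin(["0", "1"]).all(axis=1)] if terms else cells.iloc[0:0]
    if len(bad):
        for row_idx, row in bad.iterrows():
            for col in terms:
                if row[col] not in ("0", "1"):
                    raise ValidationError(
                        f"{path}: cell at row {entity_ids[row_idx]!r}, "
                        f"column {col!r} is {row[col]!r}, expected 0 or 1"
                    )
    values = cells.astype("int8").to_numpy() if terms else \
        pd.DataFrame(index=frame.index).to_numpy().reshape(len(entity_ids), 0)
    return BinaryTermMatrix(entity_ids, terms, values)


def write_matrix(matrix: BinaryTermMatrix, path, id_column: str = ID_COLUMN) -> None:
    """Write a binary term matrix as TSV with lexicographically sorted terms."""
    frame = matrix.to_frame()
    frame.insert(0, id_column, matrix.entity_ids)
    frame.to_csv(path, sep="\t", index=False)
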