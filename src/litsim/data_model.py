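"""Core domain types: entity tables, abstracts, concept annotations and the
binary term matrix.

The binary term matrix (entities x terms, cells in {0, 1}) is the central
object of the pipeline: a cell is 1 iff the term belongs to the entity's
selected vocabulary.  Terms are kept sorted lexicographically and a term
column exists only because at least one entity selected it; entity rows may
be all zero (an entity with no literature).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "EntityRecord",
    "EntityTable",
    "AbstractRecord",
    "ConceptAnnotation",
    "BinaryTermMatrix",
    "CONCEPT_CATEGORIES",
]

#: PubTator concept categories supported by the concept pipeline.
CONCEPT_CATEGORIES = ("gene", "disease", "chemical", "mutation", "species", "cellline")


def _dedupe(items):
    seen = set()
    out = []
    for it in items:
        if it not in seen:
            seen.add(it)
            out.append(it)
    return out


@dataclass
class EntityRecord:
    """One biomedical entity: its identifier, grouping labels, PubMed query,
    curated PMIDs and free texts (abstracts and/or custom notes)."""

    entity_id: str
    grouping: dict[str, str] = field(default_factory=dict)
    query: str | None = None
    pmids: list[str] = field(default_factory=list)
    texts: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.entity_id:
            raise ValidationError("entity identifier must be non-empty")
        for pmid in self.pmids:
            if not pmid.isdigit():
                raise ValidationError(
                    f"entity {self.entity_id!r}: PMID {pmid!r} is not all-digit"
                )
        # duplicates within one record are removed, first occurrence kept
        self.pmids = _dedupe(self.pmids)

    def replace(self, **kwargs) -> "EntityRecord":
        data = {
            "entity_id": self.entity_id,
            "grouping": dict(self.grouping),
            "query": self.query,
            "pmids": list(self.pmids),
            "texts": list(self.texts),
        }
        data.update(kwargs)
        return EntityRecord(**data)


@dataclass
class EntityTable:
    """An ordered collection of entity records with declared grouping columns."""

    records: list[EntityRecord]
    grouping_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.entity_id for r in self.records]
        dup = sorted({i for i, c in Counter(ids).items() if c > 1})
        if dup:
            raise ValidationError(f"duplicate entity identifiers: {', '.join(dup)}")
        for rec in self.records:
            for col in self.grouping_columns:
                rec.grouping.setdefault(col, "")

    @property
    def entity_ids(self) -> list[str]:
        return [r.entity_id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def grouping_labels(self, column: str) -> list[str]:
        if column not in self.grouping_columns:
            raise ValidationError(
                f"unknown grouping column {column!r}; declared: {self.grouping_columns}"
            )
        return [r.grouping.get(column, "") for r in self.records]


@dataclass(frozen=True)
class AbstractRecord:
    """A PMID paired with its plain-text abstract (markup stripped,
    whitespace collapsed)."""

    pmid: str
    text: str


@dataclass(frozen=True)
class ConceptAnnotation:
    """A PubTator annotation: which concept of which category was mentioned
    in which abstract.  ``concept_id`` is absent for unnormalized mentions."""

    pmid: str
    category: str
    concept_id: str | None
    mention: str

    def __post_init__(self) -> None:
        if self.category not in CONCEPT_CATEGORIES:
            raise ValidationError(
                f"unknown concept category {self.category!r}; "
                f"valid: {', '.join(CONCEPT_CATEGORIES)}"
            )


class BinaryTermMatrix:
    """Entities x terms presence/absence matrix.

    Parameters
    ----------
    entity_ids : sequence of str
        Unique entity identifiers, one per row.
    terms : sequence of str
        Unique term names; stored sorted lexicographically (columns are
        reordered on construction if needed).
    values : array-like of shape (n_entities, n_terms)
        Cells in {0, 1}.
    """

    def __init__(self, entity_ids, terms, values) -> None:
        entity_ids = list(entity_ids)
        terms = list(terms)
        values = np.asarray(values)
        if values.shape != (len(entity_ids), len(terms)):
            raise ValidationError(
                f"matrix shape {values.shape} does not match "
                f"{len(entity_ids)} entities x {len(terms)} terms"
            )
        if len(set(entity_ids)) != len(entity_ids):
            raise ValidationError("entity identifiers must be unique")
        if len(set(terms)) != len(terms):
            raise ValidationError("terms must be unique")
        if values.size and not np.isin(values, (0, 1)).all():
            raise ValidationError("matrix cells must be 0 or 1")
        order = np.argsort(np.asarray(terms, dtype=object))
        terms = [terms[i] for i in order]
        values = values.astype(np.int8)[:, order] if values.size else values.astype(np.int8)
        if values.size and (values.sum(axis=0) == 0).any():
            dead = [t for t, s in zip(terms, values.sum(axis=0)) if s == 0]
            raise ValidationError(f"all-zero term columns not allowed: {dead}")
        self.entity_ids: list[str] = entity_ids
        self.terms: list[str] = terms
        self.values: np.ndarray = values

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.entity_ids, columns=self.terms)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BinaryTermMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy())

    def row(self, entity_id: str) -> np.ndarray:
        return self.values[self.entity_ids.index(entity_id)]

    def __eq__(self, other) -> bool:
        if not isinstance(other, BinaryTermMatrix):
            return NotImplemented
        return (
            self.entity_ids == other.entity_ids
            and self.terms == other.terms
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:
        return f"BinaryTermMatrix({len(self.entity_ids)} entities x {len(self.terms)} terms)"
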