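"""From per-entity text or concept annotations to the binary term matrix.

The word pipeline tokenizes all collected text of an entity (lowercasing,
punctuation/digit stripping, length and stopword filtering, optional Porter
stemming), counts raw occurrences, and keeps each entity's ``n_top`` most
frequent terms.  The concept pipeline counts normalized PubTator concepts
with per-document presence (a concept mentioned five times in one abstract
contributes one), because annotations repeat heavily within an abstract and
would otherwise dominate the ranking.  Either way the result is a binary
entities x terms matrix: cell = 1 iff the term is in that entity's selected
vocabulary.

``BinaryTermVectorizer`` wraps the word pipeline as a scikit-learn style
transformer so it composes with sklearn pipelines and model selection.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

from .data_model import BinaryTermMatrix, ConceptAnnotation, EntityRecord, EntityTable
from .errors import ValidationError
from .pubtator import normalize_concept
from .stem import porter_stem

__all__ = [
    "TokenizationOptions",
    "TermCounts",
    "tokenize",
    "count_terms",
    "count_concepts",
    "select_top_terms",
    "build_matrix",
    "build_word_matrix",
    "build_concept_matrix",
    "BinaryTermVectorizer",
    "DEFAULT_STOPWORDS",
]

DEFAULT_STOPWORDS = frozenset(ENGLISH_STOP_WORDS)

DEFAULT_N_TOP = 50


@dataclass(frozen=True)
class TokenizationOptions:
    """Word quality-control switches, applied in a fixed order.

    Pipeline: lowercase -> strip punctuation characters -> strip digit
    characters (or drop digit-bearing tokens with ``digit_mode='drop'``) ->
    split on whitespace -> drop tokens shorter than ``min_token_length`` ->
    drop stopwords -> optional Porter stemming.  ``exclude_self`` removes an
    entity's own identifier/query tokens from its counts, since an entity's
    own name trivially tops its frequency list and carries no similarity
    signal.
    """

    lowercase: bool = True
    strip_punctuation: bool = True
    strip_digits: bool = True
    digit_mode: str = "strip"  # "strip" removes digit chars, "drop" drops the token
    min_token_length: int = 3
    stopwords: frozenset[str] = DEFAULT_STOPWORDS
    stem: bool = False
    exclude_self: bool = True

    def __post_init__(self) -> None:
        if self.min_token_length < 1:
            raise ValidationError("min_token_length must be >= 1")
        if self.digit_mode not in ("strip", "drop"):
            raise ValidationError("digit_mode must be 'strip' or 'drop'")

    def with_extra_stopwords(self, words) -> "TokenizationOptions":
        extra = frozenset(w.lower() for w in words)
        return TokenizationOptions(
            lowercase=self.lowercase,
            strip_punctuation=self.strip_punctuation,
            strip_digits=self.strip_digits,
            digit_mode=self.digit_mode,
            min_token_length=self.min_token_length,
            stopwords=self.stopwords | extra,
            stem=self.stem,
            exclude_self=self.exclude_self,
        )


@dataclass
class TermCounts:
    """Occurrence counts of terms over all of one entity's documents."""

    entity_id: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.counts.values()):
            raise ValidationError("term counts must be strictly positive")


def tokenize(text: str, options: TokenizationOptions = TokenizationOptions()) -> list[str]:
    """Apply the word quality-control pipeline; empty input yields ``[]``."""
    if options.lowercase:
        text = text.lower()
    if options.strip_punctuation:
        text = "".join(c if c.isalnum() or c.isspace() else "" for c in text)
    drop_digit_tokens = options.strip_digits and options.digit_mode == "drop"
    if options.strip_digits and not drop_digit_tokens:
        text = "".join(c for c in text if not c.isdigit())
    tokens = text.split()
    if drop_digit_tokens:
        tokens = [t for t in tokens if not any(c.isdigit() for c in t)]
    tokens = [t for t in tokens if len(t) >= options.min_token_length]
    tokens = [t for t in tokens if t.lower() not in options.stopwords]
    if options.stem:
        tokens = [porter_stem(t) for t in tokens]
    return tokens


def _self_tokens(entity: EntityRecord, options: TokenizationOptions) -> set[str]:
    own = entity.entity_id + (" " + entity.query if entity.query else "")
    return set(tokenize(own, options))


def count_terms(
    entity: EntityRecord,
    options: TokenizationOptions = TokenizationOptions(),
) -> TermCounts:
    """Sum token counts across all of the entity's texts."""
    counts: Counter[str] = Counter()
    for text in entity.texts:
        counts.update(tokenize(text, options))
    if options.exclude_self:
        for token in _self_tokens(entity, options):
            counts.pop(token, None)
    return TermCounts(entity_id=entity.entity_id, counts=dict(counts))


def count_concepts(
    entity: EntityRecord,
    annotations: list[ConceptAnnotation],
    by_id: bool = True,
) -> TermCounts:
    """Per-document presence counts of normalized concepts for one entity.

    Annotations must already be category-filtered.  Each concept counts once
    per abstract it is annotated in, however many times it is mentioned there.
    """
    own = set(entity.pmids)
    present: set[tuple[str, str]] = set()
    for ann in annotations:
        if ann.pmid in own:
            present.add((ann.pmid, normalize_concept(ann, by_id=by_id)))
    counts: Counter[str] = Counter(term for _, term in present)
    return TermCounts(entity_id=entity.entity_id, counts=dict(counts))


def select_top_terms(counts: TermCounts, n_top: int) -> list[str]:
    """The ``n_top`` highest-count terms, ties broken lexicographically."""
    if n_top < 0:
        raise ValidationError("n_top must be non-negative")
    ranked = sorted(counts.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [term for term, _ in ranked[:n_top]]


def build_matrix(selections: dict[str, list[str]]) -> BinaryTermMatrix:
    """Assemble the binary matrix from per-entity selected vocabularies.

    Terms are the sorted union of all selections; entities with empty
    selections become all-zero rows.  No all-zero term column can exist by
    construction.
    """
    entity_ids = list(selections)
    terms = sorted(set().union(*selections.values())) if selections else []
    index = {t: j for j, t in enumerate(terms)}
    values = np.zeros((len(entity_ids), len(terms)), dtype=np.int8)
    for i, eid in enumerate(entity_ids):
        for term in selections[eid]:
            values[i, index[term]] = 1
    return BinaryTermMatrix(entity_ids, terms, values)


def build_word_matrix(
    table: EntityTable,
    options: TokenizationOptions = TokenizationOptions(),
    n_top: int = DEFAULT_N_TOP,
) -> BinaryTermMatrix:
    """Word pipeline over a whole table: tokenize, count, select, assemble."""
    selections = {
        rec.entity_id: select_top_terms(count_terms(rec, options), n_top)
        for rec in table.records
    }
    return build_matrix(selections)


def build_concept_matrix(
    table: EntityTable,
    annotations: list[ConceptAnnotation],
    by_id: bool = True,
    n_top: int = DEFAULT_N_TOP,
) -> BinaryTermMatrix:
    """Concept pipeline over a whole table using pre-fetched annotations."""
    selections = {
        rec.entity_id: select_top_terms(count_concepts(rec, annotations, by_id), n_top)
        for rec in table.records
    }
    return build_matrix(selections)


class BinaryTermVectorizer(TransformerMixin, BaseEstimator):
    """Scikit-learn style transformer for the word pipeline.

    ``fit`` learns the union vocabulary of the entities' top-``n_top`` term
    lists; ``transform`` marks presence of the fitted terms.  ``X`` is an
    :class:`~litsim.data_model.EntityTable` or a sequence of
    :class:`~litsim.data_model.EntityRecord`.

    Parameters mirror :class:`TokenizationOptions` plus ``n_top``, the size
    of each entity's selected vocabulary (default 50).
    """

    def __init__(
        self,
        n_top: int = DEFAULT_N_TOP,
        lowercase: bool = True,
        strip_punctuation: bool = True,
        strip_digits: bool = True,
        digit_mode: str = "strip",
        min_token_length: int = 3,
        stopwords=None,
        extra_stopwords=(),
        stem: bool = False,
        exclude_self: bool = True,
    ) -> None:
        self.n_top = n_top
        self.lowercase = lowercase
        self.strip_punctuation = strip_punctuation
        self.strip_digits = strip_digits
        self.digit_mode = digit_mode
        self.min_token_length = min_token_length
        self.stopwords = stopwords
        self.extra_stopwords = extra_stopwords
        self.stem = stem
        self.exclude_self = exclude_self

    def _options(self) -> TokenizationOptions:
        base = frozenset(self.stopwords) if self.stopwords is not None else DEFAULT_STOPWORDS
        opts = TokenizationOptions(
            lowercase=self.lowercase,
            strip_punctuation=self.strip_punctuation,
            strip_digits=self.strip_digits,
            digit_mode=self.digit_mode,
            min_token_length=self.min_token_length,
            stopwords=base,
            stem=self.stem,
            exclude_self=self.exclude_self,
        )
        return opts.with_extra_stopwords(self.extra_stopwords)

    @staticmethod
    def _records(X) -> list[EntityRecord]:
        if isinstance(X, EntityTable):
            return list(X.records)
        return list(X)

    def _select(self, records, options) -> dict[str, list[str]]:
        return {
            rec.entity_id: select_top_terms(count_terms(rec, options), self.n_top)
            for rec in records
        }

    def fit(self, X, y=None) -> "BinaryTermVectorizer":
        records = self._records(X)
        options = self._options()
        selections = self._select(records, options)
        self.vocabulary_ = sorted(set().union(*selections.values())) if selections else []
        self.entity_ids_ = [rec.entity_id for rec in records]
        self.n_features_out_ = len(self.vocabulary_)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "vocabulary_"):
            raise ValidationError("BinaryTermVectorizer is not fitted")
        records = self._records(X)
        options = self._options()
        index = {t: j for j, t in enumerate(self.vocabulary_)}
        out = np.zeros((len(records), len(self.vocabulary_)), dtype=np.int8)
        for i, rec in enumerate(records):
            for term in select_top_terms(count_terms(rec, options), self.n_top):
                if term in index:
                    out[i, index[term]] = 1
        return out

    def fit_transform_matrix(self, table: EntityTable) -> BinaryTermMatrix:
        """Fit on a table and return the full :class:`BinaryTermMatrix`."""
        self.fit(table)
        return BinaryTermMatrix(self.entity_ids_, list(self.vocabulary_),
                                self.transform(table))

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        if not hasattr(self, "vocabulary_"):
            raise ValidationError("BinaryTermVectorizer is not fitted")
        return np.asarray(self.vocabulary_, dtype=object)
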