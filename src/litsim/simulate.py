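"""Topic-structured synthetic corpora with known ground truth.

The generator emulates the structure the similarity assumption rests on:
related entities share co-occurring vocabulary.  It draws ``k_topics``
latent topics with pairwise disjoint characteristic vocabularies plus one
shared noise vocabulary, assigns entities to topics, and samples documents
per entity; each word comes from the shared vocabulary with probability
``noise_fraction`` and from the entity's topic vocabulary otherwise.  The
topic assignment is the ground-truth partition, playing the role an
expert-curated category column plays for real entities.

Synthetic words are pronounceable CV-syllable nonsense tokens of >= 6
letters, so the default tokenization passes them through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analysis import Partition, adjusted_rand_index, cluster_hierarchical, distance_matrix
from .data_model import EntityRecord, EntityTable
from .errors import ValidationError
from .text import DEFAULT_STOPWORDS, DEFAULT_N_TOP, TokenizationOptions, build_word_matrix

__all__ = ["CorpusSpec", "generate_corpus", "recovery_experiment", "TOPIC_COLUMN"]

TOPIC_COLUMN = "TOPIC"

_CONSONANTS = "bdfgklmnprstvz"
_VOWELS = "aeiou"


@dataclass(frozen=True)
class CorpusSpec:
    """Parameters of a synthetic corpus.

    ``topic_vocab_size`` words characterise each topic (disjoint across
    topics); ``shared_vocab_size`` words are common noise.  Each of the
    ``docs_per_entity`` documents holds ``words_per_doc`` i.i.d. words.
    """

    k_topics: int = 4
    entities_per_topic: int = 10
    topic_vocab_size: int = 30
    shared_vocab_size: int = 100
    docs_per_entity: int = 20
    words_per_doc: int = 50
    noise_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("k_topics", "entities_per_topic", "topic_vocab_size",
                     "docs_per_entity", "words_per_doc"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.shared_vocab_size < 0:
            raise ValidationError("shared_vocab_size must be >= 0")
        if not 0.0 <= self.noise_fraction <= 1.0:
            raise ValidationError("noise_fraction must lie in [0, 1]")
        if self.noise_fraction == 1.0 and self.shared_vocab_size < 1:
            raise ValidationError(
                "noise_fraction=1 requires a non-empty shared vocabulary"
            )


def _make_words(n: int, rng: np.random.Generator) -> list[str]:
    """``n`` unique pronounceable nonsense words that survive default
    tokenization (alphabetic, >= 3 chars, not stopwords)."""
    words: list[str] = []
    seen: set[str] = set()
    while len(words) < n:
        syllables = rng.integers(3, 5)
        word = "".join(
            _CONSONANTS[rng.integers(len(_CONSONANTS))] + _VOWELS[rng.integers(len(_VOWELS))]
            for _ in range(syllables)
        )
        if word in seen or word in DEFAULT_STOPWORDS:
            continue
        seen.add(word)
        words.append(word)
    return words


def generate_corpus(spec: CorpusSpec) -> tuple[EntityTable, Partition]:
    """Sample a corpus; returns the entity table (texts filled, topic label
    as grouping column) and the ground-truth partition."""
    rng = np.random.default_rng(spec.seed)
    total_vocab = spec.k_topics * spec.topic_vocab_size + spec.shared_vocab_size
    words = _make_words(total_vocab, rng)
    topic_vocabs = [
        words[t * spec.topic_vocab_size : (t + 1) * spec.topic_vocab_size]
        for t in range(spec.k_topics)
    ]
    shared_vocab = words[spec.k_topics * spec.topic_vocab_size :]

    records = []
    labels = []
    for t in range(spec.k_topics):
        topic = np.asarray(topic_vocabs[t], dtype=object)
        shared = np.asarray(shared_vocab, dtype=object)
        for e in range(spec.entities_per_topic):
            docs = []
            for _ in range(spec.docs_per_entity):
                from_shared = rng.random(spec.words_per_doc) < spec.noise_fraction
                n_shared = int(from_shared.sum())
                tokens = np.empty(spec.words_per_doc, dtype=object)
                if n_shared:
                    tokens[from_shared] = shared[rng.integers(len(shared), size=n_shared)]
                if spec.words_per_doc - n_shared:
                    tokens[~from_shared] = topic[
                        rng.integers(len(topic), size=spec.words_per_doc - n_shared)
                    ]
                docs.append(" ".join(tokens))
            label = f"topic{t + 1}"
            records.append(
                EntityRecord(
                    entity_id=f"entity_{t + 1}_{e + 1}",
                    grouping={TOPIC_COLUMN: label},
                    texts=docs,
                )
            )
            labels.append(label)
    table = EntityTable(records, grouping_columns=[TOPIC_COLUMN])
    return table, Partition(table.entity_ids, labels)


def recovery_experiment(
    spec: CorpusSpec,
    n_top: int = DEFAULT_N_TOP,
    metric: str = "jaccard",
    linkage: str = "ward",
    options: TokenizationOptions = TokenizationOptions(),
) -> float:
    """Run the full offline pipeline on a synthetic corpus and return the ARI
    between the text-based clustering (cut at the true number of topics) and
    the ground-truth topic partition."""
    table, truth = generate_corpus(spec)
    matrix = build_word_matrix(table, options=options, n_top=n_top)
    dist = distance_matrix(matrix, metric=metric)
    part = cluster_hierarchical(dist, matrix.entity_ids, linkage=linkage, k=spec.k_topics)
    return adjusted_rand_index(part, truth)
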