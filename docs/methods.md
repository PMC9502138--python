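# Methods

## Model and assumptions

`litsim` quantifies similarity among biomedical entities from the vocabulary
of their literature. The working assumption is that related entities share
more frequently co-occurring words and scientific terms in their text
sources than unrelated ones. Each entity is therefore reduced to a binary
presence/absence profile over a vocabulary, deliberately *not* an embedding:
raw term overlap is the signal, which keeps the method applicable to any
kind of string (gene names, disease names, author names) and keeps every
step inspectable. No term weighting (TF-IDF), no n-grams, and no
distributional semantics are used.

Two vocabularies are supported per entity:

- **Word pipeline** — tokens of all collected text, counted by raw
  occurrence summed over the entity's documents.
- **Concept pipeline** — PubTator annotations of selected categories,
  counted by *per-document presence*: a concept mentioned five times in one
  abstract contributes 1. Concept annotations repeat heavily within an
  abstract; presence counting prevents single verbose abstracts from
  dominating the frequency ranking. Word counting stays raw-occurrence
  because words do not repeat with the same pathology and raw counts retain
  more ranking signal there.

From either count map the top-`N` terms per entity are kept (ties broken
lexicographically so runs are deterministic), and the binary matrix is the
union of the selections. `N = 50` by default: large enough that an entity's
profile is not dominated by a handful of generic terms, small enough that
profiles stay sparse and Jaccard distances discriminate; it is exposed as
`--n-top` everywhere.

## Word quality control

Tokenization applies, in fixed order: lowercase → strip punctuation
characters → strip digit characters → whitespace split → drop tokens
shorter than `min_token_length` (default 3) → drop stopwords (scikit-learn's
318-word English list, user-extendable) → optional Porter stemming. Digit
*characters* are stripped inside tokens rather than dropping the token
(`scn1a → scna`), so gene-like tokens are kept in a consistent form;
`digit_mode="drop"` switches to token-dropping. Stemming uses an in-package
implementation of the classic Porter (1980) suffix-stripping algorithm and
runs before counting, so ranks reflect stems.

`exclude_self` (default on) removes tokens of an entity's own identifier
and query from its counts: an entity's own name trivially tops its
frequency list and carries no similarity signal, and with self-tokens kept
the matrix rewards entities for mentioning themselves rather than for
sharing context.

## Distances, embedding, clustering, validation

Binary profiles are compared by Jaccard distance by default (presence
overlap is the modelled signal; shared absences are meaningless in a
vocabulary union whose columns exist only because *some* entity selected
them) with Euclidean as an option. Two all-zero rows get distance 0 —
entities with no vocabulary are indistinguishable, not maximally distant —
and all-zero rows are kept but flagged in the report, since dropping them
would desynchronize partitions and metadata.

The default embedding is PCA (exact, deterministic); t-SNE and UMAP are
opt-in and seeded. Clustering is agglomerative on the distance matrix
(ward linkage by default, on scipy's squared-distance Lance–Williams
convention; average and complete as alternatives), cut at `k` clusters, or
k-means on the embedding (10 starts, best inertia, seeded). When a grouping
column is supplied, `k` defaults to the number of distinct group labels —
the natural choice when validating text-derived clusters against
expert-curated categories; without one, `k` is chosen by maximal mean
silhouette over hierarchical cuts (ties to the smallest k).

Agreement between the text-derived partition and a grouping variable is the
pair-counting adjusted Rand index, computed in exact rational arithmetic
(every term of the formula is an integer ratio) and defined as 1 when the
correction denominator vanishes (both partitions all-singletons, or both a
single cluster). An independent pair-enumeration oracle and scikit-learn's
implementation serve as cross-checks in the test suite only.

## Retrieval

PubMed is accessed through E-utilities ESearch (paged, deduplicated,
relevance order) and EFetch (XML, batched ≤ 200 PMIDs); PubTator through its
BioC-JSON export (batched ≤ 100 PMIDs). Abstract text is title + abstract
paragraphs joined by spaces with markup stripped — titles carry high-signal
terms; `--no-title` disables. PMIDs without abstracts are dropped with a
warning rather than failing (common for old records). The live transport
enforces NCBI etiquette (≤ 3 requests/s without an API key, ≤ 10 with one;
3 retries with exponential backoff). All clients take the transport as an
argument, so a fixture transport replaying canned payloads makes the entire
retrieval layer deterministic and offline; concept normalization defaults
to identifier level (`gene:6323`) so synonymous mentions merge, falling
back to collapsed mention text when no identifier exists.

## Synthetic corpus generator

The generator emulates exactly the structure the similarity assumption
rests on, at desk scale: `k` topics with pairwise disjoint characteristic
vocabularies plus one shared noise vocabulary; each entity belongs to one
topic; each document is `words_per_doc` i.i.d. draws, from the shared
vocabulary with probability `noise_fraction`, else uniformly from the
topic vocabulary. Words are uniform within their vocabulary (the simplest
model that makes related entities share co-occurring words; Zipfian
frequencies are deliberately omitted) and are pronounceable CV-syllable
nonsense tokens of ≥ 6 letters so default tokenization passes them through.

Default conditions: 4 topics × 10 entities, topic vocabulary 30, shared
vocabulary 100, 20 documents of 50 words per entity, noise 0.3. Under these
conditions each topic word appears ~23× per entity and each shared word
~3×, so an entity's top-50 list contains its full topic vocabulary —
recovery of the topic partition (ARI vs ground truth after the full word
pipeline, Jaccard + ward, cut at the true k) is expected to be ≈ 1, and the
matched null (noise 1.0, shared vocabulary 200, no topic signal) is
expected near 0. These problem sizes keep the full suite and the acceptance
script in the tens of seconds while leaving the recovery and null regimes
well separated.

What the generator does *not* emulate: real abstracts' Zipfian word
frequencies, topical overlap between categories, entities with very uneven
literature depth, and PubTator's annotation noise. Passing recovery tests
therefore demonstrates the pipeline's correctness and its behaviour under
clean topic structure, not the agreement level attainable on live
literature, which depends on the continuously updated PubMed/PubTator
services.

## Numerical and design choices

- Term ties (equal counts) and cluster-term ties break lexicographically;
  hierarchical merges follow scipy's deterministic ordering.
- The ARI is exact (rational arithmetic), so worked examples like −0.5 are
  reproduced bit-for-bit.
- Tokenization is idempotent on its own output when stemming is off; with
  stemming, ranks reflect stems (Porter is itself idempotent on most but
  not all of its outputs).
- TSV is the only interchange dialect (UTF-8, header, `ID` column;
  `PMID_n`/`ABSTRACT_n` runs padded to the table-wide maximum). PMIDs are
  strings throughout, never integers.
- The static report (TSVs + PNGs) replaces an interactive viewer so every
  artifact is diffable and testable; two runs with the same seed produce
  byte-identical TSV/text reports.

## Known limitations

- Word profiles are language- and spelling-sensitive; no synonym merging
  happens in the word pipeline (use the concept pipeline for that).
- Silhouette-based `k` selection inherits silhouette's bias toward compact,
  evenly sized clusters.
- The significance of an observed ARI is not assessed (no permutation
  p-value); the chance calibration only verifies that shuffled labels give
  mean ARI ≈ 0.
- Full-text retrieval, MeSH query expansion and species-aware gene
  disambiguation are out of scope.
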