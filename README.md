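# litsim

Similarity analysis of biomedical entities from the vocabulary of their
literature.

Comparing a large set of biomedical entities — genes, diseases, researchers,
any list of strings — by manually surveying the literature is slow. `litsim`
automates the comparison under one assumption: **more similar or related
entities share more frequently co-occurring words and scientific terms in
their text sources than unrelated entities.** The pipeline

1. **collects text** per entity — PubMed abstracts found by a free-text
   query (E-utilities ESearch + EFetch) or fetched for curated PMIDs, plus
   optional custom text;
2. **distills a vocabulary** per entity — either the most frequent words
   after quality control (lowercasing, punctuation/digit stripping, length
   and stopword filtering, optional Porter stemming), or PubTator concept
   annotations of chosen categories (gene, disease, chemical, mutation,
   species, cell line) counted by per-abstract presence — keeping the top
   *N* terms per entity (default *N* = 50);
3. **assembles a binary matrix** `X ∈ {0,1}^{n×p}`: `X[e,t] = 1` iff term
   *t* is among entity *e*'s selected vocabulary;
4. **analyzes the matrix** with unsupervised learning: Jaccard or Euclidean
   distances, PCA/t-SNE/UMAP embedding, hierarchical (ward/average/complete)
   or k-means clustering, per-cluster characteristic terms;
5. **validates** the text-derived grouping against any user-supplied
   categorical grouping variable with the adjusted Rand index

   ARI = (Σᵢⱼ C(nᵢⱼ,2) − Σᵢ C(aᵢ,2) Σⱼ C(bⱼ,2)/C(n,2)) /
   (½[Σᵢ C(aᵢ,2) + Σⱼ C(bⱼ,2)] − Σᵢ C(aᵢ,2) Σⱼ C(bⱼ,2)/C(n,2)),

   where nᵢⱼ is the contingency table of the two partitions — 1 for
   identical partitions, ≈ 0 for chance agreement.

All network access goes through an injectable transport, so the whole
pipeline runs offline against packaged fixture payloads, and a synthetic
topic-structured corpus generator provides ground truth for end-to-end
testing.

## Worked example (offline)

Simulate 3 topics × 5 entities with known ground truth, build the word
matrix, and analyze:

```bash
litsim simulate --k 3 --entities-per-topic 5 --docs 10 --words 40 \
    --noise 0.3 --seed 1 --outdir sim
litsim text-to-wordmatrix --input sim/entities.tsv --n-top 30 --output matrix.tsv
litsim analyze --matrix matrix.tsv --meta sim/entities.tsv --group-col TOPIC \
    --k auto --seed 1 --outdir report
```

prints

```
wrote 15 entities to sim
k=3 clusters over 15 entities
ARI vs TOPIC: 1.0000
```

With `--k auto` and a grouping column, k is the number of distinct group
labels (here 3). The ARI of 1.0 means the hierarchical clustering of the
binary vocabulary profiles (Jaccard distance, ward linkage) recovered the
ground-truth topic grouping exactly. `report/` contains `labels.tsv`
(cluster and group label per entity, plus an all-zero-row flag),
`embedding.tsv` (PCA coordinates), `ari.txt`, `cluster_terms.tsv` (top
characteristic terms per cluster) and `scatter.png` / `dendrogram.png`.

The same workflow runs against live PubMed with a query table:

```bash
litsim pubmed-by-queries --input genes.tsv --query-col QUERY --n 100 \
    --mode abstracts --output collected.tsv
litsim text-to-wordmatrix --input collected.tsv --output matrix.tsv
# or concept terms instead of words:
litsim pmids-to-pubtator-matrix --input collected.tsv \
    --categories gene,disease,chemical --output matrix.tsv
```

As a library, the word pipeline is also available as a scikit-learn style
transformer:

```python
from litsim import BinaryTermVectorizer, generate_corpus, CorpusSpec
table, truth = generate_corpus(CorpusSpec(seed=1))
X = BinaryTermVectorizer(n_top=50).fit_transform(table)   # (40, p) 0/1 array
```

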