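# Methods

## Retrieval model

A corpus of guideline topic documents is indexed in three *views* per
document, each embedded to a fixed-length vector by a sentence-embedding
backend:

* **Header** — the title and its variants joined by single spaces, title
  first. Variants are weighted uniformly with the title; nothing in the
  header is preprocessed beyond what the backend does internally, so
  short, name-like wording keeps full weight.
* **Body** — the full document text after tokenization, stop-word and
  punctuation removal, and lemmatization.
* **TF-IDF features** — the document's 50 highest-weighted n-grams under
  the corpus TF-IDF model (below), joined into one text in rank order and
  embedded like any other sentence. Embedding the *feature text* rather
  than comparing raw TF-IDF vectors lets semantically equivalent wording
  in the query match the document's distinctive terms.

A query is preprocessed once (abbreviation expansion → tokenization →
cleaning; lemmatization optional and off by default for queries),
embedded once, and every document is scored

    S_i = H_{q,i} + B_{q,i} + β · T_{q,i}

with H, B, T the cosines between the query vector and the three views.
Results are sorted by score, ties broken by ascending document id for
determinism. One shared query embedding is compared against all three
views. A view embedded from empty text (e.g. an all-stop-word body) is
the zero vector and contributes cosine 0 rather than being skipped, so
scores stay comparable across documents. A query with no embeddable
tokens raises an explicit `UnsearchableQueryError` instead of returning
an empty list — silently returning nothing is the failure mode this
engine exists to avoid.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `beta` | 1.0 | weight of the TF-IDF view in S; raise to emphasize exact corpus-term matching for queries with little distracting language, lower for noisy EHR-style queries. Unitless; 1.0 weights all three views equally. |
| `k` (features) | 50 | n-grams per document embedded in the T view |
| `top_k` | 10 | results returned by `search` |
| `lemmatize_query` | off | queries are embedded as typed; document bodies are lemmatized at index time |
| `case_sensitive_abbrev` | on | "PE" and "pe" are different clinical tokens |

## Text preprocessing

Tokens are maximal runs of alphanumerics optionally glued by `/`, `'` or
`-`, so shorthand like `r/o` and `follow-up` survives as one token.
Abbreviation expansion is whole-token and *appending*: the original text
is always a prefix of the output and each matched table entry is appended
exactly once, in first-occurrence order — the abbreviated form keeps
contributing to matching alongside its expansion. The stop-word list is
configurable and defaults to scikit-learn's English list.

Lemmatization is a pluggable callable; the default is a small rule-based
English lemmatizer (an irregular table for common clinical plurals —
*metastases*, *emboli* — followed by ordered suffix rules). It is
intentionally conservative: a rule applies only when the stem keeps at
least three characters, words ending in `-ss`/`-us` are left alone, and
genuinely ambiguous English plurals (e.g. *headaches*) may lemmatize
imperfectly. Since documents and queries pass through the same
lemmatizer, retrieval only needs it to be *consistent*, not perfect.

`extract_indication` pulls the indication section out of report text by
scanning an ordered list of section-header patterns (default
`INDICATION:`, `CLINICAL INDICATION:`, `HISTORY:`) and cutting at the
next ALL-CAPS header line. Blank sections and unmatched reports return a
`"not found"` sentinel rather than raising, so bulk extraction can count
exclusions.

## TF-IDF variant (pinned)

Fitted on *raw* cleaned bodies (no lemmatization) over unigrams, bigrams
and trigrams:

    idf(t) = ln((1 + N) / (1 + df_t)) + 1
    w(t, d) = tf(t, d) · idf(t),  per-document vectors L2-normalized

with raw term counts and no sublinear scaling — the standard default of
scikit-learn's `TfidfVectorizer`, which backs the implementation. The
variant is pinned explicitly so persisted models (JSON: vocabulary, idf,
document ids) rebuild indexes bit-for-bit. Top-feature selection order is
invariant to the positive L2 rescaling, so using normalized weights for
selection is inconsequential; ties are broken lexicographically.

## Embedding backends

The backend contract: `embed` is a pure function of the text, dimension
is constant, and the zero vector is returned iff the text has no
embeddable tokens.

The **toy backend** canonicalizes each token through a synonym table,
hashes the canonical form with a seed (BLAKE2b, platform-stable) to a
pseudorandom unit vector, and averages token vectors — the continuous
bag-of-words character of large biomedical sentence embedders at desk
scale. Synonym pairs embed identically *exactly*, which is stronger than
a trained model's approximate synonym similarity; random token pairs are
nearly orthogonal (at dimension 64, mean |cos| ≈ 0.10 over random pairs,
95th percentile < 0.3, tightening as dimension grows). Bigram-level
embedding is not modeled — a fidelity gap relative to trained
sentence-embedding models, which also embed word bigrams.

The **pretrained adapter** reads word2vec-style text files (header
`n dim`, one token vector per line) and averages in-vocabulary token
vectors. Training is out of scope; any model exported to that text format
can be dropped in.

## Synthetic benchmark

The generator emulates a simulated-indication benchmark: measurable
statistical structure, not linguistic realism.

* **Corpus**: `n_docs` documents (default 50, seed 42). The pseudo-word
  pool (consonant–vowel syllables, stop words excluded) is partitioned so
  per-document core vocabularies (12 tokens) are disjoint; 15 shared
  "glue" tokens appear across bodies at ~10% rate. Titles are 3 core
  tokens; 0–3 variants swap a title token for its synonym; bodies are
  50–200 tokens; tags are 1–3 of the seven-tag vocabulary; each document
  gets one of 12 broad category labels.
* **Simple queries**: 2–3 title keywords plus fillers from the document's
  own non-title core vocabulary, rejection-sampled until the fraction of
  query words that are title keywords is within ±0.08 of 0.32.
* **Complex queries**: exactly one title keyword, synonyms for the other
  title words, core fillers, plus distractors injected with fixed
  probabilities — age in text form (p=0.8), less relevant medical history
  (p=0.6), less relevant social history (p=0.4) — rejection-sampled to
  ±0.04 of 0.09 keyword overlap. Synonym substitution counts as a
  distractor, so every complex query has at least one; simple queries
  have none. The medical-history distractor draws content words from a
  *different* document, because distracting history is real clinical
  content that legitimately matches other topics; age and social-history
  phrases come from editable template pools in `data/distractors.json`
  and match no document.

At the default spec the measured calibration (seed 42) is 0.314 simple /
0.078 complex overlap; end-to-end with the toy backend, simple queries
reach top-3 accuracy 1.0 and complex queries score strictly lower mean
NDCG than simple ones — the qualitative difficulty ordering the design
targets. What passing these tests shows: the pipeline wiring, the score
formula, and the direction of the distractor effect. What it does not
show: performance on real clinical text, where synonymy is approximate,
vocabularies overlap heavily between documents, and abbreviations are
ambiguous.

## Evaluation conventions

* Relevance is `|query_tags ∩ doc_tags|`; NDCG sums over the full corpus
  ranking (the displayed top-k is a prefix of the ranking actually
  scored).
* All-zero relevance: NDCG is reported as 0.0 with a warning, avoiding an
  undefined 0/0.
* Top-k accuracy excludes queries with empty ground truth from the
  denominator and counts them separately; `mode="all"` requires every
  ground-truth id in the top k.
* Rank statistics use the best (minimum) ground-truth rank per query; a
  ground truth missing from the ranked list flags the query and excludes
  it from the mean.
* Per-query NDCG values are emitted in the report so downstream
  significance testing can be applied externally; no inferential
  statistics are computed here.

## Numerical and design notes

* Cosine of any zero vector is defined as 0.
* Tie-breaks (documents by id, TF-IDF features lexicographically) make
  every ranking deterministic.
* All generation is seed-deterministic via `numpy.random.default_rng`
  with structured seeds; fixed seeds yield byte-identical corpora,
  queries and tables across platforms.
* Problem sizes in the test suite (corpora of 2–50 documents, toy
  dimension 16–256, 100 ranking-oracle trials) were chosen as the
  smallest sizes at which the checked properties are non-trivial.

## Known limitations

* The default lemmatizer is rule-based and English-only; plug in a
  dictionary lemmatizer for production text.
* Abbreviation disambiguation is out of scope — tables are assumed
  curated upstream.
* The toy backend's exact synonym identity overstates what trained
  embeddings deliver; conclusions about real corpora require the
  pretrained adapter with a real model.
* β was not tuned against any real corpus; 1.0 is a neutral default and
  the headline hyperparameter to tune per deployment.
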