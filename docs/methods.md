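# Methods

## The relationship model

`cooclink` treats a corpus of abstracts as evidence about pair-wise
associations between controlled-vocabulary terms. The unit of evidence is
the sentence: a term's occurrence value in a sentence is a binary
indicator (repeated mentions count once), and the co-occurrence value
COV(t₁, t₂) is the number of sentences containing both terms. Sentences
mentioning fewer than two distinct terms carry no pair evidence and are
removed before counting; the diagonal COV(t, t) is a term's sentence
count *after* that filter, so all quantities entering a score are counted
over the same sentence population.

Two scores are derived from one index:

- **RSS** = log₁₀(COV(t₁,t₂) / (COV(t₁,t₁)·COV(t₂,t₂))). A pointwise
  mutual-information-style statistic: it rewards joint occurrence beyond
  what the two marginal frequencies predict. Raw values are rescaled
  linearly onto [1, 100] (RSS_N). The normalization bounds are taken over
  exactly the pair set being scored and stored in the table metadata — a
  normalized score is only meaningful relative to its table's scope
  (ontology selection, minimum-COV cutoff), which is why the scope is a
  run parameter rather than a global constant.
- **NMD** = (max(log D₁, log D₂) − log D₁₂) / (log M − min(log D₁, log
  D₂)) over document-level counts, following the Normalized Google
  Distance construction: 0 when the rarer term never appears without the
  other (and D₁ = D₂), growing as the joint document profile diverges.
  All three count terms enter through logarithms; the ratio is invariant
  to the log base (natural logs internally). The similarity transform is
  Sim = max(0, 1 − NMD), clamped because NMD is unbounded above on finite
  corpora. The untransformed distance remains available so any other
  monotone transform is one function away.

Pairs with zero co-occurrence are *unscored*, not assigned ±∞: the method
only ranks extracted co-occurring pairs, and an absent pair is an absence
of evidence, not evidence of maximal distance.

### Assumptions and precondition choices

- NMD requires M > min(D₁, D₂); violating corpora raise a dedicated
  degenerate-corpus error rather than returning a negative denominator.
- RSS_N with a single distinct raw value assigns 100 everywhere (with a
  warning): a one-value table has no resolution, and 100 preserves the
  "best pair gets 100" reading.
- Document-level counts are derived from the same filtered mention set as
  sentence-level counts, so COV(t, t) ≥ D(t) holds structurally.

## Sentence segmentation

The segmenter is deliberately rule-based and deterministic: a sentence
ends at `.`, `!` or `?` followed by whitespace and an uppercase letter or
digit (or at end of text), unless the period closes a listed abbreviation
(final-token match, so "et al." is guarded by "al.") or a
single-uppercase-letter token ("E. coli"). Decimal points never split
because no whitespace follows them. Whitespace runs are collapsed before
segmentation, which makes the invariant exact: joining the sentences with
single spaces reconstructs the whitespace-normalized document, and
re-segmenting any produced sentence returns it unchanged. A learned
boundary model would be marginally more accurate on pathological prose
but untestable against a closed-form oracle; the rule set mirrors the
standard "longest whitespace-trimmed sequence between two terminators"
definition used by sentence detectors in this domain.

## Term recognition

The dictionary normalization is fixed at: lowercase, split on
non-alphanumeric characters, no stemming, no plural folding — a
conservative, precision-favoring choice typical of dictionary annotators.
Matching is leftmost-longest and non-overlapping via a token trie, with
token boundaries enforced (no intra-word hits). Single-token entries
shorter than 3 characters are dropped by default (configurable); very
short labels ("all", "as") are almost always false positives in prose.
Ambiguous surface forms emit one mention per term ID — no disambiguation
is attempted, matching the upstream framework's behavior. Synonyms of all
scopes are indexed by default, with an EXACT-only flag.

## Wang similarity and gene similarity

Wang's DAG similarity is implemented from its standard formulation:
S_A(A) = 1, S_A(a) = max over children c (on paths to A) of w·S_A(c)
with is_a contribution factor w = 0.8 (the method's conventional value,
parameterized), SV(A) = Σ S_A, and sim = Σ_{common ancestors}(S_A + S_B)
/ (SV(A) + SV(B)) with ancestor sets inclusive of the term. Terms in
disjoint components score 0.

Cross-ontology validation uses explicit gene-set overlap — cosine
|G₁∩G₂|/√(|G₁||G₂|) by default, Jaccard as an alternative — on the
annotation table as given (no ancestor up-propagation by default, since
per-term direct annotation counts are the usual reference; a propagation
flag exists on the loading side via the DAG accessors). Annotations can
be filtered for IEA evidence and deduplicated at load time.

Correlations are plain Pearson r with the two-sided t-test p-value over
the intersection of pair keys, refusing to run on fewer than 3 shared
pairs or on zero-variance vectors.

## Association networks

Edges are pairs scoring ≥ θ ("equal or larger"); node sets contain only
edge-incident terms, so an isolated term is not a network member. The
random-network null for the giant-component test is G(n, m) with matched
node and edge counts — the simplest null consistent with "random
networks" — with degree-preserving double-edge-swap rewiring behind a
flag for sensitivity analysis. The empirical p-value uses the add-one
estimator (r + 1)/(n + 1), whose floor with 10,000 replicates and an
observation more extreme than all of them is 1/10001 ≈ 9.999e-05. The
power-law fit is a descriptive OLS of log₁₀ P(k) on log₁₀ k over degrees
with nonzero counts (≥ 3 distinct degrees required) reporting slope and
R² — deliberately *not* a maximum-likelihood exponent estimate, because
the quantity of interest here is the conventional log-log linearity
summary, not a calibrated exponent.

## Synthetic worlds

The generator emulates the structure of the real inputs at desk scale:

- per-namespace `is_a` DAGs (default two namespaces, DO-like and
  BP-like, 30 terms each): a random spanning tree plus extra parents with
  probability 0.25; term names of 1–3 pseudo-words drawn without
  replacement from a fixed pool, with ~10% of names deliberately
  constructed as extensions of other names so the matcher faces
  prefix-overlap cases; synonyms on ~30% of terms;
- a corpus of 500 documents × 5 sentences. Per sentence, every term is
  mentioned independently with probability 0.02 (background), and each
  *planted* pair is co-mentioned jointly with probability q·0.02. The
  planted propensity is q = 0.3·(0.35 + 0.65·sim) for within-namespace
  pairs — 100 pairs per namespace sampled with weight sim², so
  co-mention probability rises with DAG proximity — plus 60
  cross-namespace pairs with uniform q. Scaling the joint rate by the
  background rate makes `planted_prob == background_rate` an exact
  pair-level null (the injected joint rate then equals the
  background-rate² chance co-mention rate, up to the doubled-rate
  residual from independent mentions);
- gene annotations over a 150-gene pool (3–8 genes per term), with
  planted pairs forced to share round(6·0.7·q/0.3) genes so that pairs
  with high expected co-occurrence also show high gene overlap
  (coupling strength 0.7).

These sizes are chosen so a full pipeline run takes about a second while
leaving enough statistical room for the qualitative claims: with the
defaults, RSS_N vs Wang similarity correlates at r ≈ 0.2–0.25 in each
namespace and RSS_N vs gene cosine at r ≈ 0.15, all with p ≪ 0.05, and
over 99% of planted pairs score above the background median.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: linguistic variation (templated sentences,
pseudo-word vocabularies, no real synonymy or polysemy), MeSH-style
indexing effects, citation and topic clustering, corpus growth over time,
and the heavy-tailed term-frequency distributions of PubMed. Correlation
magnitudes on synthetic worlds are therefore qualitative checks of the
machinery, not forecasts of corpus-scale values. One density artifact is
worth knowing: with the default 260 planted pairs, several planted pairs
often co-inject into one sentence, which creates *induced* background
pairs with substantial COV; sparse-planting configurations (e.g. 10
within-namespace + 5 cross pairs) separate planted from background COV
completely.

All randomness flows from a single integer seed through one generator
instance, and every container is iterated in sorted order, so equal
parameters produce byte-identical serialized worlds.

## Pipeline and problem sizes

Intermediates are plain TSV/JSONL with sha256 digest sidecars; a re-run
reuses any stage whose inputs are unchanged, and deleting one
intermediate recomputes only its downstream stages. The test suite and
the acceptance script run entirely on synthetic worlds: 500 documents /
2,500 sentences for end-to-end properties, 50 random corpora of ≤ 200
sentences for the brute-force count equivalence, 100 random fixtures for
the matcher oracle, and 10,000 G(n, m) replicates on a 150-node toy
network for the significance floor.

## Known limitations

- The OBO loader keeps only `is_a` edges; `part_of` and other typed
  relations are ignored throughout (including Wang similarity).
- Obsolete terms are retained for ID lookup but excluded from
  dictionaries, edges, and similarity.
- The matcher performs no fuzzy matching, abbreviation expansion, or
  disambiguation; recall on real text is correspondingly conservative.
- Corpus-scale results depend on corpus-scale inputs; nothing in this
  package downloads or approximates the full PubMed/GO/DO data.
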