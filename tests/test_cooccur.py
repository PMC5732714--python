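"""Co-occurrence counting: sentence filter, index, pair list."""

import random
from collections import defaultdict
from itertools import combinations

import pytest

from cooclink import (
    Document,
    Sentence,
    build_index,
    filter_sentences,
    group_mentions,
    pair_list,
)
from cooclink.cooccur import CooccurrenceIndex, pair_key
from cooclink.errors import IntegrityError, InputError
from cooclink.recognize import TermMention


def mention(doc, idx, term):
    return TermMention(doc, idx, term, 0, 1, "x")


def test_filter_keeps_two_distinct_terms():
    grouped = group_mentions([mention("d", 0, "GO:1"), mention("d", 0, "DOID:2")])
    assert set(filter_sentences(grouped)) == {("d", 0)}


def test_filter_drops_single_and_repeated_same_id():
    grouped = group_mentions([
        mention("d", 0, "GO:1"),                       # one mention
        mention("d", 1, "GO:1"), mention("d", 1, "GO:1"),  # same id twice
        mention("d", 2, "GO:1"), mention("d", 2, "GO:2"),
    ])
    assert set(filter_sentences(grouped)) == {("d", 2)}


def corpus_of(sentence_terms):
    """sentence_terms: list of docs, each a list of per-sentence term lists."""
    documents, sentences, mentions = [], [], []
    for d, doc_sents in enumerate(sentence_terms):
        doc_id = f"d{d}"
        documents.append(Document(doc_id, "text"))
        for i, terms in enumerate(doc_sents):
            sentences.append(Sentence(doc_id, i, " ".join(terms) or "empty"))
            for t in terms:
                mentions.append(mention(doc_id, i, t))
    return documents, sentences, mentions


def test_cov_three_sentences():
    docs, sents, ments = corpus_of([
        [["t1", "t2"], ["t1", "t2"]],
        [["t1", "t2"], ["t1"], []],
    ])
    index = build_index(docs, sents, filter_sentences(group_mentions(ments)))
    assert index.cov("t1", "t2") == 3
    assert index.cov("t2", "t1") == 3  # symmetric access
    assert index.M == 2 and index.S == 5


def test_ov_is_binary_per_sentence():
    docs, sents, ments = corpus_of([[["t1", "t1", "t2"]]])
    index = build_index(docs, sents, filter_sentences(group_mentions(ments)))
    assert index.cov("t1", "t1") == 1
    assert index.cov("t1", "t2") == 1


def test_document_counts_use_document_granularity():
    # t1 and t2 in different sentences of one doc: doc-level pair yes,
    # sentence-level pair no (both sentences must pass the filter though)
    docs, sents, ments = corpus_of([[["t1", "t3"], ["t2", "t3"]]])
    index = build_index(docs, sents, filter_sentences(group_mentions(ments)))
    assert index.cov("t1", "t2") == 0
    assert index.dov("t1", "t2") == 1
    assert index.dov("t3", "t3") == 1
    assert index.cov("t3", "t3") == 2


def test_unknown_sentence_is_integrity_error():
    docs, sents, _ = corpus_of([[["t1", "t2"]]])
    bad = group_mentions([mention("d0", 5, "t1"), mention("d0", 5, "t2")])
    with pytest.raises(IntegrityError):
        build_index(docs, sents, bad)


def test_pair_list_threshold_and_order():
    index = CooccurrenceIndex(
        M=10, S=10, sent_count={"a": 5, "b": 5, "c": 5},
        pair_sent_count={("a", "b"): 1, ("a", "c"): 2, ("b", "c"): 5})
    assert pair_list(index, 1) == [("a", "b", 1), ("a", "c", 2), ("b", "c", 5)]
    assert pair_list(index, 2) == [("a", "c", 2), ("b", "c", 5)]
    assert pair_list(index, 6) == []
    with pytest.raises(InputError):
        pair_list(index, 0)


def brute_force_index(documents, sentences, mentions):
    """O(T^2 * S) nested-loop recount over filtered sentences."""
    by_sentence = defaultdict(set)
    for m in mentions:
        by_sentence[(m.doc_id, m.sentence_index)].add(m.term_id)
    by_sentence = {k: v for k, v in by_sentence.items() if len(v) >= 2}
    terms = sorted({t for v in by_sentence.values() for t in v})
    sent_count = {t: sum(1 for v in by_sentence.values() if t in v) for t in terms}
    pair_sent = {}
    for t1, t2 in combinations(terms, 2):
        c = sum(1 for v in by_sentence.values() if t1 in v and t2 in v)
        if c:
            pair_sent[(t1, t2)] = c
    docs_terms = defaultdict(set)
    for (doc, _), v in by_sentence.items():
        docs_terms[doc] |= v
    doc_count = {t: sum(1 for v in docs_terms.values() if t in v) for t in terms}
    pair_doc = {}
    for t1, t2 in combinations(terms, 2):
        c = sum(1 for v in docs_terms.values() if t1 in v and t2 in v)
        if c:
            pair_doc[(t1, t2)] = c
    return (dict(sent_count), pair_sent, dict(doc_count), pair_doc)


def random_corpus(rng, max_sentences=200):
    terms = [f"T:{i}" for i in range(rng.randint(3, 12))]
    n_docs = rng.randint(1, 15)
    layout = []
    total = 0
    for _ in range(n_docs):
        n_sent = rng.randint(1, 6)
        doc = []
        for _ in range(n_sent):
            if total >= max_sentences:
                break
            k = rng.randint(0, min(5, len(terms)))
            doc.append(rng.sample(terms, k))
            total += 1
        layout.append(doc)
    return corpus_of(layout)


@pytest.mark.parametrize("seed", range(50))
def test_index_equals_bruteforce_on_random_corpora(seed):
    rng = random.Random(seed)
    docs, sents, ments = random_corpus(rng)
    index = build_index(docs, sents, filter_sentences(group_mentions(ments)))
    sc, ps, dc, pd = brute_force_index(docs, sents, ments)
    assert index.sent_count == {k: v for k, v in sc.items() if v}
    assert index.pair_sent_count == ps
    assert index.doc_count == {k: v for k, v in dc.items() if v}
    assert index.pair_doc_count == pd


def test_order_invariance(world_pipeline):
    ments = list(world_pipeline["mentions"])
    rng = random.Random(0)
    rng.shuffle(ments)
    shuffled = build_index(world_pipeline["world"].corpus,
                           world_pipeline["sentences"],
                           filter_sentences(group_mentions(ments)))
    assert shuffled == world_pipeline["index"]


def test_pair_increments_are_k_choose_2():
    docs, sents, ments = corpus_of([[["a", "b", "c", "d"]]])
    index = build_index(docs, sents, filter_sentences(group_mentions(ments)))
    assert sum(index.pair_sent_count.values()) == 6  # C(4,2)


def test_invariant_pair_bounded_by_marginals(world_pipeline):
    index = world_pipeline["index"]
    for (t1, t2), c in index.pair_sent_count.items():
        assert c <= min(index.sent_count[t1], index.sent_count[t2])
    for (t1, t2), c in index.pair_doc_count.items():
        assert c <= min(index.doc_count[t1], index.doc_count[t2])
    for t, c in index.doc_count.items():
        assert c <= index.sent_count[t]
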