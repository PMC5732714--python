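import pytest

from cooclink import (
    CooccurrenceIndex,
    build_dictionary,
    build_index,
    filter_sentences,
    generate_world,
    group_mentions,
    match_terms,
    score_all,
    segment_sentences,
)

TOY_OBO = """\
format-version: 1.2

[Term]
id: GO:0000001
name: alpha process
namespace: biological_process
synonym: "first process" EXACT []
synonym: "alpha thing" RELATED []
alt_id: GO:0000099
is_a: GO:0000002

[Term]
id: GO:0000002
name: beta process
namespace: biological_process
is_a: GO:0000003

[Term]
id: GO:0000003
name: gamma process
namespace: biological_process

[Term]
id: GO:0000004
name: old thing
namespace: biological_process
is_obsolete: true
"""


@pytest.fixture
def toy_obo(tmp_path):
    path = tmp_path / "toy.obo"
    path.write_text(TOY_OBO)
    return path


@pytest.fixture(scope="session")
def default_world():
    """One default synthetic world shared across the session."""
    return generate_world(seed=7)


@pytest.fixture(scope="session")
def world_pipeline(default_world):
    """World plus everything downstream: sentences, index, RSS_N table."""
    w = default_world
    dictionary = build_dictionary(sorted(w.ontologies.values(), key=lambda g: g.name))
    sentences = [s for d in w.corpus for s in segment_sentences(d)]
    mentions = [m for s in sentences for m in match_terms(s, dictionary)]
    kept = filter_sentences(group_mentions(mentions))
    index = build_index(w.corpus, sentences, kept)
    table = score_all(index, "RSS_N")
    return {
        "world": w,
        "dictionary": dictionary,
        "sentences": sentences,
        "mentions": mentions,
        "kept": kept,
        "index": index,
        "table": table,
    }


def make_index(pair_counts, sent_counts, M=1000, S=5000, doc_counts=None,
               pair_doc_counts=None):
    """Small hand-specified index for formula tests."""
    return CooccurrenceIndex(
        M=M,
        S=S,
        sent_count=dict(sent_counts),
        doc_count=dict(doc_counts or sent_counts),
        pair_sent_count={tuple(sorted(k)): v for k, v in pair_counts.items()},
        pair_doc_count={tuple(sorted(k)): v
                        for k, v in (pair_doc_counts or pair_counts).items()},
    )
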