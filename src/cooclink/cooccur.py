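"""Sentence- and document-level co-occurrence counting.

A term's occurrence value (OV) in a sentence is a binary indicator —
repeated mentions count once. The co-occurrence value COV(t1, t2) is the
number of sentences in which both terms occur; COV(t, t) is the number of
sentences containing t. Document-level analogues feed the NMD distance.
Sentences with fewer than two distinct term IDs are filtered out before
counting, since they cannot contribute a pair.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .corpus import Document, Sentence
from .errors import IntegrityError, InputError
from .recognize import TermMention

Pair = tuple[str, str]
SentenceKey = tuple[str, int]  # (doc_id, sentence_index)


def pair_key(t1: str, t2: str) -> Pair:
    """Canonical unordered pair key (lexicographic)."""
    return (t1, t2) if t1 <= t2 else (t2, t1)


def group_mentions(mentions: Iterable[TermMention]) -> dict[SentenceKey, list[TermMention]]:
    grouped: dict[SentenceKey, list[TermMention]] = defaultdict(list)
    for m in mentions:
        grouped[(m.doc_id, m.sentence_index)].append(m)
    return dict(grouped)


def filter_sentences(
    grouped: Mapping[SentenceKey, Sequence[TermMention]]
) -> dict[SentenceKey, list[TermMention]]:
    """Keep only sentences mentioning at least two *distinct* term IDs."""
    return {
        key: list(ms)
        for key, ms in grouped.items()
        if len({m.term_id for m in ms}) >= 2
    }


@dataclass
class CooccurrenceIndex:
    """Occurrence and co-occurrence counts over a corpus.

    ``M`` counts every document read (including those contributing no
    mentions); ``S`` counts every sentence. ``sent_count[t]`` = COV(t, t);
    ``pair_sent_count[(t1, t2)]`` = COV(t1, t2) with unordered keys, and the
    ``doc_*`` maps are the document-granularity analogues used by NMD.
    """

    M: int
    S: int
    sent_count: dict[str, int] = field(default_factory=dict)
    doc_count: dict[str, int] = field(default_factory=dict)
    pair_sent_count: dict[Pair, int] = field(default_factory=dict)
    pair_doc_count: dict[Pair, int] = field(default_factory=dict)

    def cov(self, t1: str, t2: str) -> int:
        """Sentence-level co-occurrence value; COV(t, t) = sentence count."""
        if t1 == t2:
            return self.sent_count.get(t1, 0)
        return self.pair_sent_count.get(pair_key(t1, t2), 0)

    def dov(self, t1: str, t2: str) -> int:
        """Document-level analogue of :meth:`cov`."""
        if t1 == t2:
            return self.doc_count.get(t1, 0)
        return self.pair_doc_count.get(pair_key(t1, t2), 0)

    @property
    def terms(self) -> list[str]:
        return sorted(self.sent_count)


def build_index(
    documents: Sequence[Document],
    sentences: Sequence[Sentence],
    filtered_mentions: Mapping[SentenceKey, Sequence[TermMention]],
) -> CooccurrenceIndex:
    """Count occurrences and co-occurrences from filtered mention groups."""
    sentence_keys = {(s.doc_id, s.index) for s in sentences}
    for key in filtered_mentions:
        if key not in sentence_keys:
            raise IntegrityError(f"mentions reference unknown sentence {key}")

    sent_count: dict[str, int] = defaultdict(int)
    pair_sent: dict[Pair, int] = defaultdict(int)
    doc_terms: dict[str, set[str]] = defaultdict(set)
    for (doc_id, _), ms in filtered_mentions.items():
        terms = sorted({m.term_id for m in ms})
        for t in terms:
            sent_count[t] += 1
        for a, b in combinations(terms, 2):
            pair_sent[(a, b)] += 1
        doc_terms[doc_id].update(terms)

    doc_count: dict[str, int] = defaultdict(int)
    pair_doc: dict[Pair, int] = defaultdict(int)
    for _, terms in sorted(doc_terms.items()):
        ordered = sorted(terms)
        for t in ordered:
            doc_count[t] += 1
        for a, b in combinations(ordered, 2):
            pair_doc[(a, b)] += 1

    return CooccurrenceIndex(
        M=len(documents),
        S=len(sentences),
        sent_count=dict(sent_count),
        doc_count=dict(doc_count),
        pair_sent_count=dict(pair_sent),
        pair_doc_count=dict(pair_doc),
    )


def pair_list(index: CooccurrenceIndex, min_cov: int = 1) -> list[tuple[str, str, int]]:
    """All unordered pairs with COV >= min_cov, lexicographically ordered."""
    if min_cov < 1:
        raise InputError("min_cov must be >= 1")
    return sorted(
        (t1, t2, c) for (t1, t2), c in index.pair_sent_count.items() if c >= min_cov
    )


# ---------------------------------------------------------------------------
# serialization: a directory of plain-text files
# ---------------------------------------------------------------------------

def write_index(index: CooccurrenceIndex, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "meta.json").write_text(
        json.dumps({"M": index.M, "S": index.S}) + "\n", encoding="utf-8")
    with open(directory / "term_counts.tsv", "w", encoding="utf-8") as fh:
        fh.write("term\tsent_count\tdoc_count\n")
        for t in sorted(set(index.sent_count) | set(index.doc_count)):
            fh.write(f"{t}\t{index.sent_count.get(t, 0)}\t{index.doc_count.get(t, 0)}\n")
    for name, counts in (("pair_sent.tsv", index.pair_sent_count),
                         ("pair_doc.tsv", index.pair_doc_count)):
        with open(directory / name, "w", encoding="utf-8") as fh:
            fh.write("term1\tterm2\tcount\n")
            for (a, b), c in sorted(counts.items()):
                fh.write(f"{a}\t{b}\t{c}\n")


def read_index(directory: str | Path) -> CooccurrenceIndex:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text(encoding="utf-8"))
    sent_count: dict[str, int] = {}
    doc_count: dict[str, int] = {}
    for line in (directory / "term_counts.tsv").read_text(encoding="utf-8").splitlines()[1:]:
        t, sc, dc = line.split("\t")
        if int(sc):
            sent_count[t] = int(sc)
        if int(dc):
            doc_count[t] = int(dc)
    pairs = {}
    for name in ("pair_sent.tsv", "pair_doc.tsv"):
        table: dict[Pair, int] = {}
        for line in (directory / name).read_text(encoding="utf-8").splitlines()[1:]:
            a, b, c = line.split("\t")
            table[(a, b)] = int(c)
        pairs[name] = table
    return CooccurrenceIndex(
        M=meta["M"], S=meta["S"], sent_count=sent_count, doc_count=doc_count,
        pair_sent_count=pairs["pair_sent.tsv"], pair_doc_count=pairs["pair_doc.tsv"],
    )
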