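"""Dictionary-based term recognition.

Builds a normalized token-sequence dictionary from ontology term names and
synonyms, and matches sentences against it with a token trie using the
leftmost-longest, non-overlapping strategy of dictionary annotators such as
MGREP. Normalization is deliberately conservative — lowercase, split on
non-alphanumeric characters, no stemming or plural folding — which favors
precision over recall.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .corpus import Sentence
from .errors import DictionaryConfigError
from .ontology import OntologyGraph

_TOKEN_RE = re.compile(r"[0-9A-Za-z]+")


def normalize(text: str) -> tuple[str, ...]:
    """Lowercase and split on non-alphanumeric characters, dropping empties."""
    return tuple(m.group(0).lower() for m in _TOKEN_RE.finditer(text))


@dataclass(frozen=True)
class TermMention:
    """A dictionary hit inside one sentence (0-based half-open char span)."""

    doc_id: str
    sentence_index: int
    term_id: str
    char_start: int
    char_end: int
    matched_text: str


class _TrieNode:
    __slots__ = ("children", "ids")

    def __init__(self) -> None:
        self.children: dict[str, _TrieNode] = {}
        self.ids: frozenset[str] | None = None


@dataclass
class TermDictionary:
    """Mapping from normalized token sequences to the term IDs they label.

    One surface form may map to several IDs (the pipeline performs no
    disambiguation; one mention is emitted per ID). Single-token entries
    shorter than ``min_token_length`` characters are excluded to suppress
    spurious short-label matches.
    """

    entries: dict[tuple[str, ...], frozenset[str]]
    source_ontologies: tuple[str, ...] = ()
    normalization: str = "lower_alnum"
    _root: _TrieNode = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        root = _TrieNode()
        for tokens, ids in self.entries.items():
            node = root
            for tok in tokens:
                node = node.children.setdefault(tok, _TrieNode())
            node.ids = frozenset(ids)
        self._root = root

    def __len__(self) -> int:
        return len(self.entries)


def build_dictionary(
    ontologies: Sequence[OntologyGraph],
    min_token_length: int = 3,
    exact_synonyms_only: bool = False,
) -> TermDictionary:
    """Insert the name and every synonym of each non-obsolete term.

    ``exact_synonyms_only`` restricts synonym insertion to EXACT scope;
    by default synonyms of all scopes are used.
    """
    entries: dict[tuple[str, ...], set[str]] = {}
    for graph in ontologies:
        for term in graph.non_obsolete_terms():
            surfaces = [term.name]
            for text, scope in term.synonyms:
                if exact_synonyms_only and scope != "EXACT":
                    continue
                surfaces.append(text)
            for surface in surfaces:
                tokens = normalize(surface)
                if not tokens:
                    continue
                if len(tokens) == 1 and len(tokens[0]) < min_token_length:
                    continue
                entries.setdefault(tokens, set()).add(term.id)
    if not entries:
        raise DictionaryConfigError(
            "dictionary construction produced no entries "
            "(check min_token_length and ontology contents)"
        )
    return TermDictionary(
        entries={k: frozenset(v) for k, v in entries.items()},
        source_ontologies=tuple(g.name for g in ontologies),
    )


def match_terms(sentence: Sentence, dictionary: TermDictionary) -> list[TermMention]:
    """Leftmost-longest, non-overlapping dictionary matching.

    The sentence is tokenized with the dictionary's normalization (token
    character offsets retained); at each position the longest dictionary
    token-sequence match wins, one mention is emitted per ID of that entry,
    and scanning resumes after the match. Matches respect token boundaries,
    so "cancer" never fires inside "scanner".
    """
    spans = [(m.start(), m.end(), m.group(0).lower())
             for m in _TOKEN_RE.finditer(sentence.text)]
    tokens = [t for _, _, t in spans]
    mentions: list[TermMention] = []
    i, n = 0, len(tokens)
    while i < n:
        node = dictionary._root
        best_end, best_ids = -1, None
        j = i
        while j < n:
            node = node.children.get(tokens[j])
            if node is None:
                break
            j += 1
            if node.ids is not None:
                best_end, best_ids = j, node.ids
        if best_ids is None:
            i += 1
            continue
        start_char = spans[i][0]
        end_char = spans[best_end - 1][1]
        matched = sentence.text[start_char:end_char]
        for term_id in sorted(best_ids):
            mentions.append(TermMention(
                doc_id=sentence.doc_id,
                sentence_index=sentence.index,
                term_id=term_id,
                char_start=start_char,
                char_end=end_char,
                matched_text=matched,
            ))
        i = best_end
    return mentions


def write_mentions(mentions: Iterable[TermMention], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("doc_id\tsentence_index\tterm_id\tstart\tend\ttext\n")
        for m in mentions:
            fh.write(f"{m.doc_id}\t{m.sentence_index}\t{m.term_id}\t"
                     f"{m.char_start}\t{m.char_end}\t{m.matched_text}\n")


def read_mentions(path) -> list[TermMention]:
    from pathlib import Path

    lines = Path(path).read_text(encoding="utf-8").splitlines()
    out = []
    for line in lines[1:]:
        if not line.strip():
            continue
        doc_id, idx, term_id, start, end, text = line.split("\t")
        out.append(TermMention(doc_id, int(idx), term_id,
                               int(start), int(end), text))
    return out
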