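"""Abstract corpora and sentence segmentation.

Reads abstracts from MEDLINE XML (``PubmedArticleSet``) or JSONL and splits
them into sentences with a deterministic rule-based boundary detector: a
sentence ends at '.', '!' or '?' followed by whitespace and then an
uppercase letter or digit (or at end of text), unless the terminator closes
a known abbreviation or a single-uppercase-letter token (which protects
"E. coli"-style binomials). Decimal points never split because no
whitespace follows them.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from lxml import etree

from .errors import CorpusParseError, InputError

#: Default abbreviation list; the guard applies to the final token, so
#: "et al." is protected via "al.".
DEFAULT_ABBREVIATIONS: tuple[str, ...] = (
    "e.g.", "i.e.", "et al.", "Fig.", "Figs.", "Dr.", "vs.", "approx.",
    "No.", "cf.",
)


@dataclass(frozen=True)
class Document:
    """One literature record: identifier plus abstract text (may be empty)."""

    doc_id: str
    text: str


@dataclass(frozen=True)
class Sentence:
    """A whitespace-trimmed sentence span of a document."""

    doc_id: str
    index: int  # 0-based ordinal within the document
    text: str


def read_corpus(path: str | Path, format: str = "jsonl") -> list[Document]:
    """Read a corpus file into Documents, one per article, in file order.

    MEDLINE XML abstracts are the space-joined concatenation of all
    ``AbstractText`` sections (label attributes dropped); articles without
    an abstract yield a Document with empty text and are still counted in M
    downstream. Records without a PMID are skipped with a warning.
    """
    path = Path(path)
    if format == "jsonl":
        return _read_jsonl(path)
    if format == "medline_xml":
        return _read_medline_xml(path)
    raise InputError(f"unknown corpus format {format!r}")


def _read_jsonl(path: Path) -> list[Document]:
    docs: list[Document] = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        try:
            record = json.loads(line)
        except json.JSONDecodeError as exc:
            raise CorpusParseError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
        if "doc_id" not in record:
            warnings.warn(f"{path}:{lineno}: record without doc_id skipped",
                          stacklevel=2)
            continue
        docs.append(Document(doc_id=str(record["doc_id"]),
                             text=str(record.get("text", ""))))
    return docs


def _read_medline_xml(path: Path) -> list[Document]:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise CorpusParseError(f"{path}: malformed XML: {exc}") from exc
    docs: list[Document] = []
    for position, article in enumerate(tree.iter("PubmedArticle"), 1):
        pmid_el = article.find(".//PMID")
        if pmid_el is None or not (pmid_el.text or "").strip():
            warnings.warn(
                f"{path}: article #{position} has no PMID, skipped", stacklevel=2
            )
            continue
        sections = [
            " ".join("".join(el.itertext()).split())
            for el in article.findall(".//Abstract/AbstractText")
        ]
        text = " ".join(s for s in sections if s)
        docs.append(Document(doc_id=pmid_el.text.strip(), text=text))
    return docs


# ---------------------------------------------------------------------------
# sentence segmentation
# ---------------------------------------------------------------------------

def _guard_tokens(abbreviations: Iterable[str]) -> frozenset[str]:
    # the boundary test sees only the token adjacent to the terminator,
    # so multi-word abbreviations contribute their final word
    return frozenset(a.split()[-1] for a in abbreviations)


def _is_boundary(text: str, i: int, guards: frozenset[str]) -> bool:
    """Is the terminator at position i a sentence boundary?"""
    at_end = i == len(text) - 1
    if not at_end:
        if text[i + 1] != " ":
            return False  # covers decimals: '3.5' has no space after '.'
        follow = text[i + 2] if i + 2 < len(text) else ""
        if not (follow.isupper() or follow.isdigit()):
            return False
    if text[i] == ".":
        j = text.rfind(" ", 0, i) + 1
        token = text[j : i + 1]
        if token in guards:
            return False
        if len(token) == 2 and token[0].isupper():  # "E." in "E. coli"
            return False
    return True


def segment_sentences(
    doc: Document, abbreviations: Sequence[str] | None = None
) -> list[Sentence]:
    """Split a document into sentences.

    Runs of whitespace are collapsed first, so joining the returned
    sentences with single spaces reconstructs the whitespace-normalized
    text exactly. Segmentation is deterministic and idempotent.
    """
    if abbreviations is None:
        abbreviations = DEFAULT_ABBREVIATIONS
    guards = _guard_tokens(abbreviations)
    text = " ".join(doc.text.split())
    sentences: list[Sentence] = []
    start = 0
    for i, ch in enumerate(text):
        if ch in ".!?" and _is_boundary(text, i, guards):
            span = text[start : i + 1].strip()
            if span:
                sentences.append(Sentence(doc.doc_id, len(sentences), span))
            start = i + 1
    tail = text[start:].strip()
    if tail:
        sentences.append(Sentence(doc.doc_id, len(sentences), tail))
    return sentences


def load_abbreviations(path: str | Path) -> tuple[str, ...]:
    """One abbreviation per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return tuple(out)


def write_sentences(sentences: Iterable[Sentence], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sentences:
            fh.write(json.dumps(
                {"doc_id": s.doc_id, "index": s.index, "text": s.text}) + "\n")


def read_sentences(path: str | Path) -> list[Sentence]:
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if line.strip():
            r = json.loads(line)
            out.append(Sentence(r["doc_id"], int(r["index"]), r["text"]))
    return out
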