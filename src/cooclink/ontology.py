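"""OBO ontology and gene-annotation loading.

Parses OBO 1.2/1.4 flat files into an :class:`OntologyGraph` restricted to
``is_a`` edges (the subsumption DAG used throughout the pipeline), and
GAF-style or minimal TSV annotation tables into an :class:`AnnotationTable`.
OBO stanza parsing is delegated to :mod:`obonet`; synonym scopes, alternate
IDs, obsolete handling and DAG validation are layered on top.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import obonet

from .errors import (
    AnnotationFormatError,
    OboParseError,
    OntologyValidationError,
)

# canonical namespace tags used across the package
_NS_MAP = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
    "disease_ontology": "DO",
    "BP": "BP",
    "MF": "MF",
    "CC": "CC",
    "DO": "DO",
}
_NS_WRITE = {
    "BP": "biological_process",
    "MF": "molecular_function",
    "CC": "cellular_component",
    "DO": "disease_ontology",
}

_SYNONYM_RE = re.compile(r'^"(?P<text>.*)"\s*(?P<scope>[A-Z_]+)?')
_TERM_ID_RE = re.compile(r"^\S+:\S+$")


@dataclass(frozen=True)
class OntologyTerm:
    """A single ontology term: identifier, label, synonyms, category."""

    id: str
    name: str
    synonyms: tuple[tuple[str, str], ...] = ()  # (text, scope) pairs
    namespace: str = "other"  # BP | MF | CC | DO | other
    obsolete: bool = False
    alt_ids: tuple[str, ...] = ()


@dataclass
class OntologyGraph:
    """Terms plus the acyclic ``is_a`` subsumption graph between them.

    ``is_a_edges`` are (child, parent) pairs. The internal DiGraph points
    child -> parent, so "ancestors of t" are the nodes reachable *from* t.
    Obsolete terms are retained for ID lookup but carry no edges and are
    excluded from dictionaries and similarity computations.
    """

    terms: dict[str, OntologyTerm]
    is_a_edges: list[tuple[str, str]]
    name: str = "ontology"
    _dag: nx.DiGraph = field(default=None, repr=False, compare=False)
    _alt: dict[str, str] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        for child, parent in self.is_a_edges:
            for endpoint in (child, parent):
                if endpoint not in self.terms:
                    raise OntologyValidationError(
                        f"is_a edge endpoint {endpoint!r} is not a loaded term"
                    )
        dag = nx.DiGraph()
        dag.add_nodes_from(t for t, term in self.terms.items() if not term.obsolete)
        dag.add_edges_from(self.is_a_edges)
        if not nx.is_directed_acyclic_graph(dag):
            cycle = nx.find_cycle(dag)
            path = " -> ".join(e[0] for e in cycle) + " -> " + cycle[-1][1]
            raise OntologyValidationError(f"cyclic is_a relationships: {path}")
        self._dag = dag
        alt: dict[str, str] = {}
        for term in self.terms.values():
            for a in term.alt_ids:
                alt[a] = term.id
        self._alt = alt

    # -- lookup ----------------------------------------------------------
    def resolve(self, term_id: str) -> str | None:
        """Map an ID (possibly an alt_id) to its primary ID, or None."""
        if term_id in self.terms:
            return term_id
        return self._alt.get(term_id)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def parents(self, term_id: str) -> list[str]:
        return sorted(self._dag.successors(term_id))

    def children(self, term_id: str) -> list[str]:
        return sorted(self._dag.predecessors(term_id))

    def ancestors(self, term_id: str, inclusive: bool = True) -> set[str]:
        """All terms reachable by following is_a edges upward."""
        anc = nx.descendants(self._dag, term_id)
        if inclusive:
            anc = anc | {term_id}
        return anc

    def descendants(self, term_id: str, inclusive: bool = False) -> set[str]:
        des = nx.ancestors(self._dag, term_id)
        if inclusive:
            des = des | {term_id}
        return des

    def non_obsolete_terms(self) -> list[OntologyTerm]:
        return [t for _, t in sorted(self.terms.items()) if not t.obsolete]


def _canonical_namespace(raw: str | None, term_id: str) -> str:
    if raw in _NS_MAP:
        return _NS_MAP[raw]
    if term_id.startswith("DOID:"):
        return "DO"
    return "other"


def _parse_synonym(raw: str, line_hint: str) -> tuple[str, str]:
    m = _SYNONYM_RE.match(raw.strip())
    if not m:
        raise OboParseError(f"unparseable synonym line: {line_hint!r}")
    return m.group("text"), m.group("scope") or "RELATED"


def _prevalidate_obo(path: Path) -> None:
    """Cheap line scan so malformed stanzas fail with a line number."""
    in_term = False
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("!"):
                continue
            if stripped.startswith("["):
                if not stripped.endswith("]"):
                    raise OboParseError(
                        f"{path}:{lineno}: malformed stanza header {stripped!r}"
                    )
                in_term = stripped == "[Term]"
                continue
            if in_term and ":" not in stripped:
                raise OboParseError(
                    f"{path}:{lineno}: expected 'tag: value' inside [Term] "
                    f"stanza, got {stripped!r}"
                )


def load_obo(path: str | Path, namespace_filter: str | None = None) -> OntologyGraph:
    """Parse an OBO file into an :class:`OntologyGraph`.

    Only ``[Term]`` stanzas are retained; only ``is_a`` lines become edges
    (``part_of`` and other typed relationships are dropped). Obsolete terms
    are loaded, flagged, and stripped of edges. ``namespace_filter`` (one of
    BP/MF/CC/DO/other) restricts the graph to that category.
    """
    path = Path(path)
    _prevalidate_obo(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = obonet.read_obo(path, ignore_obsolete=False)
    except Exception as exc:  # noqa: BLE001 - wrap any parser failure
        raise OboParseError(f"{path}: {exc}") from exc

    terms: dict[str, OntologyTerm] = {}
    edges: list[tuple[str, str]] = []
    for term_id, data in raw.nodes(data=True):
        obsolete = str(data.get("is_obsolete", "")).lower() == "true"
        synonyms = tuple(
            _parse_synonym(s, s) for s in data.get("synonym", ())
        )
        terms[term_id] = OntologyTerm(
            id=term_id,
            name=data.get("name", ""),
            synonyms=synonyms,
            namespace=_canonical_namespace(data.get("namespace"), term_id),
            obsolete=obsolete,
            alt_ids=tuple(data.get("alt_id", ())),
        )
    for child, parent, key in raw.edges(keys=True):
        if key != "is_a":
            continue
        if terms[child].obsolete or terms.get(parent, terms[child]).obsolete:
            continue
        if parent in terms:
            edges.append((child, parent))

    if namespace_filter is not None:
        wanted = _NS_MAP.get(namespace_filter, namespace_filter)
        terms = {t: term for t, term in terms.items() if term.namespace == wanted}
        edges = [(c, p) for c, p in edges if c in terms and p in terms]

    return OntologyGraph(terms=terms, is_a_edges=sorted(set(edges)), name=path.stem)


def write_obo(graph: OntologyGraph, path: str | Path) -> None:
    """Serialize a graph back to OBO (round-trips terms, edges, synonyms)."""
    parents: dict[str, list[str]] = {}
    for child, parent in graph.is_a_edges:
        parents.setdefault(child, []).append(parent)
    lines = ["format-version: 1.2", ""]
    for term_id in sorted(graph.terms):
        term = graph.terms[term_id]
        lines.append("[Term]")
        lines.append(f"id: {term.id}")
        if term.name:
            lines.append(f"name: {term.name}")
        if term.namespace in _NS_WRITE:
            lines.append(f"namespace: {_NS_WRITE[term.namespace]}")
        for a in term.alt_ids:
            lines.append(f"alt_id: {a}")
        for text, scope in term.synonyms:
            lines.append(f'synonym: "{text}" {scope} []')
        for parent in sorted(parents.get(term_id, ())):
            lines.append(f"is_a: {parent}")
        if term.obsolete:
            lines.append("is_obsolete: true")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

@dataclass
class AnnotationTable:
    """Term -> gene annotation records with a per-term gene-set index."""

    records: list[tuple[str, str, str]]  # (term id, gene id, evidence code)
    by_term: dict[str, set[str]] = field(default=None)

    def __post_init__(self) -> None:
        if self.by_term is None:
            index: dict[str, set[str]] = {}
            for term, gene, _ in self.records:
                index.setdefault(term, set()).add(gene)
            self.by_term = index

    def genes(self, term_id: str) -> set[str]:
        return self.by_term.get(term_id, set())

    def __len__(self) -> int:
        return len(self.records)


def _sniff_dialect(first_data_line: str) -> str:
    n = len(first_data_line.rstrip("\n").split("\t"))
    if n >= 15:
        return "gaf"
    if n in (2, 3):
        return "tsv"
    raise AnnotationFormatError(
        f"unrecognized annotation dialect: line has {n} tab-separated fields "
        "(expected GAF >=15 or minimal 2-3 column TSV)"
    )


def load_annotations(
    path: str | Path, drop_iea: bool = False, dedupe: bool = True
) -> AnnotationTable:
    """Load a GAF 2.x or minimal 2-3 column (term, gene[, evidence]) TSV.

    ``drop_iea`` removes records whose evidence code is IEA (inferred from
    electronic annotation); ``dedupe`` collapses duplicate (term, gene)
    pairs, keeping the first.
    """
    path = Path(path)
    data_lines = [
        line
        for line in path.read_text(encoding="utf-8").splitlines()
        if line.strip() and not line.startswith("!")
    ]
    if not data_lines:
        warnings.warn(f"{path}: empty annotation file", stacklevel=2)
        return AnnotationTable(records=[])
    dialect = _sniff_dialect(data_lines[0])

    records: list[tuple[str, str, str]] = []
    for line in data_lines:
        fields = line.rstrip("\n").split("\t")
        if dialect == "gaf":
            # GAF 2.x: col 2 = DB Object ID, col 5 = ontology ID, col 7 = evidence
            term, gene, evidence = fields[4], fields[1], fields[6]
        else:
            term, gene = fields[0], fields[1]
            evidence = fields[2] if len(fields) > 2 else ""
        if not _TERM_ID_RE.match(term):
            raise AnnotationFormatError(
                f"{path}: syntactically invalid term id {term!r}"
            )
        if drop_iea and evidence == "IEA":
            continue
        records.append((term, gene, evidence))

    if dedupe:
        seen: set[tuple[str, str]] = set()
        unique = []
        for rec in records:
            key = rec[:2]
            if key not in seen:
                seen.add(key)
                unique.append(rec)
        records = unique
    return AnnotationTable(records=records)


def write_annotations(table: AnnotationTable, path: str | Path) -> None:
    lines = [f"{t}\t{g}\t{e}" for t, g, e in table.records]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
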