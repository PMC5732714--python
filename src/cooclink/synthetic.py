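"""Seeded synthetic worlds: toy ontologies, annotations, and corpora.

A :class:`SyntheticWorld` bundles everything the pipeline needs — per-
namespace is_a DAGs with multi-token names and synonyms, a gene annotation
table, and an abstract corpus — with a planted set of term pairs whose
sentence co-mention rate is elevated above background. It stands in for
the PubMed/GO/DO inputs so that every stage, from OBO parsing to network
statistics, is testable without downloads.

Generative model, per sentence of each document:

* every dictionary term is mentioned independently with probability
  ``background_rate``;
* every planted pair (t1, t2) is additionally co-mentioned (both terms
  injected together) with probability ``q * background_rate``, where the
  pair's propensity ``q`` is ``planted_prob`` scaled by DAG proximity
  (Wang similarity) for within-namespace pairs. Scaling the joint rate by
  ``background_rate`` makes ``planted_prob == background_rate`` an exact
  null at the pair level: the injected joint rate then equals the
  ``background_rate**2`` chance co-mention rate of any background pair.

Gene annotations are coupled to the same propensities: planted pairs are
forced to share ``round(6 * coupling * q / planted_prob)`` genes, so
pairs with high expected co-occurrence also show high gene overlap.

All randomness flows from one ``numpy`` generator seeded once; iteration
is over sorted containers, so equal parameters give byte-identical worlds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .cooccur import Pair, pair_key
from .corpus import Document
from .errors import InputError
from .ontology import AnnotationTable, OntologyGraph, OntologyTerm, write_annotations, write_obo
from .validation import wang_similarity

_NS_PREFIX = {"DO": "DOID", "BP": "GO", "MF": "GO", "CC": "GO"}

# Pseudo-word pool for term surface forms: deterministic, disjoint from the
# English filler vocabulary of the sentence templates.
_CONSONANTS = "bcdfglmnprstvz"
_VOWELS = "aeiou"

_TEMPLATES_EMPTY = (
    "Further observations were recorded during follow up.",
    "The cohort was monitored for twelve weeks.",
    "Samples were collected under standard conditions.",
)
_TEMPLATES_ONE = (
    "Recent work characterized {a} in detail.",
    "Expression changes involving {a} were observed.",
    "The study examined {a} across patients.",
)
_TEMPLATES_MANY = (
    "Recent work links {items} in several models.",
    "Our analysis connects {items} across cohorts.",
    "These findings relate {items} in this system.",
)


def _word_pool(size: int) -> list[str]:
    syllables = [c + v for c in _CONSONANTS for v in _VOWELS]
    n = len(syllables)
    if size > n**3:
        raise InputError(f"word pool capped at {n**3} words")
    pool = []
    for i in range(size):  # base-n digits of i keep words distinct
        a = syllables[i % n]
        b = syllables[(i // n) % n]
        c = syllables[(i // (n * n)) % n]
        pool.append(a + b + c)
    assert len(set(pool)) == size, "word pool collision"
    return pool


@dataclass(frozen=True)
class WorldParams:
    """Generation parameters; defaults define the standard test conditions."""

    namespaces: tuple[str, ...] = ("DO", "BP")
    n_terms: int = 30                 # per namespace
    extra_parent_prob: float = 0.25   # DAG density beyond the spanning tree
    n_docs: int = 500
    sentences_per_doc: int = 5
    background_rate: float = 0.02     # per-term per-sentence mention prob
    planted_prob: float = 0.3         # co-mention propensity scale
    n_planted_within: int = 100       # per namespace, DAG-proximity weighted
    n_planted_cross: int = 60         # across namespaces, uniform
    gene_pool: int = 150
    coupling: float = 0.7             # annotation-overlap strength in [0, 1]
    synonym_prob: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        positive = ("n_terms", "n_docs", "sentences_per_doc", "gene_pool")
        for name in positive:
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")
        if self.n_planted_within < 0 or self.n_planted_cross < 0:
            raise InputError("planted pair counts must be >= 0")
        if self.n_planted_within + self.n_planted_cross == 0:
            raise InputError("at least one planted pair required")
        for name in ("background_rate", "planted_prob", "coupling",
                     "extra_parent_prob", "synonym_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InputError(f"{name} must lie in [0, 1], got {v}")
        if not self.namespaces:
            raise InputError("at least one namespace required")


@dataclass
class SyntheticWorld:
    """A complete, seeded input bundle with planted ground truth."""

    ontologies: dict[str, OntologyGraph]
    annotations: AnnotationTable
    corpus: list[Document]
    planted_pairs: dict[Pair, float]  # pair -> co-mention propensity q
    params: WorldParams

    @property
    def term_namespace(self) -> dict[str, str]:
        out = {}
        for ns, graph in self.ontologies.items():
            for t in graph.terms:
                out[t] = ns
        return out


def _build_ontology(
    ns: str, n_terms: int, id_offset: int, params: WorldParams,
    rng: np.random.Generator, pool: list[str],
) -> OntologyGraph:
    prefix = _NS_PREFIX.get(ns, "XO")
    ids = [f"{prefix}:9{id_offset + i:06d}" for i in range(n_terms)]
    names: list[str] = []
    for i in range(n_terms):
        n_tok = rng.choice([1, 2, 3], p=[0.3, 0.5, 0.2])
        names.append(" ".join(pool.pop() for _ in range(n_tok)))
    # a few extension names so the matcher faces prefix-overlap cases
    for k in range(max(1, n_terms // 10)):
        target = int(rng.integers(1, n_terms))
        base = int(rng.integers(0, n_terms))
        if base != target and names[base] not in names[target]:
            names[target] = pool.pop() + " " + names[base]

    terms: dict[str, OntologyTerm] = {}
    edges: list[tuple[str, str]] = []
    for i, (tid, name) in enumerate(zip(ids, names)):
        synonyms = ()
        if rng.random() < params.synonym_prob:
            scope = "EXACT" if rng.random() < 0.5 else "RELATED"
            syn = " ".join(pool.pop() for _ in range(int(rng.integers(1, 3))))
            synonyms = ((syn, scope),)
        terms[tid] = OntologyTerm(id=tid, name=name, synonyms=synonyms,
                                  namespace=ns)
        if i > 0:
            parent = int(rng.integers(0, i))
            edges.append((tid, ids[parent]))
            if i > 1 and rng.random() < params.extra_parent_prob:
                second = int(rng.integers(0, i))
                if second != parent:
                    edges.append((tid, ids[second]))
    return OntologyGraph(terms=terms, is_a_edges=sorted(set(edges)), name=ns)


def _select_planted(
    world_ontologies: dict[str, OntologyGraph], params: WorldParams,
    rng: np.random.Generator,
) -> dict[Pair, float]:
    """Planted pairs: within each namespace, pairs sampled with weight
    sim^2 (strongly favoring DAG-proximal pairs) and propensity rising
    with Wang similarity, plus uniform cross-namespace pairs."""
    namespaces = sorted(world_ontologies)
    planted: dict[Pair, float] = {}

    for ns in namespaces:
        graph = world_ontologies[ns]
        ids = sorted(graph.terms)
        candidates = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]]
        sims = np.array([wang_similarity(graph, a, b) for a, b in candidates])
        weights = sims**2 + 1e-4
        n_within = min(params.n_planted_within, len(candidates))
        if n_within == 0:
            continue
        chosen = rng.choice(len(candidates), size=n_within, replace=False,
                            p=weights / weights.sum())
        for k in sorted(chosen):
            a, b = candidates[k]
            q = params.planted_prob * (0.35 + 0.65 * sims[k])
            planted[pair_key(a, b)] = float(q)

    if len(namespaces) > 1 and params.n_planted_cross > 0:
        ids_a = sorted(world_ontologies[namespaces[0]].terms)
        ids_b = sorted(world_ontologies[namespaces[1]].terms)
        n_cross = min(params.n_planted_cross, len(ids_a) * len(ids_b))
        tries = 0
        target = len(planted) + n_cross
        while len(planted) < target and tries < 100 * n_cross:
            tries += 1
            a = ids_a[int(rng.integers(0, len(ids_a)))]
            b = ids_b[int(rng.integers(0, len(ids_b)))]
            key = pair_key(a, b)
            if key not in planted:
                q = params.planted_prob * float(rng.uniform(0.35, 1.0))
                planted[key] = q
    return planted


def _annotate(
    all_terms: list[str], planted: dict[Pair, float], params: WorldParams,
    rng: np.random.Generator,
) -> AnnotationTable:
    genes = [f"GENE{i:05d}" for i in range(params.gene_pool)]
    gene_sets: dict[str, list[str]] = {}
    for t in all_terms:
        k = int(rng.integers(3, 9))
        idx = rng.choice(params.gene_pool, size=k, replace=False)
        gene_sets[t] = [genes[i] for i in sorted(idx)]
    scale = max(params.planted_prob, 1e-12)
    for (a, b), q in sorted(planted.items()):
        n_shared = int(round(6 * params.coupling * q / scale))
        if n_shared == 0:
            continue
        idx = rng.choice(params.gene_pool, size=n_shared, replace=False)
        shared = [genes[i] for i in sorted(idx)]
        for t in (a, b):
            current = [g for g in gene_sets[t] if g not in shared]
            gene_sets[t] = sorted(set(current[: max(1, len(current) - n_shared + 2)]
                                      + shared))
    records = []
    for t in sorted(gene_sets):
        for g in gene_sets[t]:
            evidence = "IEA" if rng.random() < 0.1 else "EXP"
            records.append((t, g, evidence))
    return AnnotationTable(records=records)


def _render_sentence(names: list[str], rng: np.random.Generator) -> str:
    if not names:
        return _TEMPLATES_EMPTY[int(rng.integers(0, len(_TEMPLATES_EMPTY)))]
    if len(names) == 1:
        tpl = _TEMPLATES_ONE[int(rng.integers(0, len(_TEMPLATES_ONE)))]
        return tpl.format(a=names[0])
    tpl = _TEMPLATES_MANY[int(rng.integers(0, len(_TEMPLATES_MANY)))]
    if len(names) == 2:
        items = f"{names[0]} and {names[1]}"
    else:
        items = ", ".join(names[:-1]) + " and " + names[-1]
    return tpl.format(items=items)


def generate_world(params: WorldParams | None = None, **overrides) -> SyntheticWorld:
    """Build a complete synthetic world from parameters and a seed."""
    if params is None:
        params = WorldParams(**overrides)
    elif overrides:
        params = WorldParams(**{**asdict(params), **overrides})
    params.validate()
    rng = np.random.default_rng(params.seed)
    pool = _word_pool(40 * params.n_terms * len(params.namespaces) + 200)
    # deterministic shuffle of the pool, consumed via pop() from the end
    order = rng.permutation(len(pool))
    pool = [pool[i] for i in order]

    ontologies: dict[str, OntologyGraph] = {}
    offset = 0
    for ns in params.namespaces:
        ontologies[ns] = _build_ontology(ns, params.n_terms, offset, params,
                                         rng, pool)
        offset += params.n_terms

    planted = _select_planted(ontologies, params, rng)
    all_terms = sorted(t for g in ontologies.values() for t in g.terms)
    annotations = _annotate(all_terms, planted, params, rng)

    term_name = {t: g.terms[t].name
                 for g in ontologies.values() for t in g.terms}
    planted_items = sorted(planted.items())
    joint_rates = np.array([q * params.background_rate
                            for _, q in planted_items])

    corpus: list[Document] = []
    for d in range(params.n_docs):
        doc_sentences = []
        for _ in range(params.sentences_per_doc):
            mentioned: list[str] = []
            hits = rng.random(len(all_terms)) < params.background_rate
            mentioned.extend(t for t, h in zip(all_terms, hits) if h)
            joint = rng.random(len(planted_items)) < joint_rates
            for (pair, _), h in zip(planted_items, joint):
                if h:
                    mentioned.extend(pair)
            seen = set()
            ordered = [t for t in mentioned
                       if not (t in seen or seen.add(t))]
            doc_sentences.append(
                _render_sentence([term_name[t] for t in ordered], rng))
        corpus.append(Document(doc_id=str(1_000_000 + d),
                               text=" ".join(doc_sentences)))

    return SyntheticWorld(ontologies=ontologies, annotations=annotations,
                          corpus=corpus, planted_pairs=planted, params=params)


def world_to_files(world: SyntheticWorld, directory: str | Path) -> dict[str, Path]:
    """Serialize a world: one OBO per namespace, annotation TSV, corpus in
    both JSONL and MEDLINE-XML dialects, and a planted-pair manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    for ns, graph in sorted(world.ontologies.items()):
        path = directory / f"{ns.lower()}.obo"
        write_obo(graph, path)
        files[f"obo_{ns}"] = path

    files["annotations"] = directory / "annotations.tsv"
    write_annotations(world.annotations, files["annotations"])

    files["corpus_jsonl"] = directory / "corpus.jsonl"
    with open(files["corpus_jsonl"], "w", encoding="utf-8") as fh:
        for doc in world.corpus:
            fh.write(json.dumps({"doc_id": doc.doc_id, "text": doc.text}) + "\n")

    files["corpus_xml"] = directory / "corpus.xml"
    with open(files["corpus_xml"], "w", encoding="utf-8") as fh:
        fh.write('<?xml version="1.0" encoding="UTF-8"?>\n<PubmedArticleSet>\n')
        for doc in world.corpus:
            fh.write("  <PubmedArticle><MedlineCitation>"
                     f"<PMID>{doc.doc_id}</PMID><Article><Abstract>"
                     f"<AbstractText>{doc.text}</AbstractText>"
                     "</Abstract></Article></MedlineCitation></PubmedArticle>\n")
        fh.write("</PubmedArticleSet>\n")

    files["manifest"] = directory / "planted_pairs.tsv"
    with open(files["manifest"], "w", encoding="utf-8") as fh:
        fh.write("term1\tterm2\tplanted_prob\n")
        for (a, b), q in sorted(world.planted_pairs.items()):
            fh.write(f"{a}\t{b}\t{q!r}\n")
    return files
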