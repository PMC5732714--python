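"""Reference similarities and correlation analysis.

Literature-derived relationship scores are validated against two
independent notions of term relatedness:

* **Wang's DAG similarity** — each ancestor ``a`` of a term ``A``
  contributes a semantic value ``S_A(a)`` that decays by a contribution
  factor ``w`` along every is_a edge on the best path down to ``A``
  (``S_A(A) = 1``; ``S_A(a) = max over children c of w * S_A(c)``). With
  ``SV(A) = sum of S_A over ancestors`` the similarity is::

      sim(A, B) = sum over common ancestors a of (S_A(a) + S_B(a))
                  / (SV(A) + SV(B))

  Ancestor sets include the term itself; terms in disjoint DAGs score 0.

* **Gene-set similarity** — cosine or Jaccard overlap of the gene sets
  annotated to two terms, usable across ontologies where no shared DAG
  exists.

Agreement is measured by the Pearson correlation over the pairs shared by
a score table and a similarity table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import sqrt
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
from scipy import stats

from .cooccur import Pair, pair_key
from .errors import (
    InputError,
    InsufficientDataError,
    NotScorableError,
    UndefinedCorrelationError,
)
from .ontology import AnnotationTable, OntologyGraph
from .scoring import PairScoreTable

SIM_METHODS = ("WANG", "GENE_COSINE", "GENE_JACCARD")


@dataclass
class SimilarityTable:
    """Sparse symmetric (term, term) -> similarity in [0, 1]."""

    method: str
    scores: dict[Pair, float] = field(default_factory=dict)

    def get(self, t1: str, t2: str) -> float | None:
        return self.scores.get(pair_key(t1, t2))

    def __len__(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class CorrelationReport:
    """Pearson correlation between a score table and a similarity table."""

    n_pairs: int
    pearson_r: float
    p_value: float
    method_pair: tuple[str, str]


def _semantic_values(
    graph: OntologyGraph, term: str, w_isa: float
) -> dict[str, float]:
    """S-values of every (inclusive) ancestor of ``term``."""
    anc = graph.ancestors(term, inclusive=True)
    sub = graph._dag.subgraph(anc)
    s: dict[str, float] = {}
    # edges run child -> parent, so topological order visits children first
    for node in nx.topological_sort(sub):
        if node == term:
            s[node] = 1.0
        else:
            s[node] = max(w_isa * s[c] for c in sub.predecessors(node))
    return s


def wang_similarity(
    graph: OntologyGraph, t1: str, t2: str, w_isa: float = 0.8
) -> float:
    """DAG-structure similarity of two terms in one ontology."""
    if not 0 < w_isa < 1:
        raise InputError(f"w_isa must be in (0, 1), got {w_isa}")
    for t in (t1, t2):
        if t not in graph.terms:
            raise InputError(f"term {t!r} not in ontology {graph.name!r}")
        if graph.terms[t].obsolete:
            raise InputError(f"term {t!r} is obsolete")
    s1 = _semantic_values(graph, t1, w_isa)
    s2 = _semantic_values(graph, t2, w_isa)
    common = set(s1) & set(s2)
    if not common:
        return 0.0
    return sum(s1[a] + s2[a] for a in common) / (sum(s1.values()) + sum(s2.values()))


def gene_similarity(
    annotations: AnnotationTable, t1: str, t2: str, measure: str = "cosine"
) -> float:
    """Gene-overlap similarity: cosine (default) or Jaccard."""
    g1, g2 = annotations.genes(t1), annotations.genes(t2)
    if not g1 or not g2:
        missing = t1 if not g1 else t2
        raise NotScorableError(f"term {missing!r} has no gene annotations")
    inter = len(g1 & g2)
    if measure == "cosine":
        return inter / sqrt(len(g1) * len(g2))
    if measure == "jaccard":
        return inter / len(g1 | g2)
    raise InputError(f"unknown measure {measure!r}")


def wang_table(
    graph: OntologyGraph, pairs: Iterable[Pair], w_isa: float = 0.8
) -> SimilarityTable:
    """Wang similarity for each pair whose terms both lie in ``graph``."""
    scores = {}
    for t1, t2 in pairs:
        if t1 in graph.terms and t2 in graph.terms:
            if graph.terms[t1].obsolete or graph.terms[t2].obsolete:
                continue
            scores[pair_key(t1, t2)] = wang_similarity(graph, t1, t2, w_isa)
    return SimilarityTable(method="WANG", scores=scores)


def gene_table(
    annotations: AnnotationTable, pairs: Iterable[Pair], measure: str = "cosine"
) -> SimilarityTable:
    """Gene-set similarity for each pair with annotations on both sides."""
    scores = {}
    for t1, t2 in pairs:
        try:
            scores[pair_key(t1, t2)] = gene_similarity(annotations, t1, t2, measure)
        except NotScorableError:
            continue
    return SimilarityTable(method=f"GENE_{measure.upper()}", scores=scores)


def correlate(
    score_table: PairScoreTable, sim_table: SimilarityTable
) -> CorrelationReport:
    """Pearson r (two-sided p) over the pairs shared by both tables."""
    shared = sorted(set(score_table.scores) & set(sim_table.scores))
    if len(shared) < 3:
        raise InsufficientDataError(
            f"need >= 3 shared pairs for a correlation, got {len(shared)}"
        )
    x = [score_table.scores[p] for p in shared]
    y = [sim_table.scores[p] for p in shared]
    if len(set(x)) == 1 or len(set(y)) == 1:
        raise UndefinedCorrelationError(
            "zero variance in one of the vectors; correlation undefined"
        )
    r, p = stats.pearsonr(x, y)
    return CorrelationReport(
        n_pairs=len(shared),
        pearson_r=float(r),
        p_value=float(p),
        method_pair=(score_table.method, sim_table.method),
    )


def scatter_export(
    score_table: PairScoreTable, sim_table: SimilarityTable, path: str | Path
) -> int:
    """Write (term1, term2, score, similarity) rows for the shared pairs.

    Returns the number of data rows written; an empty intersection yields
    a header-only file with a warning.
    """
    shared = sorted(set(score_table.scores) & set(sim_table.scores))
    if not shared:
        warnings.warn("no shared pairs; writing header only", stacklevel=2)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term1\tterm2\tscore\tsimilarity\n")
        for t1, t2 in shared:
            fh.write(f"{t1}\t{t2}\t{score_table.scores[(t1, t2)]!r}\t"
                     f"{sim_table.scores[(t1, t2)]!r}\n")
    return len(shared)
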