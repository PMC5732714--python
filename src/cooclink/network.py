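"""Thresholded term-association networks and their summary statistics.

Nodes are ontology terms; an edge links two terms whose relationship score
is equal to or larger than a chosen threshold. Statistics mirror the usual
characterization of association networks: degree distribution and hubs,
giant-component size with an empirical significance against G(n, m) random
graphs, and a descriptive log-log power-law fit of the degree
distribution.
"""

from __future__ import annotations

import json
import random
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .errors import InputError, InsufficientDataError
from .scoring import PairScoreTable


@dataclass
class AssociationNetwork:
    """Weighted undirected graph of term pairs at or above a threshold."""

    graph: nx.Graph
    threshold: float

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class NetworkStats:
    n_nodes: int
    n_edges: int
    degree_histogram: dict[int, int]
    hubs: list[str]
    max_degree: int
    frac_degree_one: float
    frac_degree_ge3: float
    giant_component_size: int | None = None
    gc_p_value: float | None = None
    powerlaw_slope: float | None = None
    powerlaw_r2: float | None = None

    def to_json(self) -> str:
        d = dict(self.__dict__)
        d["degree_histogram"] = {str(k): v for k, v in sorted(
            self.degree_histogram.items())}
        return json.dumps(d, indent=2)


def threshold_sweep(
    score_table: PairScoreTable, thresholds: Sequence[float]
) -> list[tuple[float, int]]:
    """Edge count at each threshold (count of pairs with score >= theta)."""
    if not score_table.scores:
        raise InputError("empty score table")
    values = np.sort(np.fromiter(score_table.scores.values(), dtype=float))
    out = []
    for theta in thresholds:
        out.append((float(theta), int(len(values) - np.searchsorted(values, theta))))
    return out


def build_network(score_table: PairScoreTable, threshold: float) -> AssociationNetwork:
    """Keep pairs scoring >= threshold; isolated terms are absent."""
    g = nx.Graph()
    for (t1, t2), s in sorted(score_table.scores.items()):
        if t1 != t2 and s >= threshold:
            g.add_edge(t1, t2, score=s)
    if g.number_of_edges() == 0:
        warnings.warn(f"no edges at threshold {threshold}", stacklevel=2)
    return AssociationNetwork(graph=g, threshold=threshold)


def degree_stats(network: AssociationNetwork) -> NetworkStats:
    """Degree histogram, hub set (all ties at max degree), leaf fractions."""
    degrees = dict(network.graph.degree())
    if not degrees:
        raise InputError("network has no nodes")
    hist = Counter(degrees.values())
    max_deg = max(hist)
    n = len(degrees)
    return NetworkStats(
        n_nodes=n,
        n_edges=network.n_edges,
        degree_histogram=dict(hist),
        hubs=sorted(t for t, d in degrees.items() if d == max_deg),
        max_degree=max_deg,
        frac_degree_one=hist.get(1, 0) / n,
        frac_degree_ge3=sum(c for d, c in hist.items() if d >= 3) / n,
    )


def giant_component(network: AssociationNetwork) -> int:
    """Node count of the largest connected component."""
    if network.n_nodes == 0:
        raise InputError("network has no nodes")
    return max(len(c) for c in nx.connected_components(network.graph))


def gc_significance(
    network: AssociationNetwork,
    n_replicates: int = 10_000,
    side: str = "smaller",
    seed: int = 0,
    null_model: str = "gnm",
) -> float:
    """Empirical p-value of the giant-component size vs random networks.

    Replicates are G(n, m) graphs with the observed node and edge counts
    (``null_model="rewire"`` uses degree-preserving double-edge swaps
    instead). With ``side="smaller"`` the count r is the number of
    replicates whose giant component is <= the observed one; the add-one
    estimator p = (r + 1) / (n_replicates + 1) keeps p in (0, 1] and yields
    1/(n+1) when the observation beats every replicate.
    """
    if n_replicates < 1:
        raise InputError("n_replicates must be >= 1")
    if side not in ("smaller", "larger"):
        raise InputError(f"side must be 'smaller' or 'larger', got {side!r}")
    observed = giant_component(network)
    n, m = network.n_nodes, network.n_edges
    rng = random.Random(seed)
    r = 0
    for _ in range(n_replicates):
        if null_model == "gnm":
            g = nx.gnm_random_graph(n, m, seed=rng.randrange(2**31))
        elif null_model == "rewire":
            g = network.graph.copy()
            nx.double_edge_swap(g, nswap=4 * m, max_tries=40 * m + 100,
                                seed=rng.randrange(2**31))
        else:
            raise InputError(f"unknown null model {null_model!r}")
        gc = max(len(c) for c in nx.connected_components(g)) if g.number_of_nodes() else 0
        if side == "smaller" and gc <= observed:
            r += 1
        elif side == "larger" and gc >= observed:
            r += 1
    return (r + 1) / (n_replicates + 1)


def powerlaw_fit(degree_histogram: dict[int, int]) -> tuple[float, float]:
    """Descriptive log-log OLS fit of the degree distribution.

    Regresses log10 P(k) on log10 k over degrees k >= 1 with nonzero node
    counts, where P(k) is the fraction of nodes with degree k. Returns
    (slope, R^2). This is the conventional R^2-reporting fit for scale-free
    eyeballing, not a maximum-likelihood exponent estimate.
    """
    points = sorted((k, c) for k, c in degree_histogram.items() if k >= 1 and c > 0)
    if len(points) < 3:
        raise InsufficientDataError(
            f"need >= 3 distinct degrees with nonzero counts, got {len(points)}"
        )
    total = sum(c for _, c in points)
    x = np.log10([k for k, _ in points])
    y = np.log10([c / total for _, c in points])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), float(r2)


def summarize(
    network: AssociationNetwork,
    n_replicates: int = 0,
    seed: int = 0,
    side: str = "smaller",
) -> NetworkStats:
    """Full statistics bundle; the null-model test runs only if requested."""
    stats = degree_stats(network)
    stats.giant_component_size = giant_component(network)
    try:
        stats.powerlaw_slope, stats.powerlaw_r2 = powerlaw_fit(stats.degree_histogram)
    except InsufficientDataError:
        pass
    if n_replicates > 0:
        stats.gc_p_value = gc_significance(network, n_replicates, side=side, seed=seed)
    return stats


def write_network(network: AssociationNetwork, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "edges.tsv", "w", encoding="utf-8") as fh:
        fh.write("term1\tterm2\tscore\n")
        for t1, t2, data in sorted(network.graph.edges(data=True)):
            fh.write(f"{t1}\t{t2}\t{data['score']!r}\n")
    nx.write_graphml(network.graph, directory / "network.graphml")
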