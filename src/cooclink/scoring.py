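"""Pair-wise relationship scores over a co-occurrence index.

Two families of scores are computed from one :class:`~cooclink.cooccur.
CooccurrenceIndex`:

* RSS (relationship-scaled score), a mutual-information-style statistic on
  sentence-level counts::

      RSS(t1, t2) = log10( COV(t1, t2) / (COV(t1, t1) * COV(t2, t2)) )

  linearly rescaled to [1, 100] over the pair set being scored::

      RSS_N = 1 + 99 * (RSS - RSS_min) / (RSS_max - RSS_min)

* NMD (Normalized MEDLINE Distance), a Normalized-Google-Distance-style
  distance on document-level counts::

      NMD = (max(log D1, log D2) - log D12) / (log M - min(log D1, log D2))

  where D1, D2, D12 are the document counts of each term and of the pair and
  M is the corpus size. The distance is 0 when the rarer term only ever
  appears alongside the other (with D1 = D2), and grows as the pair's joint
  profile diverges. The derived similarity is Sim = max(0, 1 - NMD). The log
  base cancels in the ratio; natural logs are used internally.

Pairs with zero co-occurrence are not scorable (they are excluded from
tables rather than assigned infinities): only extracted co-occurring pairs
carry a score.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .cooccur import CooccurrenceIndex, Pair, pair_key, pair_list
from .errors import DegenerateCorpusError, InputError, NotScorableError

METHODS = ("RSS", "RSS_N", "NMD", "SIM_NMD")


@dataclass
class PairScoreTable:
    """Sparse symmetric (term, term) -> score mapping for one method."""

    method: str
    scores: dict[Pair, float] = field(default_factory=dict)
    rss_min: float | None = None
    rss_max: float | None = None
    index_meta: dict = field(default_factory=dict)

    def get(self, t1: str, t2: str) -> float | None:
        return self.scores.get(pair_key(t1, t2))

    def pairs(self) -> list[Pair]:
        return sorted(self.scores)

    def __len__(self) -> int:
        return len(self.scores)


def rss(index: CooccurrenceIndex, t1: str, t2: str) -> float:
    """Raw relationship-scaled score on sentence-level counts."""
    cov12 = index.cov(t1, t2)
    cov1 = index.cov(t1, t1)
    cov2 = index.cov(t2, t2)
    if cov12 < 1:
        raise NotScorableError(f"no sentence co-occurrence for ({t1}, {t2})")
    if cov1 < 1 or cov2 < 1:
        raise NotScorableError(f"missing marginal sentence count for ({t1}, {t2})")
    return math.log10(cov12 / (cov1 * cov2))


def nmd(index: CooccurrenceIndex, t1: str, t2: str) -> float:
    """Normalized MEDLINE Distance on document-level counts."""
    d1 = index.dov(t1, t1)
    d2 = index.dov(t2, t2)
    d12 = index.dov(t1, t2)
    if d1 < 1 or d2 < 1 or d12 < 1:
        raise NotScorableError(f"no document co-occurrence for ({t1}, {t2})")
    log_m = math.log(index.M)
    lo, hi = math.log(min(d1, d2)), math.log(max(d1, d2))
    if log_m <= lo:
        raise DegenerateCorpusError(
            f"M={index.M} must exceed the smaller document count "
            f"min(D1, D2)={min(d1, d2)}"
        )
    return (hi - math.log(d12)) / (log_m - lo)


def sim_nmd(distance: float) -> float:
    """Similarity transform of the NMD distance: max(0, 1 - d)."""
    if distance < 0:
        raise InputError(f"NMD distance must be >= 0, got {distance}")
    return max(0.0, 1.0 - distance)


def normalize_rss(raw_table: PairScoreTable) -> PairScoreTable:
    """Rescale raw RSS scores linearly onto [1, 100].

    Normalization bounds are taken over exactly the pairs present in
    ``raw_table`` and recorded in the output's metadata. With a single
    distinct raw value every pair is assigned 100 (with a warning).
    """
    if not raw_table.scores:
        raise InputError("cannot normalize an empty RSS table")
    values = raw_table.scores.values()
    rss_min, rss_max = min(values), max(values)
    if rss_max == rss_min:
        warnings.warn(
            "all raw RSS values identical; assigning 100 to every pair",
            stacklevel=2,
        )
        scores = {p: 100.0 for p in raw_table.scores}
    else:
        span = rss_max - rss_min
        scores = {
            p: 1.0 + 99.0 * (v - rss_min) / span
            for p, v in raw_table.scores.items()
        }
    return PairScoreTable(
        method="RSS_N",
        scores=scores,
        rss_min=rss_min,
        rss_max=rss_max,
        index_meta=dict(raw_table.index_meta),
    )


def score_all(
    index: CooccurrenceIndex, method: str = "RSS_N", min_cov: int = 1
) -> PairScoreTable:
    """Score every co-occurring pair with COV >= min_cov.

    For RSS_N the [1, 100] normalization is performed over exactly this
    pair set, so the scope of the table (which ontologies, which min_cov)
    is part of its meaning and is recorded in the metadata.
    """
    method = method.upper()
    if method not in METHODS:
        raise InputError(f"unknown method {method!r}; expected one of {METHODS}")
    pairs = pair_list(index, min_cov=min_cov)
    meta = {"M": index.M, "S": index.S, "min_cov": min_cov}
    if not pairs:
        warnings.warn("no pairs to score; returning empty table", stacklevel=2)
        return PairScoreTable(method=method, index_meta=meta)

    scores: dict[Pair, float] = {}
    for t1, t2, _ in pairs:
        try:
            if method in ("RSS", "RSS_N"):
                scores[(t1, t2)] = rss(index, t1, t2)
            else:
                d = nmd(index, t1, t2)
                scores[(t1, t2)] = sim_nmd(d) if method == "SIM_NMD" else d
        except NotScorableError:
            continue
    table = PairScoreTable(method="RSS" if method == "RSS_N" else method,
                           scores=scores, index_meta=meta)
    if method == "RSS_N":
        return normalize_rss(table)
    return table


def write_scores(table: PairScoreTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        meta = ", ".join(f"{k}={v}" for k, v in sorted(table.index_meta.items()))
        fh.write(f"# method={table.method}, {meta}")
        if table.rss_min is not None:
            fh.write(f", rss_min={table.rss_min!r}, rss_max={table.rss_max!r}")
        fh.write("\nterm1\tterm2\tscore\n")
        for (a, b) in table.pairs():
            fh.write(f"{a}\t{b}\t{table.scores[(a, b)]!r}\n")


def read_scores(path: str | Path) -> PairScoreTable:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    header = lines[0].lstrip("# ").split(", ")
    meta = dict(kv.split("=", 1) for kv in header)
    scores: dict[Pair, float] = {}
    for line in lines[2:]:
        if line.strip():
            a, b, s = line.split("\t")
            scores[(a, b)] = float(s)
    return PairScoreTable(
        method=meta.pop("method"),
        scores=scores,
        rss_min=float(meta.pop("rss_min")) if "rss_min" in meta else None,
        rss_max=float(meta.pop("rss_max")) if "rss_max" in meta else None,
        index_meta=meta,
    )
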