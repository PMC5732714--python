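"""End-to-end pipeline: segment -> annotate -> filter -> index -> score
(-> validate) (-> network), with plain-text intermediates and digest-based
resume.

Each stage writes its output plus a sidecar ``.digest`` recording the
sha256 of the inputs it consumed; a re-run reuses a stage's output when
the digests still match, so deleting one intermediate recomputes only the
stages downstream of it. A run manifest captures versions, digests,
timestamps, and the count flowing out of every stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .cooccur import build_index, filter_sentences, group_mentions, pair_list, read_index, write_index
from .corpus import read_corpus, read_sentences, segment_sentences, write_sentences
from .errors import ConfigError
from .network import build_network, summarize, write_network
from .ontology import load_annotations, load_obo
from .recognize import build_dictionary, match_terms, read_mentions, write_mentions
from .scoring import read_scores, score_all, write_scores
from .validation import correlate, gene_table, scatter_export, wang_table

log = logging.getLogger("cooclink")


@dataclass
class RunConfig:
    """Flat configuration for a full pipeline run."""

    corpus_path: str = ""
    corpus_format: str = "jsonl"  # jsonl | medline_xml
    obo_paths: tuple[str, ...] = ()
    annotations_path: str = ""
    outdir: str = "run"
    namespace_filter: str = ""
    min_token_length: int = 3
    exact_synonyms_only: bool = False
    method: str = "RSS_N"
    min_cov: int = 1
    validate: bool = False
    wang_w: float = 0.8
    gene_measure: str = "cosine"
    network_threshold: float = float("nan")
    replicates: int = 0
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse a flat ``key = value`` file; unknown keys are rejected."""
        known = {f.name: f for f in dataclasses.fields(cls)}
        values: dict[str, object] = {}
        for lineno, line in enumerate(
                Path(path).read_text(encoding="utf-8").splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
            key, raw = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
            ftype = known[key].type
            if ftype in ("tuple[str, ...]",):
                values[key] = tuple(s.strip() for s in raw.split(",") if s.strip())
            elif ftype == "int":
                values[key] = int(raw)
            elif ftype == "float":
                values[key] = float(raw)
            elif ftype == "bool":
                values[key] = raw.lower() in ("1", "true", "yes")
            else:
                values[key] = raw
        return cls(**values)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(outdir: Path, name: str, output: Path, inputs: list[Path], compute):
    """Run ``compute`` unless ``output`` exists with matching input digests."""
    digest_file = output.with_suffix(output.suffix + ".digest")
    wanted = json.dumps({str(p): _sha256(p) for p in sorted(inputs)}, sort_keys=True)
    if output.exists() and digest_file.exists() and digest_file.read_text() == wanted:
        log.info("stage %s: reusing %s", name, output.name)
        return False
    partial = output.with_suffix(output.suffix + ".partial")
    try:
        compute(partial if not output.is_dir() else output)
    except Exception:
        log.error("stage %s failed", name)
        raise
    if partial.exists():
        partial.replace(output)
    digest_file.write_text(wanted)
    return True


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the run manifest as a dict."""
    if not config.corpus_path or not config.obo_paths:
        raise ConfigError("corpus_path and obo_paths are required")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "cooclink",
        "version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": dataclasses.asdict(config),
        "counts": {},
        "digests": {},
    }
    counts = manifest["counts"]

    corpus_path = Path(config.corpus_path)
    documents = read_corpus(corpus_path, config.corpus_format)
    counts["documents"] = len(documents)

    sentences_file = outdir / "sentences.jsonl"

    def _segment(target: Path) -> None:
        sentences = [s for d in documents for s in segment_sentences(d)]
        write_sentences(sentences, target)

    _stage(outdir, "segment", sentences_file, [corpus_path], _segment)
    sentences = read_sentences(sentences_file)
    counts["sentences"] = len(sentences)
    log.info("%d documents, %d sentences", len(documents), len(sentences))

    obo_paths = [Path(p) for p in config.obo_paths]
    ontologies = [
        load_obo(p, namespace_filter=config.namespace_filter or None)
        for p in obo_paths
    ]
    dictionary = build_dictionary(
        ontologies,
        min_token_length=config.min_token_length,
        exact_synonyms_only=config.exact_synonyms_only,
    )
    counts["dictionary_entries"] = len(dictionary)

    mentions_file = outdir / "mentions.tsv"

    def _annotate(target: Path) -> None:
        mentions = [m for s in sentences for m in match_terms(s, dictionary)]
        write_mentions(mentions, target)

    _stage(outdir, "annotate", mentions_file,
           [sentences_file, *obo_paths], _annotate)
    mentions = read_mentions(mentions_file)
    counts["mentions"] = len(mentions)

    kept = filter_sentences(group_mentions(mentions))
    counts["kept_sentences"] = len(kept)
    log.info("%d mentions in %d kept sentences", len(mentions), len(kept))

    index_dir = outdir / "index"
    index = build_index(documents, sentences, kept)
    write_index(index, index_dir)
    counts["pairs"] = len(pair_list(index, min_cov=config.min_cov))

    scores_file = outdir / "scores.tsv"

    def _score(target: Path) -> None:
        table = score_all(index, method=config.method, min_cov=config.min_cov)
        write_scores(table, target)

    _stage(outdir, "score", scores_file,
           [mentions_file, sentences_file], _score)
    table = read_scores(scores_file)
    counts["scored_pairs"] = len(table)
    log.info("%d scored pairs (%s)", len(table), config.method)

    if config.validate:
        validation: dict = {}
        pairs = table.pairs()
        for graph in ontologies:
            sim = wang_table(graph, pairs, w_isa=config.wang_w)
            if len(sim) >= 3:
                try:
                    report = correlate(table, sim)
                except Exception as exc:  # insufficient / degenerate data
                    validation[f"wang_{graph.name}"] = {"error": str(exc)}
                    continue
                validation[f"wang_{graph.name}"] = dataclasses.asdict(report)
                scatter_export(table, sim,
                               outdir / f"scatter_wang_{graph.name}.tsv")
        if config.annotations_path:
            ann = load_annotations(config.annotations_path)
            sim = gene_table(ann, pairs, measure=config.gene_measure)
            try:
                report = correlate(table, sim)
                validation[f"gene_{config.gene_measure}"] = dataclasses.asdict(report)
            except Exception as exc:
                validation[f"gene_{config.gene_measure}"] = {"error": str(exc)}
            scatter_export(table, sim, outdir / "scatter_gene.tsv")
        (outdir / "validation.json").write_text(
            json.dumps(validation, indent=2), encoding="utf-8")
        manifest["validation"] = validation

    if config.network_threshold == config.network_threshold:  # not NaN
        net = build_network(table, config.network_threshold)
        if net.n_edges:
            stats = summarize(net, n_replicates=config.replicates,
                              seed=config.seed)
            write_network(net, outdir / "network")
            (outdir / "network" / "stats.json").write_text(
                stats.to_json(), encoding="utf-8")
            manifest["network"] = json.loads(stats.to_json())

    for p in sorted(outdir.rglob("*")):
        if p.is_file() and not p.name.endswith(".digest"):
            manifest["digests"][str(p.relative_to(outdir))] = _sha256(p)
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2), encoding="utf-8")
    return manifest
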