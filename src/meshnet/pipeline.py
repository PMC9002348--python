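"""End-to-end orchestration: parse/generate → filter → build → stats → export.

The pipeline is deterministic on fixed inputs; the manifest records a SHA-256
hash per artifact so reruns can be compared file by file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import corpus as corpus_mod
from . import medline_io, network, topology
from .corpus import Corpus, apply_selection_criteria
from .ego import SeedSpec, extract_subnetwork, subnetwork_summary
from .synthetic import GeneratorParams, generate_corpus, toy_fixture

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("meshnet")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Exactly one corpus source: input files, generator params, or the toy
    fixture."""

    input_paths: list[Path] = field(default_factory=list)
    generator: GeneratorParams | None = None
    use_toy: bool = False
    label_mode: str = "distinct"
    min_weight: int = 1
    seed_specs: list[SeedSpec] = field(default_factory=list)
    blocklist_path: Path | None = None
    export_dir: Path = Path("meshnet-out")

    def validate(self) -> None:
        sources = sum([bool(self.input_paths), self.generator is not None, self.use_toy])
        if sources != 1:
            raise PipelineError(
                "config: exactly one corpus source required (files, generator, or toy fixture)"
            )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_corpus(config: PipelineConfig) -> Corpus:
    if config.use_toy:
        return toy_fixture()
    blocklist: set[int] = set()
    if config.blocklist_path is not None:
        try:
            text = Path(config.blocklist_path).read_text(encoding="utf-8")
        except OSError as exc:
            raise PipelineError(f"parse: cannot read blocklist: {exc}") from exc
        blocklist = {int(tok) for tok in text.split() if tok.strip()}
    if config.generator is not None:
        records = generate_corpus(config.generator)
    else:
        records = []
        for path in config.input_paths:
            try:
                text = Path(path).read_text(encoding="utf-8", errors="replace")
            except OSError as exc:
                raise PipelineError(f"parse: cannot read {path}: {exc}") from exc
            parsed = medline_io.parse_medline(text)
            for issue in parsed.issues:
                log.warning("parse issue %s:%d: %s", path, issue.line_no, issue.message)
            records.extend(medline_io.to_bib_record(raw) for raw in parsed.records)
        log.info("parse: read %d records from %d file(s)", len(records), len(config.input_paths))
    return apply_selection_criteria(records, blocklist=blocklist)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write all artifacts; returns the manifest dict."""
    config.validate()
    outdir = Path(config.export_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    corpus = _load_corpus(config)
    n_excluded = len(corpus.exclusions)
    log.info("filter: kept %d records, excluded %d", len(corpus), n_excluded)
    if not corpus.records:
        raise PipelineError("filter: no records left after selection criteria")

    bip = network.build_bipartite(corpus, mode=config.label_mode)
    concept_net = network.project_concepts(bip)
    article_net = network.project_articles(bip)
    if config.min_weight > 1:
        concept_net = network.filter_min_weight(concept_net, config.min_weight)
    log.info(
        "build: %d concept nodes, %d edges; %d article nodes, %d edges",
        concept_net.number_of_nodes(), concept_net.number_of_edges(),
        article_net.number_of_nodes(), article_net.number_of_edges(),
    )

    report = topology.compute_node_stats(concept_net)

    artifacts: dict[str, Path] = {}

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        artifacts[name] = path

    emit("concept_edges.tsv", lambda p: network.write_edge_list(concept_net, p))
    emit("concept_network.graphml", lambda p: network.write_graphml(concept_net, p))
    emit("article_edges.tsv", lambda p: network.write_edge_list(article_net, p))
    emit("node_stats.csv", report.write_csv)
    emit("global_stats.json", report.write_global_json)
    emit(
        "tally_year.csv",
        lambda p: corpus_mod.write_tally_csv(corpus_mod.tally_by_year(corpus), p, "year"),
    )
    emit(
        "tally_country.csv",
        lambda p: corpus_mod.write_tally_csv(corpus_mod.tally_by_country(corpus), p, "country"),
    )
    emit("exclusions.csv", lambda p: corpus_mod.write_exclusion_csv(corpus, p))

    subnet_summaries = []
    for i, spec in enumerate(config.seed_specs, start=1):
        try:
            sub = extract_subnetwork(concept_net, spec)
        except KeyError as exc:
            raise PipelineError(f"subnet: {exc}") from exc
        n_nodes, n_edges = subnetwork_summary(sub)
        log.info("subnet %d: %d nodes, %d edges", i, n_nodes, n_edges)
        emit(f"subnet_{i}_edges.tsv", lambda p, g=sub: network.write_edge_list(g, p))
        emit(f"subnet_{i}.graphml", lambda p, g=sub: network.write_graphml(g, p))
        subnet_summaries.append(
            {"seeds": sorted(spec.seeds), "nodes": n_nodes, "edges": n_edges}
        )

    manifest = {
        "counts": {
            "records_kept": len(corpus),
            "records_excluded": n_excluded,
            "concept_nodes": concept_net.number_of_nodes(),
            "concept_edges": concept_net.number_of_edges(),
            "article_nodes": article_net.number_of_nodes(),
            "article_edges": article_net.number_of_edges(),
        },
        "subnetworks": subnet_summaries,
        "artifacts": {name: _sha256(path) for name, path in sorted(artifacts.items())},
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return manifest
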