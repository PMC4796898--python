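"""Umbrella pipeline: run every stage whose inputs are configured.

Stage order mirrors the analysis flow: expression evidence -> gene lists ->
network prediction -> pruning -> summaries, plus the independent qPCR and
word-landscape stages.  Outputs are plain TSV/JSON in the run directory and
a manifest records the package version, the full config, its hash and the
seed — enough to reproduce any run byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, genelists, io, network, qpcr, seedscan
from .types import UNDETERMINED, TargetEvidence

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Input paths and thresholds for one pipeline run.

    Any input left as None disables its stage.  Threshold defaults follow
    the study's choices: array adjusted-p 0.1, qPCR adjusted-p 0.05, 10%
    fold-change cut for the enrichment input, 30% QC tolerance, hub
    threshold 7 downstream targets, PPI degree threshold 75.
    """

    out_dir: str = "regsign_run"
    edges: str | None = None
    anchors: str | None = None
    expression: str | None = None
    targets: str | None = None
    gmt: str | None = None
    utrs: str | None = None
    ranking: str | None = None
    ct_table: str | None = None
    word: str | None = None
    array_alpha: float = 0.1
    qpcr_alpha: float = 0.05
    fc_threshold: float = 0.10
    qc_tolerance: float = 0.30
    hub_threshold: int = 7
    degree_threshold: int = 75
    max_rounds: int = 25
    bin_step: int | None = None
    reference_gene: str = "Hprt"
    qc_gene: str = "Jag1"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("array_alpha", "qpcr_alpha", "fc_threshold", "qc_tolerance"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute every configured stage; returns the run directory.

    All configured input paths are validated before any stage runs.  A
    stage failure aborts the run, leaving partial outputs plus a FAILED
    marker naming the stage and cause.
    """
    logging.basicConfig(level=config.log_level, format="[%(name)s] %(message)s")
    inputs = {
        name: getattr(config, name)
        for name in ("edges", "anchors", "expression", "targets", "gmt",
                     "utrs", "ranking", "ct_table")
        if getattr(config, name) is not None
    }
    for name, path in inputs.items():
        io.ensure_exists(path, name)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "package": "regsign",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
    }

    stage = "init"
    try:
        if config.expression:
            stage = "gene_lists"
            records = genelists.collapse_probes(io.read_expression_table(config.expression))
            mis = genelists.compile_misregulated(records, config.array_alpha, config.qpcr_alpha)
            mis.to_csv(out / "misregulated.tsv", sep="\t", index=False)
            ranked_input = genelists.gsea_input(records, config.fc_threshold)
            ranked_input.to_csv(out / "enrichment_input.rnk", sep="\t", index=False, header=False)
            counts = {"misregulated": int(len(mis)), "enrichment_input": int(len(ranked_input))}
            if config.targets:
                tdf = pd.read_csv(config.targets, sep="\t")
                evidence = [
                    TargetEvidence(str(r.gene), str(r.category), str(getattr(r, "citation", "")))
                    for r in tdf.itertuples()
                ]
                targets, ttable = genelists.compile_direct_targets(evidence)
                ttable.to_csv(out / "direct_targets.tsv", sep="\t", index=False)
                counts["direct_targets"] = len(targets)
                counts["overlap"] = len(targets & set(mis["gene"]))
            if config.gmt:
                sets = io.read_gmt(config.gmt)
                universe = {r.gene for r in records}
                query = set(mis["gene"]) & universe
                ora = genelists.ora_hypergeometric(query, sets, universe)
                ora.to_csv(out / "ora.tsv", sep="\t", index=False)
                counts["ora_sets"] = int(len(ora))
            summary["stages"][stage] = counts

        if config.edges:
            stage = "network"
            edges = io.read_edge_table(config.edges)
            anchors = io.read_anchor_table(config.anchors) if config.anchors else []
            net = network.RegulatoryNetwork(edges, anchors)
            assignments, report = network.predict_states(net, config.max_rounds)
            scored = network.RegulatoryNetwork(edges, list(assignments.values()))
            scores = {g: network.score_node(scored, g) for g in scored.genes}
            io.write_assignments(out / "assignments.tsv", assignments, scores)
            pruned, removed = network.prune_inconsistent(net, assignments)
            io.write_edge_table(out / "pruned_network.tsv", pruned.edges)
            io.write_sif(out / "pruned_network.sif", pruned.edges)
            io.write_edge_table(out / "removed_edges.tsv", removed)
            hubs = network.hub_summary(pruned, config.hub_threshold)
            pd.DataFrame(
                {"gene": list(hubs.out_degree), "out_degree": list(hubs.out_degree.values())}
            ).sort_values(["out_degree", "gene"], ascending=[False, True]).to_csv(
                out / "hub_table.tsv", sep="\t", index=False
            )
            states = [assignments[g].state for g in net.genes]
            summary["stages"][stage] = {
                "nodes": len(net.genes),
                "anchored": len(net.anchored_genes()),
                "predicted_up": sum(
                    1 for g in net.genes
                    if assignments[g].state == 1 and not net.states[g].tier.anchored
                ),
                "predicted_down": sum(
                    1 for g in net.genes
                    if assignments[g].state == -1 and not net.states[g].tier.anchored
                ),
                "undetermined": sum(1 for s in states if s == UNDETERMINED),
                "pruned_edges": len(removed),
                "hubs": len(hubs.hubs),
                "rounds": report.rounds,
                "converged": report.converged,
            }

        if config.utrs and config.ranking:
            stage = "seedscan"
            ranked = io.read_fasta_with_ranking(config.utrs, config.ranking)
            step = config.bin_step or seedscan.default_bin_step(len(ranked))
            if config.word:
                land = seedscan.word_landscape(ranked, config.word, step)
                land.to_frame().to_csv(out / "landscape.tsv", sep="\t", index=False)
                summary["stages"][stage] = {
                    "word": land.word,
                    "peak_score": land.peak_score,
                    "peak_cutoff": land.peak_cutoff,
                    "n_present": land.n_present,
                }
            top = seedscan.top_words(ranked, n_words=20, bin_step=step)
            top.to_csv(out / "top_words.tsv", sep="\t", index=False)
            summary["stages"].setdefault(stage, {})["top_word"] = str(top["word"].iloc[0])

        if config.ct_table:
            stage = "qpcr"
            table = io.read_ct_table(config.ct_table)
            res = qpcr.analyze_qpcr(
                table,
                reference=config.reference_gene,
                qc=config.qc_gene if config.qc_gene in set(table["gene"]) else None,
                tolerance=config.qc_tolerance,
            )
            res.to_csv(out / "qpcr_results.tsv", sep="\t", index=False, float_format="%.6g")
            summary["stages"][stage] = {
                "genes_tested": int(len(res)),
                "significant": int((res["p_adj"] < config.qpcr_alpha).sum()) if len(res) else 0,
            }
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\ncause: {exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
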