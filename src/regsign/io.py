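"""Readers and writers for the pipeline's plain-text formats.

TSV for edges, anchors, expression evidence, Ct tables and centrality
tables; FASTA (plus a ranking sidecar TSV) for 3'UTR sets; GMT for gene
sets; SIF export for graph viewers.  All gene identifiers are
case-preserved symbols matched exactly — alias resolution is deliberately
out of scope.  Sequence coordinates everywhere are 0-based half-open,
forward strand.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seedscan import RankedUtrSet
from .types import STATE_CODES, STATE_NAMES, ExpressionRecord, NodeState, RegEdge, Tier

logger = logging.getLogger(__name__)

_SIGN_TOKENS = {"+1": 1, "1": 1, "-1": -1, "activates": 1, "represses": -1}


def read_edge_table(path) -> list[RegEdge]:
    """Edge TSV -> RegEdge list; every parse error names its line number.

    Duplicate (source, target, sign) triples are dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"source", "target", "sign"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: edge table needs columns {sorted(required)}")
    edges: list[RegEdge] = []
    seen: set[tuple[str, str, int]] = set()
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        token = str(row["sign"]).strip()
        if token not in _SIGN_TOKENS:
            raise ValueError(f"{path}, line {line}: unknown sign token {token!r}")
        try:
            edge = RegEdge(
                source=str(row["source"]),
                target=str(row["target"]),
                sign=_SIGN_TOKENS[token],
                directness=str(row.get("directness", "direct") or "direct"),
                provenance=str(row.get("provenance", "") or ""),
            )
        except ValueError as exc:
            raise ValueError(f"{path}, line {line}: {exc}") from exc
        key = (edge.source, edge.target, edge.sign)
        if key in seen:
            logger.warning("%s, line %d: duplicate edge %s->%s dropped", path, line, *key[:2])
            continue
        seen.add(key)
        edges.append(edge)
    return edges


def write_edge_table(path, edges: list[RegEdge]) -> None:
    pd.DataFrame(
        {
            "source": [e.source for e in edges],
            "target": [e.target for e in edges],
            "sign": [f"{e.sign:+d}" for e in edges],
            "directness": [e.directness for e in edges],
            "provenance": [e.provenance for e in edges],
        }
    ).to_csv(path, sep="\t", index=False)


def read_anchor_table(path) -> list[NodeState]:
    """Anchor TSV (gene, state in {up, down}, tier) -> NodeState list."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for i, row in df.iterrows():
        state = str(row["state"]).strip().lower()
        if state not in STATE_CODES:
            raise ValueError(f"{path}, line {i + 2}: unknown state {state!r}")
        try:
            tier = Tier(str(row.get("tier", "array_reported")).strip())
        except ValueError as exc:
            raise ValueError(f"{path}, line {i + 2}: {exc}") from exc
        out.append(NodeState(str(row["gene"]), STATE_CODES[state], tier))
    return out


def write_assignments(path, assignments: dict[str, NodeState], scores=None) -> None:
    """Assignments TSV (gene, state, tier, score_up, score_down)."""
    genes = sorted(assignments)
    df = pd.DataFrame(
        {
            "gene": genes,
            "state": [STATE_NAMES[assignments[g].state] for g in genes],
            "tier": [assignments[g].tier.value for g in genes],
        }
    )
    if scores is not None:
        df["score_up"] = [scores[g].score_up if g in scores else "" for g in genes]
        df["score_down"] = [scores[g].score_down if g in scores else "" for g in genes]
    df.to_csv(path, sep="\t", index=False)


def read_expression_table(path) -> list[ExpressionRecord]:
    df = pd.read_csv(path, sep="\t")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                ExpressionRecord(
                    gene=str(row["gene"]),
                    source=str(row["source"]),
                    fold_change=float(row["fold_change"]),
                    p_raw=float(row["p_raw"]),
                    p_adj=float(row["p_adj"]),
                    probe=str(row["probe"]) if "probe" in df.columns and pd.notna(row["probe"]) else None,
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}, line {i + 2}: {exc}") from exc
    return records


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"pair_id": str, "genotype": str, "gene": str})
    required = {"pair_id", "genotype", "gene", "ct"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: Ct table needs columns {sorted(required)}")
    bad = set(df["genotype"].unique()) - {"wt", "hom"}
    if bad:
        raise ValueError(f"{path}: unknown genotype values {sorted(bad)} (expected wt/hom)")
    return df


def write_ct_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_gmt(path) -> dict[str, set[str]]:
    """GMT (set name, description, members...) -> {name: gene set}."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            raw = raw.rstrip("\n")
            if not raw:
                continue
            fields = raw.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}, line {i}: GMT lines need name, description, >=1 gene")
            sets[fields[0]] = set(fields[2:])
    return sets


def write_fasta(path, ranked: RankedUtrSet, ranking_path=None) -> None:
    """FASTA of UTRs plus an optional ranking sidecar TSV (gene, rank)."""
    records = [SeqRecord(Seq(ranked.sequences[g]), id=g, description="") for g in ranked.genes]
    SeqIO.write(records, str(path), "fasta")
    if ranking_path is not None:
        pd.DataFrame({"gene": ranked.genes, "rank": range(1, len(ranked) + 1)}).to_csv(
            ranking_path, sep="\t", index=False
        )


def read_fasta_with_ranking(fasta_path, ranking_path) -> RankedUtrSet:
    """FASTA + ranking TSV -> RankedUtrSet ordered by the ranking.

    Genes present in the FASTA but absent from the ranking are dropped with
    a warning; ranked genes without a sequence raise.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"{fasta_path}: duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    ranking = pd.read_csv(ranking_path, sep="\t", dtype={"gene": str})
    if "rank" in ranking.columns:
        ranking = ranking.sort_values("rank")
    genes = [str(g) for g in ranking["gene"]]
    if not genes:
        raise ValueError(f"{ranking_path}: ranking is empty")
    missing = [g for g in genes if g not in seqs]
    if missing:
        raise ValueError(f"{ranking_path}: ranked genes without a sequence: {missing[:5]}")
    unmatched = set(seqs) - set(genes)
    if unmatched:
        logger.warning("%s: %d sequences not in the ranking; dropped", fasta_path, len(unmatched))
    return RankedUtrSet(genes, {g: seqs[g] for g in genes})


def write_sif(path, edges: list[RegEdge]) -> None:
    """SIF export: source <activates|represses> target, one edge per line."""
    with open(path, "w") as fh:
        for e in edges:
            rel = "activates" if e.sign > 0 else "represses"
            fh.write(f"{e.source}\t{rel}\t{e.target}\n")


def read_ppi_edges(path) -> list[tuple[str, str]]:
    """Undirected edge TSV (or SIF with 3 columns) -> node-pair list."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    if {"source", "target"} <= set(cols):
        return list(zip(df["source"], df["target"]))
    if len(cols) == 3:  # SIF without header: re-read raw
        raw = pd.read_csv(path, sep="\t", dtype=str, header=None)
        return list(zip(raw[0], raw[2]))
    raise ValueError(f"{path}: expected source/target columns or 3-column SIF")


def ensure_exists(path, what: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"{what} not found: {p}")
    return p
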