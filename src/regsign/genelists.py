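"""Evidence-compilation rules for misregulated genes and direct targets.

Two gene lists drive the network construction: (1) the *misregulated* list
— genes significant in either developmental microarray at adjusted P < 0.1
or by qRTPCR at adjusted P < 0.05, each carrying exactly one quantitative
fold change (qRTPCR preferred over array when both are significant); and
(2) the *direct target* list — the union of four evidence categories
(literature-confirmed, luciferase-confirmed, upregulated with a seed match
in the 3'UTR, predicted-and-expressed).

Also here: probe-to-gene collapsing (lowest raw p wins), construction of
the ranked input table for external gene-set enrichment tools, and exact
hypergeometric over-representation analysis with BH adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .qpcr import bh_adjust
from .types import ExpressionRecord, TargetEvidence

logger = logging.getLogger(__name__)

ARRAY_SOURCES = ("array_P0", "array_P4")


def compile_misregulated(
    records: list[ExpressionRecord],
    array_alpha: float = 0.1,
    qpcr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Select misregulated genes and attach one fold change per gene.

    A gene enters the list when any array record has adjusted p below
    ``array_alpha`` or any qRTPCR record has adjusted p below
    ``qpcr_alpha``.  The attached value is the significant qRTPCR fold
    change when one exists, otherwise the significant array value (P4
    preferred over P0 when both arrays are significant).  Genes whose
    significant sources disagree in sign are kept but flagged.
    """
    rows = []
    by_gene: dict[str, list[ExpressionRecord]] = {}
    for r in records:
        by_gene.setdefault(r.gene, []).append(r)
    for gene in sorted(by_gene):
        recs = by_gene[gene]
        sig_q = [r for r in recs if r.source == "qrtpcr" and r.p_adj < qpcr_alpha]
        sig_a = [r for r in recs if r.source in ARRAY_SOURCES and r.p_adj < array_alpha]
        if not sig_q and not sig_a:
            continue
        if sig_q:
            chosen = min(sig_q, key=lambda r: r.p_adj)
        else:
            # prefer the P4 array when both arrays are significant
            p4 = [r for r in sig_a if r.source == "array_P4"]
            pool = p4 if p4 else sig_a
            chosen = min(pool, key=lambda r: r.p_adj)
        signs = {np.sign(r.fold_change) for r in sig_q + sig_a}
        conflict = len(signs) > 1
        if conflict:
            logger.warning("gene %s: significant sources disagree in sign; kept, flagged", gene)
        rows.append(
            {
                "gene": gene,
                "fold_change": chosen.fold_change,
                "p_adj": chosen.p_adj,
                "source_used": chosen.source,
                "sign_conflict": conflict,
            }
        )
    return pd.DataFrame(rows, columns=["gene", "fold_change", "p_adj", "source_used", "sign_conflict"])


def compile_direct_targets(evidence: list[TargetEvidence]) -> tuple[set[str], pd.DataFrame]:
    """Union of the four evidence categories, deduplicated.

    Returns the unique gene set and a provenance table with one row per
    gene listing every category that nominated it.
    """
    cats: dict[str, list[str]] = {}
    cites: dict[str, list[str]] = {}
    for ev in evidence:
        if not isinstance(ev, TargetEvidence):
            ev = TargetEvidence(*ev)
        cats.setdefault(ev.gene, [])
        if ev.category not in cats[ev.gene]:
            cats[ev.gene].append(ev.category)
        if ev.citation:
            cites.setdefault(ev.gene, []).append(ev.citation)
    table = pd.DataFrame(
        {
            "gene": sorted(cats),
            "categories": [";".join(cats[g]) for g in sorted(cats)],
            "citations": [";".join(cites.get(g, [])) for g in sorted(cats)],
        }
    )
    return set(cats), table


def collapse_probes(records: list[ExpressionRecord]) -> list[ExpressionRecord]:
    """Keep, per gene, the probe with the lowest raw p-value.

    Ties on p are broken towards the larger |fold change| and logged.
    """
    by_gene: dict[str, list[ExpressionRecord]] = {}
    for r in records:
        by_gene.setdefault(r.gene, []).append(r)
    out = []
    for gene in sorted(by_gene):
        recs = by_gene[gene]
        best_p = min(r.p_raw for r in recs)
        best = [r for r in recs if r.p_raw == best_p]
        if len(best) > 1:
            logger.info("gene %s: %d probes tie at p=%g; keeping largest |fc|", gene, len(best), best_p)
        out.append(max(best, key=lambda r: abs(r.fold_change)))
    return out


def gsea_input(records: list[ExpressionRecord], fc_threshold: float = 0.10) -> pd.DataFrame:
    """Ranked gene table for external enrichment tools.

    Retains genes whose |signed fold change| corresponds to more than a
    ``fc_threshold`` (default 10%) change, i.e. |fc| >= 1 + threshold on
    the signed convention, ordered most-upregulated first.  Records should
    already be collapsed to one per gene.
    """
    cut = 1.0 + fc_threshold
    kept = [r for r in records if abs(r.fold_change) >= cut]
    kept.sort(key=lambda r: (-r.fold_change, r.gene))
    return pd.DataFrame(
        {"gene": [r.gene for r in kept], "fold_change": [r.fold_change for r in kept]}
    )


@dataclass
class CompiledLists:
    """The two gene lists plus their overlap."""

    direct_targets: set[str]
    misregulated: pd.DataFrame
    overlap: set[str] = field(init=False)

    def __post_init__(self) -> None:
        self.overlap = self.direct_targets & set(self.misregulated["gene"])


def ora_hypergeometric(
    query: set[str], gene_sets: dict[str, set[str]], universe: set[str]
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of ``query`` in each set.

    Each gene set is intersected with the universe first; p is the
    probability of an overlap at least as large as observed when drawing
    |query| genes from the universe.  BH adjustment runs across all sets.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    N, n = len(universe), len(query)
    rows = []
    for name in sorted(gene_sets):
        members = gene_sets[name] & universe
        K = len(members)
        k = len(query & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"set": name, "set_size": K, "overlap": k, "p_raw": min(p, 1.0)})
    df = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p_raw"])
    if len(df):
        df["p_adj"] = bh_adjust(df["p_raw"].to_numpy())
    else:
        df["p_adj"] = []
    return df
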