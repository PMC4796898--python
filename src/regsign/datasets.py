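"""Packaged reference fixtures.

* The 31-gene direct-target evidence table, transcribed from the published
  running text (four evidence categories).
* The Myod1 worked-example neighbourhood — a synthetic reconstruction of
  the published scoring illustration: only Myod1, Igll1 and Gpc1 are named
  in the original figure, so the remaining neighbourhood genes carry
  placeholder ids (RegA, Tgt1); the topology, signs and evidence tiers
  reproduce the published score arithmetic exactly.
* The high-degree row of the published PPI centrality table (18 nodes with
  degree > 75).
* The raw Wilcoxon p-values printed in the published qPCR figure captions,
  grouped by panel.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .genelists import compile_direct_targets
from .io import read_anchor_table, read_edge_table
from .network import RegulatoryNetwork
from .types import TargetEvidence


def _data_path(name: str):
    return resources.files("regsign.data").joinpath(name)


def direct_target_evidence() -> list[TargetEvidence]:
    """The packaged four-category direct-target evidence table (31 genes)."""
    with resources.as_file(_data_path("direct_target_evidence.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return [TargetEvidence(r.gene, r.category, r.citation) for r in df.itertuples()]


def direct_targets() -> set[str]:
    """Union of the four evidence categories (31 unique genes)."""
    genes, _ = compile_direct_targets(direct_target_evidence())
    return genes


def myod1_network() -> RegulatoryNetwork:
    """The Myod1 worked-example neighbourhood with its observed states."""
    with resources.as_file(_data_path("myod1_edges.tsv")) as p:
        edges = read_edge_table(p)
    with resources.as_file(_data_path("myod1_anchors.tsv")) as p:
        anchors = read_anchor_table(p)
    return RegulatoryNetwork(edges, anchors, root="Mir96")


def ppi_high_degree_table() -> pd.DataFrame:
    """The published high-degree PPI centrality rows (degree > 75)."""
    with resources.as_file(_data_path("ppi_high_degree.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def qpcr_panel_pvalues() -> pd.DataFrame:
    """Raw caption Wilcoxon p-values per qPCR panel (panel, gene, p_raw)."""
    with resources.as_file(_data_path("qpcr_panel_pvalues.tsv")) as p:
        return pd.read_csv(p, sep="\t")
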