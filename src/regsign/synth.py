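"""Seeded generators for synthetic pipeline inputs.

Three generators emulate the statistical structure of the study inputs:

* :func:`generate_regnet` — a signed directed regulatory network with a
  planted, fully sign-consistent ground truth of up/down states, a
  designated microRNA root (state down, all outgoing edges repressive: a
  loss-of-function microRNA de-represses its targets), and a sample of
  anchor nodes reporting the truth at two evidence tiers, optionally with
  observation noise (anchor flips).
* :func:`generate_ranked_utrs` — a ranked gene list with i.i.d. background
  3'UTR sequences at a chosen GC content, where a heptamer is planted into
  a fraction of the leading (most upregulated) genes.
* :func:`generate_qpcr_table` — littermate-pair Ct tables with a fixed
  reference gene and a QC marker gene, with gene-wise true expression
  ratios and Gaussian cycle noise.

All generators are deterministic functions of their spec (same seed,
byte-identical output).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import DOWN, UP, NodeState, RegEdge, Tier

ROOT_NAME = "Mir96"
REFERENCE_GENE = "Hprt"
QC_GENE = "Jag1"


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class SynthNetworkSpec:
    """Parameters of the planted signed-network generator.

    ``edge_probability`` is the per-ordered-pair edge density; the acyclic
    generator orients each sampled unordered pair along a hidden topological
    order so the expected edge count matches n(n-1) * edge_probability in
    both modes.  ``repression_fraction`` applies to the truth-setting edge
    into each node; the signs of the remaining edges are dictated by the
    planted consistency requirement (see methods note).
    """

    n_nodes: int = 200
    edge_probability: float = 0.02
    repression_fraction: float = 0.3
    anchor_fraction: float = 0.3
    qrt_fraction: float = 0.4
    anchor_flip_probability: float = 0.0
    acyclic: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError(f"n_nodes must be >= 2, got {self.n_nodes}")
        if not 0.0 < self.edge_probability <= 1.0:
            raise ValueError(f"edge_probability must be in (0, 1], got {self.edge_probability}")
        for name in ("repression_fraction", "anchor_fraction", "qrt_fraction",
                     "anchor_flip_probability"):
            _check_fraction(name, getattr(self, name))


def generate_regnet(
    spec: SynthNetworkSpec,
) -> tuple[list[RegEdge], dict[str, int], list[NodeState]]:
    """Sample a network, its planted truth, and noisy anchors.

    Every edge u->v satisfies truth(v) = sign * truth(u): ground-truth
    states propagate from random root states along the hidden order, with
    the sign of each node's first ("truth-setting") incoming edge drawn at
    the repression fraction and all other edge signs forced by consistency.
    The microRNA root is always the truth-setter of its targets, so its
    out-edges are uniformly repressive and its targets up.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    width = max(4, len(str(n)))
    others = [f"G{i:0{width}d}" for i in range(1, n)]
    rng.shuffle(others)
    order = [ROOT_NAME] + others  # hidden topological order, root first
    pos = {g: i for i, g in enumerate(order)}

    pairs: list[tuple[str, str]] = []  # directed, source earlier unless cyclic
    if spec.acyclic:
        p_pair = min(1.0, 2.0 * spec.edge_probability)
        for i in range(n):
            draws = rng.random(n - i - 1) < p_pair
            pairs.extend((order[i], order[i + 1 + j]) for j in np.nonzero(draws)[0])
    else:
        for i in range(n):
            draws = rng.random(n) < spec.edge_probability
            draws[i] = False
            pairs.extend((order[i], order[j]) for j in np.nonzero(draws)[0])

    # assign planted truth along the hidden order
    fwd_parents: dict[str, list[str]] = {g: [] for g in order}
    for u, v in pairs:
        if pos[u] < pos[v]:
            fwd_parents[v].append(u)
    truth: dict[str, int] = {}
    signs: dict[tuple[str, str], int] = {}
    for v in order:
        parents = fwd_parents[v]
        if v == ROOT_NAME:
            truth[v] = DOWN
        elif not parents:
            truth[v] = UP if rng.random() < 0.5 else DOWN
        else:
            setter = ROOT_NAME if ROOT_NAME in parents else min(parents, key=lambda g: pos[g])
            if setter == ROOT_NAME:
                sign = DOWN  # the microRNA represses every direct target
            else:
                sign = DOWN if rng.random() < spec.repression_fraction else UP
            truth[v] = sign * truth[setter]
            signs[(setter, v)] = sign
    for u, v in pairs:  # every remaining sign is forced by consistency
        if (u, v) not in signs:
            signs[(u, v)] = truth[u] * truth[v]

    directness = rng.random(len(pairs)) < 0.5
    edges = [
        RegEdge(u, v, signs[(u, v)], "direct" if d else "indirect", "synthetic")
        for (u, v), d in zip(pairs, directness)
    ]

    n_anchor = int(round(spec.anchor_fraction * n))
    anchor_genes = sorted(str(g) for g in rng.choice(order, size=n_anchor, replace=False)) if n_anchor else []
    n_qrt = int(round(spec.qrt_fraction * n_anchor))
    tier_pool = [Tier.QRT_CONFIRMED] * n_qrt + [Tier.ARRAY_REPORTED] * (n_anchor - n_qrt)
    tiers = [tier_pool[i] for i in rng.permutation(n_anchor)] if n_anchor else []
    flips = rng.random(n_anchor) < spec.anchor_flip_probability
    anchors = [
        NodeState(g, -truth[g] if flip else truth[g], tier)
        for g, tier, flip in zip(anchor_genes, tiers, flips)
    ]
    return edges, truth, anchors


@dataclass(frozen=True)
class SynthUtrSpec:
    """Parameters of the planted-heptamer ranked-UTR generator.

    The leading block is the first ``n_leading`` genes of the ranking (the
    most upregulated); the planted word is written into the first
    ceil(planted_fraction * n_leading) of them at a uniform position.
    """

    n_genes: int = 500
    utr_length: int = 500
    planted_word: str = "GTGCCAA"
    planted_fraction: float = 0.8
    n_leading: int | None = None
    background_gc: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError(f"n_genes must be >= 1, got {self.n_genes}")
        if self.utr_length < 7:
            raise ValueError(f"utr_length must be >= 7, got {self.utr_length}")
        if len(self.planted_word) != 7 or any(c not in "ACGT" for c in self.planted_word):
            raise ValueError(f"planted_word must be a DNA 7-mer, got {self.planted_word!r}")
        _check_fraction("planted_fraction", self.planted_fraction)
        _check_fraction("background_gc", self.background_gc)
        if self.n_leading is None:
            object.__setattr__(self, "n_leading", max(1, self.n_genes // 5))
        if not 1 <= self.n_leading <= self.n_genes:
            raise ValueError(f"n_leading must be in [1, n_genes], got {self.n_leading}")


def generate_ranked_utrs(spec: SynthUtrSpec):
    """Ranked UTR set with the planted word in the leading genes.

    Returns a :class:`~regsign.seedscan.RankedUtrSet`; rank 1 is the most
    upregulated gene.  Background bases are i.i.d. at ``background_gc``.
    """
    from .seedscan import RankedUtrSet

    rng = np.random.default_rng(spec.seed)
    gc = spec.background_gc
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    bases = np.array(list("ACGT"))
    width = max(4, len(str(spec.n_genes)))
    genes = [f"GENE{i:0{width}d}" for i in range(1, spec.n_genes + 1)]
    n_planted = math.ceil(spec.planted_fraction * spec.n_leading)
    seqs: dict[str, str] = {}
    for i, g in enumerate(genes):
        seq = rng.choice(bases, size=spec.utr_length, p=probs)
        if i < n_planted:
            start = int(rng.integers(0, spec.utr_length - 6))
            seq[start : start + 7] = list(spec.planted_word)
        seqs[g] = "".join(seq)
    return RankedUtrSet(genes, seqs)


@dataclass(frozen=True)
class SynthQpcrSpec:
    """Parameters of the littermate-pair Ct table generator.

    ``genes`` maps gene ids to true mutant/wildtype expression ratios.
    Reference- and QC-gene Cts are generated noise-free so the number of
    QC-violating pairs is exactly round(qc_violation_fraction * n_pairs);
    Gaussian cycle noise applies to target-gene Cts.
    """

    n_pairs: int = 5
    genes: tuple = (("Fos", 0.67),)
    ct_noise_sd: float = 0.15
    qc_violation_fraction: float = 0.0
    seed: int = 0

    baseline_ct: float = 25.0
    reference_ct: float = 20.0
    qc_ct: float = 22.0
    violation_ratio: float = 1.5  # QC ratio given to violating pairs (>30% off)

    def __post_init__(self) -> None:
        if self.n_pairs < 3:
            raise ValueError(f"n_pairs must be >= 3, got {self.n_pairs}")
        gene_items = tuple((g, float(r)) for g, r in dict(self.genes).items())
        object.__setattr__(self, "genes", gene_items)
        if any(r <= 0 for _, r in gene_items):
            raise ValueError("all true ratios must be > 0")
        if self.ct_noise_sd < 0:
            raise ValueError(f"ct_noise_sd must be >= 0, got {self.ct_noise_sd}")
        _check_fraction("qc_violation_fraction", self.qc_violation_fraction)


def generate_qpcr_table(spec: SynthQpcrSpec) -> pd.DataFrame:
    """Long-format Ct table (pair_id, genotype, gene, ct).

    Per pair and target gene: Ct_wt = baseline + noise and
    Ct_hom = baseline - log2(true ratio) + noise, so the expected 2^-ddCt
    equals the true ratio as the noise vanishes.
    """
    rng = np.random.default_rng(spec.seed)
    pair_ids = [f"P{i:02d}" for i in range(1, spec.n_pairs + 1)]
    n_viol = int(round(spec.qc_violation_fraction * spec.n_pairs))
    violators = set(rng.choice(pair_ids, size=n_viol, replace=False)) if n_viol else set()
    rows = []
    for pid in pair_ids:
        rows.append((pid, "wt", REFERENCE_GENE, spec.reference_ct))
        rows.append((pid, "hom", REFERENCE_GENE, spec.reference_ct))
        rows.append((pid, "wt", QC_GENE, spec.qc_ct))
        qc_hom = spec.qc_ct - (math.log2(spec.violation_ratio) if pid in violators else 0.0)
        rows.append((pid, "hom", QC_GENE, qc_hom))
        for j, (gene, ratio) in enumerate(spec.genes):
            base = spec.baseline_ct + j  # stagger baselines across genes
            noise_wt, noise_hom = rng.normal(0.0, spec.ct_noise_sd, size=2) if spec.ct_noise_sd else (0.0, 0.0)
            rows.append((pid, "wt", gene, base + noise_wt))
            rows.append((pid, "hom", gene, base - math.log2(ratio) + noise_hom))
    return pd.DataFrame(rows, columns=["pair_id", "genotype", "gene", "ct"])
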