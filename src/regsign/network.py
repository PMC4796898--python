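"""Sign-consistency inference on a signed, directed regulatory network.

The model: every curated interaction ``u -> v`` carries a sign *s* (+1
activation, -1 repression).  An edge is *consistent* with a pair of node
states when ``state(v) = s * state(u)`` — activation preserves the direction
of misregulation, repression inverts it.  Some nodes are *anchored*: their
up/down state has been observed (qRTPCR-confirmed or microarray-reported)
and is held fixed.  For every other node the algorithm scores the two
hypotheses (up, down) by summing evidence weights of neighbours joined by a
consistent edge — known evidence counts 2 points, predicted evidence 1 —
and assigns the winning state, ties staying undetermined.  Edges that end
up inconsistent between two determined nodes are pruned.

Scoring counts both upstream (incoming) and downstream (outgoing) links:
a node's state must explain the misregulation of its targets *and* be
explicable by its regulators.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from .types import DOWN, UNDETERMINED, UP, NodeState, PredictionScore, RegEdge, Tier

logger = logging.getLogger(__name__)


def edge_consistent(source_state: int, sign: int, target_state: int) -> bool:
    """True iff ``target_state == sign * source_state``.

    States must be determined (+1 or -1); callers filter undetermined
    endpoints before asking.
    """
    for name, s in (("source_state", source_state), ("target_state", target_state)):
        if s not in (UP, DOWN):
            raise ValueError(f"{name} must be +1 or -1, got {s!r}")
    if sign not in (UP, DOWN):
        raise ValueError(f"sign must be +1 or -1, got {sign!r}")
    return target_state == sign * source_state


class RegulatoryNetwork:
    """Node states plus a multiset of signed directed edges.

    At most one edge per (source, target, sign) triple; a pair connected by
    both an activating and a repressing edge (a literature conflict) is kept
    and flagged rather than silently merged.
    """

    def __init__(
        self,
        edges: list[RegEdge],
        anchors: list[NodeState] | None = None,
        root: str | None = None,
    ) -> None:
        self.edges: list[RegEdge] = []
        seen: set[tuple[str, str, int]] = set()
        pairs: set[tuple[str, str]] = set()
        self.conflicting_pairs: set[tuple[str, str]] = set()
        for e in edges:
            key = (e.source, e.target, e.sign)
            if key in seen:
                logger.warning("duplicate edge %s-%s sign %+d dropped", *key)
                continue
            seen.add(key)
            if (e.source, e.target) in pairs:
                self.conflicting_pairs.add((e.source, e.target))
                logger.warning(
                    "conflicting signs between %s and %s; both edges retained", e.source, e.target
                )
            pairs.add((e.source, e.target))
            self.edges.append(e)

        self.states: dict[str, NodeState] = {}
        for e in self.edges:
            for g in (e.source, e.target):
                self.states.setdefault(g, NodeState(g, UNDETERMINED, Tier.UNANCHORED))
        for a in anchors or []:
            self.states[a.gene] = a
        self.root = root
        if root is not None and root not in self.states:
            raise ValueError(f"root node {root!r} has no edges in the network")

        self._out: dict[str, list[RegEdge]] = {g: [] for g in self.states}
        self._in: dict[str, list[RegEdge]] = {g: [] for g in self.states}
        for e in self.edges:
            self._out[e.source].append(e)
            self._in[e.target].append(e)

    # -- basic accessors -------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return sorted(self.states)

    def out_edges(self, gene: str) -> list[RegEdge]:
        return self._out[gene]

    def in_edges(self, gene: str) -> list[RegEdge]:
        return self._in[gene]

    def anchored_genes(self) -> list[str]:
        return sorted(g for g, s in self.states.items() if s.tier.anchored)


def _score_one(
    net: RegulatoryNetwork,
    node: str,
    hypothesis: int,
    states: dict[str, NodeState],
    known_only: bool = False,
) -> tuple[int, list[tuple[RegEdge, int]]]:
    """Evidence points for ``node`` holding ``hypothesis`` under ``states``.

    known_only restricts contributions to anchored neighbours (the first
    pass of the weighting algorithm: known misregulation before predicted).
    """
    score = 0
    contribs: list[tuple[RegEdge, int]] = []
    for e in net.out_edges(node):
        other = states[e.target]
        w = other.weight if (other.tier.anchored or not known_only) else 0
        if w and edge_consistent(hypothesis, e.sign, other.state):
            score += w
            contribs.append((e, w))
    for e in net.in_edges(node):
        other = states[e.source]
        w = other.weight if (other.tier.anchored or not known_only) else 0
        if w and edge_consistent(other.state, e.sign, hypothesis):
            score += w
            contribs.append((e, w))
    return score, contribs


def score_hypothesis(net: RegulatoryNetwork, node: str, hypothesis: int) -> int:
    """Score one hypothesis for one node against the network's current states.

    Each incident edge contributes the other endpoint's evidence weight
    (known = 2, predicted = 1, unanchored/undetermined = 0) when the edge is
    consistent with the hypothesised state, else 0.
    """
    if node not in net.states:
        raise KeyError(f"node {node!r} not in network")
    if hypothesis not in (UP, DOWN):
        raise ValueError(f"hypothesis must be +1 or -1, got {hypothesis!r}")
    score, _ = _score_one(net, node, hypothesis, net.states)
    return score


def score_node(net: RegulatoryNetwork, node: str) -> PredictionScore:
    """Both hypothesis scores and the resulting decision for one node."""
    up, cu = _score_one(net, node, UP, net.states)
    down, cd = _score_one(net, node, DOWN, net.states)
    ps = PredictionScore(node, score_up=up, score_down=down)
    ps.contributions = [(e, UP, w) for e, w in cu] + [(e, DOWN, w) for e, w in cd]
    return ps


@dataclass
class ConvergenceReport:
    rounds: int
    converged: bool
    oscillating: list[str] = field(default_factory=list)


def predict_states(
    net: RegulatoryNetwork, max_rounds: int = 25
) -> tuple[dict[str, NodeState], ConvergenceReport]:
    """Assign up/down states to unanchored nodes by iterative weighted voting.

    Round 1 scores every unanchored node against *known* (anchored)
    neighbours only; later rounds re-score synchronously with predicted
    neighbours contributing weight 1.  Ties stay undetermined.  Iteration
    stops at a fixed point or after ``max_rounds``; nodes caught in a state
    cycle are frozen as undetermined so the result is deterministic.
    """
    anchored = {g for g, s in net.states.items() if s.tier.anchored}
    if not anchored:
        raise ValueError("nothing to propagate: network has no anchored nodes")
    free = [g for g in net.genes if g not in anchored]

    current: dict[str, NodeState] = dict(net.states)
    for g in free:  # inference starts from a clean slate for non-anchored nodes
        current[g] = NodeState(g, UNDETERMINED, Tier.UNANCHORED)

    frozen: set[str] = set()
    history: list[tuple] = []
    rounds_used = 0
    converged = False
    for rnd in range(1, max_rounds + 1):
        rounds_used = rnd
        known_only = rnd == 1
        nxt = dict(current)
        for g in free:
            if g in frozen:
                continue
            up, _ = _score_one(net, g, UP, current, known_only=known_only)
            down, _ = _score_one(net, g, DOWN, current, known_only=known_only)
            if up > down:
                nxt[g] = NodeState(g, UP, Tier.PREDICTED)
            elif down > up:
                nxt[g] = NodeState(g, DOWN, Tier.PREDICTED)
            else:
                nxt[g] = NodeState(g, UNDETERMINED, Tier.UNANCHORED)
        snapshot = tuple(nxt[g].state for g in free)
        if history and snapshot == history[-1]:
            converged = True
            current = nxt
            rounds_used = rnd - 1  # the confirming pass changed nothing
            break
        if snapshot in history:
            # state cycle: freeze every node that still flips, keep iterating
            start = history.index(snapshot)
            cyc = history[start:] + [snapshot]
            for i, g in enumerate(free):
                if len({snap[i] for snap in cyc}) > 1:
                    frozen.add(g)
                    nxt[g] = NodeState(g, UNDETERMINED, Tier.UNANCHORED)
        history.append(snapshot)
        current = nxt

    report = ConvergenceReport(rounds=rounds_used, converged=converged, oscillating=sorted(frozen))
    if not converged and max_rounds > 1:
        logger.warning("predict_states stopped at max_rounds=%d without a fixed point", max_rounds)
    return current, report


def prune_inconsistent(
    net: RegulatoryNetwork, assignments: dict[str, NodeState]
) -> tuple[RegulatoryNetwork, list[RegEdge]]:
    """Drop every edge inconsistent between two determined endpoints.

    Edges touching an undetermined node are retained — absence of a call is
    not evidence of inconsistency.  Removed edges are returned with their
    provenance for the audit log.
    """
    keep: list[RegEdge] = []
    removed: list[RegEdge] = []
    for e in net.edges:
        s, t = assignments[e.source].state, assignments[e.target].state
        if s != UNDETERMINED and t != UNDETERMINED and not edge_consistent(s, e.sign, t):
            removed.append(e)
            logger.info("pruned inconsistent edge %s -> %s (%+d) [%s]",
                        e.source, e.target, e.sign, e.provenance)
        else:
            keep.append(e)
    pruned = RegulatoryNetwork(keep, anchors=list(assignments.values()), root=net.root)
    # orphaned nodes (all edges pruned) are kept out; states carry over otherwise
    return pruned, removed


@dataclass
class HubSummary:
    out_degree: dict[str, int]
    histogram: dict[int, int]
    hubs: list[tuple[str, int]]


def hub_summary(net: RegulatoryNetwork, hub_threshold: int = 7) -> HubSummary:
    """Distinct-downstream-target counts, their histogram, and hub nodes.

    A hub is a node with at least ``hub_threshold`` distinct downstream
    target genes (parallel edges to one target count once).
    """
    if not net.states:
        raise ValueError("network is empty")
    deg = {g: len({e.target for e in net.out_edges(g)}) for g in net.genes}
    hist = dict(sorted(Counter(deg.values()).items()))
    hubs = sorted(
        ((g, d) for g, d in deg.items() if d >= hub_threshold),
        key=lambda x: (-x[1], x[0]),
    )
    return HubSummary(out_degree=deg, histogram=hist, hubs=hubs)
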