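"""Sign-consistency scoring, state prediction, pruning and hub summaries."""

import itertools

import networkx as nx
import pytest

from regsign import (
    DOWN,
    UP,
    NodeState,
    RegEdge,
    RegulatoryNetwork,
    Tier,
    edge_consistent,
    hub_summary,
    predict_states,
    prune_inconsistent,
    score_hypothesis,
    score_node,
)
from regsign.synth import SynthNetworkSpec, generate_regnet


@pytest.mark.parametrize(
    "src,sign,tgt,expected",
    [
        (DOWN, -1, UP, True),  # loss of a repressor de-represses the target
        (UP, +1, UP, True),
        (UP, +1, DOWN, False),
        (DOWN, +1, DOWN, True),
        (UP, -1, DOWN, True),
        (DOWN, -1, DOWN, False),
    ],
)
def test_edge_consistency_is_sign_arithmetic(src, sign, tgt, expected):
    assert edge_consistent(src, sign, tgt) is expected


def test_edge_consistency_rejects_undetermined_states():
    with pytest.raises(ValueError):
        edge_consistent(0, 1, 1)


class TestWorkedExample:
    """The packaged Myod1 neighbourhood reproduces the published arithmetic."""

    def test_full_scores_favour_downregulation(self, myod1_net):
        assert score_hypothesis(myod1_net, "Myod1", DOWN) == 4
        assert score_hypothesis(myod1_net, "Myod1", UP) == 3

    def test_downstream_only_scores_tie(self, myod1_net):
        downstream = RegulatoryNetwork(
            [e for e in myod1_net.edges if e.source == "Myod1"],
            [myod1_net.states[g] for g in ("Igll1", "Tgt1")],
        )
        assert score_hypothesis(downstream, "Myod1", UP) == 2
        assert score_hypothesis(downstream, "Myod1", DOWN) == 2

    def test_prediction_decides_down_and_prunes_two_edges(self, myod1_net):
        assignments, report = predict_states(myod1_net)
        assert assignments["Myod1"].state == DOWN
        assert assignments["Myod1"].tier == Tier.PREDICTED
        assert report.converged
        pruned, removed = prune_inconsistent(myod1_net, assignments)
        assert {(e.source, e.target) for e in removed} == {
            ("Myod1", "Igll1"),
            ("Gpc1", "Myod1"),
        }
        assert len(pruned.edges) == len(myod1_net.edges) - 2

    def test_score_node_records_contributing_edges(self, myod1_net):
        ps = score_node(myod1_net, "Myod1")
        assert (ps.score_up, ps.score_down, ps.decision) == (3, 4, DOWN)
        assert len(ps.contributions) == 4


def test_chain_propagates_in_two_rounds():
    edges = [RegEdge("A", "B", +1), RegEdge("B", "C", +1)]
    net = RegulatoryNetwork(edges, [NodeState("A", UP, Tier.QRT_CONFIRMED)])
    assignments, report = predict_states(net)
    assert assignments["B"].state == UP
    assert assignments["C"].state == UP
    assert report.rounds == 2


def test_single_pass_mode_scores_known_only():
    edges = [RegEdge("A", "B", +1), RegEdge("B", "C", +1)]
    net = RegulatoryNetwork(edges, [NodeState("A", UP, Tier.QRT_CONFIRMED)])
    assignments, _ = predict_states(net, max_rounds=1)
    assert assignments["B"].state == UP
    assert assignments["C"].state == 0  # second-hand evidence needs a second round


def test_no_anchors_raises():
    net = RegulatoryNetwork([RegEdge("A", "B", 1)])
    with pytest.raises(ValueError, match="nothing to propagate"):
        predict_states(net)


def test_anchored_states_are_conserved():
    edges, truth, anchors = generate_regnet(SynthNetworkSpec(n_nodes=60, seed=11))
    net = RegulatoryNetwork(edges, anchors)
    assignments, _ = predict_states(net)
    for a in anchors:
        assert assignments[a.gene].state == a.state
        assert assignments[a.gene].tier == a.tier


def test_assignments_invariant_under_edge_order():
    edges, truth, anchors = generate_regnet(SynthNetworkSpec(n_nodes=50, seed=5))
    fwd = RegulatoryNetwork(edges, anchors)
    rev = RegulatoryNetwork(edges[::-1], anchors)
    a1, _ = predict_states(fwd)
    a2, _ = predict_states(rev)
    assert {g: s.state for g, s in a1.items()} == {g: s.state for g, s in a2.items()}
    p1 = prune_inconsistent(fwd, a1)[1]
    p2 = prune_inconsistent(rev, a2)[1]
    assert sorted((e.source, e.target) for e in p1) == sorted((e.source, e.target) for e in p2)


def test_conflicting_parallel_edges_are_kept_and_flagged():
    net = RegulatoryNetwork([RegEdge("A", "B", +1), RegEdge("A", "B", -1)])
    assert len(net.edges) == 2
    assert ("A", "B") in net.conflicting_pairs


def _anchor_reachable(net):
    g = nx.Graph()
    g.add_nodes_from(net.genes)
    g.add_edges_from((e.source, e.target) for e in net.edges)
    anchored = set(net.anchored_genes())
    return set().union(*(c for c in nx.connected_components(g) if c & anchored))


def test_noise_free_recovery_is_exact_on_reachable_nodes():
    edges, truth, anchors = generate_regnet(SynthNetworkSpec(n_nodes=100, seed=2))
    net = RegulatoryNetwork(edges, anchors)
    assignments, _ = predict_states(net)
    for gene in _anchor_reachable(net):
        assert assignments[gene].state == truth[gene]


def _joint_objective(net, assignment):
    """Total consistency weight of a complete assignment (anchored=2, free=1)."""
    anchored = set(net.anchored_genes())
    total = 0
    for e in net.edges:
        if edge_consistent(assignment[e.source], e.sign, assignment[e.target]):
            total += (2 if e.source in anchored else 1) + (2 if e.target in anchored else 1)
    return total


@pytest.mark.parametrize("seed", range(6))
def test_iterative_decision_matches_exhaustive_optimum(seed):
    """On small consistent acyclic networks the unique joint optimum is the
    planted truth, and the iterative pass agrees node for node."""
    edges, truth, anchors = generate_regnet(
        SynthNetworkSpec(n_nodes=10, edge_probability=0.2, anchor_fraction=0.4, seed=seed)
    )
    net = RegulatoryNetwork(edges, anchors)
    free = [g for g in _anchor_reachable(net) if g not in set(net.anchored_genes())]
    if len(free) > 12:
        pytest.skip("joint enumeration too large")
    base = {a.gene: a.state for a in anchors}
    best, argmax = None, []
    for combo in itertools.product((UP, DOWN), repeat=len(free)):
        full = dict(base, **dict(zip(free, combo)))
        for g in net.genes:
            full.setdefault(g, truth[g])
        score = _joint_objective(net, full)
        if best is None or score > best:
            best, argmax = score, [combo]
        elif score == best:
            argmax.append(combo)
    if len(argmax) != 1:
        pytest.skip("exhaustive optimum not unique")
    assignments, _ = predict_states(net)
    assert dict(zip(free, argmax[0])) == {g: assignments[g].state for g in free}


def test_pruning_is_sound_after_noisy_inference():
    edges, truth, anchors = generate_regnet(
        SynthNetworkSpec(n_nodes=120, anchor_flip_probability=0.15, seed=9)
    )
    net = RegulatoryNetwork(edges, anchors)
    assignments, _ = predict_states(net)
    pruned, removed = prune_inconsistent(net, assignments)
    for e in pruned.edges:
        s, t = assignments[e.source].state, assignments[e.target].state
        if s != 0 and t != 0:
            assert edge_consistent(s, e.sign, t)


def test_fully_consistent_network_prunes_nothing():
    edges, truth, anchors = generate_regnet(SynthNetworkSpec(n_nodes=80, seed=4))
    net = RegulatoryNetwork(edges, anchors)
    assignments, _ = predict_states(net)
    assert prune_inconsistent(net, assignments)[1] == []


class TestHubSummary:
    def test_star(self):
        edges = [RegEdge("hub", f"leaf{i}", 1) for i in range(5)]
        summary = hub_summary(RegulatoryNetwork(edges), hub_threshold=5)
        assert summary.out_degree["hub"] == 5
        assert summary.out_degree["leaf0"] == 0
        assert summary.histogram == {0: 5, 5: 1}
        assert summary.hubs == [("hub", 5)]

    def test_microrna_root_has_31_downstream_targets(self, target_evidence):
        from regsign.genelists import compile_direct_targets

        genes, _ = compile_direct_targets(target_evidence)
        edges = [RegEdge("Mir96", g, -1) for g in sorted(genes)]
        summary = hub_summary(RegulatoryNetwork(edges), hub_threshold=7)
        assert summary.out_degree["Mir96"] == 31
        assert summary.hubs[0] == ("Mir96", 31)

    def test_parallel_edges_count_one_target(self):
        edges = [RegEdge("A", "B", +1), RegEdge("A", "B", -1)]
        assert hub_summary(RegulatoryNetwork(edges)).out_degree["A"] == 1
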