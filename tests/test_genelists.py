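"""Gene-list compilation rules and hypergeometric over-representation."""

import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regsign.genelists import (
    collapse_probes,
    compile_direct_targets,
    compile_misregulated,
    gsea_input,
    ora_hypergeometric,
)
from regsign.types import ExpressionRecord, TargetEvidence


def _rec(gene, source="array_P4", fc=1.5, p_raw=0.01, p_adj=0.05, probe=None):
    return ExpressionRecord(gene, source, fc, p_raw, p_adj, probe)


class TestCompileMisregulated:
    def test_array_rule_admits_sub_point_one(self):
        # the borderline array case: adjusted p 0.0522 passes the 0.1 gate
        table = compile_misregulated([_rec("Dynlrb2", "array_P4", 2.1, 0.001, 0.0522)])
        assert list(table["gene"]) == ["Dynlrb2"]
        assert table["source_used"].iloc[0] == "array_P4"

    def test_both_thresholds_failing_excludes(self):
        recs = [
            _rec("g", "array_P4", 1.5, 0.1, 0.2),
            _rec("g", "qrtpcr", 1.5, 0.1, 0.2),
        ]
        assert compile_misregulated(recs).empty

    def test_qrt_between_alphas_is_not_admitted_by_array_gate(self):
        # adjusted p 0.07 passes the array gate but not the qRTPCR gate
        assert compile_misregulated([_rec("g", "qrtpcr", 1.5, 0.01, 0.07)]).empty

    def test_empty_input(self):
        assert compile_misregulated([]).empty

    def test_significant_qrt_value_preferred_over_array(self):
        recs = [
            _rec("g", "array_P4", 3.0, 0.001, 0.01),
            _rec("g", "qrtpcr", 2.0, 0.002, 0.02),
        ]
        table = compile_misregulated(recs)
        assert table["fold_change"].iloc[0] == 2.0
        assert table["source_used"].iloc[0] == "qrtpcr"

    def test_array_fallback_when_qrt_not_significant(self):
        recs = [
            _rec("g", "array_P4", 3.0, 0.001, 0.01),
            _rec("g", "qrtpcr", 2.0, 0.5, 0.8),
        ]
        table = compile_misregulated(recs)
        assert table["fold_change"].iloc[0] == 3.0

    def test_p4_preferred_over_p0(self):
        recs = [
            _rec("g", "array_P0", 2.0, 0.001, 0.01),
            _rec("g", "array_P4", 3.0, 0.002, 0.02),
        ]
        assert compile_misregulated(recs)["source_used"].iloc[0] == "array_P4"

    def test_sign_conflict_is_kept_and_flagged(self):
        recs = [
            _rec("g", "array_P4", 2.0, 0.001, 0.01),
            _rec("g", "qrtpcr", -1.5, 0.002, 0.02),
        ]
        table = compile_misregulated(recs)
        assert len(table) == 1 and bool(table["sign_conflict"].iloc[0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        padj=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=10),
        bump=st.floats(0, 0.5),
    )
    def test_monotone_in_alpha(self, padj, bump):
        recs = [_rec(f"g{i}", "array_P4", 1.5, 0.01, p) for i, p in enumerate(padj)]
        low = set(compile_misregulated(recs, array_alpha=0.1)["gene"])
        high = set(compile_misregulated(recs, array_alpha=min(1.0, 0.1 + bump))["gene"])
        assert low <= high


class TestDirectTargets:
    def test_packaged_evidence_yields_31_unique_genes(self, target_evidence):
        genes, table = compile_direct_targets(target_evidence)
        assert len(genes) == 31
        assert len(table) == 31

    def test_category_counts(self, target_evidence):
        by_cat = {}
        for ev in target_evidence:
            by_cat.setdefault(ev.category, set()).add(ev.gene)
        assert len(by_cat["literature_confirmed"]) == 19
        assert len(by_cat["luciferase_confirmed"]) == 3
        assert len(by_cat["upregulated_with_seed_match"]) == 7
        assert by_cat["predicted_and_expressed"] == {"Zic2", "Osbpl2"}

    def test_duplicate_gene_counted_once_and_order_invariant(self):
        ev = [
            TargetEvidence("A", "literature_confirmed"),
            TargetEvidence("A", "luciferase_confirmed"),
            TargetEvidence("B", "predicted_and_expressed"),
        ]
        genes, table = compile_direct_targets(ev)
        assert genes == {"A", "B"}
        genes_rev, _ = compile_direct_targets(ev[::-1])
        assert genes_rev == genes

    def test_empty_evidence(self):
        genes, table = compile_direct_targets([])
        assert genes == set() and table.empty

    def test_unknown_category_raises(self):
        with pytest.raises(ValueError, match="category"):
            TargetEvidence("A", "wishful_thinking")


class TestCollapseProbes:
    def test_lowest_p_probe_survives(self):
        recs = [
            _rec("g", fc=1.5, p_raw=0.01, probe="p1"),
            _rec("g", fc=3.0, p_raw=0.2, probe="p2"),
        ]
        (kept,) = collapse_probes(recs)
        assert (kept.p_raw, kept.fold_change) == (0.01, 1.5)

    def test_tie_keeps_larger_fold_change(self):
        recs = [
            _rec("g", fc=1.5, p_raw=0.01, probe="p1"),
            _rec("g", fc=-3.0, p_raw=0.01, probe="p2"),
        ]
        assert collapse_probes(recs)[0].fold_change == -3.0

    def test_one_record_per_gene(self):
        recs = [_rec(f"g{i}", probe=f"p{i}{j}", p_raw=0.01 * (j + 1)) for i in range(3) for j in range(2)]
        assert len(collapse_probes(recs)) == 3


class TestGseaInput:
    def test_ten_percent_threshold(self):
        recs = [_rec("small", fc=1.05), _rec("down", fc=-1.12), _rec("up", fc=2.0)]
        table = gsea_input(recs)
        assert list(table["gene"]) == ["up", "down"]  # sorted most-up first

    def test_all_pass_sorted(self):
        recs = [_rec(f"g{i}", fc=1.1 + 0.1 * i) for i in range(5)]
        table = gsea_input(recs)
        assert len(table) == 5
        assert list(table["fold_change"]) == sorted(table["fold_change"], reverse=True)

    def test_known_pass_count(self):
        recs = [_rec(f"g{i}", fc=(1.2 if i % 3 == 0 else 1.05)) for i in range(12)]
        assert len(gsea_input(recs)) == 4


def _ora_bruteforce(query, members, universe):
    """Enumerate every |query|-subset of the universe; exact tail fraction."""
    obs = len(query & members)
    hits = total = 0
    for combo in itertools.combinations(sorted(universe), len(query)):
        total += 1
        if len(set(combo) & members) >= obs:
            hits += 1
    return hits / total


class TestOra:
    def test_worked_example(self):
        universe = {f"u{i}" for i in range(20)}
        members = set(sorted(universe)[:5])
        query = set(sorted(universe)[1:6])  # overlap 4
        res = ora_hypergeometric(query, {"s": members}, universe)
        assert res["overlap"].iloc[0] == 4
        assert res["p_raw"].iloc[0] == pytest.approx(76 / 15504)

    def test_saturated_query(self):
        universe = {f"u{i}" for i in range(8)}
        res = ora_hypergeometric(universe, {"s": set(sorted(universe)[:3])}, universe)
        assert res["p_raw"].iloc[0] == pytest.approx(1.0)

    def test_zero_overlap_with_tiny_set(self):
        universe = {f"u{i}" for i in range(30)}
        res = ora_hypergeometric(
            {"u0", "u1"}, {"s": {"u28", "u29"}}, universe
        )
        assert res["p_raw"].iloc[0] == pytest.approx(1.0, abs=0.2)

    def test_empty_universe_raises(self):
        with pytest.raises(ValueError):
            ora_hypergeometric(set(), {"s": {"a"}}, set())

    @pytest.mark.parametrize("n_universe,n_set,n_query", [(10, 4, 5), (12, 6, 4), (15, 5, 7)])
    def test_matches_exhaustive_enumeration(self, n_universe, n_set, n_query):
        universe = {f"u{i:02d}" for i in range(n_universe)}
        ordered = sorted(universe)
        members = set(ordered[:n_set])
        query = set(ordered[n_universe - n_query:])
        res = ora_hypergeometric(query, {"s": members}, universe)
        assert res["p_raw"].iloc[0] == pytest.approx(_ora_bruteforce(query, members, universe))
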