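"""Convergence detection: classification rules, expected counts against
brute force, focal summaries and the convergent-site tree."""

import numpy as np
import pytest
from scipy import stats

from selconv.aamodels import AA_ORDER
from selconv.asr import marginal_asr
from selconv.convergence import (ConvergencePair, SubstitutionEvent,
                                 clade_membership, convergence_tree,
                                 convergent_site_union,
                                 detect_pairwise_convergence, exchange_pairs,
                                 expected_convergence_counts,
                                 extract_substitutions, focal_branch_summary)
from selconv.io import DomainPartition
from selconv.simulate import SimulationConfig, simulate_protein_evolution
from selconv.synthetic import build_dataset, gpx6_scenario, gpx6_tagged_tree
from selconv.trees import EXCHANGE, PhyloTree

A, S, T = (AA_ORDER.index(x) for x in "AST")


@pytest.fixture(scope="module")
def quartet():
    return PhyloTree.from_newick("((a:0.1,b:0.2)x:0.15,(c:0.3,d:0.25)y:0.1)r;",
                                 is_path=False)


def _ev(branch, site, anc, der):
    return SubstitutionEvent(branch, site, anc, der)


class TestClassification:
    def test_same_anc_same_derived_is_parallel(self, quartet):
        ba, bc = quartet.node_by_name("a"), quartet.node_by_name("c")
        pairs = detect_pairwise_convergence(
            [_ev(ba, 5, A, S), _ev(bc, 5, A, S)], [(ba, bc)], quartet)
        assert pairs[0].parallel_sites == [5]
        assert pairs[0].convergent_sites == []

    def test_different_anc_same_derived_is_convergent(self, quartet):
        ba, bc = quartet.node_by_name("a"), quartet.node_by_name("c")
        pairs = detect_pairwise_convergence(
            [_ev(ba, 5, T, S), _ev(bc, 5, A, S)], [(ba, bc)], quartet)
        assert pairs[0].convergent_sites == [5]
        assert pairs[0].parallel_sites == []

    def test_different_derived_is_neither(self, quartet):
        ba, bc = quartet.node_by_name("a"), quartet.node_by_name("c")
        iw = AA_ORDER.index("W")
        pairs = detect_pairwise_convergence(
            [_ev(ba, 5, A, S), _ev(bc, 5, A, iw)], [(ba, bc)], quartet)
        assert pairs[0].observed == 0

    def test_similar_derived_reported_separately(self, quartet):
        ba, bc = quartet.node_by_name("a"), quartet.node_by_name("c")
        iD, iE = AA_ORDER.index("D"), AA_ORDER.index("E")
        pairs = detect_pairwise_convergence(
            [_ev(ba, 5, A, iD), _ev(bc, 5, A, iE)], [(ba, bc)], quartet)
        assert pairs[0].similar_sites == [5]
        assert pairs[0].observed == 0

    def test_counts_symmetric_in_branch_order(self, quartet):
        ba, bc = quartet.node_by_name("a"), quartet.node_by_name("c")
        events = [_ev(ba, 1, A, S), _ev(bc, 1, T, S), _ev(ba, 2, A, S),
                  _ev(bc, 2, A, S)]
        p1 = detect_pairwise_convergence(events, [(ba, bc)], quartet)[0]
        p2 = detect_pairwise_convergence(events, [(bc, ba)], quartet)[0]
        assert p1.observed == p2.observed
        assert sorted(p1.all_sites) == sorted(p2.all_sites)

    def test_nested_pair_rejected(self, quartet):
        bx, ba = quartet.node_by_name("x"), quartet.node_by_name("a")
        with pytest.raises(ValueError, match="nested"):
            detect_pairwise_convergence([], [(bx, ba)], quartet)

    def test_union_shrinks_with_event_subset(self, quartet):
        ba, bc = quartet.node_by_name("a"), quartet.node_by_name("c")
        events = [_ev(ba, 1, A, S), _ev(bc, 1, T, S), _ev(ba, 2, A, S),
                  _ev(bc, 2, A, S)]
        full = convergent_site_union(
            detect_pairwise_convergence(events, [(ba, bc)], quartet))
        sub = convergent_site_union(
            detect_pairwise_convergence(events[:2], [(ba, bc)], quartet))
        assert set(sub) <= set(full)


class TestSubstitutionExtraction:
    def test_identical_endpoints_give_no_events(self, quartet, jtt_model):
        rec = marginal_asr({t: "AAAA" for t in "abcd"}, quartet, jtt_model)
        assert extract_substitutions(rec, quartet, quartet.branches) == []

    def test_excluded_sites_never_emit(self, quartet, jtt_model):
        seqs = {"a": "SA", "b": "SA", "c": "AA", "d": "AA"}
        rec = marginal_asr(seqs, quartet, jtt_model)
        ev = extract_substitutions(rec, quartet, quartet.branches,
                                   exclude_sites=[0])
        assert all(e.site != 0 for e in ev)

    def test_simulated_branch_count_matches_truth(self, jtt_model):
        tree = PhyloTree.from_newick("(a:0.35,b:0.01)r;", is_path=False)
        cfg = SimulationConfig(tree, 400, jtt_model, None, 1, seed=8)
        rep = simulate_protein_evolution(cfg)[0]
        ba = tree.node_by_name("a")
        true_changes = int(np.sum(rep.node_states[tree.root]
                                  != rep.node_states[ba]))
        expect = 400 * (1 - np.sum(jtt_model.pi * np.diag(jtt_model.P(0.35))))
        sd = np.sqrt(expect)
        assert abs(true_changes - expect) < 4 * sd


class TestExpectedCounts:
    def test_zero_branch_lengths_give_zero_expectation(self, quartet,
                                                       jtt_model):
        t0 = quartet.with_lengths(np.zeros(quartet.n_nodes))
        rec = marginal_asr({"a": "K", "b": "K", "c": "K", "d": "K"}, t0,
                           jtt_model)
        ba, bc = t0.node_by_name("a"), t0.node_by_name("c")
        cp = ConvergencePair((ba, bc), [], [], [])
        cp = expected_convergence_counts(rec, t0, cp, jtt_model)
        assert cp.expected == pytest.approx(0.0, abs=1e-12)
        assert cp.poisson_p == 1.0

    def test_single_site_matches_brute_force(self, quartet, jtt_model):
        rec = marginal_asr({"a": "K", "b": "R", "c": "E", "d": "D"},
                           quartet, jtt_model)
        ba, bc = quartet.node_by_name("a"), quartet.node_by_name("c")
        cp = expected_convergence_counts(
            rec, quartet, ConvergencePair((ba, bc), [], [], []), jtt_model)
        px = rec.node_posterior(quartet.node_by_name("x"))[0]
        py = rec.node_posterior(quartet.node_by_name("y"))[0]
        P1 = jtt_model.P(float(quartet.lengths[ba]))
        P2 = jtt_model.P(float(quartet.lengths[bc]))
        etot = epar = 0.0
        for a in range(20):
            for b in range(20):
                for x in range(20):
                    if x == a or x == b:
                        continue
                    v = px[a] * py[b] * P1[a, x] * P2[b, x]
                    etot += v
                    if a == b:
                        epar += v
        assert cp.expected == pytest.approx(etot, abs=1e-12)
        assert cp.expected_parallel == pytest.approx(epar, abs=1e-12)
        assert cp.expected_convergent == pytest.approx(etot - epar, abs=1e-12)

    def test_poisson_tail_uses_upper_tail_at_observed(self, quartet,
                                                      jtt_model):
        rec = marginal_asr({"a": "K", "b": "R", "c": "E", "d": "D"},
                           quartet, jtt_model)
        ba, bc = quartet.node_by_name("a"), quartet.node_by_name("c")
        cp = ConvergencePair((ba, bc), [1, 2], [3], [])   # observed = 3
        cp = expected_convergence_counts(rec, quartet, cp, jtt_model)
        assert cp.poisson_p == pytest.approx(
            stats.poisson.sf(2, cp.expected))
        # the worked tail value: P(X >= 3 | lambda = 0.5) ~ 0.0144
        assert float(stats.poisson.sf(2, 0.5)) == pytest.approx(0.0144,
                                                                abs=2e-4)

    def test_null_simulations_fall_inside_poisson_band(self, jtt_model):
        """On data simulated without injected convergence the observed
        pair counts should sit within the central 95% of the module's own
        Poisson expectation for ~all pairs."""
        tree = gpx6_tagged_tree()
        aa_tree = tree.with_lengths(tree.lengths * 0.4)
        inside = total = 0
        for seed in range(6):
            cfg = SimulationConfig(aa_tree, 200, jtt_model, None, 1,
                                   seed=100 + seed)
            rep = simulate_protein_evolution(cfg)[0]
            rec = marginal_asr(rep.leaf_seqs, aa_tree, jtt_model)
            pairs = exchange_pairs(aa_tree)
            ev = extract_substitutions(rec, aa_tree, aa_tree.tagged(EXCHANGE))
            cps = detect_pairwise_convergence(ev, pairs, aa_tree)
            for cp in cps:
                cp = expected_convergence_counts(rec, aa_tree, cp, jtt_model)
                lo = stats.poisson.ppf(0.025, cp.expected)
                hi = stats.poisson.ppf(0.975, cp.expected)
                inside += lo <= cp.observed <= hi
                total += 1
        assert inside / total >= 0.9


class TestFocalSummary:
    def test_percentages_match_exact_arithmetic(self):
        dom = DomainPartition([("N", 0, 39), ("G", 39, 152), ("C", 152, 217)])
        conv = list(range(39, 51)) + list(range(152, 159)) + [0, 1, 2]
        events = [_ev(7, s, A, S) for s in conv]
        rep = focal_branch_summary(events, conv, 7, dom)
        assert rep.domain_counts == {"N": 3, "G": 12, "C": 7}
        assert rep.domain_percent["G"] == pytest.approx(100 * 12 / 22)
        assert rep.domain_percent["C"] == pytest.approx(100 * 7 / 22)
        assert rep.domain_percent["N"] == pytest.approx(100 * 3 / 22)
        assert rep.total == 22

    def test_no_events_gives_empty_report(self):
        rep = focal_branch_summary([], [], 3, None)
        assert rep.focal_sites == []
        assert rep.total == 0

    def test_selection_percentile_flags(self):
        post = np.linspace(0, 1, 100)
        rep = focal_branch_summary([], [], 3, None,
                                   selection_posteriors=post, percentile=90,
                                   percentile_region=(0, 100))
        assert len(rep.selected_sites) == 10
        assert min(rep.selected_sites) == 90


class TestConvergenceTree:
    def test_clean_data_recovers_species_topology(self, jtt_model):
        import dendropy

        tree = gpx6_tagged_tree()
        aa_tree = tree.with_lengths(tree.lengths * 1.0)
        cfg = SimulationConfig(aa_tree, 800, jtt_model, None, 1, seed=17)
        rep = simulate_protein_evolution(cfg)[0]
        built = convergence_tree(rep.leaf_seqs)
        tns = dendropy.TaxonNamespace()
        d1 = dendropy.Tree.get(data=aa_tree.to_newick(), schema="newick",
                               taxon_namespace=tns)
        d2 = dendropy.Tree.get(data=built.to_newick(), schema="newick",
                               taxon_namespace=tns)
        d1.encode_bipartitions()
        d2.encode_bipartitions()
        rf = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
        assert rf == 0

    def test_injected_convergence_pulls_cys_taxa_together(self, gpx6_dataset):
        aln, tree, truth = gpx6_dataset
        prot = aln.protein()
        built = convergence_tree(prot, sites=truth.convergent_sites)
        cys = set()
        for b in tree.tagged(EXCHANGE):
            cys |= tree.leaf_set_below(b)
        assert clade_membership(built, cys) <= 2
        assert clade_membership(tree, cys) == 5  # species arrangement

    def test_output_tree_is_midpoint_rooted(self, gpx6_dataset):
        aln, tree, truth = gpx6_dataset
        built = convergence_tree(aln.protein(), sites=truth.convergent_sites)

        def depth(node):
            best = 0.0
            for c in built.children[node]:
                best = max(best, built.lengths[c] + depth(c))
            return best

        kids = built.children[built.root]
        depths = [built.lengths[c] + depth(c) for c in kids]
        assert max(depths) == pytest.approx(sorted(depths)[-2], abs=1e-6)

    def test_too_few_taxa_rejected(self, jtt_model):
        with pytest.raises(ValueError, match="4 taxa"):
            convergence_tree({"a": "AA", "b": "AA", "c": "AA"})
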