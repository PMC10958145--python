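"""GY94 codon model: rate matrix structure, transition probabilities,
pruning likelihood against enumeration, and fits/LRTs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.linalg import expm

from selconv.codon import (GENETIC_CODE, CodonModelParams, ModelFit,
                           ReversibleEigen, build_gy94_matrix,
                           f3x4_frequencies, fit_branch_model, lrt,
                           pruning_loglik, transition_matrix)
from selconv.io import CodonAlignment
from selconv.synthetic import ScenarioConfig, simulate_codon_dataset
from selconv.trees import EXCHANGE, INHERITED, SEC, PhyloTree

UNIFORM = np.full(61, 1 / 61)


class TestRateMatrix:
    def test_neutral_uniform_matrix_symmetric_single_changes(self):
        Q = build_gy94_matrix(1.0, 1.0, UNIFORM, scale=False)
        off = Q[~np.eye(61, dtype=bool)]
        vals = np.unique(np.round(off[off > 0], 12))
        assert len(vals) == 1          # all single-change rates equal
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        assert np.all(Q[~GENETIC_CODE.single & ~np.eye(61, dtype=bool)] == 0)

    def test_omega_zero_kills_nonsynonymous_rates(self):
        Q = build_gy94_matrix(2.0, 0.0, UNIFORM, scale=False)
        assert np.all(Q[GENETIC_CODE.is_nonsyn] == 0)

    def test_kappa_omega_ratio_of_two_entries(self):
        # TTT->TTC: synonymous transition; TTT->TTA: nonsynonymous transversion
        Q = build_gy94_matrix(2.0, 0.5, UNIFORM, scale=False)
        i = GENETIC_CODE.index["TTT"]
        j = GENETIC_CODE.index["TTC"]
        k = GENETIC_CODE.index["TTA"]
        assert Q[i, j] / Q[i, k] == pytest.approx(2.0 / 0.5)

    def test_unit_expected_rate_after_scaling(self):
        Q = build_gy94_matrix(3.0, 0.2, UNIFORM)
        assert -UNIFORM @ np.diag(Q) == pytest.approx(1.0)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(kappa=st.floats(0.2, 10), omega=st.floats(0.01, 5),
           seed=st.integers(0, 10**6))
    def test_detailed_balance(self, kappa, omega, seed):
        rng = np.random.default_rng(seed)
        pi = rng.dirichlet(np.ones(61))
        Q = build_gy94_matrix(kappa, omega, pi)
        F = pi[:, None] * Q
        assert np.allclose(F, F.T, atol=1e-12)


class TestTransitionMatrix:
    def test_zero_time_is_identity(self):
        Q = build_gy94_matrix(2.0, 0.3, UNIFORM)
        assert np.allclose(transition_matrix(Q, 0.0), np.eye(61), atol=1e-12)

    def test_long_time_reaches_stationarity(self):
        rng = np.random.default_rng(0)
        pi = rng.dirichlet(np.ones(61) * 5)
        Q = build_gy94_matrix(2.0, 0.3, pi)
        P = ReversibleEigen(Q, pi).P(400.0)
        assert np.allclose(P, np.tile(pi, (61, 1)), atol=1e-9)

    def test_eigen_matches_scaling_and_squaring(self):
        rng = np.random.default_rng(1)
        pi = rng.dirichlet(np.ones(61) * 5)
        Q = build_gy94_matrix(1.7, 0.4, pi)
        for t in (0.01, 0.3, 2.0):
            assert np.allclose(ReversibleEigen(Q, pi).P(t), expm(Q * t),
                               atol=1e-10)
            P = transition_matrix(Q, t)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
            assert np.all(P >= 0)

    def test_negative_time_rejected(self):
        Q = build_gy94_matrix(2.0, 0.3, UNIFORM)
        with pytest.raises(ValueError):
            transition_matrix(Q, -0.1)


def _params(tree, kappa, omega, pi, length_map):
    lengths = np.zeros(tree.n_nodes)
    for name, t in length_map.items():
        lengths[tree.node_by_name(name)] = t
    return CodonModelParams(kappa, np.array([omega]),
                            {b: 0 for b in tree.branches}, pi, lengths)


class TestPruningLikelihood:
    def test_single_taxon_single_codon(self):
        tree = PhyloTree.from_newick("(a:0.0)r;", is_path=False)
        aln = CodonAlignment.from_sequences(["a"], ["AAA"])
        pi = np.full(61, 1 / 61)
        ll = pruning_loglik(aln, tree, _params(tree, 2.0, 0.5, pi, {"a": 0.0}))
        assert ll == pytest.approx(np.log(pi[GENETIC_CODE.index["AAA"]]))

    def test_two_taxa_equals_direct_sum(self):
        tree = PhyloTree.from_newick("(a:0.1,b:0.2)r;", is_path=False)
        aln = CodonAlignment.from_sequences(["a", "b"], ["AAATTT", "AAGTTC"])
        pi = np.full(61, 1 / 61)
        params = _params(tree, 2.0, 0.5, pi, {"a": 0.1, "b": 0.2})
        Q = build_gy94_matrix(2.0, 0.5, pi)
        eig = ReversibleEigen(Q, pi)
        Pa, Pb = eig.P(0.1), eig.P(0.2)
        direct = 0.0
        for site in range(2):
            ca = GENETIC_CODE.index[aln.codons[0, site]]
            cb = GENETIC_CODE.index[aln.codons[1, site]]
            direct += np.log(np.sum(pi * Pa[:, ca] * Pb[:, cb]))
        assert pruning_loglik(aln, tree, params) == pytest.approx(direct)

    def test_three_taxa_equals_enumeration_over_internal_states(self):
        tree = PhyloTree.from_newick("((a:0.1,b:0.15)x:0.05,c:0.2)r;",
                                     is_path=False)
        seqs = ["AAATTTGGGCCCATG", "AAGTTCGGACCCATG", "AATTTAGGGCCAATG"]
        aln = CodonAlignment.from_sequences(["a", "b", "c"], seqs)
        rng = np.random.default_rng(2)
        pi = rng.dirichlet(np.ones(61) * 10)
        params = _params(tree, 1.5, 0.8, pi,
                         {"a": 0.1, "b": 0.15, "x": 0.05, "c": 0.2})
        eig = ReversibleEigen(build_gy94_matrix(1.5, 0.8, pi), pi)
        Pa, Pb, Px, Pc = eig.P(0.1), eig.P(0.15), eig.P(0.05), eig.P(0.2)
        direct = 0.0
        for site in range(5):
            ca, cb, cc = (GENETIC_CODE.index[aln.codons[i, site]]
                          for i in range(3))
            # sum over root and internal node states (61 x 61 enumeration)
            inner = Pa[:, ca] * Pb[:, cb]            # given state at x
            site_lik = np.sum(pi[:, None] * Px * inner[None, :]
                              * Pc[:, cc][:, None])
            direct += np.log(site_lik)
        assert pruning_loglik(aln, tree, params) == pytest.approx(direct)

    def test_gap_contributes_all_ones_partial(self):
        tree = PhyloTree.from_newick("(a:0.1,b:0.2)r;", is_path=False)
        aln = CodonAlignment.from_sequences(["a", "b"], ["AAA", "---"])
        pi = np.full(61, 1 / 61)
        params = _params(tree, 2.0, 0.5, pi, {"a": 0.1, "b": 0.2})
        # with b missing, likelihood reduces to the stationary probability
        assert pruning_loglik(aln, tree, params) == pytest.approx(
            np.log(pi[GENETIC_CODE.index["AAA"]]))

    def test_invariant_to_leaf_order_and_rerooting(self):
        pi = np.full(61, 1 / 61)
        seq = {"a": "AAATTT", "b": "AAGTTC", "c": "AATTTA"}
        t1 = PhyloTree.from_newick("((a:0.1,b:0.15)x:0.05,c:0.2)r;",
                                   is_path=False)
        t2 = PhyloTree.from_newick("(c:0.2,(b:0.15,a:0.1)x:0.05)r;",
                                   is_path=False)
        # same unrooted tree, root slid along the x--c branch
        t3 = PhyloTree.from_newick("((a:0.1,b:0.15)x:0.15,c:0.1)r;",
                                   is_path=False)
        lls = []
        for t in (t1, t2, t3):
            aln = CodonAlignment.from_sequences(list(seq), list(seq.values()))
            lmap = {"a": 0.1, "b": 0.15, "c": 0.2 if t is not t3 else 0.1,
                    "x": 0.05 if t is not t3 else 0.15}
            lls.append(pruning_loglik(aln, t, _params(t, 2.0, 0.5, pi, lmap)))
        assert lls[0] == pytest.approx(lls[1])
        assert lls[0] == pytest.approx(lls[2])


class TestFitsAndLRT:
    def test_identical_fits_give_lr_zero_p_one(self, plain_dataset):
        aln, tree, _ = plain_dataset
        sub = aln.drop_columns([aln.catalytic_site])
        f = fit_branch_model(sub, tree, "one-ratio", n_starts=1)
        f_alt = ModelFit(f.params, f.loglik, f.n_free + 2, True, "partition")
        res = lrt(f, f_alt)
        assert res.lr == 0.0
        assert res.p == 1.0

    def test_chi2_reference_value(self):
        null = ModelFit(None, -100.0, 3, True, "one-ratio")
        alt = ModelFit(None, -100.0 + 12.43 / 2, 5, True, "partition")
        res = lrt(null, alt)
        assert res.df == 2
        assert res.p == pytest.approx(stats.chi2.sf(12.43, 2))
        assert res.p == pytest.approx(0.002, abs=3e-4)

    def test_one_ratio_fit_recovers_simulated_omega(self, plain_dataset):
        aln, tree, _ = plain_dataset
        sub = aln.drop_columns([aln.catalytic_site])
        f = fit_branch_model(sub, tree, "one-ratio", n_starts=1)
        assert f.converged
        assert f.params.omegas[0] == pytest.approx(0.2, abs=0.1)
        assert f.params.kappa == pytest.approx(2.5, rel=0.5)

    def test_extra_ratio_never_decreases_loglik(self, plain_dataset):
        aln, tree, _ = plain_dataset
        sub = aln.drop_columns([aln.catalytic_site])
        f0 = fit_branch_model(sub, tree, "one-ratio", n_starts=1)
        f1 = fit_branch_model(sub, tree, "partition", n_starts=1, init=f0)
        assert f1.loglik >= f0.loglik - 1e-6
        assert f1.n_free - f0.n_free == 2

    def test_free_ratio_matches_partition_with_one_branch_per_class(self):
        # 3 taxa: three branches, partition scheme assigns each its own class
        nwk = "(a:0.08,b:0.12,c:0.1)r;"
        tree = PhyloTree.from_newick(nwk, is_path=False)
        tree.tags[tree.node_by_name("a")] = SEC
        tree.tags[tree.node_by_name("b")] = EXCHANGE
        tree.tags[tree.node_by_name("c")] = INHERITED
        cfg = ScenarioConfig(tree=tree, omegas={SEC: 0.2, EXCHANGE: 0.6,
                                                INHERITED: 0.3},
                             domain_lengths={"A": 200}, catalytic_site=100,
                             n_focal_changes=0, n_injected=0, seed=4)
        aln, tree, _ = simulate_codon_dataset(cfg)
        sub = aln.drop_columns([100])
        fp = fit_branch_model(sub, tree, "partition", n_starts=1)
        ff = fit_branch_model(sub, tree, "free-ratio", n_starts=1, init=fp)
        assert ff.loglik == pytest.approx(fp.loglik, abs=0.02)
        by_name = {tree.names[b]: ff.params.omega_of_branch(b)
                   for b in tree.branches}
        part = fp.omega_by_class_name()
        assert by_name["a"] == pytest.approx(part["SEC"], rel=0.05, abs=0.02)
        assert by_name["b"] == pytest.approx(part["EXCHANGE"], rel=0.05, abs=0.02)


class TestF3x4:
    def test_frequencies_sum_to_one_and_cover_observed(self):
        cfg = ScenarioConfig(tree=None, n_taxa=6, n_exchange=2,
                             domain_lengths={"A": 50}, catalytic_site=10,
                             n_focal_changes=0, n_injected=0, seed=5)
        aln, tree, _ = simulate_codon_dataset(cfg)
        from selconv.codon import encode_codon_states

        states = encode_codon_states(aln.drop_columns([10]))
        pi = f3x4_frequencies(states)
        assert pi.sum() == pytest.approx(1.0)
        observed = np.unique(states[states >= 0])
        assert np.all(pi[observed] > 0)
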