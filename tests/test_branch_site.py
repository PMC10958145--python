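"""Branch-site model A: mixture likelihood, NEB posteriors, enrichment."""

import numpy as np
import pytest
from scipy import stats

from selconv.branchsite import (BranchSiteParams, _class_site_logliks,
                                enrichment_test, fit_branch_site_pair,
                                site_posteriors)
from selconv.codon import (GENETIC_CODE, ReversibleEigen, build_gy94_matrix,
                           f3x4_frequencies, make_engine)
from selconv.io import CodonAlignment
from selconv.synthetic import ScenarioConfig, simulate_codon_dataset
from selconv.trees import EXCHANGE, INHERITED, SEC, PhyloTree


class TestParams:
    def test_class_proportions_follow_model_a(self):
        p = BranchSiteParams((1,), 0.6, 0.2, 0.1, 3.0, 2.0, np.zeros(3))
        rest = 1 - 0.6 - 0.2
        assert p.p2a == pytest.approx(rest * 0.6 / 0.8)
        assert p.p2b == pytest.approx(rest * 0.2 / 0.8)
        assert p.proportions.sum() == pytest.approx(1.0)


class TestSingleSiteOracle:
    def test_class_likelihoods_against_direct_sums(self):
        """Two-taxon, one-codon alignment: each class likelihood is a
        directly computable 61-term sum over root states, with the
        foreground branch carrying that class's foreground omega and all
        classes sharing one time scale."""
        tree = PhyloTree.from_newick("(a:0.2,b:0.3)r;", is_path=False)
        aln = CodonAlignment.from_sequences(["a", "b"], ["AAA", "AGA"])
        engine, states = make_engine(aln, tree)
        pi = f3x4_frequencies(states)
        ba, bb = tree.node_by_name("a"), tree.node_by_name("b")
        lengths = np.zeros(3)
        lengths[ba], lengths[bb] = 0.2, 0.3
        kappa, w0, w2 = 2.0, 0.3, 4.0
        props = np.array([0.6, 0.2, 0.15, 0.05])
        cls = _class_site_logliks(engine, tree, (ba,), kappa, w0, w2,
                                  lengths, pi, props)

        Qs = {w: build_gy94_matrix(kappa, w, pi, scale=False)
              for w in (w0, 1.0, w2)}
        rate = {w: -float(pi @ np.diag(Q)) for w, Q in Qs.items()}
        qf = (props[0] + props[2]) * rate[w0] + (props[1] + props[3]) * rate[1.0]

        def direct(w_fore, w_back):
            Pa = ReversibleEigen(Qs[w_fore] / qf, pi).P(0.2)
            Pb = ReversibleEigen(Qs[w_back] / qf, pi).P(0.3)
            ca, cb = GENETIC_CODE.index["AAA"], GENETIC_CODE.index["AGA"]
            return np.log(np.sum(pi * Pa[:, ca] * Pb[:, cb]))

        assert cls[0, 0] == pytest.approx(direct(w0, w0))
        assert cls[1, 0] == pytest.approx(direct(1.0, 1.0))
        assert cls[2, 0] == pytest.approx(direct(w2, w0))
        assert cls[3, 0] == pytest.approx(direct(w2, 1.0))


def _fit_dataset(omega_fg, seed, n_codons=150, frac=0.1, w0=0.2, kappa=2.5):
    """Two long foreground branches; selected columns evolve under
    omega_fg on the foreground with the matching rate speed-up (all site
    classes share one time scale)."""
    from selconv.codon import build_gy94_matrix as _gy
    from selconv.synthetic import (DEFAULT_POSITION_FREQS,
                                   _pi_from_position_freqs)

    nwk = ("(((a:0.1,b:0.1)ab:0.2,(c:0.1,d:0.1)cd:0.08)abcd:0.06,"
           "((e:0.1,f:0.1)ef:0.2,(g:0.1,h:0.1)gh:0.08)efgh:0.06)root;")
    tree = PhyloTree.from_newick(nwk, is_path=False)
    for b in tree.branches:
        tree.tags[b] = SEC
    for nm in ("ab", "ef"):
        b = tree.node_by_name(nm)
        tree.tags[b] = EXCHANGE
        for d in tree.subtree_nodes(b):
            if d != b:
                tree.tags[d] = INHERITED
    tree.validate_tags()
    if omega_fg is None:
        cfg = ScenarioConfig(tree=tree, omegas={SEC: w0, EXCHANGE: w0,
                                                INHERITED: w0},
                             domain_lengths={"A": n_codons + 1},
                             catalytic_site=0, kappa=kappa,
                             n_focal_changes=0, n_injected=0, seed=seed)
        aln, tree, _ = simulate_codon_dataset(cfg)
        return aln.drop_columns([0]), tree, []
    n_sel = int(n_codons * frac)
    cfg_bg = ScenarioConfig(tree=tree, omegas={SEC: w0, EXCHANGE: w0,
                                               INHERITED: w0},
                            domain_lengths={"A": n_codons - n_sel + 1},
                            catalytic_site=0, kappa=kappa,
                            n_focal_changes=0, n_injected=0, seed=seed)
    aln_bg, tree, _ = simulate_codon_dataset(cfg_bg)
    pi = _pi_from_position_freqs(DEFAULT_POSITION_FREQS)

    def rate(w):
        return -float(pi @ np.diag(_gy(kappa, w, pi, scale=False)))

    tree_sel = tree.copy()
    for nm in ("ab", "ef"):
        tree_sel.lengths[tree_sel.node_by_name(nm)] *= rate(omega_fg) / rate(w0)
    cfg_sel = ScenarioConfig(tree=tree_sel, omegas={SEC: w0,
                                                    EXCHANGE: omega_fg,
                                                    INHERITED: w0},
                             domain_lengths={"A": n_sel + 1},
                             catalytic_site=0, kappa=kappa,
                             n_focal_changes=0, n_injected=0, seed=seed + 1)
    aln_sel, _, _ = simulate_codon_dataset(cfg_sel)
    codons = np.concatenate([aln_bg.codons[:, 1:], aln_sel.codons[:, 1:]],
                            axis=1)
    merged = CodonAlignment(aln_bg.taxa, codons)
    sel_cols = list(range(aln_bg.n_codons - 1, merged.n_codons))
    return merged, tree, sel_cols


class TestBranchSiteFit:
    def test_alternative_never_below_null(self):
        aln, tree, _ = _fit_dataset(None, seed=21)
        alt, null, res = fit_branch_site_pair(aln, tree, ["ab"], n_starts=1,
                                              seed=1)
        assert alt.loglik >= null.loglik - 1e-6
        assert res.lr >= 0.0
        assert 0.0 <= res.p <= 1.0
        assert res.df == 1
        assert alt.n_free - null.n_free == 1

    def test_power_and_localisation_over_replicates(self):
        """Foreground omega2 = 3 at 10% of 300 codons: the LRT should fire
        in at least ~half the replicates and posteriors should be higher at
        the selected sites in nearly all of them."""
        hits = localised = 0
        n_reps = 10
        for rep in range(n_reps):
            aln, tree, sel = _fit_dataset(3.0, seed=200 + 3 * rep,
                                          n_codons=300)
            alt, null, res = fit_branch_site_pair(
                aln, tree, ["ab", "ef"], n_starts=1, seed=rep)
            hits += res.p < 0.05
            post = site_posteriors(aln, tree, alt)
            other = [i for i in range(aln.n_codons) if i not in sel]
            localised += (np.median(post.values[sel])
                          > np.median(post.values[other]))
        assert hits >= 3
        assert localised >= 8

    def test_type_one_error_not_inflated(self):
        """No selection anywhere: the df=1 chi-square reference should not
        reject markedly above the nominal 5% level (it is conservative at
        the omega2 = 1 boundary)."""
        rejections = 0
        for rep in range(20):
            aln, tree, _ = _fit_dataset(None, seed=400 + rep, n_codons=150)
            _, _, res = fit_branch_site_pair(aln, tree, ["ab", "ef"],
                                             n_starts=1, seed=rep)
            rejections += res.p < 0.05
        assert rejections <= 3

    def test_class_posteriors_sum_to_one(self):
        aln, tree, _ = _fit_dataset(None, seed=22)
        alt, _, _ = fit_branch_site_pair(aln, tree, ["ab"], n_starts=1, seed=3)
        post = site_posteriors(aln, tree, alt)
        assert np.allclose(post.class_posteriors.sum(axis=1), 1.0, atol=1e-9)
        assert np.all((post.values >= 0) & (post.values <= 1))

    def test_percentile_flags_use_midpoint_interpolation(self):
        from selconv.branchsite import SitePosteriors

        vals = np.linspace(0, 1, 20)
        sp = SitePosteriors(vals, np.zeros((20, 4)))
        flags = sp.percentile_flags(90.0)
        assert flags.sum() == 2


class TestEnrichment:
    def test_exact_p_for_separated_sets(self):
        res = enrichment_test(np.arange(6.0), [3, 4, 5], [0, 1, 2],
                              alternative="greater")
        assert res.method == "exact"
        assert res.u == 9.0
        assert res.p == pytest.approx(1 / 20)

    def test_identical_multisets_not_enriched(self):
        vals = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        res = enrichment_test(vals, [0, 1, 2], [3, 4, 5],
                              alternative="greater")
        assert res.p >= 0.5

    def test_disjointness_required(self):
        with pytest.raises(ValueError, match="disjoint"):
            enrichment_test(np.arange(6.0), [0, 1], [1, 2])

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            enrichment_test(np.arange(6.0), [], [1, 2])

    def test_exact_and_asymptotic_agree_without_ties(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=16)
        a, b = list(range(8)), list(range(8, 16))
        exact = enrichment_test(vals, a, b, alternative="greater",
                                exact_max=8)
        approx = enrichment_test(vals, a, b, alternative="greater",
                                 exact_max=0)
        assert approx.method == "asymptotic"
        assert exact.p == pytest.approx(approx.p, rel=0.10, abs=0.02)

    def test_matches_scipy_exact_reference(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(size=12)
        a, b = list(range(5)), list(range(5, 12))
        mine = enrichment_test(vals, a, b, alternative="greater")
        ref = stats.mannwhitneyu(vals[a], vals[b], alternative="greater",
                                 method="exact")
        assert mine.p == pytest.approx(float(ref.pvalue), abs=1e-12)
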