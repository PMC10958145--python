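"""Branch-site positive-selection model (model A) with NEB site
posteriors and enrichment testing at designated site sets.

The mixture has four site classes over (background, foreground) omega
pairs: (w0, w0), (1, 1), (w0, w2) and (1, w2) with proportions p0, p1,
p2a, p2b where p2a = (1-p0-p1) p0/(p0+p1) and p2b = (1-p0-p1) p1/(p0+p1).
The alternative lets w2 >= 1 vary; the null pins w2 = 1.  The LRT uses a
chi-square with df = 1.  Site posteriors are naive empirical Bayes at
the MLEs.  Branch lengths and kappa can be supplied (e.g. from a branch-
model fit) or are estimated first under a one-ratio model.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .codon import (LRTResult, ReversibleEigen, build_gy94_matrix,
                    f3x4_frequencies, fit_branch_model, make_engine)
from .trees import PhyloTree


@dataclass
class BranchSiteParams:
    foreground: tuple[int, ...]
    p0: float
    p1: float
    omega0: float
    omega2: float
    kappa: float
    lengths: np.ndarray

    @property
    def p2a(self) -> float:
        rest = max(1.0 - self.p0 - self.p1, 0.0)
        return rest * self.p0 / (self.p0 + self.p1)

    @property
    def p2b(self) -> float:
        rest = max(1.0 - self.p0 - self.p1, 0.0)
        return rest * self.p1 / (self.p0 + self.p1)

    @property
    def proportions(self) -> np.ndarray:
        return np.array([self.p0, self.p1, self.p2a, self.p2b])


@dataclass
class BranchSiteFit:
    params: BranchSiteParams
    loglik: float
    n_free: int
    converged: bool
    boundary: bool = False     # p0+p1 pinned at 1 (no selected class mass)
    message: str = ""
    x: np.ndarray | None = None   # optimiser coordinates (internal)


@dataclass
class SitePosteriors:
    """Per-site posterior of the positively selected classes (2a + 2b)."""

    values: np.ndarray
    class_posteriors: np.ndarray   # (n_sites, 4)

    def percentile_flags(self, percentile: float = 90.0,
                         region: tuple[int, int] | None = None) -> np.ndarray:
        ref = self.values if region is None else self.values[region[0]:region[1]]
        cut = float(np.percentile(ref, percentile, method="midpoint"))
        return self.values >= cut


# ----------------------------------------------------------------------
def _class_site_logliks(engine, tree, foreground, kappa, omega0, omega2,
                        lengths, pi, proportions, eig_cache=None):
    """Per-pattern log-likelihood under each of the four site classes.

    All class matrices share one time scale (the proportion-weighted mean
    background rate is normalised to 1), so a site in the selected class
    evolves faster on the foreground, not merely more nonsynonymously —
    the usual mixture-model convention.  Scaling is folded into the
    branch lengths so the eigendecompositions of the unscaled matrices
    can be cached across optimiser evaluations.
    """
    if eig_cache is None:
        eig_cache = {}

    def get_eig(w):
        key = (round(float(kappa), 12), round(float(w), 12))
        if key not in eig_cache:
            Q = build_gy94_matrix(kappa, w, pi, scale=False)
            eig_cache[key] = (ReversibleEigen(Q, pi),
                              -float(pi @ np.diag(Q)))
        return eig_cache[key]

    eig = {w: get_eig(w) for w in {omega0, 1.0, omega2}}
    p = np.asarray(proportions, dtype=float)
    qfactor = ((p[0] + p[2]) * eig[omega0][1] + (p[1] + p[3]) * eig[1.0][1])
    qfactor = max(qfactor, 1e-12)
    branches = tree.branches
    ts = np.array([max(lengths[b], 0.0) for b in branches]) / qfactor
    P = {}
    for w, (e, _) in eig.items():
        mats = e.P_batch(ts)
        P[w] = {b: mats[j] for j, b in enumerate(branches)}
    fg = set(foreground)

    def mix(back_w, fore_w):
        return {b: (P[fore_w][b] if b in fg else P[back_w][b])
                for b in tree.branches}

    rows = [
        engine.pattern_logliks(mix(omega0, omega0), pi),
        engine.pattern_logliks(mix(1.0, 1.0), pi),
        engine.pattern_logliks(mix(omega0, omega2), pi),
        engine.pattern_logliks(mix(1.0, omega2), pi),
    ]
    return np.stack(rows)  # (4, n_patterns)


def _mixture_loglik(class_ll, props, weights):
    lw = np.log(np.maximum(props, 1e-300))[:, None]
    m = class_ll.max(axis=0)
    lse = m + np.log(np.sum(np.exp(class_ll - m + lw - 0.0), axis=0))
    # note: weights on classes included via lw
    return float(np.sum(weights * lse))


def fit_branch_site_pair(aln, tree: PhyloTree, foreground, *,
                         lengths=None, kappa0=None, n_starts: int = 2,
                         seed: int = 0):
    """Fit the alternative and null branch-site models and form the LRT.

    ``foreground`` is a collection of node ids (or branch names) whose
    branches form the foreground set.  Branch lengths are taken from
    ``lengths`` (per-node array) or estimated once under a one-ratio
    model and then held fixed for both mixture fits.

    Returns (alt BranchSiteFit, null BranchSiteFit, LRTResult).
    """
    fg = tuple(
        b if isinstance(b, (int, np.integer)) else tree.node_by_name(b)
        for b in foreground
    )
    if not fg:
        raise ValueError("foreground branch set is empty")
    engine, states = make_engine(aln, tree)
    pi = f3x4_frequencies(states)
    if lengths is None or kappa0 is None:
        base = fit_branch_model(aln, tree, "one-ratio", n_starts=1, seed=seed)
        if lengths is None:
            lengths = base.params.lengths
        if kappa0 is None:
            kappa0 = base.params.kappa
    lengths = np.asarray(lengths, dtype=float)
    rng = np.random.default_rng(seed)
    eig_cache: dict = {}

    def unpack(x, alt):
        q = 1.0 / (1.0 + np.exp(-x[0]))        # p0 + p1
        r = 1.0 / (1.0 + np.exp(-x[1]))        # p0 / (p0 + p1)
        kappa = float(np.exp(x[2]))
        w0 = 1.0 / (1.0 + np.exp(-x[3]))       # in (0, 1)
        w2 = 1.0 + float(np.exp(x[4])) if alt else 1.0
        return q * r, q * (1 - r), kappa, w0, w2

    weights = engine.weights

    def make_obj(alt):
        def obj(x):
            p0, p1, kappa, w0, w2 = unpack(x, alt)
            pr = BranchSiteParams(fg, p0, p1, w0, w2, kappa, lengths)
            cls = _class_site_logliks(engine, tree, fg, kappa, w0, w2,
                                      lengths, pi, pr.proportions, eig_cache)
            return -_mixture_loglik(cls, pr.proportions, weights)
        return obj

    def run(alt, extra_starts=()):
        obj = make_obj(alt)
        best = None
        starts = [np.array([np.log(0.85 / 0.15), 0.8, np.log(kappa0),
                            0.0, 0.0])]
        starts += [np.asarray(x, dtype=float) for x in extra_starts]
        while len(starts) < max(1, n_starts) + len(extra_starts):
            starts.append(np.array([
                rng.normal(1.5, 0.8), rng.normal(0.8, 0.8),
                np.log(kappa0) + rng.normal(0, 0.3),
                rng.normal(0, 1.0), rng.normal(0, 1.0),
            ]))
        for x0 in starts:
            res = optimize.minimize(
                obj, x0[:5] if alt else x0[:4].copy(),
                method="L-BFGS-B",
                bounds=[(-12, 12), (-12, 12), (np.log(1e-2), np.log(100)),
                        (-12, 12), (np.log(1e-4), np.log(50))][:5 if alt else 4],
                options={"ftol": 1e-8, "maxiter": 150, "maxfun": 1500},
            ) if alt else optimize.minimize(
                lambda y: obj(np.append(y, 0.0)), x0[:4].copy(),
                method="L-BFGS-B",
                bounds=[(-12, 12), (-12, 12), (np.log(1e-2), np.log(100)),
                        (-12, 12)],
                options={"ftol": 1e-8, "maxiter": 150, "maxfun": 1500},
            )
            if best is None or res.fun < best.fun:
                best = res
        x = best.x if alt else np.append(best.x, 0.0)
        p0, p1, kappa, w0, w2 = unpack(x, alt)
        pr = BranchSiteParams(fg, p0, p1, w0, w2, kappa, lengths)
        boundary = (p0 + p1) > 0.999
        if boundary:
            warnings.warn("branch-site fit at boundary: p0 + p1 ~ 1 "
                          "(no mass on the selected classes)")
        n_free = 4 + (1 if alt else 0)
        return BranchSiteFit(pr, -float(best.fun), n_free,
                             bool(best.success), boundary,
                             str(best.message), x=x)

    alt_fit = run(alt=True)
    # the null is nested: warm-start it from the alternative's optimum
    null_fit = run(alt=False, extra_starts=[alt_fit.x])
    if alt_fit.loglik < null_fit.loglik - 1e-6:
        # w2 = 1 is inside the alternative; never worse in exact arithmetic
        alt_fit = BranchSiteFit(
            BranchSiteParams(fg, null_fit.params.p0, null_fit.params.p1,
                             null_fit.params.omega0, 1.0,
                             null_fit.params.kappa, lengths),
            null_fit.loglik, alt_fit.n_free, null_fit.converged,
            null_fit.boundary, "restarted from null optimum")
    lr = max(0.0, 2.0 * (alt_fit.loglik - null_fit.loglik))
    res = LRTResult(lr=lr, df=1, p=float(stats.chi2.sf(lr, 1)))
    return alt_fit, null_fit, res


def site_posteriors(aln, tree: PhyloTree, fit: BranchSiteFit) -> SitePosteriors:
    """Naive empirical-Bayes posterior of classes 2a + 2b per site."""
    engine, states = make_engine(aln, tree)
    pi = f3x4_frequencies(states)
    p = fit.params
    cls = _class_site_logliks(engine, tree, p.foreground, p.kappa, p.omega0,
                              p.omega2, p.lengths, pi, p.proportions)
    lw = np.log(np.maximum(p.proportions, 1e-300))[:, None]
    joint = cls + lw
    m = joint.max(axis=0)
    post = np.exp(joint - m)
    post /= post.sum(axis=0)
    # expand patterns back to sites
    from .likelihood import compress_patterns

    _, _, site_to_pat = compress_patterns(states)
    per_site = post[:, site_to_pat].T          # (n_sites, 4)
    return SitePosteriors(values=per_site[:, 2:].sum(axis=1),
                          class_posteriors=per_site)


# ----------------------------------------------------------------------
def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


@dataclass
class EnrichmentResult:
    u: float
    p: float
    method: str
    alternative: str
    n_a: int
    n_b: int


def enrichment_test(values, set_a, set_b, alternative: str = "greater",
                    exact_max: int = 8,
                    max_labelings: int = 200_000) -> EnrichmentResult:
    """Mann-Whitney U test that sites in ``set_a`` carry larger values
    (e.g. positive-selection posteriors) than sites in ``set_b``.

    Exact enumeration of all labelings when min(|A|, |B|) <= ``exact_max``
    and the number of labelings C(|A|+|B|, |A|) is tractable (ties handled
    by the 0.5 convention); otherwise the normal approximation with tie
    correction.
    """
    from math import comb

    set_a, set_b = list(set_a), list(set_b)
    if not set_a or not set_b:
        raise ValueError("both site sets must be non-empty")
    if set(set_a) & set(set_b):
        raise ValueError("site sets must be disjoint")
    values = np.asarray(values, dtype=float)
    a, b = values[set_a], values[set_b]
    na, nb = len(a), len(b)
    if min(na, nb) <= exact_max and comb(na + nb, na) <= max_labelings:
        pool = np.concatenate([a, b])
        u_obs = _u_statistic(a, b)
        us = np.array([
            _u_statistic(pool[list(idx)],
                         pool[[i for i in range(na + nb) if i not in idx]])
            for idx in itertools.combinations(range(na + nb), na)
        ])
        tol = 1e-12
        p_greater = float(np.mean(us >= u_obs - tol))
        p_less = float(np.mean(us <= u_obs + tol))
        if alternative == "greater":
            p = p_greater
        elif alternative == "less":
            p = p_less
        else:
            p = min(1.0, 2.0 * min(p_greater, p_less))
        return EnrichmentResult(u_obs, p, "exact", alternative, na, nb)
    res = stats.mannwhitneyu(a, b, alternative=alternative,
                             method="asymptotic")
    return EnrichmentResult(float(res.statistic), float(res.pvalue),
                            "asymptotic", alternative, na, nb)
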