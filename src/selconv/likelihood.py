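"""Felsenstein pruning with rescaling, outside messages and branch gradients.

State-count agnostic: the same engine drives the 61-state codon models and
the 20-state amino-acid models.  Partial likelihoods are rescaled per node
and pattern (max-normalisation) so that alignments of any depth stay in
range; all downstream quantities (site likelihoods, posteriors, branch
derivatives) are formed as ratios in which the scalers cancel.
"""

from __future__ import annotations

import numpy as np

from .trees import PhyloTree


class PruningEngine:
    """Likelihood engine bound to one tree shape and one pattern matrix.

    Parameters
    ----------
    tree : PhyloTree
    leaf_states : (n_leaves_in_tree_order?, n_patterns) int array keyed by
        node id via ``leaf_state_map``: mapping node id -> row of states,
        with -1 meaning missing/ambiguous (all-ones partial likelihood).
    n_states : int
    weights : (n_patterns,) pattern multiplicities.
    """

    def __init__(self, tree: PhyloTree, leaf_state_map: dict[int, np.ndarray],
                 n_states: int, weights: np.ndarray):
        self.tree = tree
        self.n_states = int(n_states)
        self.weights = np.asarray(weights, dtype=float)
        self.n_patterns = len(self.weights)
        self.leaf_state_map = {
            k: np.asarray(v, dtype=int) for k, v in leaf_state_map.items()
        }
        for i in tree.leaves:
            if i not in self.leaf_state_map:
                raise ValueError(f"no states for leaf {tree.names[i]!r}")
        self._post = tree.postorder()

    # ------------------------------------------------------------------
    def _leaf_partial(self, node: int) -> np.ndarray:
        L = np.zeros((self.n_states, self.n_patterns))
        st = self.leaf_state_map[node]
        ok = st >= 0
        L[st[ok], np.nonzero(ok)[0]] = 1.0
        L[:, ~ok] = 1.0
        return L

    def inside(self, P: dict[int, np.ndarray]):
        """Post-order pass.

        Returns (partials, messages, logscale) where ``partials[v]`` is the
        (S, n_pat) conditional likelihood at node v, ``messages[v]`` is
        P_v @ partials[v] for non-root v, and ``logscale`` is the summed log
        of the per-pattern rescaling factors.
        """
        tree = self.tree
        partials: dict[int, np.ndarray] = {}
        messages: dict[int, np.ndarray] = {}
        logscale = np.zeros(self.n_patterns)
        for v in self._post:
            if tree.is_leaf(v):
                L = self._leaf_partial(v)
            else:
                L = np.ones((self.n_states, self.n_patterns))
                for c in tree.children[v]:
                    L = L * messages[c]
                mx = L.max(axis=0)
                bad = mx <= 0
                if np.any(bad):
                    # impossible pattern under P==deterministic; keep tiny
                    mx = np.where(bad, 1.0, mx)
                L = L / mx
                logscale += np.log(mx)
            partials[v] = L
            if v != tree.root:
                messages[v] = P[v] @ L
        return partials, messages, logscale

    def loglik(self, P: dict[int, np.ndarray], pi: np.ndarray) -> float:
        return float(np.sum(self.weights * self.pattern_logliks(P, pi)))

    def pattern_logliks(self, P: dict[int, np.ndarray], pi: np.ndarray) -> np.ndarray:
        """Per-pattern log-likelihoods (unweighted)."""
        partials, _, logscale = self.inside(P)
        site = pi @ partials[self.tree.root]
        site = np.maximum(site, 1e-300)
        return np.log(site) + logscale

    # ------------------------------------------------------------------
    def outside(self, partials, messages, P, pi):
        """Pre-order pass computing, for every node, the likelihood of the
        rest of the tree (root prior included), up to per-pattern scaling.

        Returns (above, at): ``above[c]`` is indexed by the state of c's
        *parent* (the outside message before crossing branch c) and
        ``at[v]`` by the state of v itself (transported through P_v).
        """
        tree = self.tree
        above: dict[int, np.ndarray] = {}
        at: dict[int, np.ndarray] = {
            tree.root: np.repeat(pi[:, None], self.n_patterns, axis=1)
        }
        for v in reversed(self._post):
            if tree.is_leaf(v):
                continue
            kids = tree.children[v]
            msgs = [messages[c] for c in kids]
            # prefix/suffix products over siblings
            k = len(kids)
            prefix = [None] * (k + 1)
            prefix[0] = np.ones((self.n_states, self.n_patterns))
            for j in range(k):
                prefix[j + 1] = prefix[j] * msgs[j]
            suffix = np.ones((self.n_states, self.n_patterns))
            sib_prod = [None] * k
            for j in range(k - 1, -1, -1):
                sib_prod[j] = prefix[j] * suffix
                suffix = suffix * msgs[j]
            for j, c in enumerate(kids):
                ab = at[v] * sib_prod[j]
                mx = ab.max(axis=0)
                mx = np.where(mx <= 0, 1.0, mx)
                ab = ab / mx
                above[c] = ab
                at[c] = P[c].T @ ab
        return above, at

    def branch_gradient(self, P, QP, pi):
        """Log-likelihood and its gradient w.r.t. every branch length.

        ``QP[v]`` must be Q_v @ P_v for the rate matrix governing branch v.
        Returns (loglik, grad dict node id -> d loglik / d t_v).
        """
        tree = self.tree
        partials, messages, logscale = self.inside(P)
        site = pi @ partials[tree.root]
        site = np.maximum(site, 1e-300)
        ll = float(np.sum(self.weights * (np.log(site) + logscale)))
        above, _ = self.outside(partials, messages, P, pi)
        grad: dict[int, float] = {}
        for v in tree.branches:
            # f and df share the scaling of above[v] and partials[v]
            f = np.einsum("ip,ip->p", above[v], messages[v])
            df = np.einsum("ip,ip->p", above[v], QP[v] @ partials[v])
            f = np.where(f <= 0, 1e-300, f)
            grad[v] = float(np.sum(self.weights * df / f))
        return ll, grad

    def node_posteriors(self, P, pi):
        """Marginal posterior state distributions for every node.

        Returns dict node id -> (n_states, n_patterns) column-normalised.
        """
        partials, messages, _ = self.inside(P)
        _, at = self.outside(partials, messages, P, pi)
        post: dict[int, np.ndarray] = {}
        for v in range(self.tree.n_nodes):
            w = at[v] * partials[v]
            s = w.sum(axis=0)
            s = np.where(s <= 0, 1.0, s)
            post[v] = w / s
        return post


def compress_patterns(columns: np.ndarray):
    """Compress an (n_taxa, n_sites) state matrix into unique patterns.

    Returns (patterns (n_taxa, n_pat), weights, site_to_pattern).
    """
    columns = np.asarray(columns)
    pats, inv, counts = np.unique(
        columns.T, axis=0, return_inverse=True, return_counts=True
    )
    return pats.T, counts.astype(float), inv
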