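"""Marginal empirical-Bayes ancestral sequence reconstruction at protein
level, with per-node reconstruction accuracy and a parsimony helper for
the catalytic Sec/Cys character.

The marginal posterior at an internal node integrates over all other
nodes (inside-outside on the tree); the MAP state per node and site is
reported with a deterministic lexicographic tie-break.  Node accuracy is
the mean MAP posterior across sites — the standard self-assessment of a
marginal reconstruction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .aamodels import AA_ORDER, AminoAcidModel, encode_protein, jtt
from .likelihood import PruningEngine, compress_patterns
from .trees import PhyloTree


@dataclass
class AncestralReconstruction:
    """Per-node, per-site posterior state distributions (internal nodes)."""

    tree: PhyloTree
    node_ids: list[int]                      # internal node ids
    posteriors: np.ndarray                   # (n_internal, n_sites, 20)
    map_states: np.ndarray                   # (n_internal, n_sites) int
    leaf_states: np.ndarray                  # (n_leaves, n_sites) int, -1 gap
    leaf_ids: list[int]
    branch_lengths: np.ndarray               # lengths used (per tree node)
    model_name: str = "JTT"

    @property
    def n_sites(self) -> int:
        return self.posteriors.shape[1]

    def _row(self, node: int) -> int:
        return self.node_ids.index(node)

    def map_sequence(self, node: int) -> str:
        return "".join(AA_ORDER[s] for s in self.map_states[self._row(node)])

    def node_posterior(self, node: int) -> np.ndarray:
        return self.posteriors[self._row(node)]

    def state_at(self, node: int, site: int) -> int:
        """MAP state index at any node: reconstructed for internal nodes,
        observed for leaves (-1 if the leaf has a gap)."""
        if node in self.node_ids:
            return int(self.map_states[self._row(node), site])
        return int(self.leaf_states[self.leaf_ids.index(node), site])

    def map_posterior(self, node: int) -> np.ndarray:
        """Posterior probability of the MAP state per site."""
        row = self._row(node)
        return self.posteriors[row, np.arange(self.n_sites), self.map_states[row]]

    def to_fasta(self, path):
        with open(path, "w") as fh:
            for node in self.node_ids:
                name = self.tree.names[node] or f"node{node}"
                fh.write(f">{name}\n{self.map_sequence(node)}\n")


def _map_with_lex_tiebreak(post: np.ndarray) -> np.ndarray:
    """Argmax over the state axis, ties broken by alphabetical amino acid."""
    # reorder columns alphabetically, argmax (first wins), map back
    alpha_order = sorted(range(20), key=lambda i: AA_ORDER[i])
    idx = np.argmax(post[..., alpha_order], axis=-1)
    return np.asarray(alpha_order, dtype=int)[idx]


def optimize_branch_lengths(engine: PruningEngine, tree: PhyloTree,
                            model: AminoAcidModel, tol: float = 1e-8) -> np.ndarray:
    """ML branch lengths under a fixed amino-acid model (analytic gradients)."""
    branches = tree.branches
    t0 = np.array([max(tree.lengths[b], 0.01) for b in branches])

    def nll_grad(x):
        t = np.exp(x)
        P, QP = {}, {}
        for j, b in enumerate(branches):
            P[b], QP[b] = model.eigen.P_and_QP(t[j])
        ll, gt = engine.branch_gradient(P, QP, model.pi)
        grad = -np.array([gt[b] * t[j] for j, b in enumerate(branches)])
        return -ll, grad

    res = optimize.minimize(
        nll_grad, np.log(t0), jac=True, method="L-BFGS-B",
        bounds=[(np.log(1e-8), np.log(20.0))] * len(branches),
        options={"ftol": tol},
    )
    lengths = tree.lengths.copy()
    lengths[branches] = np.exp(res.x)
    return lengths


def marginal_asr(protein_seqs: dict[str, str], tree: PhyloTree,
                 model: AminoAcidModel | None = None,
                 optimize_lengths: bool = False) -> AncestralReconstruction:
    """Marginal ancestral reconstruction for every internal node.

    ``protein_seqs`` maps taxon name -> amino-acid sequence (gaps and
    unknown symbols are treated as missing data).  If ``optimize_lengths``
    the branch lengths are first refit by ML under ``model``; otherwise
    the tree's lengths are used as expected substitutions per site.
    """
    model = model or jtt()
    taxa, mat = encode_protein(protein_seqs)
    order = {t: i for i, t in enumerate(taxa)}
    missing = set(tree.leaf_names) - set(taxa)
    if missing:
        raise ValueError(f"no sequence for taxa: {sorted(missing)}")
    all_gap = np.nonzero(np.all(mat < 0, axis=0))[0]
    if len(all_gap):
        warnings.warn(f"{len(all_gap)} all-gap column(s); posteriors are uniform there")

    pats, weights, site_to_pat = compress_patterns(mat)
    leaf_ids = tree.leaves
    leaf_map = {i: pats[order[tree.names[i]]] for i in leaf_ids}
    engine = PruningEngine(tree, leaf_map, 20, weights)

    lengths = tree.lengths.copy()
    if optimize_lengths:
        lengths = optimize_branch_lengths(engine, tree, model)
    work_tree = tree.with_lengths(lengths)
    engine = PruningEngine(work_tree, leaf_map, 20, weights)

    P = {b: model.P(max(lengths[b], 0.0)) for b in tree.branches}
    post_by_node = engine.node_posteriors(P, model.pi)

    internal = [i for i in range(tree.n_nodes) if not tree.is_leaf(i)]
    n_sites = mat.shape[1]
    posteriors = np.empty((len(internal), n_sites, 20))
    for r, node in enumerate(internal):
        posteriors[r] = post_by_node[node][:, site_to_pat].T
    if len(all_gap):
        posteriors[:, all_gap, :] = 1.0 / 20.0  # no information at all
    map_states = _map_with_lex_tiebreak(posteriors)
    leaf_states = np.stack([mat[order[tree.names[i]]] for i in leaf_ids])
    return AncestralReconstruction(
        tree=work_tree, node_ids=internal, posteriors=posteriors,
        map_states=map_states, leaf_states=leaf_states, leaf_ids=leaf_ids,
        branch_lengths=lengths, model_name=model.name,
    )


def node_accuracy(rec: AncestralReconstruction, sites=None) -> dict[str, float]:
    """Mean MAP posterior per internal node (sites equally weighted).

    ``sites`` restricts the average to a subset of columns (e.g. after
    masking); by default all columns enter.
    """
    sites = np.arange(rec.n_sites) if sites is None else np.asarray(sites, int)
    out = {}
    for node in rec.node_ids:
        name = rec.tree.names[node] or f"node{node}"
        out[name] = float(np.mean(rec.map_posterior(node)[sites]))
    return out


# ----------------------------------------------------------------------
def fitch_character_losses(tree: PhyloTree, leaf_char: dict[str, str],
                           ancestral_state: str):
    """Fitch parsimony on a discrete character (e.g. Sec/Cys at the
    catalytic site), rooted with a preferred ancestral state.

    Returns (n_transitions_away_from_ancestral, assignments, ambiguous)
    where ``assignments`` maps node id -> state set from the Fitch
    down-pass (sets of size > 1 are reported as ties, not resolved).
    """
    sets: dict[int, frozenset] = {}
    for v in tree.postorder():
        if tree.is_leaf(v):
            sets[v] = frozenset({leaf_char[tree.names[v]]})
        else:
            inter = None
            union = frozenset()
            for c in tree.children[v]:
                inter = sets[c] if inter is None else (inter & sets[c])
                union = union | sets[c]
            sets[v] = inter if inter else union
    # top-down resolution preferring the declared ancestral state
    resolved: dict[int, str] = {}
    for v in reversed(tree.postorder()):
        options = sets[v]
        if v == tree.root:
            parent_state = ancestral_state
        else:
            parent_state = resolved[tree.parent[v]]
        resolved[v] = parent_state if parent_state in options else sorted(options)[0]
    transitions = sum(
        1 for v in tree.branches
        if resolved[tree.parent[v]] == ancestral_state and resolved[v] != ancestral_state
    )
    ambiguous = sorted(v for v, s in sets.items() if len(s) > 1 and not tree.is_leaf(v))
    return transitions, sets, ambiguous
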