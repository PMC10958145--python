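"""Protein-evolution simulation along a tree and the convergence null.

Replicates evolve amino-acid states site-independently down the tree by
sampling from the model's transition matrices, with branch lengths set
to the per-branch amino-acid substitution rate (the dN-derived lengths
exported by the codon fits).  Each replicate is pushed through the same
reconstruction-and-counting pipeline as the observed data, so ancestral-
reconstruction error is part of the null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .aamodels import AA_ORDER, AminoAcidModel, jtt
from .asr import marginal_asr
from .convergence import (convergent_site_union, detect_pairwise_convergence,
                          exchange_pairs, extract_substitutions)
from .trees import PhyloTree

log = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Settings for protein simulation under an empirical model.

    ``tree`` must carry branch lengths on the amino-acid substitution
    scale.  ``root_sequence`` fixes the root (string over the 20 residues);
    when None the root is drawn from the model's stationary frequencies.
    """

    tree: PhyloTree
    n_sites: int
    model: AminoAcidModel = field(default_factory=jtt)
    root_sequence: str | None = None
    n_replicates: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("replicate count must be >= 1")
        blen = [self.tree.lengths[b] for b in self.tree.branches]
        if any(t < 0 for t in blen):
            raise ValueError("branch lengths must be non-negative")
        if self.root_sequence is not None:
            self.n_sites = len(self.root_sequence)


@dataclass
class SimulatedReplicate:
    """One replicate: leaf sequences plus the true internal states."""

    leaf_seqs: dict[str, str]
    node_states: np.ndarray      # (n_nodes, n_sites) int, tree node order

    def true_events(self, tree: PhyloTree):
        out = []
        for b in tree.branches:
            parent = tree.parent[b]
            diff = np.nonzero(self.node_states[parent] != self.node_states[b])[0]
            for s in diff:
                out.append((b, int(s),
                            int(self.node_states[parent][s]),
                            int(self.node_states[b][s])))
        return out


def simulate_protein_evolution(cfg: SimulationConfig, rng=None
                               ) -> list[SimulatedReplicate]:
    """Evolve replicate alignments down the tree (site-independent)."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    tree, model = cfg.tree, cfg.model
    P = {b: model.P(max(float(tree.lengths[b]), 0.0)) for b in tree.branches}
    cum = {b: np.cumsum(P[b], axis=1) for b in tree.branches}
    preorder = list(reversed(tree.postorder()))
    if cfg.root_sequence is not None:
        root = np.array([AA_ORDER.index(a) for a in cfg.root_sequence.upper()])
    else:
        root = None
    reps = []
    for _ in range(cfg.n_replicates):
        states = np.empty((tree.n_nodes, cfg.n_sites), dtype=int)
        states[tree.root] = (
            root if root is not None
            else rng.choice(20, size=cfg.n_sites, p=model.pi)
        )
        for v in preorder:
            if v == tree.root:
                continue
            parent_states = states[tree.parent[v]]
            u = rng.random(cfg.n_sites)
            rows = cum[v][parent_states]                    # (n_sites, 20)
            states[v] = (u[:, None] > rows).sum(axis=1)
        leaf_seqs = {
            tree.names[i]: "".join(AA_ORDER[s] for s in states[i])
            for i in tree.leaves
        }
        reps.append(SimulatedReplicate(leaf_seqs, states))
    return reps


# ----------------------------------------------------------------------
@dataclass
class NullDistribution:
    counts: np.ndarray            # per-replicate total convergent-site counts
    pair_counts: dict             # (b1, b2) -> per-replicate counts array
    observed: int
    empirical_p: float
    n_replicates: int
    dropped: int = 0

    def quantiles(self, qs=(0.025, 0.5, 0.975)):
        return {q: float(np.quantile(self.counts, q)) for q in qs}


def count_convergence(leaf_seqs: dict[str, str], tree: PhyloTree,
                      model: AminoAcidModel, pairs, exclude_sites=(),
                      use_true_states: np.ndarray | None = None):
    """Run the observed-data procedure on one alignment: reconstruct
    ancestors (or use supplied true states) and count the convergent-site
    union over the designated pairs."""
    if use_true_states is not None:
        from .convergence import SubstitutionEvent

        events = []
        excl = set(int(s) for s in exclude_sites)
        for b in sorted({b for p in pairs for b in p}):
            parent = tree.parent[b]
            diff = np.nonzero(use_true_states[parent] != use_true_states[b])[0]
            for s in diff:
                if int(s) in excl:
                    continue
                events.append(SubstitutionEvent(
                    b, int(s), int(use_true_states[parent][s]),
                    int(use_true_states[b][s])))
    else:
        rec = marginal_asr(leaf_seqs, tree, model, optimize_lengths=False)
        branches = sorted({b for p in pairs for b in p})
        events = extract_substitutions(rec, tree, branches,
                                       exclude_sites=exclude_sites)
    cps = detect_pairwise_convergence(events, pairs, tree)
    return cps, convergent_site_union(cps)


def convergence_null_test(cfg: SimulationConfig, tree: PhyloTree,
                          observed_count: int, pairs=None,
                          exclude_sites=(), max_drop_frac: float = 0.05
                          ) -> NullDistribution:
    """Empirical p-value of an observed convergent-site count.

    Each replicate is simulated under ``cfg`` and re-analysed with the
    same reconstruction-and-counting settings; the p-value is
    (1 + #{replicate count >= observed}) / (R + 1).
    """
    pairs = pairs if pairs is not None else exchange_pairs(tree)
    if not pairs:
        raise ValueError("no branch pairs to evaluate")
    rng = np.random.default_rng(cfg.seed)
    counts = []
    pair_counts = {tuple(p): [] for p in pairs}
    dropped = 0
    for i in range(cfg.n_replicates):
        rep = simulate_protein_evolution(
            SimulationConfig(cfg.tree, cfg.n_sites, cfg.model,
                             cfg.root_sequence, 1, seed=0), rng=rng)[0]
        try:
            cps, union = count_convergence(rep.leaf_seqs, tree, cfg.model,
                                           pairs, exclude_sites)
        except Exception as exc:  # pragma: no cover - defensive
            dropped += 1
            log.warning("replicate %d dropped: %s", i, exc)
            continue
        counts.append(len(union))
        for cp in cps:
            pair_counts[tuple(cp.branches)].append(cp.observed)
    if dropped > max_drop_frac * cfg.n_replicates:
        raise RuntimeError(f"{dropped} of {cfg.n_replicates} replicates failed")
    counts = np.asarray(counts)
    r = len(counts)
    p = (1 + int(np.sum(counts >= observed_count))) / (r + 1)
    return NullDistribution(
        counts=counts,
        pair_counts={k: np.asarray(v) for k, v in pair_counts.items()},
        observed=observed_count, empirical_p=float(p),
        n_replicates=r, dropped=dropped,
    )
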