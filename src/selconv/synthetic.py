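"""Synthetic codon datasets with branch-partitioned dN/dS, domain
structure and injected convergent substitutions, with full ground truth.

The generator emulates the statistical shape of a 22-mammal selenoprotein
alignment in which five lineages independently exchanged the catalytic
selenocysteine (TGA) for cysteine: elevated omega on the exchange
branches, three domains of 39/113/65 codons, a catalytic column that is
TGA in Sec lineages and TGC in Cys lineages, and a configurable number of
convergent amino-acid substitutions shared across the exchange branches.
Injection happens post hoc on the simulated histories so the convergent-
site list is exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .codon import GENETIC_CODE, ReversibleEigen, build_gy94_matrix
from .io import CodonAlignment, DomainPartition
from .trees import EXCHANGE, INHERITED, SEC, PhyloTree

#: position-specific nucleotide frequencies used to build the simulation's
#: codon equilibrium (mild GC bias typical of mammalian coding sequence)
DEFAULT_POSITION_FREQS = np.array([
    [0.26, 0.22, 0.31, 0.21],   # codon position 1, order A C G T
    [0.30, 0.23, 0.19, 0.28],
    [0.22, 0.27, 0.26, 0.25],
])

SEC_CODON = "TGA"
CYS_CODON = "TGC"


@dataclass
class ScenarioConfig:
    """Everything needed to generate one synthetic dataset."""

    tree: PhyloTree | None = None
    n_taxa: int = 22
    n_exchange: int = 5
    omegas: dict = field(default_factory=lambda: {
        SEC: 0.217, EXCHANGE: 0.370, INHERITED: 0.279})
    kappa: float = 3.0
    domain_lengths: dict = field(default_factory=lambda: {
        "N-terminus": 39, "GPX": 113, "C-terminus": 65})
    n_focal_changes: int = 25
    n_injected: int = 14
    catalytic_site: int = 72           # codon coordinate, inside the GPX domain
    focal_branch: str | None = None    # branch name; default: first EXCHANGE
    position_freqs: np.ndarray = field(
        default_factory=lambda: DEFAULT_POSITION_FREQS.copy())
    seed: int = 0

    def __post_init__(self):
        if self.n_injected > self.n_focal_changes:
            raise ValueError("injected sites cannot exceed focal changes")
        n = self.total_codons
        if not (0 <= self.catalytic_site < n):
            raise ValueError("catalytic site outside the alignment")

    @property
    def total_codons(self) -> int:
        return sum(self.domain_lengths.values())

    def domains(self) -> DomainPartition:
        ivals, pos = [], 0
        for name, ln in self.domain_lengths.items():
            ivals.append((name, pos, pos + ln))
            pos += ln
        return DomainPartition(ivals)


@dataclass
class GroundTruth:
    """True states and events of a simulated dataset."""

    tree: PhyloTree
    node_states: np.ndarray          # (n_nodes, n_codons) codon indices;
                                     # catalytic column: -1 = Sec (TGA)
    catalytic_site: int | None
    omegas: dict                     # tag -> omega used
    kappa: float = 3.0
    convergent_sites: list = field(default_factory=list)
    injected_targets: dict = field(default_factory=dict)   # site -> aa
    multi_step: list = field(default_factory=list)         # (site, branch)
    focal_branch: int | None = None

    def aa_state(self, node: int, site: int) -> str:
        s = self.node_states[node, site]
        if site == self.catalytic_site:
            return "U" if s < 0 else GENETIC_CODE.aa[s]
        return GENETIC_CODE.aa[s]

    def aa_events(self, branches=None, include_catalytic=False):
        """True amino-acid substitutions: (branch, site, anc, der)."""
        tree = self.tree
        branches = branches if branches is not None else tree.branches
        out = []
        for b in branches:
            p = tree.parent[b]
            for s in range(self.node_states.shape[1]):
                if s == self.catalytic_site and not include_catalytic:
                    continue
                a, d = self.aa_state(p, s), self.aa_state(b, s)
                if a != d:
                    out.append((b, s, a, d))
        return out

    def codon_events(self, branches=None):
        tree = self.tree
        branches = branches if branches is not None else tree.branches
        out = []
        for b in branches:
            p = tree.parent[b]
            diff = np.nonzero(self.node_states[p] != self.node_states[b])[0]
            out.extend((b, int(s)) for s in diff)
        return out

    def focal_change_sites(self) -> list[int]:
        return sorted({s for (_, s, _, _) in self.aa_events([self.focal_branch])})


# ----------------------------------------------------------------------
def _pi_from_position_freqs(pos_freqs: np.ndarray) -> np.ndarray:
    nuc_idx = {n: k for k, n in enumerate("ACGT")}
    pi = np.array([
        pos_freqs[0][nuc_idx[c[0]]] * pos_freqs[1][nuc_idx[c[1]]] *
        pos_freqs[2][nuc_idx[c[2]]]
        for c in GENETIC_CODE.codons
    ])
    return pi / pi.sum()


def random_tagged_tree(n_taxa: int, n_exchange: int, rng,
                       height: float = 0.25) -> PhyloTree:
    """Random birth-death topology with tags: ``n_exchange`` mutually
    independent branches are tagged EXCHANGE, their descendants INHERITED
    and everything else SEC."""
    import dendropy
    from dendropy.simulate import treesim

    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n_taxa)])
    dtree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.2, taxon_namespace=taxa,
        num_extant_tips=n_taxa,
        rng=__import__("random").Random(int(rng.integers(2**31))),
    )
    dtree.seed_node.edge.length = 0.0
    depth = max(leaf.distance_from_root() for leaf in dtree.leaf_node_iter())
    for e in dtree.preorder_edge_iter():
        if e.length is not None:
            e.length = e.length / depth * height
    tree = PhyloTree.from_dendropy(dtree)
    from .trees import label_internal_nodes

    tree = label_internal_nodes(tree)
    # pick mutually independent exchange branches (prefer non-root-adjacent)
    candidates = [b for b in tree.branches]
    rng.shuffle(candidates)
    chosen: list[int] = []
    for b in candidates:
        if len(chosen) == n_exchange:
            break
        if any(tree.is_ancestral(b, c) or tree.is_ancestral(c, b)
               for c in chosen):
            continue
        chosen.append(b)
    if len(chosen) < n_exchange:
        raise RuntimeError("could not place the requested exchange branches")
    for b in tree.branches:
        tree.tags[b] = SEC
    for b in chosen:
        tree.tags[b] = EXCHANGE
        for d in tree.subtree_nodes(b):
            if d != b:
                tree.tags[d] = INHERITED
    tree.validate_tags()
    return tree


# ----------------------------------------------------------------------
def _cys_nodes(tree: PhyloTree) -> set[int]:
    """Nodes on or below an EXCHANGE branch (carry Cys at the catalytic site)."""
    out: set[int] = set()
    for b in tree.tagged(EXCHANGE):
        out.update(tree.subtree_nodes(b))
    return out


def simulate_codon_dataset(cfg: ScenarioConfig, rng=None):
    """Simulate a base dataset (no injection).

    Returns (CodonAlignment, PhyloTree, GroundTruth).  The catalytic
    column is not simulated: it is TGA (Sec) above/outside the exchange
    branches and TGC (Cys) on and below them, recorded as -1 / TGC index
    in the truth states.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    tree = cfg.tree if cfg.tree is not None else random_tagged_tree(
        cfg.n_taxa, cfg.n_exchange, rng)
    tree.validate_tags()
    n_codons = cfg.total_codons
    pi = _pi_from_position_freqs(cfg.position_freqs)
    eigs = {tag: ReversibleEigen(build_gy94_matrix(cfg.kappa, w, pi), pi)
            for tag, w in cfg.omegas.items()}
    cum = {b: np.cumsum(eigs[tree.tags[b]].P(float(tree.lengths[b])), axis=1)
           for b in tree.branches}

    states = np.empty((tree.n_nodes, n_codons), dtype=int)
    states[tree.root] = rng.choice(GENETIC_CODE.n, size=n_codons, p=pi)
    for v in reversed(tree.postorder()):
        if v == tree.root:
            continue
        rows = cum[v][states[tree.parent[v]]]
        u = rng.random(n_codons)
        states[v] = (u[:, None] > rows).sum(axis=1)

    cys = _cys_nodes(tree)
    cat = cfg.catalytic_site
    cys_idx = GENETIC_CODE.index[CYS_CODON]
    for v in range(tree.n_nodes):
        states[v, cat] = cys_idx if v in cys else -1

    truth = GroundTruth(
        tree=tree, node_states=states, catalytic_site=cat,
        omegas=dict(cfg.omegas), kappa=cfg.kappa,
        focal_branch=_focal_branch_id(tree, cfg),
    )
    aln = _alignment_from_states(tree, states, cat)
    return aln, tree, truth


def _focal_branch_id(tree: PhyloTree, cfg: ScenarioConfig) -> int:
    if cfg.focal_branch is not None:
        return tree.node_by_name(cfg.focal_branch)
    ex = tree.tagged(EXCHANGE)
    if not ex:
        raise ValueError("tree has no EXCHANGE branch")
    # prefer the exchange branch subtending the most taxa
    return max(ex, key=lambda b: len(tree.leaf_set_below(b)))


def _alignment_from_states(tree: PhyloTree, states: np.ndarray,
                           cat: int | None) -> CodonAlignment:
    taxa = [tree.names[i] for i in tree.leaves]
    rows = []
    for i in tree.leaves:
        row = [GENETIC_CODE.codons[s] if s >= 0 else SEC_CODON
               for s in states[i]]
        rows.append(row)
    return CodonAlignment(taxa, np.array(rows, dtype="<U3"), cat)


# ----------------------------------------------------------------------
def _resimulate_site_below(tree, states, branch, site, cum, rng):
    """Redraw the states at one site for all descendants of ``branch``."""
    order = [v for v in reversed(tree.postorder())]
    below = set(tree.subtree_nodes(branch)) - {branch}
    for v in order:
        if v not in below:
            continue
        row = cum[v][states[tree.parent[v], site]]
        states[v, site] = int((rng.random() > row).sum())


def _codons_of_aa(aa: str) -> list[int]:
    return [i for i, a in enumerate(GENETIC_CODE.aa) if a == aa]


def _single_step(i: int, j: int) -> bool:
    return bool(GENETIC_CODE.single[i, j])


def inject_convergence(aln: CodonAlignment, tree: PhyloTree,
                       truth: GroundTruth, n_sites: int, branches=None,
                       rng=None, sites=None):
    """Force ``n_sites`` convergent substitutions across the given
    (EXCHANGE by default) branches.

    At each chosen site every designated branch is switched to the same
    derived amino acid, using a codon one nucleotide step from the
    parent's codon where possible (otherwise the (site, branch) pair is
    recorded in ``truth.multi_step``); descendant states at that site are
    re-simulated from the new state.  Returns (alignment, truth) updated.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    branches = list(branches) if branches is not None else tree.tagged(EXCHANGE)
    if n_sites == 0:
        return aln, truth
    states = truth.node_states
    n_codons = states.shape[1]
    eligible = [s for s in range(n_codons)
                if s != truth.catalytic_site and s not in truth.convergent_sites]
    if sites is None:
        if n_sites > len(eligible):
            raise ValueError("not enough eligible sites for injection")
        sites = list(rng.choice(eligible, size=n_sites, replace=False))
    else:
        sites = list(sites)[:n_sites]

    pi = _recover_pi(states)
    eigs = {tag: ReversibleEigen(build_gy94_matrix(truth.kappa, w, pi), pi)
            for tag, w in truth.omegas.items()}
    cum = {b: np.cumsum(eigs[tree.tags[b]].P(float(tree.lengths[b])), axis=1)
           for b in tree.branches}

    for site in sites:
        parent_codons = {b: int(states[tree.parent[b], site]) for b in branches}
        parent_aas = {GENETIC_CODE.aa[c] for c in parent_codons.values()}
        candidates = []
        for aa in sorted(set(GENETIC_CODE.aa) - parent_aas):
            reach = sum(
                any(_single_step(pc, cj) for cj in _codons_of_aa(aa))
                for pc in parent_codons.values()
            )
            candidates.append((reach, aa))
        best = max(r for r, _ in candidates)
        target_aa = str(rng.choice([aa for r, aa in candidates if r == best]))
        truth.injected_targets[int(site)] = target_aa
        for b in branches:
            pc = parent_codons[b]
            single = [cj for cj in _codons_of_aa(target_aa)
                      if _single_step(pc, cj)]
            if single:
                new = int(rng.choice(single))
            else:
                new = int(rng.choice(_codons_of_aa(target_aa)))
                truth.multi_step.append((int(site), int(b)))
            states[b, site] = new
            _resimulate_site_below(tree, states, b, site, cum, rng)
        truth.convergent_sites.append(int(site))
    truth.convergent_sites.sort()
    return _alignment_from_states(tree, states, truth.catalytic_site), truth


def _recover_pi(states: np.ndarray) -> np.ndarray:
    flat = states.ravel()
    flat = flat[flat >= 0]
    counts = np.bincount(flat, minlength=GENETIC_CODE.n).astype(float) + 0.5
    return counts / counts.sum()


def force_focal_changes(aln: CodonAlignment, tree: PhyloTree,
                        truth: GroundTruth, n_total: int, rng=None):
    """Top up amino-acid changes on the focal branch to ``n_total`` sites
    by forcing focal-only substitutions at random eligible sites."""
    rng = np.random.default_rng(0) if rng is None else rng
    focal = truth.focal_branch
    states = truth.node_states
    current = set(truth.focal_change_sites())
    need = n_total - len(current)
    if need <= 0:
        return aln, truth
    n_codons = states.shape[1]
    eligible = [s for s in range(n_codons)
                if s != truth.catalytic_site and s not in current
                and s not in truth.convergent_sites]
    chosen = rng.choice(eligible, size=need, replace=False)
    pi = _recover_pi(states)
    eigs = {tag: ReversibleEigen(build_gy94_matrix(truth.kappa, w, pi), pi)
            for tag, w in truth.omegas.items()}
    cum = {b: np.cumsum(eigs[tree.tags[b]].P(float(tree.lengths[b])), axis=1)
           for b in tree.branches}
    for site in chosen:
        pc = int(states[tree.parent[focal], site])
        pa = GENETIC_CODE.aa[pc]
        single = [j for j in range(GENETIC_CODE.n)
                  if _single_step(pc, j) and GENETIC_CODE.aa[j] != pa]
        new = int(rng.choice(single)) if single else int(
            rng.choice([j for j in range(GENETIC_CODE.n)
                        if GENETIC_CODE.aa[j] != pa]))
        states[focal, site] = new
        _resimulate_site_below(tree, states, focal, site, cum, rng)
    return _alignment_from_states(tree, states, truth.catalytic_site), truth


# ----------------------------------------------------------------------
GPX6_TREE_NEWICK = (
    "((((((((mouse:0.040,rat:0.045)Murinae:0.030,golden_hamster:0.060)"
    "Muridae:0.020,prairie_vole:0.070)Eumuroida:0.060,jerboa:0.100)"
    "Myomorpha:0.030,(squirrel:0.090,guinea_pig:0.110)Sciuromorpha:0.020)"
    "Rodentia:0.020,rabbit:0.120)Glires:0.020,((((human:0.020,chimp:0.020)"
    "Hominini:0.020,macaque:0.040)Catarrhini:0.025,(marmoset:0.030,"
    "squirrel_monkey:0.030)Platyrrhini:0.050)Simiiformes:0.015,"
    "bushbaby:0.110)Primates:0.030)Euarchontoglires:0.025,"
    "(((dog:0.060,cat:0.060)Carnivora:0.030,(horse:0.080,(cow:0.060,"
    "pig:0.060)Artiodactyla:0.025)Ungulata:0.015)Ferungulata:0.020,"
    "(hedgehog:0.140,shrew:0.150)Eulipotyphla:0.030)Laurasiatheria:0.025,"
    "elephant:0.160)Mammalia;"
)

#: the five independent Sec-loss branches: each separated from the others
#: by at least two Sec-retaining lineages, so the five losses are the
#: unambiguous parsimony reading of the catalytic character
GPX6_EXCHANGE_BRANCHES = (
    "Eumuroida", "rabbit", "Platyrrhini", "hedgehog", "elephant")


def gpx6_tagged_tree() -> PhyloTree:
    tree = PhyloTree.from_newick(GPX6_TREE_NEWICK, is_path=False)
    for b in tree.branches:
        tree.tags[b] = SEC
    for name in GPX6_EXCHANGE_BRANCHES:
        b = tree.node_by_name(name)
        tree.tags[b] = EXCHANGE
        for d in tree.subtree_nodes(b):
            if d != b:
                tree.tags[d] = INHERITED
    tree.validate_tags()
    return tree


def gpx6_scenario(seed: int = 0) -> ScenarioConfig:
    """Packaged preset emulating the 22-mammal GPX6 study conditions:
    five independent Sec-to-Cys exchange branches, omega = 0.217 (Sec) /
    0.370 (exchange) / 0.279 (inherited), domains of 39/113/65 codons,
    25 focal-branch changes of which 14 are convergent across the
    exchange lineages."""
    return ScenarioConfig(
        tree=gpx6_tagged_tree(),
        n_taxa=22,
        n_exchange=5,
        focal_branch="Eumuroida",
        seed=seed,
    )


def build_dataset(cfg: ScenarioConfig):
    """Simulate, inject convergence and top up focal changes per config.

    Returns (CodonAlignment, PhyloTree, GroundTruth).
    """
    rng = np.random.default_rng(cfg.seed)
    aln, tree, truth = simulate_codon_dataset(cfg, rng=rng)
    if cfg.n_injected:
        aln, truth = inject_convergence(aln, tree, truth, cfg.n_injected,
                                        rng=rng)
    if cfg.n_focal_changes:
        aln, truth = force_focal_changes(aln, tree, truth,
                                         cfg.n_focal_changes, rng=rng)
    return aln, tree, truth


def emit_fixture(cfg: ScenarioConfig, outdir):
    """Write FASTA + Newick + tag/domain/truth tables for a dataset."""
    import pathlib

    import pandas as pd

    from .io import write_branch_tags

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aln, tree, truth = build_dataset(cfg)
    aln.write_fasta(outdir / "alignment.fasta")
    tree.write_newick(outdir / "tree.nwk")
    write_branch_tags(tree, outdir / "branch_tags.tsv")
    cfg.domains().write_tsv(outdir / "domains.tsv")
    pd.DataFrame({
        "site": truth.convergent_sites,
        "target_aa": [truth.injected_targets[s] for s in truth.convergent_sites],
    }).to_csv(outdir / "truth_convergent_sites.tsv", sep="\t", index=False)
    return aln, tree, truth
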