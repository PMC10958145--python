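"""Convergent and parallel substitution detection between branch pairs.

Observed events come from MAP ancestral states at branch endpoints; the
expected counts integrate the ancestral posteriors against the model's
transition probabilities (treating the two ancestors as independent,
the usual pairwise approximation).  A site where two branches end in the
same derived residue is *parallel* when the ancestral residues agree and
*convergent* when they differ; reports use "convergent sites" for the
union of the two classes while keeping them distinguishable.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .aamodels import AA_ORDER, AminoAcidModel, encode_protein, jtt
from .asr import AncestralReconstruction
from .io import DomainPartition
from .trees import PhyloTree

#: default physicochemical similarity grouping for the "similar residue" class
DEFAULT_SIMILARITY_GROUPS = (
    "AVLIMC", "FWY", "STNQ", "DE", "KRH", "G", "P",
)


@dataclass(frozen=True)
class SubstitutionEvent:
    branch: int          # node id owning the branch
    site: int
    ancestral: int       # state index at the parent endpoint
    derived: int         # state index at the child endpoint

    @property
    def label(self) -> str:
        return f"{AA_ORDER[self.ancestral]}{self.site}{AA_ORDER[self.derived]}"


@dataclass
class ConvergencePair:
    branches: tuple[int, int]
    parallel_sites: list[int]
    convergent_sites: list[int]
    similar_sites: list[int]
    expected_parallel: float = np.nan
    expected_convergent: float = np.nan
    poisson_p: float = np.nan

    @property
    def observed(self) -> int:
        return len(self.parallel_sites) + len(self.convergent_sites)

    @property
    def expected(self) -> float:
        return self.expected_parallel + self.expected_convergent

    @property
    def all_sites(self) -> list[int]:
        return sorted(set(self.parallel_sites) | set(self.convergent_sites))


@dataclass
class ConvergenceReport:
    focal_branch: int | None
    focal_sites: list[int]                    # sites changing on the focal branch
    focal_convergent: list[int]               # subset in the convergent-site set
    domain_counts: dict[str, int]
    domain_percent: dict[str, float]
    selected_sites: list[int] = field(default_factory=list)
    pairs: list[ConvergencePair] = field(default_factory=list)
    convergent_site_set: list[int] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(self.domain_counts.values())


# ----------------------------------------------------------------------
def extract_substitutions(rec: AncestralReconstruction, tree: PhyloTree,
                          branches=None, exclude_sites=()) -> list[SubstitutionEvent]:
    """One event per (branch, site) where the MAP endpoint states differ.

    Sites in ``exclude_sites`` (e.g. masked columns or the catalytic
    column) never yield events.  Leaf endpoints use the observed residue;
    leaf gaps yield no event.
    """
    branches = list(branches) if branches is not None else tree.branches
    excl = set(int(s) for s in exclude_sites)
    events = []
    for b in branches:
        if b == tree.root or b >= tree.n_nodes:
            raise ValueError(f"invalid branch node id {b}")
        parent = tree.parent[b]
        for site in range(rec.n_sites):
            if site in excl:
                continue
            a = rec.state_at(parent, site)
            d = rec.state_at(b, site)
            if a >= 0 and d >= 0 and a != d:
                events.append(SubstitutionEvent(b, site, a, d))
    return events


def _similar(a: int, b: int, groups) -> bool:
    aa, bb = AA_ORDER[a], AA_ORDER[b]
    return any(aa in g and bb in g for g in groups)


def detect_pairwise_convergence(events, branch_pairs, tree: PhyloTree,
                                similarity_groups=DEFAULT_SIMILARITY_GROUPS
                                ) -> list[ConvergencePair]:
    """Classify shared-site substitutions for each branch pair.

    Each pair must be phylogenetically independent (neither branch on the
    other's root path).  Sites with events on both branches are classified:
    same derived + same ancestral -> parallel; same derived + different
    ancestral -> convergent; different derived but in the same similarity
    group -> similar (reported separately, never in headline counts).
    """
    by_branch: dict[int, dict[int, SubstitutionEvent]] = {}
    for ev in events:
        by_branch.setdefault(ev.branch, {})[ev.site] = ev
    out = []
    for b1, b2 in branch_pairs:
        if b1 == b2:
            raise ValueError("branch pair must contain two distinct branches")
        if tree.is_ancestral(b1, b2) or tree.is_ancestral(b2, b1):
            raise ValueError(
                f"branches {tree.names[b1] or b1} and {tree.names[b2] or b2} "
                "are nested; pairs must be independent"
            )
        e1 = by_branch.get(b1, {})
        e2 = by_branch.get(b2, {})
        par, conv, sim = [], [], []
        for site in sorted(set(e1) & set(e2)):
            x, y = e1[site], e2[site]
            if x.derived == y.derived:
                (par if x.ancestral == y.ancestral else conv).append(site)
            elif _similar(x.derived, y.derived, similarity_groups):
                sim.append(site)
        out.append(ConvergencePair((b1, b2), par, conv, sim))
    return out


def exchange_pairs(tree: PhyloTree, tag: str = "EXCHANGE"):
    """All unordered independent pairs among branches carrying ``tag``."""
    branches = tree.tagged(tag)
    pairs = []
    for b1, b2 in itertools.combinations(branches, 2):
        if not tree.is_ancestral(b1, b2) and not tree.is_ancestral(b2, b1):
            pairs.append((b1, b2))
    return pairs


def convergent_site_union(pairs) -> list[int]:
    s: set[int] = set()
    for p in pairs:
        s.update(p.all_sites)
    return sorted(s)


# ----------------------------------------------------------------------
def expected_convergence_counts(rec: AncestralReconstruction, tree: PhyloTree,
                                pair: ConvergencePair,
                                model: AminoAcidModel | None = None,
                                exclude_sites=()) -> ConvergencePair:
    """Model-based expected parallel/convergent counts and a Poisson tail p.

    Per site, the probability that both branches substitute and end in the
    same state is accumulated from the ancestral posteriors and the
    model's transition matrices; the expectation is the sum over sites and
    the p-value is P(X >= observed) for X ~ Poisson(expected).
    """
    model = model or jtt()
    b1, b2 = pair.branches
    t1 = max(float(rec.branch_lengths[b1]), 0.0)
    t2 = max(float(rec.branch_lengths[b2]), 0.0)
    P1, P2 = model.P(t1), model.P(t2)
    excl = set(int(s) for s in exclude_sites)
    sites = [s for s in range(rec.n_sites) if s not in excl]

    def parent_post(b):
        p = tree.parent[b]
        if p in rec.node_ids:
            return rec.node_posterior(p)
        raise ValueError("branch parent has no posterior (is it the root?)")

    A = parent_post(b1)[sites]           # (n, 20)
    B = parent_post(b2)[sites]
    # u_k(x) = sum_{a != x} p_k(a) P_k(a, x): change-and-land-on-x probability
    U1 = A @ P1 - A * np.diag(P1)[None, :]
    U2 = B @ P2 - B * np.diag(P2)[None, :]
    e_total = float(np.sum(U1 * U2))
    # parallel part: both start from the same ancestral residue
    # sum_x sum_{a != x} p1(a) p2(a) P1(a,x) P2(a,x)
    W = A * B                             # (n, 20) joint same-ancestor weight
    PP = P1 * P2                          # (20, 20) elementwise
    par_land = W @ PP - W * np.diag(PP)[None, :]
    e_par = float(np.sum(par_land))
    e_conv = e_total - e_par
    lam = e_total
    obs = pair.observed
    if lam <= 0:
        p = 1.0 if obs == 0 else 0.0
    else:
        p = float(stats.poisson.sf(obs - 1, lam))
    pair.expected_parallel = e_par
    pair.expected_convergent = e_conv
    pair.poisson_p = p
    return pair


# ----------------------------------------------------------------------
def focal_branch_summary(events, convergent_sites, focal_branch: int,
                         domains: DomainPartition | None = None,
                         selection_posteriors=None,
                         percentile: float = 90.0,
                         percentile_region: tuple[int, int] | None = None,
                         pairs=None) -> ConvergenceReport:
    """Summarise convergence around one focal (Sec-loss) branch.

    Lists sites changing on the focal branch, flags those in the
    convergent-site set, tabulates the convergent-site set per domain, and
    (when per-site selection posteriors are supplied) flags sites whose
    posterior lies at or above the given percentile computed over
    ``percentile_region`` (midpoint interpolation).
    """
    conv = sorted(set(int(s) for s in convergent_sites))
    focal_sites = sorted({ev.site for ev in events if ev.branch == focal_branch})
    focal_conv = [s for s in focal_sites if s in conv]

    counts: dict[str, int] = {}
    if domains is not None:
        for name in domains.names:
            counts[name] = 0
        other = 0
        for s in conv:
            d = domains.domain_of_site(s)
            if d is None:
                other += 1
            else:
                counts[d] += 1
        if other:
            counts["other"] = other
    else:
        counts["all"] = len(conv)
    total = sum(counts.values())
    percent = {k: (100.0 * v / total if total else 0.0) for k, v in counts.items()}

    selected: list[int] = []
    if selection_posteriors is not None:
        post = np.asarray(selection_posteriors, dtype=float)
        if percentile_region is not None:
            s, e = percentile_region
            ref = post[s:e]
        else:
            ref = post
        cut = float(np.percentile(ref, percentile, method="midpoint"))
        selected = [int(s) for s in np.nonzero(post >= cut)[0]]

    return ConvergenceReport(
        focal_branch=focal_branch, focal_sites=focal_sites,
        focal_convergent=focal_conv, domain_counts=counts,
        domain_percent=percent, selected_sites=selected,
        pairs=list(pairs) if pairs else [], convergent_site_set=conv,
    )


# ----------------------------------------------------------------------
def ml_protein_distance(s1: np.ndarray, s2: np.ndarray,
                        model: AminoAcidModel) -> float:
    """Pairwise ML distance under the model (states -1 ignored)."""
    ok = (s1 >= 0) & (s2 >= 0)
    a, b = s1[ok], s2[ok]
    if len(a) == 0:
        return 0.0
    pairs, counts = np.unique(np.stack([a, b]), axis=1, return_counts=True)

    def nll(logt):
        P = model.P(float(np.exp(logt)))
        lik = model.pi[pairs[0]] * P[pairs[0], pairs[1]]
        return -float(np.sum(counts * np.log(np.maximum(lik, 1e-300))))

    res = optimize.minimize_scalar(nll, bounds=(np.log(1e-6), np.log(20.0)),
                                   method="bounded")
    t = float(np.exp(res.x))
    # prefer t ~ 0 when the sequences are identical
    if np.all(a == b) and nll(np.log(1e-6)) <= res.fun + 1e-9:
        t = 1e-6
    return t


def convergence_tree(protein_seqs: dict[str, str], sites=None,
                     model: AminoAcidModel | None = None) -> PhyloTree:
    """Neighbor-joining tree from ML distances on a site subset, rooted at
    the midpoint of the longest leaf-to-leaf path."""
    import skbio

    model = model or jtt()
    taxa, mat = encode_protein(protein_seqs)
    if len(taxa) < 4:
        raise ValueError("need at least 4 taxa")
    if sites is not None:
        sites = np.asarray(list(sites), dtype=int)
        if len(sites) < 1:
            raise ValueError("need at least one site")
        mat = mat[:, sites]
    n = len(taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = ml_protein_distance(mat[i], mat[j], model)
    if np.allclose(D, 0):
        warnings.warn("all pairwise distances are zero; tree is star-like")
        D = D + 1e-9
        np.fill_diagonal(D, 0.0)
    for i in range(n):
        for j in range(i + 1, n):
            if D[i, j] < 0:
                D[i, j] = D[j, i] = 0.0
    dm = skbio.DistanceMatrix(D, ids=taxa)
    tr = skbio.tree.nj(dm)
    for node in tr.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0  # NJ can emit small negatives
    tr = tr.root_at_midpoint()
    import io as _io

    buf = _io.StringIO()
    tr.write(buf, format="newick")
    return PhyloTree.from_newick(buf.getvalue(), is_path=False)


def clade_membership(tree: PhyloTree, taxa: set[str]) -> int:
    """Number of maximal clades of ``tree`` whose leaves all belong to
    ``taxa`` (1 = the set is monophyletic): walk top-down and count
    maximal all-inside subtrees."""
    taxa = set(taxa)
    count = 0
    stack = [tree.root]
    while stack:
        node = stack.pop()
        leaves = tree.leaf_set_below(node)
        if leaves and leaves <= taxa:
            count += 1
        else:
            stack.extend(tree.children[node])
    return count
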