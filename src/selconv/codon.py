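"""GY94-style codon substitution model with branch-partitioned dN/dS.

The rate matrix follows Goldman–Yang: single-nucleotide changes only,
target-codon frequency multiplier, kappa for transitions and omega for
nonsynonymous changes, scaled to one expected substitution per codon per
unit branch length.  Branches are grouped into ratio classes (one-ratio,
SEC/EXCHANGE/INHERITED partition, or free-ratio) and the likelihood is
maximised over kappa, the class omegas and all branch lengths, with
codon frequencies fixed at F3x4 counts from the analysed alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable
from scipy import linalg, optimize, stats

from .likelihood import PruningEngine, compress_patterns
from .trees import EXCHANGE, INHERITED, SEC, PhyloTree

NUCS = "ACGT"
TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class _GeneticCode:
    """Universal code restricted to the 61 sense codons, with the pair
    structure (single-nt neighbour, transition, nonsynonymous) precomputed."""

    def __init__(self):
        table = CodonTable.unambiguous_dna_by_id[1]
        self.stop_codons = tuple(table.stop_codons)
        self.codons = tuple(
            a + b + c
            for a in NUCS for b in NUCS for c in NUCS
            if a + b + c not in self.stop_codons
        )
        self.n = len(self.codons)  # 61
        self.index = {c: i for i, c in enumerate(self.codons)}
        self.aa = tuple(table.forward_table[c] for c in self.codons)
        n = self.n
        single = np.zeros((n, n), dtype=bool)
        is_ts = np.zeros((n, n), dtype=bool)
        nonsyn = np.zeros((n, n), dtype=bool)
        for i, ci in enumerate(self.codons):
            for j, cj in enumerate(self.codons):
                if i == j:
                    continue
                diff = [k for k in range(3) if ci[k] != cj[k]]
                if len(diff) != 1:
                    continue
                single[i, j] = True
                k = diff[0]
                is_ts[i, j] = (ci[k], cj[k]) in TRANSITIONS
                nonsyn[i, j] = self.aa[i] != self.aa[j]
        self.single = single
        self.is_transition = is_ts
        self.is_nonsyn = nonsyn

    def translate(self, codon: str) -> str:
        if codon in self.index:
            return self.aa[self.index[codon]]
        if codon == "TGA":
            return "U"  # selenocysteine readthrough; caller decides validity
        return "X"


GENETIC_CODE = _GeneticCode()


# ----------------------------------------------------------------------
def f3x4_frequencies(codon_matrix: np.ndarray) -> np.ndarray:
    """F3x4 codon frequencies from an (n_taxa, n_codons) matrix of codon
    state indices (-1 = missing).  Stop codons get zero frequency and the
    61 sense-codon frequencies are renormalised."""
    gc = GENETIC_CODE
    counts = np.zeros((3, 4))
    nuc_idx = {n: k for k, n in enumerate(NUCS)}
    flat = codon_matrix.ravel()
    flat = flat[flat >= 0]
    for s in flat:
        c = gc.codons[s]
        for pos in range(3):
            counts[pos, nuc_idx[c[pos]]] += 1
    if counts.sum() == 0:
        raise ValueError("no codons observed; cannot compute F3x4 frequencies")
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [freqs[0, nuc_idx[c[0]]] * freqs[1, nuc_idx[c[1]]] * freqs[2, nuc_idx[c[2]]]
         for c in gc.codons]
    )
    observed = np.bincount(flat, minlength=gc.n) > 0
    if np.any(pi[observed] <= 0):
        bad = [gc.codons[i] for i in np.nonzero(observed & (pi <= 0))[0]]
        raise ValueError(f"observed codons with zero F3x4 frequency: {bad}")
    return pi / pi.sum()


def build_gy94_matrix(kappa: float, omega: float, pi: np.ndarray,
                      scale: bool = True) -> np.ndarray:
    """GY94 rate matrix over the 61 sense codons.

    Off-diagonal q_ij is zero unless i and j differ at one nucleotide, and
    otherwise proportional to pi_j, times kappa for transitions and omega
    for nonsynonymous changes.  With ``scale`` the matrix is normalised to
    one expected substitution per codon (-sum pi_i q_ii = 1).
    """
    gc = GENETIC_CODE
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (gc.n,) or np.any(pi < 0):
        raise ValueError("pi must be 61 non-negative frequencies")
    Q = np.where(gc.single, np.tile(pi, (gc.n, 1)), 0.0)
    Q = Q * np.where(gc.is_transition, kappa, 1.0)
    Q = Q * np.where(gc.is_nonsyn, omega, 1.0)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if scale:
        rate = -float(pi @ np.diag(Q))
        if rate > 0:
            Q = Q / rate
    return Q


def transition_matrix(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = expm(Q t); rows sum to one, entries clipped at zero."""
    if t < 0:
        raise ValueError("branch length must be non-negative")
    P = linalg.expm(Q * t)
    return np.clip(P, 0.0, None)


class ReversibleEigen:
    """Spectral decomposition of a reversible rate matrix for fast P(t).

    Uses the symmetrisation B = D^{1/2} Q D^{-1/2} with D = diag(pi); valid
    whenever detailed balance pi_i q_ij = pi_j q_ji holds (GY94 and the
    empirical amino-acid models both satisfy it).
    """

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        self.Q = Q
        pi = np.maximum(np.asarray(pi, dtype=float), 1e-300)
        d = np.sqrt(pi)
        B = (Q * d[:, None]) / d[None, :]
        B = 0.5 * (B + B.T)
        lam, V = np.linalg.eigh(B)
        self.lam = lam
        self.left = V / d[:, None] * 1.0      # D^{-1/2} V
        self.right = (V * d[:, None]).T        # V^T D^{1/2}

    def P(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("branch length must be non-negative")
        P = (self.left * np.exp(self.lam * t)) @ self.right
        return np.clip(P, 0.0, None)

    def P_and_QP(self, t: float):
        P = self.P(t)
        return P, self.Q @ P

    def P_batch(self, ts: np.ndarray) -> np.ndarray:
        """Transition matrices for many branch lengths at once (B, n, n)."""
        ts = np.asarray(ts, dtype=float)
        expl = np.exp(self.lam[None, :] * ts[:, None])
        A = self.left[None, :, :] * expl[:, None, :]
        return np.clip(A @ self.right, 0.0, None)


# ----------------------------------------------------------------------
@dataclass
class CodonModelParams:
    """Parameters of a branch-partitioned GY94 model on a given tree."""

    kappa: float
    omegas: np.ndarray                 # one omega per ratio class
    branch_class: dict[int, int]       # node id -> ratio class index
    pi: np.ndarray                     # 61 codon frequencies
    lengths: np.ndarray                # per-node branch lengths (tree order)

    def omega_of_branch(self, node: int) -> float:
        return float(self.omegas[self.branch_class[node]])

    def validate(self):
        if self.kappa <= 0 or np.any(self.omegas < 0):
            raise ValueError("kappa must be > 0 and omegas >= 0")
        if abs(self.pi.sum() - 1.0) > 1e-8 or np.any(self.pi < 0):
            raise ValueError("pi must be a probability vector")


@dataclass
class ModelFit:
    params: CodonModelParams
    loglik: float
    n_free: int
    converged: bool
    scheme: str
    n_starts: int = 1
    message: str = ""
    class_names: list = field(default_factory=list)

    def omega_by_class_name(self) -> dict[str, float]:
        return {name: float(w) for name, w in zip(self.class_names, self.params.omegas)}


@dataclass
class LRTResult:
    lr: float
    df: int
    p: float


# ----------------------------------------------------------------------
def encode_codon_states(aln) -> np.ndarray:
    """Map a CodonAlignment to an (n_taxa, n_codons) index matrix.

    Gaps and ambiguous codons become -1.  Stop codons raise (the catalytic
    column must be excluded before model fitting).
    """
    gc = GENETIC_CODE
    mat = np.full(aln.codons.shape, -1, dtype=int)
    for i in range(aln.codons.shape[0]):
        for j in range(aln.codons.shape[1]):
            c = str(aln.codons[i, j]).upper()
            if c in gc.index:
                mat[i, j] = gc.index[c]
            elif c in gc.stop_codons:
                raise ValueError(
                    f"stop codon {c} at taxon {aln.taxa[i]!r}, codon column {j}; "
                    "exclude the catalytic column before model fitting"
                )
    return mat


def _branch_classes(tree: PhyloTree, scheme: str):
    branches = tree.branches
    if scheme == "one-ratio":
        return {b: 0 for b in branches}, ["all"]
    if scheme == "partition":
        order = [SEC, EXCHANGE, INHERITED]
        for b in branches:
            if tree.tags[b] not in order:
                raise ValueError("partition scheme requires SEC/EXCHANGE/INHERITED tags")
        return {b: order.index(tree.tags[b]) for b in branches}, order
    if scheme == "free-ratio":
        names = [tree.names[b] or f"node{b}" for b in branches]
        return {b: k for k, b in enumerate(branches)}, names
    raise ValueError(f"unknown scheme {scheme!r}")


def make_engine(aln, tree: PhyloTree):
    states = encode_codon_states(aln)
    order = {name: i for i, name in enumerate(aln.taxa)}
    missing = set(tree.leaf_names) - set(aln.taxa)
    if missing:
        raise ValueError(f"alignment lacks tree taxa: {sorted(missing)}")
    pats, weights, _ = compress_patterns(states)
    leaf_map = {i: pats[order[tree.names[i]]] for i in tree.leaves}
    engine = PruningEngine(tree, leaf_map, GENETIC_CODE.n, weights)
    return engine, states


def pruning_loglik(aln, tree: PhyloTree, params: CodonModelParams) -> float:
    params.validate()
    engine, _ = make_engine(aln, tree)
    return _loglik_engine(engine, tree, params)


def _loglik_engine(engine, tree, params: CodonModelParams) -> float:
    eigs = {}
    P = {}
    for b in tree.branches:
        k = params.branch_class[b]
        if k not in eigs:
            eigs[k] = ReversibleEigen(
                build_gy94_matrix(params.kappa, float(params.omegas[k]), params.pi),
                params.pi,
            )
        P[b] = eigs[k].P(max(params.lengths[b], 0.0))
    return engine.loglik(P, params.pi)


MIN_BRANCH = 1e-8


def fit_branch_model(aln, tree: PhyloTree, scheme: str = "one-ratio", *,
                     n_starts: int = 3, seed: int = 0, tol: float = 1e-8,
                     max_iter: int = 500, init: ModelFit | None = None) -> ModelFit:
    """Maximum-likelihood fit of the GY94 branch model.

    Branch lengths are free (expected substitutions per codon), codon
    frequencies are F3x4 counts from ``aln``, and the scheme selects the
    omega structure.  Optimisation is L-BFGS-B on log parameters with
    analytic branch-length gradients; ``n_starts`` runs are taken from
    perturbed starting points and the best retained.  ``init`` warm-starts
    the first run from a previous (typically nested) fit's solution.
    """
    engine, states = make_engine(aln, tree)
    pi = f3x4_frequencies(states)
    branch_class, class_names = _branch_classes(tree, scheme)
    branches = tree.branches
    n_cls = len(class_names)
    rng = np.random.default_rng(seed)

    t0 = np.array([max(tree.lengths[b], 0.02) for b in branches])
    kap_init, om_init = 2.0, np.full(n_cls, 0.3)
    if init is not None:
        kap_init = init.params.kappa
        w = init.params.omegas
        om_init = (np.full(n_cls, float(w[0])) if len(w) == 1
                   else np.resize(np.asarray(w, float), n_cls))
        t0 = np.array([max(init.params.lengths[b], MIN_BRANCH) for b in branches])

    def unpack(x):
        kappa = np.exp(x[0])
        omegas = np.exp(x[1:1 + n_cls])
        lengths = np.zeros(tree.n_nodes)
        lengths[branches] = np.exp(x[1 + n_cls:])
        return kappa, omegas, lengths

    central_fd = n_cls <= 8
    h = 1e-5

    def negloglik_only(x):
        kappa, omegas, lengths = unpack(x)
        params = CodonModelParams(kappa, omegas, branch_class, pi, lengths)
        return -_loglik_engine(engine, tree, params)

    def negloglik_grad(x):
        kappa, omegas, lengths = unpack(x)
        eigs = [ReversibleEigen(build_gy94_matrix(kappa, float(w), pi), pi)
                for w in omegas]
        P, QP = {}, {}
        for b in branches:
            P[b], QP[b] = eigs[branch_class[b]].P_and_QP(lengths[b])
        ll, gt = engine.branch_gradient(P, QP, pi)
        grad = np.zeros_like(x)
        for j, b in enumerate(branches):
            grad[1 + n_cls + j] = gt[b] * lengths[b]  # chain rule, log scale
        # finite differences for kappa and class omegas
        for idx in range(1 + n_cls):
            xp = x.copy()
            xp[idx] += h
            fp = -negloglik_only(xp)
            if central_fd:
                xm = x.copy()
                xm[idx] -= h
                fm = -negloglik_only(xm)
                grad[idx] = (fp - fm) / (2 * h)
            else:
                grad[idx] = (fp - ll) / h
        return -ll, -grad

    lb = np.concatenate([[np.log(1e-3)], np.full(n_cls, np.log(1e-6)),
                         np.full(len(branches), np.log(MIN_BRANCH))])
    ub = np.concatenate([[np.log(200.0)], np.full(n_cls, np.log(60.0)),
                         np.full(len(branches), np.log(30.0))])

    best = None
    for s in range(max(1, n_starts)):
        if s == 0:
            kap0, om0 = kap_init, om_init
            tt0 = t0
        else:
            kap0 = float(np.exp(rng.normal(np.log(2.0), 0.5)))
            om0 = np.exp(rng.normal(np.log(0.3), 0.5, n_cls))
            tt0 = t0 * np.exp(rng.normal(0, 0.3, len(branches)))
        x0 = np.concatenate([[np.log(kap0)], np.log(om0), np.log(np.maximum(tt0, MIN_BRANCH))])
        x0 = np.clip(x0, lb, ub)
        res = optimize.minimize(
            negloglik_grad, x0, jac=True, method="L-BFGS-B",
            bounds=list(zip(lb, ub)),
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-6},
        )
        if best is None or res.fun < best.fun:
            best = res

    kappa, omegas, lengths = unpack(best.x)
    params = CodonModelParams(kappa, omegas, branch_class, pi, lengths)
    n_free = 1 + n_cls + len(branches)
    converged = bool(best.success) or best.status == 1
    if not converged:
        warnings.warn(f"branch-model fit did not fully converge: {best.message}")
    return ModelFit(params, -float(best.fun), n_free, converged, scheme,
                    n_starts=n_starts, message=str(best.message),
                    class_names=list(class_names))


# ----------------------------------------------------------------------
def lrt(null_fit: ModelFit, alt_fit: ModelFit, tol: float = 1e-4) -> LRTResult:
    """Likelihood-ratio test of nested branch models (chi-square reference)."""
    df = alt_fit.n_free - null_fit.n_free
    if df <= 0:
        raise ValueError("alternative must have more free parameters than null")
    lr = 2.0 * (alt_fit.loglik - null_fit.loglik)
    if lr < -tol:
        warnings.warn(
            f"alternative log-likelihood below null by {-lr / 2:.4g}; "
            "optimisation likely stopped early — consider more restarts"
        )
    lr = max(lr, 0.0)
    return LRTResult(lr=lr, df=df, p=float(stats.chi2.sf(lr, df)))


def branch_rate_table(fit: ModelFit, tree: PhyloTree):
    """Per-branch omega, dN, dS and amino-acid substitution rate.

    dN and dS follow the usual decomposition of the fitted flux into
    nonsynonymous and synonymous parts, with site proportions taken from
    the neutral (omega=1) matrix at the fitted kappa.  ``aa_rate`` is the
    expected number of amino-acid substitutions per codon site (t times
    the nonsynonymous fraction of the flux), the natural branch length for
    protein-level simulation.
    """
    gc = GENETIC_CODE
    p = fit.params
    Q1 = build_gy94_matrix(p.kappa, 1.0, p.pi)
    flowN1 = float(np.sum(p.pi[:, None] * Q1 * gc.is_nonsyn))
    fN = flowN1  # Q1 scaled to unit total flux
    rows = []
    for b in tree.branches:
        w = p.omega_of_branch(b)
        Q = build_gy94_matrix(p.kappa, w, p.pi)
        rhoN = float(np.sum(p.pi[:, None] * Q * gc.is_nonsyn))
        t = float(p.lengths[b])
        rows.append({
            "branch": tree.names[b] or f"node{b}",
            "node": b,
            "tag": tree.tags[b],
            "t": t,
            "omega": w,
            "dN": t * rhoN / (3.0 * fN) if fN > 0 else 0.0,
            "dS": t * (1.0 - rhoN) / (3.0 * (1.0 - fN)) if fN < 1 else 0.0,
            "aa_rate": t * rhoN,
        })
    return rows
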