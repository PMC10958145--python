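"""One-command orchestration: mask -> branch-model LRTs per region ->
ancestral reconstruction -> convergence (observed + expected) ->
simulation null -> branch-site + enrichment -> convergence tree.

Every stage is an importable function; ``run_pipeline`` wires them
together, emits TSV/JSON artifacts and a manifest with the seed and
input hashes so a run can be reproduced bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
import time
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import __version__
from .aamodels import jtt
from .asr import marginal_asr, node_accuracy
from .branchsite import enrichment_test, fit_branch_site_pair, site_posteriors
from .codon import branch_rate_table, fit_branch_model, lrt
from .convergence import (convergence_tree, clade_membership,
                          convergent_site_union, detect_pairwise_convergence,
                          exchange_pairs, expected_convergence_counts,
                          extract_substitutions, focal_branch_summary)
from .io import (CodonAlignment, ColumnConfidence, DomainPartition,
                 apply_column_mask, extract_region, load_inputs)
from .simulate import SimulationConfig, convergence_null_test
from .trees import EXCHANGE, PhyloTree

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Settings for a full analysis run."""

    alignment: str | None = None
    tree: str | None = None
    tags: str | None = None
    domains: str | None = None
    confidence: str | None = None
    catalytic_site: int | None = None
    scenario_seed: int | None = None      # generate the preset dataset instead
    mask_threshold: float = 0.95
    regions: tuple = ("full",)            # "auto" in run_pipeline adds domains
    n_replicates: int = 1000
    percentile: float = 90.0
    dn_source: str = "free-ratio"         # or "partition"
    n_starts: int = 3
    seed: int = 0
    outdir: str | None = None

    def validate(self):
        if not (0 <= self.mask_threshold <= 1):
            raise ValueError("mask threshold must be in [0, 1]")
        if self.n_replicates < 1:
            raise ValueError("replicate count must be >= 1")
        if self.scenario_seed is None:
            for f in (self.alignment, self.tree, self.tags, self.domains):
                if f is None or not pathlib.Path(f).exists():
                    raise FileNotFoundError(f"input file missing: {f}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(pathlib.Path(path).read_bytes())
    return h.hexdigest()


def _load(cfg: PipelineConfig):
    if cfg.scenario_seed is not None:
        from .synthetic import build_dataset, gpx6_scenario

        scen = gpx6_scenario(seed=cfg.scenario_seed)
        aln, tree, truth = build_dataset(scen)
        return aln, tree, scen.domains(), truth
    aln, tree, dom = load_inputs(cfg.alignment, cfg.tree, cfg.tags,
                                 cfg.domains, cfg.catalytic_site)
    return aln, tree, dom, None


def fit_region_models(aln: CodonAlignment, tree: PhyloTree,
                      dom: DomainPartition, regions, n_starts=3, seed=0):
    """Branch-model LRT (one-ratio vs SEC/EXCHANGE/INHERITED partition)
    for each region; returns rows shaped like a per-region summary table."""
    rows, fits = [], {}
    for k, region in enumerate(regions):
        sub = extract_region(aln, dom, region, exclude_catalytic=True)
        null = fit_branch_model(sub, tree, "one-ratio",
                                n_starts=n_starts, seed=seed + 10 * k)
        alt = fit_branch_model(sub, tree, "partition",
                               n_starts=n_starts, seed=seed + 10 * k + 1)
        res = lrt(null, alt)
        w = alt.omega_by_class_name()
        rows.append({
            "region": region,
            "n_codons": sub.n_codons,
            "omega_SEC": w["SEC"],
            "omega_EXCHANGE": w["EXCHANGE"],
            "omega_INHERITED": w["INHERITED"],
            "omega_all": null.params.omegas[0],
            "LR": res.lr, "df": res.df, "p": res.p,
        })
        fits[region] = (null, alt, res)
    return rows, fits


def protein_lengths_from_fit(fit, tree: PhyloTree) -> np.ndarray:
    """Per-node amino-acid substitution rates (dN-scale branch lengths)."""
    lengths = np.zeros(tree.n_nodes)
    for row in branch_rate_table(fit, tree):
        lengths[row["node"]] = max(row["aa_rate"], 1e-8)
    return lengths


def run_pipeline(cfg: PipelineConfig) -> dict:
    cfg.validate()
    t_start = time.time()
    seeds = np.random.SeedSequence(cfg.seed).spawn(6)
    stage_seed = [int(s.generate_state(1)[0] % (2**31)) for s in seeds]
    outdir = pathlib.Path(cfg.outdir) if cfg.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}}

    def _stage(name):
        report["stages"][name] = round(time.time() - t_start, 2)
        log.info("stage %s done at %.1fs", name, time.time() - t_start)

    aln, tree, dom, truth = _load(cfg)

    # ---- mask ---------------------------------------------------------
    if cfg.confidence is not None:
        conf = ColumnConfidence.read_tsv(cfg.confidence)
        aln, dom2 = apply_column_mask(aln, conf, cfg.mask_threshold, dom)
        dom = dom2 or dom
    _stage("mask")

    regions = list(cfg.regions)
    if regions == ["auto"] or regions == ("auto",):
        regions = ["full"] + dom.names

    # ---- branch-model LRTs -------------------------------------------
    rows, fits = fit_region_models(aln, tree, dom, regions,
                                   n_starts=cfg.n_starts, seed=stage_seed[0])
    table1 = pd.DataFrame(rows)
    if outdir is not None:
        table1.to_csv(outdir / "region_models.tsv", sep="\t", index=False)
    _stage("fit")

    # ---- dN branch lengths for protein-level work --------------------
    full = extract_region(aln, dom, "full", exclude_catalytic=True)
    if cfg.dn_source == "free-ratio":
        dn_fit = fit_branch_model(full, tree, "free-ratio", n_starts=1,
                                  seed=stage_seed[1])
    else:
        dn_fit = fits["full"][1]
    aa_lengths = protein_lengths_from_fit(dn_fit, tree)
    prot_tree = tree.with_lengths(aa_lengths)
    if outdir is not None:
        pd.DataFrame(branch_rate_table(dn_fit, tree)).to_csv(
            outdir / "branch_rates.tsv", sep="\t", index=False)

    # ---- ancestral reconstruction ------------------------------------
    prot = aln.protein()
    model = jtt()
    cat = aln.catalytic_site
    excl = [cat] if cat is not None else []
    rec = marginal_asr(prot, prot_tree, model, optimize_lengths=False)
    acc = node_accuracy(rec, sites=[s for s in range(rec.n_sites)
                                    if s not in excl])
    if outdir is not None:
        rec.to_fasta(outdir / "ancestral_map.fasta")
        pd.DataFrame(sorted(acc.items()), columns=["node", "accuracy"]).to_csv(
            outdir / "node_accuracy.tsv", sep="\t", index=False)
    _stage("asr")

    # ---- convergence --------------------------------------------------
    pairs = exchange_pairs(tree)
    ex_branches = tree.tagged(EXCHANGE)
    events = extract_substitutions(rec, tree, ex_branches, exclude_sites=excl)
    cps = detect_pairwise_convergence(events, pairs, tree)
    for cp in cps:
        expected_convergence_counts(rec, tree, cp, model, exclude_sites=excl)
    union = convergent_site_union(cps)
    focal = truth.focal_branch if truth is not None else max(
        ex_branches, key=lambda b: len(tree.leaf_set_below(b)))
    summary = focal_branch_summary(events, union, focal, dom, pairs=cps)
    if outdir is not None:
        pd.DataFrame([{
            "branch_1": tree.names[c.branches[0]],
            "branch_2": tree.names[c.branches[1]],
            "parallel": len(c.parallel_sites),
            "convergent": len(c.convergent_sites),
            "similar": len(c.similar_sites),
            "expected_parallel": c.expected_parallel,
            "expected_convergent": c.expected_convergent,
            "poisson_p": c.poisson_p,
            "sites": ",".join(map(str, c.all_sites)),
        } for c in cps]).to_csv(outdir / "pair_convergence.tsv", sep="\t",
                                index=False)
    _stage("converge")

    # ---- simulation null ----------------------------------------------
    root_seq = rec.map_sequence(tree.root)
    null_tree = prot_tree
    sim_cfg = SimulationConfig(null_tree, rec.n_sites, model, root_seq,
                               cfg.n_replicates, seed=stage_seed[2])
    null = convergence_null_test(sim_cfg, null_tree, len(union), pairs=pairs,
                                 exclude_sites=excl)
    if outdir is not None:
        pd.DataFrame({"replicate_count": null.counts}).to_csv(
            outdir / "null_counts.tsv", sep="\t", index=False)
    _stage("null")

    # ---- branch-site + enrichment -------------------------------------
    gpx_name = next((n for n in dom.names if "GPX" in n.upper()), dom.names[0])
    gpx = extract_region(aln, dom, gpx_name, exclude_catalytic=True)
    fg_names = [tree.names[b] for b in ex_branches]
    bs_kw = {}
    if gpx_name in fits:   # reuse the region's one-ratio solution
        base = fits[gpx_name][0]
        bs_kw = dict(lengths=base.params.lengths, kappa0=base.params.kappa)
    alt_bs, null_bs, bs_lrt = fit_branch_site_pair(
        gpx, tree, fg_names, n_starts=1, seed=stage_seed[3], **bs_kw)
    post = site_posteriors(gpx, tree, alt_bs)
    # map convergent sites into GPX-region coordinates
    gpx_cols = list(gpx.column_map)
    conv_in_gpx = [gpx_cols.index(s) for s in union if s in gpx_cols]
    other_in_gpx = [i for i in range(gpx.n_codons) if i not in conv_in_gpx]
    enr = None
    if conv_in_gpx and other_in_gpx:
        enr = enrichment_test(post.values, conv_in_gpx, other_in_gpx,
                              alternative="greater")
    flagged = post.percentile_flags(cfg.percentile)
    selected_sites = [int(gpx.column_map[i]) for i in np.nonzero(flagged)[0]]
    if outdir is not None:
        pd.DataFrame({
            "gpx_site": np.arange(gpx.n_codons),
            "alignment_site": gpx.column_map,
            "posterior_selected": post.values,
        }).to_csv(outdir / "site_posteriors.tsv", sep="\t", index=False)
    _stage("branchsite")

    # ---- convergence tree ---------------------------------------------
    conv_tree = None
    n_clades = None
    if len(union) >= 1 and aln.n_taxa >= 4:
        conv_tree = convergence_tree(prot, sites=union)
        cys_taxa = set()
        for b in ex_branches:
            cys_taxa |= tree.leaf_set_below(b)
        n_clades = clade_membership(conv_tree, cys_taxa)
        if outdir is not None:
            conv_tree.write_newick(outdir / "convergence_tree.nwk")
    _stage("tree")

    report.update({
        "table1": rows,
        "node_accuracy": acc,
        "pairs": [{
            "branches": (tree.names[c.branches[0]], tree.names[c.branches[1]]),
            "observed": c.observed,
            "expected": c.expected,
            "poisson_p": c.poisson_p,
        } for c in cps],
        "convergent_sites": union,
        "focal": {
            "branch": tree.names[focal],
            "n_sites_changed": len(summary.focal_sites),
            "n_convergent": len(summary.focal_convergent),
            "domain_counts": summary.domain_counts,
            "domain_percent": summary.domain_percent,
        },
        "null": {
            "observed": null.observed,
            "empirical_p": null.empirical_p,
            "quantiles": null.quantiles(),
            "n_replicates": null.n_replicates,
        },
        "branch_site": {
            "lr": bs_lrt.lr, "df": bs_lrt.df, "p": bs_lrt.p,
            "omega2": alt_bs.params.omega2,
            "boundary": alt_bs.boundary,
            "selected_sites": selected_sites,
            "percentile": cfg.percentile,
        },
        "enrichment": (None if enr is None else {
            "U": enr.u, "p": enr.p, "method": enr.method,
            "n_convergent": enr.n_a, "n_other": enr.n_b,
        }),
        "convergence_tree_clades": n_clades,
    })
    if truth is not None:
        inj = set(truth.convergent_sites)
        found = set(union)
        report["truth"] = {
            "injected": sorted(inj),
            "recovered": sorted(inj & found),
            "false_positives": sorted(found - inj),
        }

    if outdir is not None:
        manifest = {
            "version": __version__,
            "seed": cfg.seed,
            "stage_seeds": stage_seed,
            "config": {k: v for k, v in asdict(cfg).items()
                       if not isinstance(v, (np.ndarray,))},
            "inputs": {
                name: _sha256(p) for name, p in [
                    ("alignment", cfg.alignment), ("tree", cfg.tree),
                    ("tags", cfg.tags), ("domains", cfg.domains),
                    ("confidence", cfg.confidence)]
                if p is not None
            },
            "elapsed_s": round(time.time() - t_start, 2),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, default=_jsonable))
    return report


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    return str(x)
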