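# Methods

This note records the models implemented in `selconv`, the conventions
and numerical choices behind them, what the synthetic-data generator does
and does not emulate, and the known limitations.

## Codon model and branch-partitioned dN/dS

The substitution model is GY94: states are the 61 sense codons of the
universal code; the instantaneous rate from codon *i* to *j* is zero
unless they differ at exactly one nucleotide position, and otherwise
proportional to the equilibrium frequency π*j*, multiplied by κ for
transitions and ω for nonsynonymous changes. Frequencies are F3x4
(position-specific nucleotide counts from the analysed region, stops
zeroed and renormalised), fixed rather than ML-estimated. Each rate
matrix is scaled so that −Σ πᵢqᵢᵢ = 1, making a branch length the
expected number of substitutions per codon on that branch; in the branch
models each ω class carries its own scaled matrix, so a branch's length
keeps this meaning regardless of its class.

Three ω structures are fitted: one ratio for all branches; one ratio per
branch partition tag (SEC / EXCHANGE / INHERITED); and one ratio per
branch (free-ratio). The likelihood is Felsenstein pruning with
per-node, per-pattern rescaling; site patterns are compressed before
evaluation. Gaps and ambiguous codons contribute all-ones partial
likelihoods. Optimisation is L-BFGS-B on log-transformed parameters with
**analytic branch-length gradients** (an inside–outside pass yields all
branch derivatives at roughly the cost of three likelihood evaluations)
and finite differences for κ and the ω's; by default three starts are
taken from perturbed initial points, and a nested fit can warm-start a
richer one. Convergence tolerance is 1e-8 in scaled log-likelihood;
branch lengths are floored at 1e-8 to keep the likelihood differentiable.

Likelihood-ratio tests use the plain χ² reference with df equal to the
difference in free-parameter counts (df = 2 for the three-vs-one ratio
contrast); no boundary mixture correction is applied to branch models.
The LR statistic is clipped at zero, with a warning (and the advice to
restart) if the alternative optimises below the null beyond tolerance.

Per-branch dN and dS are derived from the fitted matrix by splitting the
flux into nonsynonymous and synonymous parts, with site proportions from
the neutral (ω = 1) matrix at the fitted κ. For protein-level work the
exported branch length is the **expected number of amino-acid
substitutions per codon site** (t × nonsynonymous flux fraction); this
is the dN-scale rate the simulation null consumes. It differs from
PAML's per-nonsynonymous-site dN by the factor 3·fN, a choice made so
that protein branch lengths predict amino-acid divergence directly; both
quantities appear in the exported branch-rate table.

The catalytic column (TGA in Sec lineages) is excluded from every codon
fit and from convergence counting — the Sec→Cys exchange is the
conditioning event of the analysis, not a change to be counted — and is
retained as metadata. Masking by a per-column confidence track
(threshold 0.95 by default) is applied codon-wise before analysis;
coordinates are 0-based half-open throughout, and codon coordinates
equal amino-acid coordinates.

## Ancestral reconstruction

Protein-level marginal empirical-Bayes reconstruction under an empirical
amino-acid model (JTT built in; any reversible 20-state model can be
supplied). The marginal posterior at each internal node integrates over
all other nodes via one inside and one outside pass; the MAP state is
reported with a deterministic alphabetical tie-break. Node accuracy is
the mean MAP posterior over (unmasked) sites — the standard
self-assessment of a marginal reconstruction; it is a statement about
posterior concentration, not an external validation. All-gap columns
get an explicit uniform posterior and a warning. Branch lengths are
either taken from the supplied tree (the dN-scale lengths in the
pipeline) or refit by ML under the amino-acid model.

Marginal rather than joint reconstruction is used because every
downstream quantity (per-node accuracy, per-site posteriors in the
expected-convergence computation) is a marginal. The catalytic Sec/Cys
character is excluded from the probabilistic reconstruction; its
ancestral states are assigned by Fitch parsimony (preferring the
declared ancestral state at ties, with ambiguous nodes reported), which
is used only to count and date the independent losses.

## Convergence detection

Observed substitutions are read off MAP states at branch endpoints (leaf
states are the observed residues). For an unordered pair of
phylogenetically independent branches, a site with events on both
branches and the same derived residue is *parallel* if the ancestral
residues agree and *convergent* if they differ; reports use "convergent
sites" for the union of the two classes (the field's umbrella usage)
while keeping them distinguishable. Sites whose derived residues differ
but fall in the same physicochemical group (default classes:
AVLIMC / FWY / STNQ / DE / KRH / G / P) are reported separately as
"similar" and never enter headline counts.

Expected counts per pair treat the two ancestors as independent and
integrate their marginal posteriors against the model's transition
matrices: per site, Σₓ Σ_{a≠x} Σ_{b≠x} p₁(a) p₂(b) P₁(a→x) P₂(b→x),
with the a = b term giving the parallel part. The pair p-value is the
Poisson tail P(X ≥ observed) at λ = expected total. The independence
approximation over ancestors is the standard pairwise treatment; it is
exact when the two ancestral nodes are well separated and slightly
optimistic when they are adjacent.

The convergent-site tree is neighbor joining on pairwise ML distances
under JTT restricted to the convergent sites, midpoint-rooted; the
summary statistic is the number of maximal clades covering the
Cys-bearing taxa (1 = monophyletic) rather than exact topology, which a
distance method on few sites cannot promise.

## Simulation null

Replicates evolve protein sequences site-independently down the tree by
sampling from JTT transition matrices, with branch lengths set to the
fitted per-branch amino-acid substitution rates and the root fixed at
the reconstructed ancestral sequence. Each replicate is re-analysed with
the same reconstruction-and-counting settings as the observed data, so
reconstruction error is inside the null (the conservative reading).
The empirical p is (1 + #{replicates ≥ observed}) / (R + 1); R defaults
to 1,000, and the test suite uses 35–200 replicates. Per-pair and total
counts are both recorded. Replicate failures are dropped with a log
entry and more than 5% drops abort the run.

## Branch-site model and enrichment

Model A: four site classes over (background, foreground) ω pairs —
(ω₀, ω₀), (1, 1), (ω₀, ω₂), (1, ω₂) — with proportions p₀, p₁,
p₂ₐ = (1−p₀−p₁)p₀/(p₀+p₁), p₂_b = (1−p₀−p₁)p₁/(p₀+p₁); ω₀ ∈ (0, 1),
ω₂ ≥ 1 free in the alternative and pinned at 1 in the null. All class
matrices share one time scale (the proportion-weighted mean background
rate is normalised to 1), so a site in the selected class evolves faster
on the foreground rather than merely more nonsynonymously — without this
shared scale the test has essentially no power. Branch lengths and the
starting κ are taken from a one-ratio fit of the same region and held
fixed during the mixture fits (a deliberate simplification; PAML
re-estimates lengths per hypothesis). The null fit is warm-started from
the alternative's optimum in addition to its own starts, and the
alternative is restarted from the null when optimisation leaves it
below (ω₂ = 1 is an interior point of the alternative). The LRT uses
χ² with df = 1 — the conservative convention at the ω₂ = 1 boundary.

Site posteriors are naive empirical Bayes at the MLEs (not BEB; flagged
in output metadata). "Signatures of positive selection" for reporting
purposes are posteriors at or above the 90th percentile of a designated
region, computed with midpoint interpolation. Enrichment of posteriors
at one site set against another uses the Mann–Whitney U statistic with
the 0.5 tie convention: exact enumeration of labelings when the smaller
set has ≤ 8 sites **and** C(n, |A|) ≤ 200,000 (the feasibility cap that
the small worked examples satisfy), otherwise the normal approximation
with tie correction; the default alternative is one-sided ("greater").

## Synthetic data

The generator produces codon alignments by simulating GY94 down a tagged
tree with tag-specific ω (stop codons never arise by construction), from
a root drawn from the F3x4 stationary distribution built on mildly
GC-biased position-specific nucleotide frequencies typical of mammalian
coding sequence. κ defaults to 3.0, a mid-range mammalian transition
bias. The packaged preset fixes a 22-taxon mammal-like topology with
five exchange branches — a four-species muroid clade (the focal branch),
rabbit, a two-species New-World-monkey clade, hedgehog, and elephant —
chosen so the five losses are the unambiguous parsimony reading of the
catalytic character; nine taxa carry Cys. Branch classes use
ω = 0.217 (SEC), 0.370 (EXCHANGE), 0.279 (INHERITED); domains are
39/113/65 codons with the catalytic site at codon 72.

Convergence is injected post hoc: at each chosen site every exchange
branch is forced to one common derived amino acid, preferring codons one
nucleotide step from the parent codon (multi-step choices are recorded),
and descendant states at that site are re-simulated from the new state;
the injected-site list is therefore exact ground truth. Focal-branch
changes are topped up to the configured count (25) by focal-only forced
substitutions. The generator does not emulate indels, rate variation
across sites, alignment error (the confidence track is synthetic input),
or base-composition heterogeneity across lineages — so green tests
certify the statistical machinery under the stated generative model, not
robustness to real-data artefacts.

## Problem sizes used in the tests

Unit and property tests run on 2–10-taxon trees with enumeration
oracles. Calibration and recovery suites use: 200 null replicates of
10 taxa × 100 codons for the branch-LRT type-I error; 20 replicates of
15 taxa × 300 codons for ω recovery; 20 preset replicates at 200 codons
for end-to-end convergent-site recovery; 20 negative-control runs with
an 80-replicate null; 60 outer × 35 inner replicates for null-p
uniformity; and 10/20 replicates for branch-site power/calibration.
These sizes are the package's validation design; the full-scale pipeline
(217 codons, R = 1,000) runs in a few minutes.

## Known limitations

- The expected-convergence computation treats the two ancestors of a
  pair as independent (product of marginals).
- Branch-site fits hold branch lengths fixed; very long foreground
  branches estimated under a misspecified one-ratio model can blunt the
  test.
- NEB posteriors understate uncertainty in the mixture parameters
  relative to BEB.
- The codon model is GY94+F3x4 only (no F61, no site-heterogeneous ω
  outside model A); the amino-acid layer is time-reversible and
  site-homogeneous.
- The simulation null inherits any error in the fitted dN-scale branch
  lengths; with very short branches the discrete convergent-site counts
  make the empirical p conservative.
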