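# Methods

This note documents the models implemented in `mitochronos`, the choices
made where the design was genuinely open, what the synthetic data do and do
not emulate, and the known limitations.

## Coordinates, variants and haplotypes

All interfaces report 1-based inclusive positions in the reference
mitogenome's numbering. Alignment columns where the reference carries a gap
are addressed as (position of the preceding reference base, insertion index
≥ 1). Variant effects in protein genes are classified under the vertebrate
mitochondrial genetic code (NCBI table 2, shipped as data and cross-checked
against an independent implementation in the tests), honouring gene strand;
positions inside a gene span but trimmed from the CDS (terminal stop
codons) get effect `NA`.

Haplotype identity uses substitution variants only. Indels and columns
containing N are excluded from the identity key because length variation and
coverage artifacts would otherwise split biologically identical matrilines.
Two N-handling modes exist: the default *strict* mode keeps sequences whose
N positions differ as separate haplotypes (conservative, logged); the
relaxed mode lets N match anything. Neither is claimed to be what any
particular study did — real papers rarely state this — so the choice is a
flag, and the default is the reproducible, conservative one.

Haplogroup calls take a user-supplied rule table (label, parent, full
diagnostic motif as (position, derived allele) pairs). The deepest fully
satisfied rule wins; equally deep matches on different branches return an
explicit `conflict:<labels>` value rather than a silent tie-break.

## Diversity statistics

Hd = n/(n−1)(1 − Σpᵢ²). Pairwise differences are counted with pairwise
deletion of gap/N columns; the SD reported alongside the mean is the
population SD across the C(n,2) pair values (a dispersion label like
"69.0 ± 16.5" is ambiguous in the literature; this interpretation is
documented rather than asserted). π uses, as effective length, the number
of columns whose majority state is not a gap; π is emitted both raw and
×100 because mitogenome papers conventionally print it as a percentage
(0.422 ≈ 100 × 69.0 / 16 351.5). The syn/nonsyn ratio counts *distinct*
coding substitutions by (position, alternate allele), so a variant shared
by many haplotypes counts once.

## Synonymous masking

Protein genes are concatenated in genomic order; minus-strand genes are
reverse-complemented into the common reading direction. Terminal stop
codons are removed; a 1–2 nt overhang is treated as a
polyadenylation-completed stop (T/TA) and trimmed with it — any other
overhang is a hard error naming the gene, because a silent frameshift would
poison every downstream codon call.

Ancestral bases default to the outgroup consensus per column (ties to the
first-listed outgroup); Fitch reconstruction at the root of a supplied tree
(ties toward the outgroup state) is available as an alternative. Masking
replaces a base with its ancestral state whenever substituting it into the
ancestral codon context changes the encoded amino acid. Codons carrying two
or three changes are judged jointly and conservatively: if the joint codon
*or any single change alone* is nonsynonymous, all changed positions in the
codon are masked. Consequences that the tests verify: masking is
idempotent; only nonsynonymous-classified columns are touched; after
masking every fully determined codon translates to the ancestral amino
acid.

## Maximum parsimony

Fitch counting treats gaps and N as full wildcards. The search space is
handled in three regimes: exact branch-and-bound (default up to 10 leaves;
the bound is that attaching leaves never decreases the Fitch length),
randomized stepwise addition from several seeded starts, and NNI followed by
SPR hill climbing with re-polishing. Site patterns are compressed with
weights, and subtree Fitch states are memoized during candidate scans, so a
~100-haplotype search runs in seconds. Monophyly constraints are treated as
unrooted splits and checked at every insertion and rearrangement; a
constraint set containing the planted outgroup is interpreted through its
complement. Equally parsimonious results are tie-broken by the
lexicographically smallest newick string for reproducibility.

The returned tree is rooted on the edge separating the outgroups from the
ingroup when the ingroup forms a split (otherwise on the first outgroup's
pendant edge). The Fitch backtrace then fixes one most-parsimonious state
per node and column — root ties resolved toward the supplied ancestral
base, lower ties toward the parent state — and records each change on the
branch where it occurs, so that the per-branch counts sum exactly to the
tree's Fitch length on binary trees.

## Poisson clock

Branch counts are modelled as k_b ~ Poisson(r·L·Δt_b). Calibrations enter
as exact pins (fixed mode), Gaussian log-density penalties (the printed
"±" of fossil ages is interpreted as an SE, consistent with the convention
that a 95% CI is ±1.96 SE), or dated tips whose ages are data. The
likelihood is concave in the node ages for fixed rate, and the rate has the
closed form r̂ = Σk/(L·ΣΔt), so the optimizer alternates exact 1-D
bisection updates per free node age (each coordinate derivative is strictly
decreasing) with rate updates; several initializations guard against the
rare flat ridge. Standard errors come from a finite-difference observed
information matrix in natural parameters (rate and free ages); ages stuck
at an ordering boundary (zero-length branches) are not identified and are
excluded rather than reported with a spurious SE.

One modelling decision deserves emphasis: **the two branches meeting at the
root are treated as a single Poisson edge** (summed count, summed
duration). An outgroup-rooted parsimony tree places the root on one
unrooted edge, and the apportionment of mutations between its two halves is
purely an artifact of ancestral-state tie-breaking — with a consensus-like
outgroup ancestral state, essentially all changes on the deep path land on
the ingroup side. Modelling the halves separately lets that artifact
overwhelm a deep calibration (we observed a two-fold age compression on
synthetic data); merging removes the artifact without touching genuine
information. The clock LRT uses the same merged-edge convention, giving the
classical df = (unrooted branches) − (internal nodes) = n−2 for n modern
tips.

Rate-unit ambiguity: a synonymous rate can be quoted per nucleotide or per
codon, and published prose sometimes mixes the two (a rate of 3.75×10⁻⁵
"per nucleotide" over 3 790 codons yields one substitution per ~7.03 Ky
only if applied per codon). The API therefore takes an explicit
`site_count` and unit, and `waiting_time(rate, units)` makes the conversion
arithmetic a first-class, testable operation.

## Bayesian skyline

The coalescent density of a genealogy under piecewise-constant Ne is the
standard Σ[−k(k−1)Δτ/(2Ne)] − Σ log Ne with times in generations
(generation time 6 yr by default, configurable). The MCMC state is (group
sizes, one Ne per group), with group boundaries at coalescent event times.
Proposals: multiplicative log-scale moves on a single Ne (acceptance
reduces to the likelihood ratio under the log-uniform prior, default bounds
10⁻²–10⁹) and single-interval shifts between adjacent groups. Defaults are
desk-scale (m = 10 groups, 5×10⁵ iterations thinned by 100, 10% burn-in);
production-scale settings are plain flags. The trajectory is summarized on
a uniform grid by the median and the shortest-interval 95% HPD; an
effective sample size of the log-likelihood trace below 100 flags
non-convergence prominently instead of failing.

The skyline operates on a *fixed* dated genealogy (the clock-dated MP
tree), not jointly with the sequence likelihood, and — because the tree is
built on haplotype representatives — repeated haplotypes do not contribute
extra near-present coalescences. Both simplifications bias the most recent
part of the trajectory and are the reason validation is done by simulation
recovery (coverage of a known constant Ne; sign recovery of a
bottleneck-then-expansion history) rather than by matching any published
curve.

## Synthetic data

Genealogies come from msprime's piecewise-constant coalescent (haploid,
single locus, optional ancient tips; the study-like fixture uses two
derived populations splitting from a common ancestor to create two
macro-lineages). Sequences then evolve along the dated tree under HKY
(κ = 20) with 8-category discretized-gamma rates (α = 0.5), an invariant
class (p_inv = 0.3, with the gamma categories rescaled so the overall mean
rate is the nominal 2×10⁻⁸ substitutions/site/year), and a faster control
region (×5). Coding sites respect the mitochondrial code: proposed changes
creating a stop codon are always rejected, other nonsynonymous codon
changes are rejected with probability 0.8 by default — a deliberately
simple stand-in for purifying selection whose knob tunes the syn/nonsyn
ratio monotonically. Terminal stop codons are held invariant so every tip
keeps a readable frame. True branch counts, the dated tree, and all
parameters are recorded in a truth bundle; everything is a deterministic
function of (parameters, seed).

The study-like fixture (defaults: 100 ingroup tips, coding 11 370 nt /
3 790 codons across 13 genes with one minus-strand gene, 900 nt control
region, ~13 kb genome) hangs a two-tip divergent outgroup clade (coalescing
at 80 Kya) and one ancient dated tip (6.7 Kya) from a root at 900 Kya that
carries a Gaussian fossil-style calibration (±50 Ky) — the same
deep-fossil-plus-ancient-tip calibration design used in mitogenome dating
studies, at fixture scale. The demography is a bottleneck-then-expansion
history (40k → 20k → 5k → 50k females) chosen to produce study-like
diversity levels (Hd ≈ 0.99, π ≈ 0.4%, ~60–70 haplotypes per 100
sequences).

What the generator does **not** emulate: indels and alignment error (output
is gap-free), context-dependent mutation and hypervariable control-region
hotspots, codon-model selection (rejection sampling is not a dN/dS model),
sequencing artifacts/Ns, and recombination (absent in mtDNA). Passing
recovery tests therefore validates the estimators under their own model
class plus mild misspecification (rate heterogeneity, selection,
saturation), not robustness to alignment or assembly error.

## Problem sizes used in validation

The routine test-suite and acceptance-script runs use: exhaustive-search
oracles at 5–7 taxa (50 instances), coalescent-likelihood oracles on 50
random genealogies (agreement to 10⁻¹⁰), 200 replicate clock datasets
(8 tips, L = 2×10⁴) for CI coverage, 200/100 replicate constant-Ne
skylines (n = 30, single group, 6 000 iterations) for HPD coverage, one
80-tip bottleneck-then-expansion skyline (80 000 iterations, chosen from
genealogies with at least 8 coalescences in the oldest epoch so the deepest
groups are informed) for trend signs, and one full ~103-record study-like
pipeline run. These sizes were
chosen so the whole validation cycle completes on a laptop-class single
core in a few minutes while keeping Monte-Carlo error well below the
asserted margins.

## Known limitations

- Parsimony counts undercount multiple hits on deep branches; the clock
  inherits this saturation bias for very old nodes (partially absorbed by
  the calibration).
- Wald (±1.96 SE) intervals understate uncertainty for nodes whose age
  information is a handful of mutations, and the clock SE excludes
  topology and masking error (the end-to-end fixture test allows 3 SE for
  this reason).
- The grouped-skyline MCMC mixes slowly for large m on small genealogies;
  the ESS flag is the guard.
- Haplogroup assignment is motif-based only; it does not attempt placement
  of sequences carrying back-mutations at diagnostic positions (these
  surface as `unassigned` or `conflict`).
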