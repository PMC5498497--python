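# mitochronos

Tools for reconstructing the maternal history of a population from complete
mitochondrial genomes, built around the workflow used for Asian swamp
buffalo (*Bubalus bubalis carabensis*): collapse aligned mitogenomes into
haplotypes and summarize their diversity, strip the protein-coding region
down to its synonymous variation, build a maximum-parsimony haplotype tree,
convert per-branch mutation counts into node ages with a calibrated Poisson
molecular clock, and infer the effective female population size through time
with a Bayesian skyline. A synthetic-data module generates mitogenome-like
datasets with full ground truth so every stage can be validated without any
external download.

## Who this is for

Population geneticists and molecular ecologists working with non-recombining
organellar genomes (mtDNA haplogroup studies, domestication history,
phylogeography) who want a scriptable, fully testable version of the
classic mitogenome pipeline instead of a chain of GUI tools.

## The models

**Diversity.** For n sequences collapsed into haplotypes with sample
frequencies pᵢ, haplotype diversity is Hd = n/(n−1)·(1 − Σpᵢ²). Nucleotide
diversity π is the mean pairwise difference count k̄ divided by the
effective alignment length (reported both raw and ×100 as a percentage),
with the SD of k̄ taken across all C(n,2) pairs. The synonymous /
nonsynonymous ratio counts distinct coding substitutions classified under
the vertebrate mitochondrial genetic code (translation table 2).

**Synonymous masking.** The 13 protein-coding genes are concatenated in
genomic order (ND6-like minus-strand genes reverse-complemented, terminal
stop codons — complete or polyadenylation-completed — trimmed). Ancestral
bases come from the outgroup consensus (or Fitch reconstruction on a tree);
every nonsynonymous substitution is replaced by its ancestral base, leaving
an alignment whose only variation is synonymous and therefore closest to
clock-like.

**Maximum parsimony.** The Fitch algorithm scores topologies (gaps/N as
wildcards); search is exact branch-and-bound up to 10 leaves and randomized
stepwise addition + NNI + SPR hill climbing above that, honouring user
monophyly constraints, rooted on the outgroup split. A Fitch backtrace
assigns every mutation to a branch.

**Poisson clock.** A branch of duration Δt carries k ~ Poisson(r·L·Δt)
mutations, with r the per-site rate and L the site count. Given calibrations
(a Gaussian fossil age on a node, a fixed node age, or radiocarbon-dated
ancient tips), r and all free node ages are estimated by maximum
likelihood (coordinate ascent with closed-form rate updates); standard
errors come from the inverse observed information and 95% CIs are
age ± 1.96·SE. The two branches meeting at the root are modelled as one
edge, because parsimony cannot apportion mutations across the root. A
generalized likelihood-ratio test compares the clock against one free
rate·time product per branch.

**Bayesian skyline.** On the dated genealogy, the n−1 coalescent intervals
are partitioned into m contiguous groups, each with a constant effective
female size N_ef; Metropolis–Hastings samples group sizes and N_ef values
under a log-uniform prior, and the trajectory is summarized by the posterior
median and 95% highest-posterior-density band on a uniform time grid
(generation time 6 years by default).

## Worked example

```python
from mitochronos import (
    make_study_like_dataset, collapse_haplotypes, summarize,
    extract_coding, infer_ancestral, mask_nonsynonymous,
    mp_search, assign_branch_mutations, fit_clock, waiting_time,
)

fx = make_study_like_dataset(seed=42)           # ~100 swamp-like mitogenomes
ref = next(r for r in fx.records if r.id == fx.reference_id)
swamp = [r for r in fx.records if r.btype == "swamp"]
table = collapse_haplotypes(swamp, ref, fx.genemap)
stats = summarize(swamp, table)
print(len(table), round(stats.Hd, 3), round(stats.pi_percent, 3))
# 67 0.99 0.389

coding = extract_coding(fx.records, fx.genemap)
ancestral = infer_ancestral(coding, outgroup_ids=fx.outgroup_ids)
masked, audit = mask_nonsynonymous(coding, ancestral)
print(masked.length_nt, masked.codon_count)
# 11370 3790

reps = [h.member_ids[0] for h in table.haplotypes]
seqs = {i: masked.sequences[i] for i in reps + fx.outgroup_ids}
tree = mp_search(seqs, constraints=[set(reps)], outgroup_ids=fx.outgroup_ids, seed=7)
assign_branch_mutations(tree, seqs, ancestral.bases)
for leaf in tree.leaves():
    leaf.tip_age = next(r.tip_age for r in fx.records if r.id == leaf.name)

fit = fit_clock(tree, fx.calibrations, masked.length_nt)
age, se = fit.node_age(reps)
print(round(age / 1000, 1), "+/-", round(se / 1000, 1), "Kya")
# 274.5 +/- 39.5 Kya      (simulated truth: 222.7 Kya)
print(round(waiting_time(fit.rate, masked.length_nt), 1), "Ky per substitution")
# 15.6 Ky per substitution
```

The first block collapses 100 swamp-type sequences into 67 haplotypes with
haplotype diversity 0.99 and π ≈ 0.39% — the fixture is tuned to the same
orders of magnitude seen in real water-buffalo mitogenome panels. The
masked coding alignment is exactly 11,370 nt (3,790 codons). The clock run
then dates the swamp ancestor at 274.5 ± 39.5 Kya against a simulated truth
of 222.7 Kya (within 1.4 SE), and converts the fitted synonymous rate into a
waiting time of one substitution per ~15.6 Ky.

The same stages are available from the shell:

```bash
mitochronos simulate --preset study-like --seed 42 --out fx/
mitochronos run --config pipeline.toml
```

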