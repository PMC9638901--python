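# Methods

## The measurement problem

Dual metabolic labelling with nucleotide recoding lets two RNA samples be
pooled into a single sequencing library and still be told apart: the
"experimental" sample is fed 4-thiouridine (s4U), whose recoded bases read
out as T-to-C mismatches, and the "control" sample is fed 6-thioguanosine
(s6G), read out as G-to-A mismatches.  Because both samples travel through
library preparation and sequencing together, the per-gene ratio of labelled
material between them is internally normalized — no spike-ins or library-size
factors are needed.  To cancel label-specific incorporation biases the
experiment is run in two reciprocal *combinations*: **forward**
(experimental = s4U, control = s6G) and **reverse** (labels swapped), plus an
**unlabelled** control that received neither analogue and measures the
background mismatch rate from sequencing error alone.

The estimand per gene g is the labelled-abundance ratio
θ_exp,g / θ_cntl,g, where θ_c,g is the fraction of gene g's reads carrying
condition c's label; we report it as log2(θ_exp,g / θ_cntl,g).

## Model

For each read, each mutation channel m ∈ {T-to-C, G-to-A} contributes a
count y_m modelled as a two-component Poisson mixture:

    y_m | θ ~ I_s · θ · Poisson(λ_l,m) + (1 − I_s · θ) · Poisson(λ_u,m)

λ_u,m is the background rate (mutations per read) and λ_l,m = λ_u,m + TL_m
the labelled rate; both are **global across genes**.  I_s is 1 for labelled
samples and 0 for unlabelled controls.  Which θ a channel informs is routed
by the sample's combination: forward → T-to-C informs θ_exp and G-to-A
informs θ_cntl; reverse → swapped.  All replicates of a combination share
the gene's θ pair.  Reads are grouped by (gene, sample, channel,
mutations-per-read), so the likelihood is evaluated once per group and
weighted by the group's read count.

Priors (weakly informative): log λ_u,m ~ Normal(−2, 2);
TL_m ~ Exponential(rate 0.5), i.e. prior mean 2 mutations per read,
matching the ≈2.5 expected for s4U-labelled 200-base reads;
logit θ ~ Normal(0, 1.5) per gene and condition.  θ is parameterized on the
logit scale and floored at (1e−6, 1 − 1e−6); mixtures are computed by
log-space summation throughout.

The Poisson rate is **per read**, not conditioned on that read's U/G
content.  This is deliberate: it makes the likelihood a function of count
groups only.  A per-read exposure correction could be added but is not the
default.

## Fitting

Fitting is two-stage empirical Bayes, which keeps the per-gene problems
two-dimensional and embarrassingly parallel:

1. **Global rates.**  The joint posterior of (log λ_u,TC, log λ_u,GA,
   log TL_TC, log TL_GA) and the θ pairs of up to 25 highest-coverage genes
   is sampled by Metropolis-within-Gibbs: a vectorised random-walk update of
   all subset θs, then a random-walk update of the rate block.  The
   unlabelled-read histogram of *every* gene (not just the subset) enters
   the rate likelihood, so λ_u is pinned by all available background reads.
   Rates are then fixed at their posterior means.
2. **Per-gene θ.**  Each gene's 2-D posterior over (logit θ_exp,
   logit θ_cntl) is sampled by adaptive random-walk Metropolis with 4
   independent chains.  Because the Poisson pmfs are constants once rates
   are fixed, every gene's chains are advanced simultaneously in one numpy
   sweep over the concatenated group arrays; 600 genes take ~20 s on one
   core.  Chains start from method-of-moments estimates
   θ̂ = (ȳ − λ_u)/(λ_l − λ_u) with overdispersed jitter.

Warm-up (1000 sweeps) adapts a per-target scalar step size toward 40%
acceptance (Robbins–Monro) and rescales proposals by the empirical
per-parameter spread estimated mid-warm-up; 2000 sweeps per chain are kept.
Convergence is gated per quantity on split R-hat ≤ 1.01 and bulk effective
sample size ≥ 100 (computed with arviz); genes failing the gate are flagged
`converged = False`, reported, and excluded from the downstream testing
family rather than silently accepted.  Divergence counts are reported as 0 —
the concept does not apply to a Metropolis sampler.

**Independent oracle.**  `grid_posterior_oracle` computes the same per-gene
posterior (rates fixed) by deterministic 2-D trapezoid quadrature over
(logit θ_exp, logit θ_cntl) ∈ [−9, 9]², doubling the resolution until the
posterior mean log2 ratio moves < 1e−3.  The test suite requires the MCMC
mean to agree with the quadrature mean within 3 Monte-Carlo standard errors
on randomized single-gene instances.

## Significance testing

The composite null |mean log2 ratio| ≤ μ_cutoff (default 0.5) is tested at
its boundary under a normal approximation to the posterior, using the
two-boundary tail sum of the fold-change-threshold construction (TREAT):

    p = S((|m| − c)/s) + S((|m| + c)/s),   c = μ_cutoff,

with S the standard-normal survival function, m and s the posterior mean
and sd; p is capped at 1 and equals exactly 1 at m = 0.  P-values are
BH-adjusted across all converged genes (statsmodels) and called significant
at adjusted p < α = 0.05.  Using the (mean, sd) summary rather than raw
draws follows the normal-approximation form of the test; draws are retained
in `PosteriorSummary.log2_draws` so a draw-based variant can be compared.

## Tallying front end

Reads are kept iff FLAG ∈ {83, 163, 99, 147} and MAPQ ≥ 2.  A read is
assigned to a gene by interval overlap: fully inside one gene's exons →
exonic; within a single gene but touching non-exonic sequence → intronic;
overlapping ≥ 2 genes → ambiguous (dropped).  Mismatch counting is
transcript-strand aware: for minus-strand genes, genomic A→G events count as
T-to-C and genomic C→T as G-to-A.  Excluded from both numerator and
denominator: masked SNP positions (from a VCF), bases below quality 20
(configurable), insertions, soft clips, and mate-overlap positions already
counted on the first mate.  Reference bases come from the MD tag when
present, otherwise from a FASTA.  Coordinates are converted to 0-based
half-open at the parsers (SAM/VCF/GTF are 1-based, BED 0-based).  A
`strandedness` switch ({unstranded, forward, reverse}, default unstranded)
optionally requires the fragment orientation implied by the flag pair to
match the gene strand.  Exonic and intronic reads are tallied separately but
pooled when fitting; `feature_class` is retained for stratification.

Coverage filtering keeps genes with ≥ 200 reads in ≥ 2 samples (inclusive
boundary, applied uniformly).  Raw per-gene mutation-rate summaries
(Σ mutations / Σ base observations, per feature class) use a strict
"> 200 reads" rule and omit — rather than zero-fill — groups with no
observed bases.

## Simulator

The generator mirrors the experimental regime and is the package's fixture
factory.  Per transcript: a true ratio r (grid
{0.01, 0.1, 0.5, 1, 1.5, 2, 10, 100}, a template, or a constant);
logit θ_cntl ~ Normal(logit(1/(1+r)), 0.5) and θ_exp = r·θ_cntl (pairs
summing above 1 are rescaled to 1 − 1e−9, preserving r).  Per sample and
read: pool assignment ~ Multinomial(θ_exp, θ_cntl, remainder); U/G content
~ Multinomial(200; 0.25, 0.25); mutation counts Binomial with per-base rates
0.05/0.001 (T-to-C labelled/background) and 0.02/0.004 (G-to-A).  Unlabelled
samples draw every read at background rates.  Note the simulator is
Binomial while the model is Poisson — a mild, intentional misspecification
that matches how finite site counts generate real data.  The printed
formula for the θ_cntl draw admits two readings (scale factor vs location
shift); the location-shift reading is used because it makes θ_exp + θ_cntl
concentrate near 1 at zero noise.

`synthetic_template` provides a fully synthetic stand-in for a
template dataset from a transcription-inhibition experiment (85% of
transcripts log2-depleted around −2.5, log-normal read depths); real
templates are accepted as DataFrames/TSV.  `apply_regulation_mode`
re-expresses a template as global depletion (unchanged), global enrichment
(log-ratios negated) or symmetric regulation (mean log-ratio subtracted).
The optional 15-read template floor is applied to template means, before
the Poisson read-count draw.

`emit_synthetic_sam` materialises simulated tallies as SAM + FASTA + GTF:
one contig per gene built from one 200-base window per read (n_U T sites,
n_G G sites, filler A), reads recoded at the first y_TC/y_GA sites, MD/NM
tags, flag 99, MAPQ 60.  Re-tallying this output recovers the generating
counts bit-for-bit, which is the round-trip guarantee the tally tests and
the acceptance suite rely on.

What the simulator does **not** emulate: PCR duplicates, quality-score
profiles, alignment error, multi-mapping, coverage non-uniformity along
transcripts, or gene-specific label-uptake differences.  Passing tests
therefore demonstrate correctness of the inference given the stated
generative model, not robustness to those artifacts.

## Problem sizes and numerical choices

Default analysis scales chosen for the bundled studies: the false-discovery
study uses 600 transcripts (80% null, 20% at |log2 ratio| = 2) at 500 reads
per transcript per sample with one forward / one reverse / one unlabelled
sample; dynamic-range sweeps use 50 transcripts per grid ratio at 300
reads; `sweep` defaults are desk-scale and accept larger grids for
full-scale runs.  Ties and degenerate inputs: empty count tables are legal
and yield prior posteriors; genes with no labelled groups fall back to the
prior; a design without any unlabelled sample is refused unless λ_u is
fixed explicitly (`fixed_background`) or the whole rate set is supplied
(`fixed_rates`).

## Known limitations

- The two-stage scheme conditions per-gene posteriors on point estimates of
  the global rates; rate uncertainty (tiny at realistic depths: the
  unlabelled pool has tens of thousands of reads) is not propagated.
- No hierarchical shrinkage across genes, no dispersion modelling, no
  multi-condition (> 2) designs.
- At ratios ≤ 0.01 with few hundred reads the control-condition fraction is
  near the θ floor and estimates saturate; the reliable range at ≥ 200
  reads is about 0.1–100, consistent with the dynamic-range test.
- The tally stage assumes a single genome alignment plus annotation; it does
  not reconcile separate transcriptome alignments, call SNPs, or
  deduplicate.
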