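# Methods

`mutspectra` tests whether temporal and interpopulation changes in the
germline mutation spectrum — read off polymorphisms annotated with
genealogy-based allele ages — can be explained by shifts in average
reproductive ages, using parental-age effects fitted to trio de novo
mutation (DNM) counts. This note documents the models, the defaults and why
they were chosen, the numerical decisions, and what the synthetic data do
and do not establish.

## Mutation classes and context

Polarized SNPs are collapsed so the ancestral base is T or C, giving six
base classes (T>A, T>C, T>G, C>A, C>G, C>T). CpG status is defined solely by
a G immediately 3' of the collapsed ancestral C (a 5' flank never confers
it); TpG status is the analogous predicate for ancestral T. The default
eight-class scheme splits C>T by CpG (deamination of methylated cytosine)
and T>C by TpG (TpG>CpG changes are enriched for mis-polarized CpG
transitions); a `full` scheme additionally splits C>A and C>G by CpG for
CpG-matched ratio denominators. Variants with a missing or ambiguous flank
are excluded, and the classification is exactly invariant under
reverse-complementing the alleles together with swapping/complementing the
flanks (tested exhaustively over all 8 strand/context cases per
substitution).

As a proxy for the UV-associated and alkylation-associated somatic
signatures (SBS7a/b and SBS11), C>T mutations with a pyrimidine on either
flank (YCN or NCY contexts) can be flagged and removed; the loading-table
reader computes the corresponding context shares from any COSMIC-style
table.

## Allele-age binning and pseudo-counts

Genealogy-derived allele ages come as (lower, upper) bounds in generations,
often an order of magnitude apart. Variants with upper bound above 3,000,000
generations are discarded as incompatible with human evolutionary history.
Bin boundaries are the empirical 0, 1/n, ..., 1 quantiles of one uniformly
sampled point age per variant in a designated reference population (default
n = 15 bins); bins are half-open except the last. Each variant then spreads
unit mass across bins in proportion to the overlap of its age interval with
each bin under a uniform age distribution; the resulting class-by-bin sums
are the *pseudo-counts*.

Numerical decisions: the weight denominator is always the full interval
length (upper − lower); a point estimate (upper = lower) contributes unit
mass to its containing bin, with the top boundary belonging to the last bin;
mass falling outside the outermost boundaries is truncated and the weight
vector renormalized to one (an interval entirely outside the range yields an
all-zero, flagged vector and drops out of the tables). Renormalization
rather than plain truncation was chosen so that every retained variant
counts exactly once — the alternative silently down-weights very young and
very old variants. Boundary ties from duplicate sampled ages are broken by
enforcing strictly increasing boundaries with an epsilon step.

## Pairwise ratios and tests

GC-biased gene conversion (gBGC) favors strong (C/G) over weak (A/T) alleles
with population-size-dependent intensity, so raw class fractions confound
mutation and transmission. The four ratios compared are matched for gBGC
side: non-CpG C>T / non-CpG C>A, CpG C>T / CpG C>A, C>G / T>A, and
T>C / T>G (with a TpG-excluded variant of the last). The CI of a ratio
n1/n2 treats n1 as binomial given n1+n2: the proportion gets the Wald
interval p̂ ± z·sqrt(p̂(1−p̂)/(n1+n2)) (z = 1.96 by default) and is mapped to
the ratio scale by p → p/(1−p). Interpopulation differences are tested per
bin and ratio with a Pearson chi-square on the 2 × N_pop pseudo-count table
— fractional entries are used directly, without rounding or continuity
correction — and Bonferroni-corrected by (bins × ratios), 60 tests by
default, with significance tiers *p<0.01, **p<1e-4, ***p<1e-8. Bins where a
class has zero pseudo-counts propagate NaN p-values rather than fabricating
a test.

Region stratification (accessibility masks, maternal C>G hotspots, B-score
and recombination strata) uses BED intervals (0-based, half-open) against
1-based variant positions; the conversion lives in one function.

## Poisson parental-age model for DNMs

Per mutation class, the expected DNM count inherited from a parent is linear
in that parent's age at conception: paternal mean βp·Fa + αp, maternal mean
βm·Mo + αm (intercepts at age zero, slopes per year). Counts are Poisson.
Parent-of-origin is known only for phased DNMs; with the per-trio phased
fraction φ treated as known (computed from the trio's own phased/unphased
totals pooled across classes), the likelihood is

    phased_paternal ~ Poisson(φ·(βp·Fa + αp))
    phased_maternal ~ Poisson(φ·(βm·Mo + αm))
    unphased        ~ Poisson((1−φ)·(βp·Fa + αp + βm·Mo + αm))

which uses all DNMs and reduces to the plain Poisson model at φ ∈ {0, 1}.
The log-likelihood is concave wherever the means are positive, so the MLE is
found by SLSQP with analytic gradients, linear non-negativity constraints on
the means at the observed age extremes, a method-of-moments start plus
random restarts (three for point fits, one per bootstrap replicate), and a
1e-8 relative tolerance on the log-likelihood. An all-zero count table
returns the boundary MLE (all parameters zero); a design with a single
distinct age per parent raises an identifiability error.

Trio-level filters mirror standard pedigree practice: named outlier trios
are dropped, as are trios with maternal age strictly above 40 years, where
the maternal effect is known to turn nonlinear. Uncertainty is by bootstrap
resampling of trios (default 500 replicates, percentile CIs at 90%); the
quintile contrast ranks trios by the sum of parental ages (the simplest
symmetric score — the choice of score is genuinely open) and compares the
CpG C>T / CpG C>A count ratio between the bottom and top 20% by a 2×2
chi-square.

## Generation-time inversion

If reproductive-age shifts alone drove a ratio change, the observed
pseudo-count ratio R in a bin satisfies
(βp1·Gp + αp1 + βm1·Gm + αm1)/(βp2·Gp + αp2 + βm2·Gm + αm2) = R. Fixing
γ = Gp/Gm (grid 0.8, 1.0, 1.1, 1.2) gives the closed form

    Gm = [R·(αp2 + αm2) − (αp1 + αm1)] / [(βp1·γ + βm1) − R·(βp2·γ + βm2)]

flagged infeasible when the denominator is below 1e-12 in magnitude, Gm is
non-positive, or either age leaves the plausible reproductive range
(default 13–55 years, puberty to reproductive cessation; configurable). With
Gp, Gm free the solutions form a line a·Gp + b·Gm = c whose coefficients are
reported for contour plots. Bootstrap CIs pair the two classes' replicates
by resample index (both classes refit on the same resampled trios),
preserving their correlation; percentiles are taken among feasible solutions
and the infeasible fraction is reported. The solver optionally accepts the
observed ratio's own CI endpoints alongside the point estimate, folding
polymorphism-count noise into the interval — at desk-scale variant counts
that noise dominates the pedigree uncertainty and ignoring it would make
even a true constant-generation-time scenario look internally inconsistent.

## Power simulations

For two populations with generation times G1 and G2, expected fractions of
C>G and T>A among all de novo single-nucleotide mutations follow from the
fitted effects at (G, G); per replicate, binomial counts at the observed SNP
number feed a 2×2 chi-square (types × populations), and power is the
fraction of replicates with p below α (default 0.001, 10,000 replicates).
Maternal C>G hotspots are modeled from their defining property: 10% of the
genome holding one-third of the overall maternal age effect while containing
<15% of SNPs. All parameters scale with the region's genome share except the
maternal C>G slope, whose hotspot share is derived as
(total maternal slope / 3) / βm(C>G), capped at 1 — with a realistic
maternal slope structure this concentrates nearly the whole maternal C>G
effect in the hotspots, which is exactly what makes the within-hotspot test
better powered despite far fewer SNPs.

## NMF signature extraction

The 96-context × (bin × population) matrix is column-normalized by the SNP
total per bin (columns sum to one). Factorization uses the classic
KL-divergence multiplicative updates, implemented in-package so that the
per-iteration objective is available (its monotone decrease is tested) and
so that consensus restarts can be accumulated: across random restarts each
column is assigned to its dominant signature, the mean connectivity matrix
over restarts is clustered by average linkage, and the cophenetic
correlation measures assignment stability. `select_rank` returns the
smallest rank maximizing the cophenetic coefficient among ranks explaining
at least 99% of variance (both the threshold and the number of restarts,
default 50, are parameters; ties in cophenetic value break toward the
smaller rank). scikit-learn's KL-NMF serves as an independent cross-check in
the tests, never as the implementation.

## Synthetic data: what it emulates and what it does not

The variant generator draws independent SNPs under a piecewise-constant
(epoch-wise) spectrum: a variant's epoch is chosen in proportion to epoch
duration, its true age uniformly within the epoch, its class from the
epoch's fraction vector, its flanking context uniformly among triplets
compatible with the class, and its strand orientation at random. The
reported age interval is a uniform uncertainty window containing the true
age whose relative half-width is lognormal with median 0.5 and log-sd 0.6,
mimicking the order-of-magnitude uncertainty of genealogy-based ages and
exercising multi-bin weight spreading. Presence flags are Bernoulli per
population with per-epoch probabilities; a variant observed nowhere is
assigned to one random population, since unobserved variants never enter a
call set.

The trio generator draws parental ages from normals truncated to [10, 60]
years (defaults 30 ± 5 paternal, 28 ± 5 maternal), Poisson counts from the
linear means, and phases each DNM independently with a fixed probability
(default 0.4), so phased + unphased totals are conserved exactly.

The default per-class effects (`DECODE_SCALE_EFFECTS`) are calibrated to the
scale of large Icelandic pedigree cohorts: ~60 DNMs per trio at parental age
30, paternal slopes several-fold maternal ones for most classes, a strongly
maternal C>G slope, and pairwise-ratio age dependencies of the reported
magnitudes (C>G/T>A rising ~12% and non-CpG C>T/C>A falling ~9% between
parental ages 20 and 40, T>C/T>G falling a few percent). These are synthetic
defaults, not fitted values.

Not modeled: coalescent genealogy, linkage, selection, gBGC dynamics,
recurrent mutation and mis-polarization, posterior (non-uniform) allele-age
distributions, or context frequency biases beyond the class definitions.
Consequently, passing tests demonstrate the correctness and calibration of
the estimators and tests under the assumed models — they do not certify
robustness to genealogical correlation between variants, systematically
biased age intervals, or polarization error, all of which affect real data.

## Problem sizes

The test suite and the acceptance script run everything at desk scale, as
the package's own defaults for simulation studies: 10,000 trios for point
recovery; 200 outer simulations × 120 bootstrap replicates at 1,000 trios
for CI coverage; 1,000 tables for chi-square calibration; 10,000 replicates
for power calibration at up to 10^6 SNPs; 60,000–240,000 variants for the
end-to-end scenarios; 96 × 45 matrices with ~10 restarts per rank for NMF.
Real-data analyses would scale the same code to millions of variants and
thousands of trios.
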