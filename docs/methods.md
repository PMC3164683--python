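# Methods

## Crossover calling by sibling comparison

A marker is *informative* for a parent when that parent is heterozygous,
the co-parent is homozygous, and every child of the nuclear family is
called and consistent with the co-parent's obligate allele.  The allele the
heterozygous parent transmitted to each child is then the child's call
minus the co-parent's contribution.  Genotypes are coded as the dosage of
the BIM's second allele, with −1 as the missing sentinel; coordinates are
1-based as in BIM, and all internal intervals are closed `[left_bp,
right_bp]` (conversion to 0-based half-open happens only in the BED
writer).

Phasing uses the first child (pedigree order) as reference: at each
informative marker, a sibling is in state H1 if it received the same
parental allele as the reference child, H2 otherwise, and the reference
child itself starts in H1.  A switch appearing simultaneously in *all*
non-reference children at one inter-marker interval is re-attributed to the
reference child (its state toggles; the others' apparent switches vanish).
For families of up to four children this rule makes the called total equal,
at every interval, the minimum over all parental haplotype assignments —
the test suite verifies equality with an exhaustive 2^M enumeration oracle
on every toy family at three sizes and on random families up to 4 children
× 12 markers.  With five or more children the rule can exceed the
parsimony minimum at intervals where a strict majority (but not all) of
children switch; such configurations are essentially always artifacts and
are caught by the shared-event filter below.  With exactly two children a
switch cannot be attributed to a specific child, so 2-child families
contribute pair-level events flagged `assigned=False` and never enter
per-child analyses.

Three refinements on the basic heuristic:

1. **Pre-treatment.** A single informative marker whose state in some
   child differs from both flanking informative markers, with the flanks
   less than `window_bp = 1 Mb` apart, implies two crossovers within 1 Mb —
   at fine scale almost always one genotyping error.  The *marker* is
   removed for all children (not just the events), left-to-right,
   repeating to a fixpoint since a removal can expose a new blip.
   Two-marker islands are retained at any span: two markers support the
   switch, and at realistic error rates adjacent double errors are
   negligible.
2. **Unique events only.** Events with `n_children_sharing ≥ 2` (same
   parent, same inter-marker interval) are removed entirely, in families
   of every size — shared switches are phase errors or shared artifacts.
3. **Reduced families.** Unique-only counting biases large families
   downward, so families with ≥ 4 children are re-called over every
   3-child subset (deduplication applied inside each subset), and a
   child's unbiased count is the mean over the C(n−1, 2) subsets
   containing it.  Three-child families pass through unchanged.

Switch intervals interrupted by removed or undetermined markers are
delimited by the nearest determined flanking markers.

## QC and filters

SNP QC removes call rate < 0.95 and founder-only Hardy–Weinberg exact
p < 0.01 (children would distort the genotype frequencies; the exact test
follows the standard conditional-on-allele-counts construction, checked in
tests against full enumeration with rational arithmetic).
Mendelian-inconsistent trio genotypes are set missing in all three members,
and a SNP is dropped when inconsistencies occur in more than one family
(configurable).  The family-missingness filter then removes every SNP with
any missing call in any member of any calling-eligible nuclear family, so
all families are evaluated on an identical, fully-called SNP set.

## Synthetic cohorts

The simulator is first-class, tested code; its defaults are the study
condition used throughout: 40 nuclear families of 3 children, 4
chromosomes of 150 Mb × 2,000 SNPs, allele-B frequency ~ Uniform(0.1,
0.5), maternal first-birth age ~ Normal(26, 4) clipped to [18, 40] with
inter-birth spacing 1 + Gamma(2, 1.25) years (mean 3.5), paternal age =
maternal + 2.  Crossovers per meiosis and chromosome are
Poisson(max(0, a_c + b_c·age)); the default genome-wide maternal slope is
−0.5 crossovers/year split evenly (b_c = −0.125) with intercepts set so
the maternal mean at age 28 is 2 events per chromosome (a large-autosome
female rate; a 4-chromosome desk genome cannot carry a 42-event genome-wide
mean and is not meant to).  Positions are uniform on physical length — no
interference, no arm-position gradient — with an optional hotspot mode
placing a fraction *h* of events inside supplied intervals.  Genotyping
errors are single-step code flips (0↔1, 2↔1, 5% of errors 0↔2), chosen
because single-marker flips are exactly what produces spurious tight
double recombinants; missingness is independent.  Sampling-time ages are
assigned (mother observed 10 years after her last birth) so that
age-rounding analyses can recompute ages-at-birth from coarsened
individual ages.

What passing tests on these cohorts do **not** show: behaviour under LD
among founder haplotypes, crossover interference, sex-specific genetic
maps beyond per-sex rates, platform-specific error structure, or cohort
ascertainment.  Results on real data depend on those.

## Age statistics

Counts are treated as Gaussian throughout.  Family adjustment subtracts
the mother's own mean from each transmission's count and age, so only
within-family contrasts remain; the adjusted regression is OLS on those
residuals.  The mixed model adds a random intercept per mother (REML), and
optionally the mother's number of children as a fixed covariate.  The
penalized spline is the standard mixed-model representation of a linear
spline: fixed intercept + slope, one truncated-line term (age − κ)₊ per
distinct age treated as iid random coefficients (the largest knot's term is
identically zero and is dropped), plus the mother intercepts; the
smoothing parameter is reported as λ = σ²_residual / σ²_spline from REML.

Permutation p-values use the add-one convention p = (b+1)/(n_perm+1)
(never zero, exactly valid under exchangeability) with two-sided
extremeness by absolute value unless a direction is stated.  Three schemes
fix the exchangeability unit: ages permuted across all transmissions;
ages permuted within each mother's transmissions (for family-adjusted
analyses — between-family structure must be preserved); and children
reassigned among parents with family sizes kept (for the among-parent
variation ANOVA).  The spline-vs-linear test permutes linear-fit
residuals, which preserves the straight-line trend while destroying
curvature; the reference LRT distribution at a variance boundary is
non-standard, so no parametric p is offered.  The adjusted regression's
permutation loop is vectorized (sort-by-random-key within family) so that
calibration studies with thousands of replicates stay cheap.

Age categories are left-closed: <25, [25, 30), [30, 35), ≥35, and the
under/over-30 split places a parent aged exactly 30 in the older group.

## Chromosome effects and genome position

Per-chromosome shift tests compare mean counts between the two maternal
age groups, one-sided for a decrease by default, with label permutation.
Redistribution simulations reallocate each transmission's total across
chromosomes by a multinomial draw — probabilities proportional to the
cohort's per-chromosome means ("proportional", conserving both totals and
the expected chromosome profile) or equal ("uniform") — and rerun the
shift tests, giving the null distribution of the number of significant
chromosomes.  Normalized counts divide by the cohort's per-chromosome
mean.  The closed-form chance probability that ≥ 2 of n chromosomes reach
per-chromosome significance p with both shifts in the same direction is
[1 − (1−p)ⁿ − np(1−p)ⁿ⁻¹]·0.25.  A hypergeometric enrichment helper for
centromere-position classes takes a user-supplied classification;
chromosome classifications differ between sources, so none is packaged or
asserted.

Event location is the interval midpoint (the interval is the caller's
native resolution; no point representation is canonical).  Relative arm
position is |midpoint − centromere| / arm length, 0 at the centromere and
1 at the telomere, binned by floor(position/width) with 1.0 closed into
the last bin.  The packaged centromere/length table is an approximate
NCBI36-era autosome table for convenience; pass your own for real
coordinates.  Hotspot congruence restricts to events localized to < 30 kb
(wider intervals carry too little positional information), counts
any-overlap of the closed interval with merged hotspot intervals, and
compares with the interval-dilation expectation min(1, Σ_h(len_h +
len_event)/len_chrom) per event — a uniform-placement approximation that
ignores edge effects and overlapping dilations, adequate at realistic
hotspot densities.

## The non-disjunction protection model

Inputs: π(r), the proportion of oocytes with r crossovers (assumed the
same at every age — the ovarian pool's recombination make-up is fixed
before birth), and P_k(r), the probability of proper disjunction at age
period k.  Direct conditioning gives the mean crossover count among
properly disjoined (E_N) and non-disjoined (E_A) oocytes, and the law of
total expectation holds identically (tested to 1e-12).

A point the algebra forces: for E_N to *decrease* and E_A to *increase*
with age — the pattern that reconciles falling recombination in live
births with rising recombination in trisomies — it is the
*r-discrimination* of protection that must weaken with age, not merely its
level.  Scaling P_k by an r-independent factor leaves both conditional
means unchanged, and a family like r/(r+c_k) with c_k growing becomes
*steeper* in r, enriching survivors for high-r oocytes and pushing E_N
up.  The three shipped presets therefore flatten the r-dependence with k
(a shrinking-weight mixture with an r-independent baseline, a
shrinking-slope linear family, and a widening logistic), pulling E_N and
E_A toward the unconditional mean from above and below while the
aneuploidy rate climbs; each is verified numerically rather than assumed,
and `check_monotonicity` reports (never asserts) the trends for arbitrary
user-supplied models.  r ranges over 0..6 by default, appropriate for
single-chromosome counts; π may be supplied empirically from caller
output.

## Pipeline, resampling, power

The pipeline derives a logged sub-seed per stage from the master seed
(SeedSequence, kept below 2³¹), writes events BED / records TSV / stats
JSON, and keeps exact filter bookkeeping (SNPs in = retained + removals at
every step).  The bootstrap resamples whole families with replacement
(transmissions within a mother are correlated; resampling them
independently would understate variance) with percentile 95% intervals —
with ~25 families the realized coverage is ≈92%, the usual small-sample
percentile shortfall.  The jackknife variant leaves one family out at a
time.  The power analysis re-calls events after keeping a random fraction
of SNPs (0.8/0.4/0.3/0.2/0.05 by default, four replicates each) and
optionally after rounding ages up to 5-year multiples, re-estimating the
age effect each time; with rounded ages the categorical ANOVA replaces the
linear fit, since rounding breaks the linear age scale.

## Numerical choices and degenerate inputs

Zero-variance responses in the regression return slope 0 with a
`degenerate` flag instead of NaN.  Permutation comparisons use a 1e-12
slack so exact ties count as "at least as extreme".  MixedLM boundary
warnings (variance estimates at zero) are suppressed inside the fitting
routines and surfaced via the `converged` flag.  Problem sizes in the test
suite (cohorts of 10–40 families, 2–4 chromosomes, 300–2,500 SNPs each;
permutation counts of 50–2,000; 1,000 calibration replicates at n_perm =
199) were chosen as the smallest sizes at which the statistical assertions
have comfortable power.

## Limitations

The caller is a parsimony heuristic, not a probabilistic model: it cannot
see crossovers beyond the outermost informative markers (called means sit
a few percent below truth at desk-scale densities), cannot separate tight
true double crossovers from artifacts below the 1 Mb window, and inherits
the reference-child attribution convention.  The expected-overlap formula
and the packaged centromere table are approximations.  The spline's
p_vs_linear is a residual-permutation construction, not an exact boundary
LRT.  None of the statistics model count overdispersion beyond what the
mother random effect absorbs.
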