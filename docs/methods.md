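# Methods

This package re-implements, as a tested pipeline over synthetic data, the
analysis chain used to contrast the molecular evolution of male-biased (MB),
female-biased (FB) and unbiased (UB) genes in a dioecious plant with
replicated two-tissue RNA-seq: classification of sex-biased expression, then
category-level divergence, polymorphism, selection and codon-usage-bias
statistics.  This note documents the models, the defaults, the numerical
choices, and what the synthetic validation does and does not establish.

## Expression processing and sex-bias calls

RPKM is `1e9 * count / (length_bp * library_size)`.  A gene is "expressed"
in a tissue when at least ceil(n/2) individuals of at least one sex reach
2 RPKM (inclusive; for 3 individuals per sex this is 2 of 3).  Samples are
TMM-normalized per tissue: reference sample by upper-quartile count
fraction closest to the mean, gene-wise M/A values against the reference
doubly trimmed (30% per tail on M, 5% on A), precision-weighted mean M,
factors rescaled to geometric mean 1.  The factors agree with edgeR's
`calcNormFactors` to ~1e-3 on test matrices (edgeR is used only as a test
oracle, never called by the pipeline).

The differential test is a stand-in with a documented contract rather than a
bit-reproduction of any DE package: counts are scaled to a common effective
library size, a single common NB dispersion is estimated by the method of
moments across genes (median of per-gene `(var - mean)/mean^2`, floored at
1e-4), and the two group sums are compared with an exact-style conditional
NB test (group sums are NB with dispersion phi/n; conditioning on the total,
the two-sided p sums outcome probabilities no larger than the observed
one).  For conditional totals above 5,000 a normal approximation to the same
conditional distribution is used.  P-values are BH-adjusted across tested
genes.  Calls: MB iff log2 M:F > 1 with adjusted p < .05, FB iff < -1 with
adjusted p < .05, else UB.  The log2 fold change uses mean normalized
abundances with a pseudo-offset of 0.25 counts (the source analysis is
silent on this; the offset only matters near zero).  Fold-change classes:
FC <= -3, (-3, -1], (-1, 1), [1, 3), >= 3.

"Average expression" in summaries is the mean over individuals of
log2(RPKM + 1), averaged over genes; rank tests are two-sided
Mann-Whitney/Wilcoxon (exact for small n, normal approximation with tie
correction otherwise, via scipy).

## Alignment masking

Two sliding-window passes per taxon on gap-stripped codon alignments:
window 15 with more than 7 amino-acid mismatches against the column majority
of the other taxa masks the window; then window 4 with more than 2.  Both
inequalities are strict; windows slide by one codon and masked windows
union; majority ties are not scored (conservative); codons containing N are
excluded from window counts.  The upstream tool this emulates compares
branch-specific substitutions; the per-taxon-vs-majority comparison is a
documented approximation, not asserted identical.  After masking, genes with
fewer than 300 clean bp are dropped (exactly 300 passes).

## Divergence on the focal branch

The focal-species branch is isolated by reconstructing the codon sequence of
the Salix ancestor with per-site Fitch parsimony over S. suchowensis and the
three Populus outgroups.  A site whose most-parsimonious assignments are
tied is unresolved; any codon containing an unresolved site (or whose
reconstruction is a stop) is skipped.  Because the skip rule involves only
non-focal taxa, retention is independent of focal-branch events and does not
bias the focal rates.  Differences between the focal tip and the ancestor
are scored with Nei-Gojobori counting: single differences directly,
multi-difference codons by equal-weight averaging over stop-free mutational
pathways (if every pathway crosses a stop, all pathways are used and stop
steps score as nonsynonymous).  Site totals use the NG86 convention (per
position, the synonymous fraction of single-nucleotide changes, stops
excluded from numerator and denominator) on the *ancestor* sequence, so
N + S = 3 x counted codons exactly.  Genes with d_S > 2 are discarded as
saturated (strict inequality).

This counting estimator stands in for an ML branch model.  Its validated
operating range is moderate outgroup divergence: at the generator defaults
(below) ancestor misassignment affects < 0.1% of codons and the category
omega is recovered within ~2%.  At substantially deeper outgroup branches,
irreducible double events (a change on the Salix-ancestor branch plus a
parallel change or reversal on the sister branch) contaminate the focal
counts — predominantly with synonymous changes — and the estimator reads
low; this is precisely why ML is the tool of choice on real willow/poplar
data, and why per-gene values here are not comparable bit-for-bit with ML
output.

## Polymorphism and the matched site basis

A site is a valid SNP when coverage >= 20 in at least half the individuals
of one sex, the pooled minor-allele frequency is >= 0.20, and the alternate
allele has >= 3 supporting reads.  MAF pools read counts over all
individuals at the site: pooling only over coverage-passing individuals
(one reading of the rules) breaks monotonicity — raising the coverage
threshold could then *admit* sites — so the monotone variant is
implemented.  Read-level caller parameters (base quality, strand filter,
homozygote frequency) are not reproducible from a site table and are
omitted.  Variants are classified against the reference codon in frame;
variants creating stops are nonsynonymous and flagged; codons with several
segregating sites contribute each variant independently.

For MK-style contrasts, both analyses are recomputed over "matched" codons:
all three sites pass the coverage rule, the codon survived gap stripping,
and no taxon is masked or ambiguous.  Divergence counts, polymorphism
counts, and the shared (N, S) totals all come from this one codon set, so
d_N/p_N and d_S/p_S use identical denominators by construction.

## Category statistics

Category-level rates are ratios of sums (`d_N = sum D_N / sum N`, etc.),
never means of per-gene ratios — low-d_S genes would otherwise contribute
unstable, occasionally infinite ratios.  Concatenating gene sequences and
estimating once is algebraically identical for a counting estimator, and
that identity is asserted exactly in the tests.  Uncertainty: percentile
bootstrap over genes (1,000 reps, 2.5/97.5 percentiles); contrasts:
two-sided permutation tests on the difference of group aggregates (1,000
label shuffles preserving group sizes) with the add-one p-value
`(1 + #extreme)/(reps + 1)`.  The gene is the resampling unit in both.
Resampled statistics that are undefined (zero denominators) count as
extreme, and a contrast whose observed statistic is undefined reports NaN
rather than a p-value.  The three pairwise contrasts (MB-UB, FB-UB, MB-FB)
are reported without multiplicity adjustment.  Strata: genes overlapping
the nonrecombining-Z BED interval (3.5-8.8 Mbp) versus everything else
(autosomes plus the recombining/pseudoautosomal Z).

## Selection tests

Per gene, the 2x2 MK table contrasts (D_N, D_S) with (P_N, P_S);
pathway-averaged D counts are rounded half-up to integers.  Genes with any
row or column margin below 6 are excluded (the four margins of the 2x2).
Fisher's exact test is two-sided (scipy; verified against hypergeometric
enumeration to 1e-10); a significant gene is "positive" when additionally
D_N x P_S > P_N x D_S, which on the shared site basis is d_N/d_S >
p_N/p_S.  DoS = D_N/(D_N+D_S) - P_N/(P_N+P_S), defined only when both sums
are positive; category DoS is the unweighted mean over defined genes, with
Fisher tests on DoS > 0 counts and Wilcoxon rank-sum on per-gene values.

## Effective number of codons

Per amino-acid family, F = (n * sum p_i^2 - 1)/(n - 1); Nc = 2 + 9/F2 +
1/F3 + 5/F4 + 3/F6 over the universal-code degeneracy classes, capped at
61.  Families with n < 2 or F <= 0 are dropped from their class average; a
missing threefold class is recovered as F3 = (F2 + F4)/2; if a 2/4/6-fold
class is entirely absent the gene is flagged undefined and excluded from
category means.  Stops are excluded throughout.  Other implementations may
handle missing families differently; the rule here is documented, not
asserted identical to codonW.

## Expression-level confounders

Quartile analysis: within each bias class, quartile cuts on mean
log2(RPKM+1) with sum-aggregated d_N/d_S and bootstrap CIs per cell.
Regression: OLS of per-gene d_N/d_S (genes with d_S = 0 excluded and
counted) on expression, a degree-of-sex-bias code, and their interaction.
The bias coding is genuinely ambiguous in the source description; the
default maps the five fold-change groups to a signed ordinal -2..+2 (so a
negative coefficient means lower d_N/d_S toward male bias); a magnitude
coding 0/1/2 is available via `coding="magnitude"`.  d_N/d_S is regressed
untransformed.

## The synthetic-data generator

The generator defines the study conditions every test runs under.

*Alignments.*  Codon sequences evolve root-to-tips on the fixed tree
((S.viminalis, S.suchowensis), ((P.tremula, P.tremuloides),
P.trichocarpa)).  Per branch, a Poisson number of candidate
single-nucleotide events (branch length = expected candidates per codon)
lands uniformly on sites; candidates creating stops are rejected,
synonymous candidates accepted, nonsynonymous accepted with probability
omega (focal branch: the gene category's omega; other branches: the UB
omega).  With the default ts/tv ratio of 1 the candidate distribution
matches the equal-weight NG86 site convention, making the counting
estimator asymptotically calibrated — that is the point of this process;
setting kappa != 1 reintroduces the classical NG86 bias.  Root sequences
draw codons with a per-category preferred-codon weight (the first codon of
each family), which is what makes the ENC contrast rehearsable.  Defaults:
focal branch 0.045 (expected d_S ~ 0.015, the magnitude the study reports),
category omegas 0.22/0.195/0.21 (UB/MB/FB), outgroup branches 0.03-0.12 —
deliberately shallower than the real willow/poplar divergence to stay in
the estimator's validated range (see above).  Every accepted event is
logged; replaying the log from the root reproduces each tip exactly, and
the log is the oracle for estimator validation.

*Expression.*  NB counts (dispersion 0.1) for 3+3 individuals in catkin and
leaf; MB/FB genes get +/- half the configured log2 fold change (default 2)
per sex in catkin only; leaf has no injected bias, mirroring the near-total
absence of leaf sex-bias in the study system.  Library sizes vary ~25%.

*Site tables.*  Candidate variants at 0.02 per CDS site; nonsynonymous
candidates survive with probability omega (purifying selection on
segregating variation), so realized synonymous polymorphism lands near the
study's p_S ~ 0.01.  Alternate-allele counts follow the neutral 1/k
spectrum over the 12 chromosomes; coverage is Poisson (mean 30) per
individual; read counts split binomially by genotype dosage.  Both
MAF-passing and MAF-failing variants therefore exist.

What the generator does *not* emulate: alignment error (masking is
exercised on constructed fixtures, and on clean simulations the masked
fraction is ~0), indels, sequencing error in read counts, mapping bias,
linkage between sites, demography beyond the fixed SFS, and expression-
divergence coupling (d_N/d_S is independent of expression level by
construction, so the regression stage's null behaviour is testable but its
power comes from separately constructed count sets).  Passing tests
demonstrate internal correctness and statistical calibration under these
conditions, not performance on real sequencing data.

## Problem sizes used by the test suite

The calibration checks run at sizes chosen to give tight Monte-Carlo error
on one CPU: permutation type-I error on 1,000 exchangeable count-level null
pairs (200 genes per group, 200 permutations); omega recovery/power on 50
replicate simulations of 200 genes x 300 codons (omega 0.10 vs 0.22, 1,000
permutations); bootstrap coverage on 500 replicate simulations of 150 genes
x 300 codons (1,000 bootstrap reps).  The numbered analysis scripts run a
300-gene x 400-codon study.
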