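# Methods

This note documents the statistical models, default parameters and design
choices behind `crevol`, and what the synthetic-data validation does and
does not establish about real data.

## Count model for differential histone modification

ChIP-seq read counts over orthologous regions are modelled as negative
binomial, `Var(Y) = mu + alpha*mu^2`.  For a comparison of two species
groups A and B, each region is fitted with the log-link GLM

    log mu_ij = beta0 + beta1*assay_j + beta2*cond_j + beta3*assay_j*cond_j + log s_j

where `assay_j` indicates IP vs input chromatin, `cond_j` membership of
group A, and `s_j` the sample's median-of-ratios size factor.  `beta3` is
the quantity of interest: the group difference in IP enrichment *over
input*.  Testing the interaction rather than the IP counts alone means
shared artefacts (mappability, copy number, input-visible signal) cancel,
because they move IP and input together.  The Wald statistic
`beta3/se(beta3)` is referred to the standard normal; two-sided p-values
are BH-adjusted within each comparison (FDR < 10% for histone marks,
< 5% for expression).  `log2FC = beta3/ln 2`.

Fitting is IRLS with step halving (deviance is non-increasing by
construction), convergence at max coefficient change < 1e-8 or 100
iterations, covariance from the inverse Fisher information at fixed
dispersion.

**Dispersion.**  Per-region maximum likelihood with the Cox–Reid
adjustment `-0.5 log det(X'WX)`, profiled on fitted means from an initial
Poisson-limit fit, bounded to [1e-8, 10].  The adjustment matters: with
12 samples and 4 coefficients, unadjusted ML underestimates alpha by
roughly 40% and visibly inflates the Wald test's tails; with it, the null
type-I error at p < 0.05 is within a couple of points of nominal (the
residual inflation of the normal reference at n = 12 is accepted — the
Wald/normal convention is part of the testing contract).  No
empirical-Bayes shrinkage across regions is applied; with >= 6 samples
per comparison per-feature estimation is adequate and keeps the estimator
free of cross-feature modelling assumptions.  This is a deliberate,
documented divergence from shrinkage-based packages.

Regions with all-zero IP counts in a comparison are reported `untested`
and excluded from that comparison's BH denominator.

## Conservation classification

Nine comparisons form the battery: the reference (human) against each of
the five other species, reference vs all others, ape vs the rest,
Catarrhini vs the rest, and Haplorrhini vs Strepsirrhini.  Group A always
contains the reference, fixing the sign convention.  Labels from the
per-CRE significance vector:

- `conserved` — no comparison significant (`ns`/`untested` everywhere);
- `human_specific` — reference-vs-rest significant and all five pairwise
  significant with one sign;
- `ape_specific` / `catarrhini_specific` / `haplorrhini_specific` — the
  clade group test significant, within-clade pairwise comparisons `ns`,
  and all cross-clade pairwise comparisons significant with one sign;
- `other_divergent` — anything else.

The conjunction of group and pairwise evidence is the strictest reading
of a battery that is defined only by its comparisons; a group-test-only
mode (`require_pairwise=False`) is provided.  An `untested` entry in a
required comparison always blocks a lineage-specific label — missing
evidence never produces a positive claim.  The classifier is a pure
function of the vector, so calls can be re-derived at any FDR from the
stored tables (`calls_at_threshold`), and the conserved count is monotone
non-increasing in the threshold.

## Orthology mapping and divergence

A human interval is projected through each MAF block as the span of a
species' non-gap columns aligned to the human interval's columns.
Coverage is the fraction of human bases aligned to a base in the species;
the default `min_coverage = 0.5` defines presence, and `six_way` requires
all six species present.  Multi-block projections are stitched only when
collinear on one strand; otherwise the best single block wins (ties to
the lower coordinate) — preventing chimeric orthologs.  Minus-strand rows
are normalised to forward coordinates.  These rules are explicit design
choices: there is no standard convention for coverage thresholds or
multi-block stitching when defining six-way orthologous intervals, so
both are exposed as configuration.

Divergence is counted over the CRE ± 500 bp: columns where human has a
gap are excluded entirely; columns where the other species has a gap, or
either base is N, are excluded from the denominator; divergence =
mismatches/compared columns, case-insensitive.  Per species-pair
distributions are screened with an iterative two-sided Grubbs test at
alpha = 0.05 (groups < 3 never flagged); flagged records are excluded
from downstream regressions.

## TE annotation and enrichment

A CRE is TE-derived when the union of TE intervals covers >= 20% of its
length (boundary inclusive; nested repeats not double-counted).  The
enrichment null re-places every CRE uniformly at random on its own
chromosome, preserving length but not spacing, 1,000 times; per
subfamily, the empirical enrichment p is `(r+1)/(n+1)` with `r` the
number of shuffles reaching the observed flagged count — so p is never 0
and bottoms at 1/1001.  A one-sided depletion p is reported but does not
feed the enriched flag (FDR < 1% on BH-adjusted enrichment p).  An
optional exclusion mask (rejection sampling) stands in for assembly-gap
masking; GC- or mappability-matched nulls are out of scope.

## Association statistics

- **CMH**: Mantel–Haenszel common OR `sum(a_i d_i/n_i)/sum(b_i c_i/n_i)`
  with the chi-square computed without continuity correction; the strata
  are the five reference-centric pairwise comparisons (gene DE x gene has
  a differentially modified CRE), a documented assumption since the
  stratification is not pinned down externally.
- **Fisher**: two-sided exact p by hypergeometric enumeration with the
  conditional-MLE odds ratio; zero-margin tables return p = 1 with OR
  undefined.
- **Logistic**: Newton-fitted logit GLM, Wald p on the slope; complete or
  quasi-separation and non-convergence are flagged with the p omitted;
  constant covariates are rejected.  Quantile covariates (TSS distance,
  cell-type specificity) default to deciles with ties assigned to the
  lower bin.

## Reporter assays

Construct vs pooled control activities are compared by the two-sided
Wilcoxon rank-sum test — exact null enumeration when both n <= 25 with no
ties, normal approximation with tie correction otherwise.  Direction
(activator/repressor) requires p < alpha = 0.05 and uses the median
ratio; six replicates per construct is the default design.  Raw p-values
are reported per construct with a BH column available but not used for
direction by default.

## Synthetic data generator

The generator emulates the study conditions so that every stage is
testable against ground truth:

- **Tree**: fixed topology
  `(((((human,chimp),rhesus),marmoset),(mouse_lemur,bushbaby)))` with
  branch lengths calibrated so observed mismatch fractions to human run
  from ~1% (chimp) to ~15% (strepsirrhines).
- **Sequence**: Jukes–Cantor substitutions (the downstream divergence
  estimator is model-free mismatch counting, so the simplest generator
  suffices); indels at one tenth of the substitution rate, geometric
  lengths (mean 3) — enough to exercise gap handling without dominating
  the alignment.  TE insertions are extra aligned columns appearing on
  their insertion branch: SVA_F on the human branch, SVA_B/C/D and LTR12C
  on the ape branch, AluY/L2/MIR at the root.  One alignment block per
  CRE (400–1,000 bp core + 500 bp flanks), laid out with 2 kb unaligned
  spacers on three chromosomes.
- **Counts**: IP ~ NB(depth x 2^(ip_enrichment + effect), alpha), input ~
  NB(depth, alpha), with depth 100, IP/input enrichment 2 (log2),
  dispersion alpha = 0.05, and |log2FC| = 2 activity effects on the
  gained/lost branch; three individuals per species (both sexes except
  bushbaby).  Per-sample log-normal factors (sigma 0.15) inject the depth
  heterogeneity that size-factor normalisation must remove.  RNA counts
  couple each linked gene to half of its CREs' mean activity effect.
  The within-species dispersion is not externally constrained; 0.05 is a
  typical bulk-tissue value and is exposed in the config.
- **Truth mixture**: 60% conserved and 8% in each divergent class
  (human-, ape-, Catarrhini-, Haplorrhini-specific, and "other" branches)
  — conserved dominates, as in real primate liver data, while every
  lineage class stays large enough (~160 of 2,000) for stable recovery
  estimates.  TE placement is state-dependent (young families on recently
  gained CREs, ancient families on conserved ones), rescaled so ~25% of
  CREs carry a TE.
- **Seeding**: a single master seed; per-stage generators derived
  deterministically, so identical configs give byte-identical bundles.

**What the synthetic validation does not show.**  The generator omits
read-level artefacts (mappability, GC bias), peak-calling uncertainty,
assembly incompleteness, batch structure and sex chromosomes, and it does
*not* couple sequence divergence to activity divergence — so the
divergence-vs-modification logistic regression on synthetic data tests
the machinery, not the biological association (its slope is expected
near 0 there).  Passing recovery tests demonstrate correctness of the
statistics and bookkeeping under the stated model, not robustness to
real-data artefacts.

## Problem sizes and numerics

The default validation bundle is 2,000 CREs / 1,000 genes; the full
nine-comparison battery on it fits ~18,000 GLMs in about half a minute,
and the standard validation runs (tests plus the acceptance script)
complete in a few minutes on one CPU.  Boundary conventions are explicit
and tested: TSS distance is edge-based with exactly 1 kb classed as
enhancer; the TE rule is >= 20% inclusive; gene-distance ties break
lexicographically; empirical p-values use the +1 convention.  All
intervals are 0-based half-open.
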