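# Methods

`otukit` implements an end-to-end SNP-based species-delimitation workflow for
reduced-representation (DArTseq-style) genotype data, together with the
supporting morphometric analyses and a synthetic-data generator that emulates
the sampling design the genetic methods assume.  This note records the models,
the defaults and why they were chosen, the numerical conventions, and the
limitations a user should know before trusting a result.

## Genotype data model and quality filtering

Genotypes are diploid allele dosages (0 = homozygous reference, 1 =
heterozygous, 2 = homozygous alternate) with a distinguished MISSING sentinel
that is never treated as a numeric value.  Allele frequency `p` always refers
to the alternate allele.  Per-locus metadata carry the sequence-tag identity
(CloneID), the SNP offset in the tag, technical repeatability (RepAvg), call
rate and mean read depth.

The filter chain runs in a fixed order — one SNP per sequence tag, read depth
in [5x, 100x] (closed interval), individual call rate >= 0.5, removal of
monomorphic loci, repeatability >= 0.99, locus call rate >= 0.95 — with these
conventions:

* **Secondary-SNP choice.** Within a tag the SNP with highest repeatability is
  kept; ties break to the lowest SNP position, then input order.  This favours
  data quality and is deterministic.
* **Unknown metadata passes.** Generic VCF input lacks depth/repeatability;
  such loci pass the metadata filters so the pipeline stays usable (a
  `strict` flag fails them instead).
* **Thresholds are strict "less than" removals** at 0.5 / 0.99 / 0.95, i.e.
  a locus exactly at a threshold is retained.
* **Locus call rate is recomputed** on the current individuals after the
  individual-call-rate stage, rather than trusting the vendor column (kept
  for provenance).
* All-missing columns count as monomorphic; a column whose only genotype is
  heterozygous is polymorphic (both alleles are present).

Every filter is idempotent, and the stage report reconciles exactly
(initial − Σ removed = final, per dimension).

## Ordination

Inter-individual distance is Euclidean on dosages rescaled by 1/2, computed
pairwise-complete with a `sqrt(L / L_shared)` correction for missingness.
After the filter chain call rates are >= 95%, so the correction is minor; a
pair sharing zero called loci is an error.  PCoA is classical scaling
(double-centred −½D², symmetric eigendecomposition).  Negative eigenvalues —
possible because the missingness correction makes the distance slightly
non-Euclidean — are reported but excluded from the percent-variance
denominator.  Axis signs are fixed by making the largest-magnitude loading
positive, so runs are bit-reproducible.  On complete data this PCoA equals
PCA of the centred dosage matrix up to sign (tested to 1e−8), which is why
the same picture is often labelled either way.

## Fixed-difference delimitation

A locus is a fixed difference between two populations when each is fixed for
a different allele (`p <= t` vs `p >= 1 − t`; the tolerance `t` defaults to 0
= strict fixation, and is exposed because very small samples rarely show
exact fixation).  The denominator is the count of loci callable in both
populations and is always reported next to the count.

**False-positive test.** Small samples fake fixed differences.  The null
treats the pair as one panmictic population: at each shared locus the pooled
(count-weighted) frequency is taken as true, `n_A` and `n_B` diploid
genotypes are resampled, and apparent fixed differences counted.  Because a
sample of `n` diploids is fixed exactly when all `2n` binomial allele draws
agree, the per-locus probability of an apparent fixed difference has a closed
form; the implementation draws per-locus Bernoulli indicators with that
probability, which is distributionally identical to simulating the genotypes
and much faster.  The reported p-value is the fraction of replicates whose
count reaches the observed count.  The single-locus sanity case (pooled
p = 0.5, n_A = n_B = 1 → probability 2 · 0.25² = 0.125) is asserted in tests.

**Progressive amalgamation.** Phase 1 repeatedly merges a pair with zero
fixed differences (lowest count first, ties lexicographic), recomputing
merged-population frequencies from genotypes after every merge.  Phase 2
tests the remaining pairs against the false-positive null and merges pairs
with p > alpha (default 0.05), smallest observed count first.  Putative
hybrids must be excluded beforehand — a single F1 is heterozygous at every
diagnostic locus and erases the fixed differences of its whole population
(the pipeline does this automatically from the hybrid-stage posteriors,
threshold: combined non-parental posterior > 0.5).

A property worth knowing: under the pooled-frequency null, a panmictic pair
with samples of 6 and 9 individuals has a per-locus apparent-fixation
probability below 4e−9 — effectively zero.  Two same-population samples of
that size therefore merge at the zero-difference stage; the significance
phase only becomes decisive for very small samples (2–3 individuals), where
apparent fixation rates reach the percent scale.

**Private alleles** are counted per allele per locus (alternate private to A
when `p_A > 0, p_B = 0`; reference when `p_A < 1, p_B = 1`), so a fixed
difference contributes one private allele to each direction and the
private-allele count always bounds the fixed-difference count from above.

## Genetic diversity

Expected heterozygosity is the mean over callable loci of `2p(1−p)` (the
small-sample `2n/(2n−1)` correction is available by flag, off by default to
match common usage).  Pairwise differences are tested by randomly reassigning
the pooled individuals to groups of the original sizes (the randomization
unit is the individual, preserving within-individual genotype structure),
recomputing `|ΔHe|` each replicate (default 10,000), with the add-one rule
`p = (1 + #{replicate >= observed}) / (reps + 1)` so p is never exactly zero.
The test is two-sided in `|ΔHe|`.

A limitation found while validating: when the two populations are strongly
diverged, permuted groups are mixtures, and mixture composition inflates
`2p(1−p)` at diagnostic loci; the null spread of `|ΔHe|` is then dominated by
hypergeometric composition noise and does not shrink with locus count, so the
test has little power *between diverged groups*.  It is sharp when the
populations differ in diversity but not in fixed differences, which is the
regime the calibration and separation checks exercise.

## Hybrid classification

Six genotype-frequency classes are defined by the probability that a random
locus carries (both gene copies from pool 0, one from each, both from pool 1):
P0 = (1,0,0), P1 = (0,0,1), F1 = (0,1,0), F2 = (¼,½,¼), F1×P0 = (½,½,0),
F1×P1 = (0,½,½).  A Gibbs sampler jointly infers per-individual class labels,
per-pool per-locus allele frequencies (Jeffreys Beta(½,½) priors) and class
mixing proportions (Jeffreys Dirichlet), without pre-specifying which
individuals are parental.  Data augmentation with the latent gene-pair origin
per (individual, locus) — and, for heterozygotes of mixed origin, which copy
came from which pool — makes all conditionals conjugate.  Missing genotypes
contribute likelihood 1.  Defaults are a single chain with 10,000 burn-in and
10,000 retained sweeps.

Numerical/identifiability choices:

* **Initialization** splits individuals into two provisional pools by the
  sign of the leading eigenvector of the centred genotype matrix.  A cold
  start can stall at the symmetric point theta0 = theta1 where all classes
  have equal likelihood; the spectral split breaks that symmetry
  deterministically.
* **Label anchoring.** The model is invariant under swapping pool labels
  (P0↔P1, F1×P0↔F1×P1).  After the run, labels are swapped if the first
  individual's P1 posterior exceeds its P0 posterior, so averaged posteriors
  are well-defined.
* **Known limitation.** When the pools have little or no divergence the
  posterior has symmetric modes and a single chain sits in one of them
  (typically "everyone parental in one pool"), reporting confident parental
  assignments instead of diffuse uncertainty.  The guarantee that survives is
  the scientifically load-bearing one: a planted hybrid never receives
  confident support for a *hybrid* class without real divergence.  An
  `n_chains > 1` option runs independent chains and reports their maximum
  posterior spread as a cheap convergence/identifiability diagnostic.
* Loci are assumed unlinked (one SNP per tag upstream); no LD modelling.

## Relatedness

Opposing homozygotes (one individual 0, the other 2 at a locus) are
impossible for an error-free parent–offspring pair, so true pairs sit far
below the Hardy–Weinberg background rate `E[2p²(1−p)²]`.  All C(n,2) pairwise
rates form an empirical null summarized by the median and the normalized MAD
(scaled by 1.4826, the consistent robust estimate of sigma); pairs below
`median − k·MAD` (k = 5) are flagged.  The normalized MAD matters: with
~1,300 pairs a 5·(raw MAD) cut is only ~3.4 sigma and false-flags constantly,
while 5 normalized MADs is a genuine 5-sigma rule.

Caveats: full siblings also depress the count, so flags mean
"parent–offspring-like"; and the scan should be run within a population —
over a structured dataset the between-group pairs dominate the null spread
and nothing can be flagged (the pipeline therefore scopes per population by
default).  Resolution scales with locus count: with balanced frequencies
1,000 loci separate a planted pair cleanly, while within a low-diversity
group (He ≈ 0.04) background counts are single-digit and ~5,000 loci are
needed for a 5-MAD separation.

## Morphometrics

Eight traits (mass kg; head length/width mm; body and tail length cm;
knee-to-heel, ear length/width mm) on adults only, summarized per region
(sample mean and SD).  Sex effects are screened per trait with linear models
for unbalanced data (`trait ~ region + sex + region:sex`, type-II ANOVA) and
backward elimination, interaction first, at alpha = 0.05.  Note the screen is
compound: "any sex term retained" occurs at roughly twice the nominal level
(the interaction and the main effect each get a look), while the final-model
main effect with the interaction eliminated is calibrated near alpha; the
calibration test also uses region-homoscedastic draws, because the default
emulation parameters have genuinely region-dependent SDs that inflate the
interaction F.

Region comparisons use the Tukey–Kramer studentized-range test: pooled
within-group variance across all groups, SE = sqrt(MSE · (1/n_a + 1/n_b)),
adjusted p from the studentized range with q = |diff|·sqrt(2)/SE.  Difference
signs follow the canonical region order (Northern, Central, Southern);
magnitudes are what should be interpreted.  Group structure is summarized by
canonical variate analysis (generalized symmetric eigenproblem of
between-group scatter in the pooled within-group covariance metric; scores
have unit within-group variance, so centroid distances are Mahalanobis
distances) and by correlation-matrix PCA (the traits mix kg/cm/mm, so
covariance PCA would be dominated by the mm-scale traits).

## Synthetic data

The generator emulates the study design the analyses assume: five sampling
sites from three divergent groups (18/15/18/9/6 individuals), pairwise fixed
differences planted at fractions on the observed scale (defaults North–
Central 0.25, North–South 0.40, Central–South 0.16 of loci), group expected
heterozygosities 0.04/0.10/0.11, one F1 and one F1×P0 backcross that also
form a true parent–offspring pair, per-genotype error 0.002 and missingness
0.02, and DArT-style per-locus metadata that pass the default filters.  The
default 1,000 loci are a runtime-scaled stand-in for a full DArT panel
(~11,000 post-filter loci); tests that need finer resolution state their own
sizes.

Mechanics that make planted truth exact:

* Group frequencies at non-planted loci are drawn **comonotonically** — one
  shared uniform quantile per locus pushed through each group's symmetric
  Beta quantile function — so all groups sit on the same side of 0.5 and
  accidental between-group fixation is effectively impossible.  Planted loci
  are set to exactly p = 0/1 (random orientation, disjoint blocks), so the
  realized population-level fixed fraction equals the request.
* The symmetric Beta shape is calibrated so the group's overall expected He,
  *including* the planted-fixed loci (which contribute zero), hits the
  target: shape a = h′/(1 − 2h′) with h′ = target/(1 − fixed fraction).
  Targets implying h′ >= 0.5 are rejected as infeasible.
* Sites within a group add clipped Gaussian drift (sd 0.005) at non-planted
  loci only.
* Hybrids are Mendelian gamete draws (F1: one gamete from each pool's
  frequencies; backcross: a gamete from a realized F1 genotype plus a pool
  gamete; F2: gametes from two realized F1s).  A planted offspring inherits
  one true parental gamete, so error-free parent–offspring pairs have exactly
  zero opposing homozygotes by construction.
* A `uniform(0.3, 0.7)` frequency law is available for balanced panels (used
  by the kinship scenario, where the opposing-homozygote background must sit
  far above the flag threshold).
* Artifact injection appends loci/individuals that each violate exactly one
  filter stage, so the filter report reconciles with the plant on a clean
  base; overlapping violations belong to the first stage that removes them.

What the generator does **not** emulate: linkage, coalescent ancestry,
clinal structure, batch effects, allele-dropout-style genotyping error, or
missingness that correlates with genotype.  Passing tests therefore show the
methods behave correctly under their own assumptions, not that those
assumptions hold for any particular real dataset.

## Orchestration and reproducibility

The pipeline runs filter → ordination → hybrids → delimitation (with
hybrid-flagged individuals excluded) → diversity → relatedness →
morphometrics from one YAML config with a single mandatory seed, forked into
named per-stage streams (SHA-256 of `seed:stage`), so toggling one stage
never perturbs another's randomness.  Every output file is checksummed into a
JSON manifest; identical configs and seeds produce identical files, including
the MCMC stage.
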