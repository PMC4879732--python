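# Methods

## The analysis

The pipeline operates on a samples × genera abundance table with
per-sample age (plus sex and, for children under 4, feeding stage).
Samples are assigned to 14 age groups: three infant groups defined by
weaning status (preweaning, weaning, weaned-to-3), ages 4–9, decade bins
10–90, and a pooled ≥100 group.

**Co-abundance groups.** All genera (optionally minus an unidentified
catch-all taxon) enter a pairwise Kendall τ-b matrix computed on
relative abundances. τ-b applies the tie correction; two-sided p-values
come from the tie-corrected normal approximation (scipy switches to
exact enumeration for small tie-free vectors). The upper-triangle
p-values get Storey q-values: π₀ is estimated with the smoother method
(cubic smoothing spline of π₀(λ) on λ = 0.05…0.95, evaluated at
λ = 0.95) and reset to 1 — making the q-values exactly
Benjamini-Hochberg — whenever the estimate leaves (0, 1] or fewer than
100 tests are available. Genera are then Ward-clustered into K CAGs
(K is a required parameter, default 9; no automatic cut rule is
offered). The inter-genus distance is 1 − Pearson correlation between
the two genera's τ-matrix rows with both self-entries excluded,
computed in closed form from full-row sums; `profile_distance=False`
switches to 1 − τ directly. Constant genera have no defined τ and are
excluded from clustering with a warning.

Transition profiles sum each subject's member-genus z-scores per CAG
(z-scores are per-genus across samples, sample SD with n−1). Because
CAGs partition the genera, each subject's profile row sums to its total
z-score — an identity the tests verify to 1e-9. Per age group the
profiles are summarised by median and quartiles, with values outside
[Q1 − 1.5·IQR, Q3 + 1.5·IQR] flagged mild and outside the 3·IQR bounds
extreme outliers. The correlation network retains edges with q < 0.05
and |τ| strictly greater than 0.3; node attributes carry cohort mean
relative abundance, prevalence, CAG membership, and a display flag for
taxa present in more than half of the subjects. The prevalence filter
is deliberately asymmetric: cohort-wide filtering uses a strict ">"
("more than 50 %") while the any-cluster scope uses "≥".

**Diversity.** Shannon entropy defaults to log base 2 (a flag selects
natural log), Chao1 uses the bias-corrected singleton/doubleton form,
and Faith's PD is the branch length of the minimal subtree spanning the
root and the observed taxa. These and both UniFrac variants are
computed with scikit-bio; weighted UniFrac is normalised by default.
Rarefaction is optional (depth + seed); without it alpha metrics use
raw counts. PCoA eigendecomposes the double-centred −D²/2 matrix
directly: axes are ordered by descending eigenvalue, the
largest-magnitude loading on each axis is made positive (deterministic
sign), and negative eigenvalues are reported but excluded from the
proportion-explained denominator (no Cailliez correction).

**Subject clustering.** Subjects are Ward-clustered on their z-scored
genus profiles with `scipy`'s `linkage(method="ward")`. This is the
ward.D2 variant, i.e. the classical Ward objective whose merge costs
are expressed in squared Euclidean distances; an hclust-style ward.D on
pre-squared distances yields the same merge tree up to a monotone
height transform, so cluster memberships at any k agree. The 3- and
5-cluster solutions are nested cuts of one dendrogram. Clusters are
labelled by life stage from their median member age — below 20 infant,
20–69 adult, 70 and above elderly, the cohort's two observed transition
points — with Roman-numeral suffixes ordered by median age when a stage
repeats. A subject is *mismatched* when its own life stage differs from
its cluster's label; the mismatch notion is this package's
formalisation (the boundaries above), not an external standard.
Quartiles use the linear-interpolation convention, which produces
fractional values such as 24.75 on even-sized clusters.

**PERMANOVA.** One-way, on any symmetric distance matrix:
SS_total = (1/N)·Σ_{i<j} d²_ij, SS_within the analogous per-group sums,
pseudo-F = (SS_between/(a−1))/(SS_within/(N−a)), and
p = (#{F_perm ≥ F_obs} + 1)/(n_perm + 1) over random label
permutations (default 999, so the smallest attainable p is 0.001; the
seed is mandatory in the CLI). For the CAG test the distance is
Euclidean on the subjects × CAG transition-profile matrix; Bray-Curtis
on relative abundances is available behind a flag. If every distance is
zero there is nothing to partition: pseudo-F is NaN and p is 1.

**Intergroup statistics.** Per-genus two-sided Mann-Whitney U with the
tie-corrected normal approximation, raw p and BH-adjusted q both
reported (the significance flag uses raw p at α = 0.05, with q
alongside, since no correction convention is canonical here). The
sex-by-group test is exact for 2×2 tables; for R×2 tables a
Monte-Carlo Fisher test conditions on both margins and uses the
probability-ordering criterion (a simulated table is at least as
extreme when its conditional probability does not exceed the observed
one), reporting p with its binomial standard error. This matches R's
`fisher.test(simulate.p.value=TRUE)` on the same tables. A
Kruskal-Wallis screen across all clusters is offered as a convenience;
it is not a discriminant-analysis substitute.

**Function projection.** Taxon counts are divided by integer 16S rRNA
copy numbers, projected through a nonnegative taxon × function
gene-content matrix, and the transporter columns are renormalised per
sample. Projection is linear before renormalisation, and copy-number
correction commutes with projection against a pre-scaled content
matrix — both identities are tested numerically. Functions are
z-scored across samples and Ward-clustered (same machinery as subject
clustering) into k = 2 groups; each group is labelled adult-enriched or
infant/elderly-enriched by comparing its mean z-scores within the
life-stage strata, and the census counts drug-transporter-flagged
functions per group. The reference databases behind real 16S function
prediction are out of scope: this module reproduces the computation,
not the catalogue.

## The synthetic cohort generator

The generator exists so every stage is testable without downloads; its
defaults are the study conditions the pipeline is demonstrated under.

- **Design.** 14 age groups, n = (14, 12, 18, 14, 10, 40, 88, 34, 25,
  28, 15, 48, 19, 6), 158 male / 213 female, 371 samples in total. Ages
  are uniform within each group's range (no attempt to match per-group
  age means/SDs); the infant groups carry feeding-stage labels because
  they are defined by weaning status, not age alone.
- **Abundance model.** Per sample, a latent Gaussian over genera:
  fixed per-genus baseline b_g ~ N(0, 1.5²) (the rank-abundance
  curve), plus the block's life-stage trend, plus √ρ·(shared block
  factor) + √(1−ρ)·noise. Softmax gives the composition; counts are
  multinomial at depth ~ round(TruncNormal(4959, 1813²)) floored at
  500 reads (diversity estimators are unstable below a few hundred
  reads). A logistic-normal/multinomial scheme is used because it
  delivers both the compositional constraint and tunable Kendall
  correlations; ρ_within defaults to 0.8 and the log-scale effect size
  to 2.0. The within- versus between-genus correlation magnitudes are
  calibration choices of this package, not measured quantities.
- **Trends.** Piecewise-linear life-stage weights with knots at ages 3,
  20 and 70: the infant weight is 1 until 3 and fades by 20, the
  elderly weight ramps from 70 to 100, the adult weight is the
  remainder. Nine default blocks follow the archetypes three ×
  elderly-associated, infant+elderly, infant/child, adult, two more
  elderly-leaning, and one flat; for other K the five archetypes cycle.
- **Infant dominance.** The infant-stage effect is graded across all
  infant-trending genera (multiplier 3.5·0.55^rank, floor 0.25,
  infant_high blocks first) rather than applied uniformly. Real
  preweaning communities are dominated by one or two genera; grading
  reproduces that dominance, which is what makes simulated infant
  Shannon diversity lower than adult diversity. The grading is global —
  one dominant genus cohort-wide — so that the large trend variance
  sits in a single block and block recovery stays identifiable for any
  K.
- **Tree and gene content.** A random coalescent-style bifurcating
  genus tree with exponential branch lengths supports PD and UniFrac.
  The toy gene-content matrix assigns each transporter function a host
  stratum (Poisson(5) inside, Poisson(0.05) outside); when a block spec
  is supplied, drug-transporter functions load only on genera in
  infant/elderly-trending blocks and the remaining functions alternate
  between the strata, mimicking an age-split transporter repertoire.
  Copy numbers are uniform integers in [1, 15].

**What the generator does not emulate.** Real cohorts have
overdispersed (non-multinomial) counts, many structurally absent taxa,
phylogenetically-structured abundances (the random tree is independent
of the blocks), OTU-level substructure, and covariates (diet, medication,
geography) that confound age. Passing tests therefore demonstrate that
the implementation is correct and that the methods recover structure of
the planted kind — not that they would behave identically on real
sequencing data.

## Numerical and design choices

- Sample SD (n−1) for z-scores, matching the default of the usual
  statistical environments.
- Kendall p-values from the tie-corrected normal approximation: at
  cohort sizes in the hundreds the approximation is accurate; exact
  enumeration applies only to tiny tie-free inputs.
- Ward ties are broken deterministically by input order; cluster ids
  are renumbered by first appearance so partitions are reproducible.
- The 0.3 network cut-off applies to τ itself and is strict (> 0.3),
  as is q < 0.05.
- Clustering input for subjects defaults to z-scored relative
  abundances (the heat-map scale); raw relative abundances can be
  passed instead.
- Degenerate inputs: all-zero samples are an error for normalisation
  and UniFrac; constant taxa z-score to 0 with a warning and are
  excluded from correlation clustering; an all-zero distance matrix
  gives PERMANOVA p = 1 with NaN pseudo-F; empty prevalence-filter
  results warn rather than fail.
- Every stochastic step (simulation, rarefaction, permutations,
  Monte-Carlo tests) takes an explicit seed, and the pipeline echoes
  its effective config into the output directory.

## Problem sizes used in the tests

The test-suite cohorts use the full 371-sample design with 40–60 genera
(block recovery, subject clustering, function census), the full 186
genera for the end-of-pipeline PERMANOVA check, 20 null cohorts of 50
genera for the spurious-edge census, and 1,000 simulated null datasets
of n = 20 for the PERMANOVA type-I-error calibration. Oracle
comparisons (brute-force τ, branch-enumeration UniFrac/PD, exhaustive
permutation) run on instances small enough to enumerate exactly.

## Known limitations

Single-factor PERMANOVA only (no strata or dispersion test); no
bootstrap stability assessment of CAG or subject clusters; no
rarefaction curves or jackknifed UniFrac; LEfSe-style effect-size
screening is deliberately replaced by rank tests; plots are not
rendered — all outputs are tables meant for downstream tools.
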