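# Methods

## The analysis problem

Tumor-only targeted panel sequencing produces, per sample, deep-coverage
variant calls with no matched normal. The pipeline therefore leans on
catalogues (Ensembl known variants, COSMIC with FATHMM-based
somatic/pathogenic labels and per-variant tissue reports, ICGC) and on
the variant allele fraction (VAF) to separate somatic from germline
signal, and then profiles the cohort: which genes are recurrently
mutated, how mutations distribute over clinicopathological strata, which
genes co-occur, and which genes associate with dichotomized clinical
traits at the single-gene (Fisher/chi-square) and rare-variant-set
(SKAT-O) level.

## Classification cascade

All flags are resolved per distinct variant key `(chrom, pos, ref, alt)`
at cohort level; carrier VAFs are aggregated across samples.

* **Quality gate.** A call passes when depth > 300 and site QUAL > 50.
  Both are read as strict inequalities (the protocol wording is "more
  than"), and both are configurable, so the boundary convention is
  testable either way. "Read quality" is taken to be the site-level QUAL
  field; records missing depth or QUAL fail the gate. The gate is
  idempotent and never raises on content.
* **Common-variant exclusion.** A variant previously catalogued in
  Ensembl is excluded unless COSMIC marks it confirmed-somatic or
  pathogenic. An optional population-AF override (exclude when
  AF > 1%) exists in `FilterConfig` but is off by default.
* **Novelty.** `novel_vs_cosmic` = absent from COSMIC;
  `novel_vs_both` additionally requires absence from ICGC, so
  `n_novel_vs_both = n_novel_vs_cosmic − n_in_icgc_among_novel` holds on
  every input (a tested conservation law).
* **Tissue routing.** Among pathogenic variants, those with a prior
  report in the target tissue (default `large_intestine`) are
  *tissue-specific*; the remainder are *first-time in the target
  tissue*. The two sets partition the pathogenic set.
* **Germline heuristic.** A variant is `germline_suspect_vaf` when at
  least one carrier's VAF lies in [49, 51] or [99, 100] percent (closed
  bands — "between 49–51" is read inclusively). The suspicion is
  MAF-supported when the cohort minor allele frequency exceeds 1%.
  Because tumor-only data has no genotypes, cohort MAF counts each
  carrier as one minor allele over 2·n_samples chromosomes. This is a
  stated convention (what a PLINK run on presence/absence calls would
  see), not a biological claim.
* **Damaging inclusion.** SIFT `deleterious` and/or PolyPhen
  `probably_damaging`/`possibly_damaging`. Folding *possibly* into
  "damaging" is a deliberate reading of an underspecified rule; the two
  PolyPhen levels are kept distinct in the data model so the stricter
  reading is recoverable.

The somatic (561 by default) and pathogenic (299) sets are not asserted
to partition: `cascade_counts` reports both sets and their intersection,
and both the pre- and post-quality totals, rather than guessing an
unstated branch topology.

## Profiling conventions

* Incidence matrices are binary with set semantics: duplicated identical
  call rows cannot change a cell.
* Dichotomizations: young = age < 50 (50.0 is old); early = stage I–II;
  lymph node N0 vs N1/N2; metastasis M0 vs M1; site left vs right for
  two-level contrasts with rectum/other folded into "other" (and kept
  separate in descriptive stratification). Stratification adds a
  `missing` stratum so strata always partition the samples and sum to
  the matrix row sums.
* Every percentage carries its own non-missing denominator. Reference
  cohort tables of this kind mix denominators across fields (95 patients
  overall, 94 with a known stage, 90 with a known site); reporting the
  denominator next to each percentage keeps the table reproducible.
  Integer percents round half away from zero.
* Gene summaries report both the all-tissue pathogenic sample fraction
  and the tissue-specific fraction as separate documented columns, and
  order genes by pathogenic fraction, then somatic fraction, then gene
  symbol — a total order, so the output is permutation-invariant.

## Association statistics

* **Fisher's exact test** (two-sided) sums hypergeometric probabilities
  of all 2×2 tables with the observed margins whose probability does not
  exceed the observed table's (relative tolerance 1e-7) — the
  probability-ordering convention of the widely used implementations.
  Empty-margin tables give p = 1 with the odds ratio reported missing.
  The suite verifies exact agreement with a rational-arithmetic
  enumeration oracle on all small tables and random tables with n ≤ 40,
  and cross-checks against an independent library implementation.
* **Co-occurrence correlation** is the Pearson coefficient of binary
  incidence vectors, identical to the phi coefficient of the 2×2
  cross-table (verified algebraically on random matrices, along with
  n·r² = chi-square). Two-sided p from t = r·sqrt((n−2)/(1−r²)) with
  n−2 df; zero-variance genes are excluded and listed. Significance
  stars at p < 0.05/0.01/0.001; no FDR layer is added on the correlation
  matrix.
* **Hardy–Weinberg** is the exact conditional test: enumerate all
  heterozygote counts compatible with the observed allele counts and sum
  the probabilities of outcomes no more probable than the observed one.
  Invariant to allele relabeling. Chi-square tests use no continuity
  correction by default.
* **Bonferroni**: alpha/m; for a 409-gene panel at alpha = 0.05 this is
  1.22e-4, conventionally printed as 0.0001 at one significant figure.

## Rare-variant association (burden / SKAT / SKAT-O)

Null models are intercept-only by default (covariates accepted):
logistic via iteratively reweighted least squares for binary traits —
with explicit separation and convergence checks — and OLS with a
moment-estimated dispersion for quantitative traits. Variant weights are
the Beta(a, b) density at the sample MAF, default (a, b) = (1, 25): the
standard choice that up-weights rare variants and only assumes the
stated monotonicity requirement. Common variants are not excluded; they
are merely down-weighted, so `n_marker_test` equals `n_marker_all`
unless a variant has no carriers among the analyzed samples.

With Z the weighted genotypes, the score is s = Z'r and
Q_rho = (1−rho)·s's + rho·(1's)², interpolating SKAT (rho = 0) and the
weighted burden test (rho = 1); both reductions are verified exactly
against independently coded oracles. Under the null, s ~ N(0, K) with
K = Z'VZ − Z'VX(X'VX)⁻¹X'VZ, so Q_rho is a chi-square mixture with
weights eig(R_rho^{1/2} K R_rho^{1/2}).

**Mixture tails.** The primary evaluator inverts the characteristic
function (Imhof's form of the Davies approach): the oscillatory
integrand is integrated with a 15-point Gauss–Legendre rule per
oscillation period, vectorized, out to a truncation point where the
cycle-cancellation bound drops below the accuracy target; the truncation
bound is returned as the error estimate. In the deep tail (p below
~1e-5, where an absolute-accuracy inversion is uninformative) the
evaluator switches to Kuonen's saddlepoint approximation, and a
moment-matching (Liu-type) approximation is the final fallback; the
path taken is recorded in each result's method label. Agreement with
1e5-draw Monte-Carlo estimates within three Monte-Carlo standard errors
is part of the test suite.

**Combination.** The minimum p over the rho grid (default
0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1; rho = 1 is mapped to 0.999
inside the combination, the usual implementation convention) is
converted to one p-value by conditioning on the common component of the
projected genotypes and integrating the conditional survival function
against the chi-square(1) density; substituting x = t² removes the
density's singularity at zero, so a fixed 64-node Gauss–Legendre rule
suffices. The result is clamped to [p_min, min(1, n_rho·p_min)] — the
theoretical range of a minimum-p statistic — as a numerical safeguard.
Single-variant genes collapse: SKAT, burden and SKAT-O all equal the
single-variant score test.

Small-sample exact/resampling machinery for binary traits is not
reimplemented; instead an optional permutation p-value (default off,
resampling the null residuals and using fast moment-matched per-rho
tails consistently for observed and permuted statistics) serves as the
small-sample safeguard, with the minimum achievable p reported.

Tumor-only carrier status enters the genotype matrix as one
minor-allele copy, the same convention as the MAF/HWE computations.

## Synthetic cohorts: what they emulate and what they do not

The generator emulates the *post-calling, post-annotation* state of a
deep-coverage panel run: per-sample calls with depth in 301–2000, QUAL
in 50.5–99, and an annotation table whose database flags realize a
`CascadeComposition` *count-exactly* (flag vectors with exact tallies,
shuffled; chosen over Bernoulli draws so cascade regression tests are
deterministic). The default composition is the reference 409-gene
colorectal cascade: 4256 variants, 483 absent from COSMIC, 17 of those
in ICGC, 561 confirmed somatic, 299 pathogenic with 125 prior
large-intestine reports, SIFT 130/111 deleterious/tolerated, PolyPhen
418/143 damaging/benign, consequences 240/247/74
synonymous/missense/other within the somatic set, and 69 germline-band
variants of which 45 are cohort-MAF-supported (realized by giving those
45 at least two carriers of 90 — MAF 2/180 > 1% — and the rest exactly
one).

Somatic VAFs are Beta(2, 3) scaled onto (5, 95)% — a plausible FFPE
tumor-only spread; no tumor purity estimate exists for the reference
data, so this is a stand-in, not an estimate. Germline-band VAFs are
drawn inside [49.2, 50.8] (80%) or [99.2, 99.9] (20%), and non-germline
draws are rejection-sampled away from the bands with margin for
alt-depth rounding, keeping band tallies exact. Clinicopathological
fields are realized count-exactly from marginal counts (defaults: the
reference 95-patient table; age ~ Normal(62, 14) clipped to [18, 100])
and independently across fields — the joint distribution is unknown, so
none is invented. Panel genes default to synthetic symbols G001–G409; a
real gene list can be supplied.

What the generator does **not** emulate: read-level error and caller
artifacts, linkage between variants, per-gene mutation-rate
heterogeneity, correlated clinicopathological features, or real COSMIC
tissue distributions. Passing tests therefore demonstrate the
correctness and calibration of the *pipeline machinery* on data with
the assumed structure, not the biological conclusions of any real
cohort.

The simulation harnesses are separate: `generate_skat_null` draws
genotypes Binomial(2, MAF) independently of a Bernoulli(1/2) binary (or
standard normal quantitative) trait, with MAFs from a configurable
spectrum (default Uniform(0.01, 0.10), a rare-to-low-frequency panel
spectrum giving expected MAC ≈ 220 at n = 200 with 10 variants);
`inject_gene_association` resamples carrier status of a gene's
pathogenic variants so the population log-odds association with a
dichotomized trait equals log(OR), with a configurable control-stratum
carrier rate (default 0.25).

## Problem sizes and numerical choices

The acceptance script and test suite run the cascade at full size
(4256 variants, 90 patients), calibration at 500 null replicates
(n = 200, 10 variants) and power at 200 replicates (n = 300) with a
compact 150-variant composition — sizes chosen so the whole study
re-runs in about a minute on one CPU while keeping Monte-Carlo standard
errors small relative to the acceptance bands. Mixture-tail accuracy
targets 1e-6 absolute in the bulk (saddlepoint in the deep tail);
eigenvalues below 1e-10 of the spectral maximum are treated as zero;
p-values from the t transform are floored at 1e-300 rather than
reported as exact zeros. All randomness flows from
`numpy.random.default_rng` seeds carried in configs, making every table
byte-reproducible.

## Known limitations

* Germline inference from VAF bands is a heuristic; without matched
  normals the "germline-suspect" label is advisory, and the cohort-MAF
  encoding of tumor-only carriers is a convention.
* The asymptotic SKAT-O p-values can be conservative for very small
  minor-allele counts; the permutation option is the mitigation.
* The co-mutation GraphML export is a structural stand-in for
  knowledge-base network analysis and carries no pathway semantics.
* Multi-gene/multi-transcript variants must be resolved to one gene per
  variant upstream (canonical-transcript convention); the pipeline does
  not re-pick.
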