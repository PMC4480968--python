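# Methods

## Data model

Genotypes are integer alt-allele counts (0/1/2) with −1 as the missing
sentinel; every downstream statistic consumes per-group genotype counts
`(n_homRef, n_het, n_homAlt)`, never allele strings. The risk allele of
each SNP is declared on the SNP definition (for all eight study SNPs it
is the alternate/variant allele); dosage and carrier analyses count risk
alleles as the genotype code when risk = alt and as its complement when
risk = ref. The TSV dialect stores genotypes as unordered two-character
strings ("GT" ≡ "TG"); VCF import accepts biallelic records only and
maps 0/0, 0/1, 1/1, ./. to 0, 1, 2, missing.

## Association statistics

Contrasts orient the variant category as the exposure, so OR > 1 means
the variant raises disease odds. The Woolf CI uses the conventional
critical value 1.96 at the default 95% level — the value standard
epidemiology software prints, and the choice under which every published
CI of the study's count tables (including the extreme 2.94–174.82)
reproduces to 2 decimals; other confidence levels use the exact normal
quantile. χ² is Pearson without continuity correction (required to match
the study's significance calls); the Fisher exact test is triggered by
the classic any-expected-cell < 5 rule. With exactly one zero cell the
Haldane–Anscombe +0.5 correction is applied before the OR; tables with
an empty margin or two zero cells have no defined OR and raise. A
contrast with no variant carriers in either group (e.g. the absent
homozygote class at rs1801726) is omitted with a logged note, mirroring
a blank table cell.

HWE is computed separately in cases and controls, each with its own
flag at α = 0.05; reporting both sidesteps the ambiguity over which
group a published HWE claim refers to. Bonferroni m defaults to the
number of SNPs tested (8 for the study set) and is overridable.

Known inconsistencies in the published tables, treated with the counts
as ground truth: the rs219777 allelic OR prints as 1.90 but the counts
give 1.71; the rs731236 crude OR column duplicates rs219777's values
(its counts give 1.81 / 1.15 / 1.46); the rs731236 case allele
frequency prints as 0.48 where the counts give 0.495. These rows are
excluded from golden comparisons; everything else reproduces to the
printed precision.

## LD estimation

Two-locus haplotype frequencies are estimated by EM on the unphased
genotype likelihood, initialized at linkage equilibrium of the observed
allele frequencies, iterating until the largest frequency change is
below `tol` (default 1e−8, `max_iter` 1000 with a warning on
non-convergence). Only double heterozygotes are phase-ambiguous; the
E-step splits them between the two configurations in proportion to the
current haplotype-product probabilities. The log-likelihood is
non-decreasing by construction and asserted in tests; the estimate
conserves the observed allele margins exactly. The degenerate
all-double-heterozygote sample has a flat likelihood; the equilibrium
initializer is returned with a flag. D′ normalizes by the classical
frequency-bound D_max; r² = D²/(p_A q_A p_B q_B) and is invariant to
allele relabeling. Case and control matrices are computed separately
(mirroring the study's two-panel LD figure), with pooled available.

## Covariate adjustment

Each genotype contrast is its own logistic fit (case status ~ exposure +
age + sex + bmi) via Newton-type maximum likelihood; sex is coded 0/1
female/male, age and BMI untransformed — the exposure OR is invariant to
affine covariate rescaling, which is property-tested. Separation is
surfaced (converged = False, no estimate) rather than silently
extrapolated; a fit whose exposure standard error exceeds 50 on the log
scale is likewise flagged as quasi-separated. The published adjusted
ORs cannot be verified without the unpublished individual-level
covariates, so validation is structural: a no-covariate fit equals the
crude 2×2 OR (tolerance 1e−6), and on synthetic cohorts with known
exposure log-odds 0.8 and null covariates the Wald CI covers the truth
in ≥ 93 of 100 seeded replicates at n = 2000.

## Dosage score and carrier strata

The formula and its boundary behaviour: score = Σ W_i (R_i/2) / Σ W_i,
effective alleles = 2k·score = k·Σ W_i R_i / Σ W_i. The all-homozygous
subject scores exactly 2k (= 8 for the four study risk SNPs), zero risk
alleles score 0, equal weights reduce to the plain allele count, and the
score depends on the weights only through ratios, so the log base used
for W is irrelevant (property-tested with natural vs base-10 logs).
Default weights are the natural logs of the four significant SNPs'
allelic ORs (2.54, 2.21, 3.01, 2.19); the source of weights is
configurable since the original analysis does not state whether crude
allelic, dominant or adjusted ORs were used.

Category bins on the effective-allele axis: reference [0, 2] ("two or
fewer"), then half-open (2, 3], (3, 4], (4, 2k]. The source material
labels its reference both "<2" and "2 or less"; the Methods-text reading
("two or fewer") was adopted and the boundaries are configurable.
Subjects missing any scored genotype are excluded and counted, matching
the complete-genotype requirement of the original analysis.

## Traits

The default two-sample test is pooled-variance Student (the test the
study names); Welch and Mann–Whitney are available per call since the
original per-row choice is unstated. The summary-statistic form
reproduces the raw-data form to 1e−9 on computed summaries. Sign
convention: statistics are positive when the second (variant-carrier)
group's mean exceeds the first's. Mann–Whitney uses the exact null
distribution for both n ≤ 20 without ties, else the tie-corrected
normal approximation. On the printed summaries, the serum-calcium
comparison for four-risk-allele carriers gives p = 0.0045 (printed
0.005); the urinary-calcium row (printed 0.014) reproduces under
neither pooled (0.031) nor Welch (0.004) t and is presumed to come from
a different test — it is not asserted.

## Synthetic cohorts

Exact-count mode lays out each group's genotype vector from the
specified counts and permutes it with the seeded generator: count-based
statistics are therefore seed-invariant by construction, and the study
cohort (200/200, the eight published count tables) reproduces every
count-derived result deterministically. Frequency mode samples HWE
genotypes at a given alt frequency — one shared frequency for a null
SNP, or a (case, control) pair to induce a known allelic odds ratio.
Pairwise r² targets are honoured by sampling haplotype pairs at
D = +√(r² p₁q₁p₂q₂) (positive-D convention; infeasible targets raise
with the feasible maximum). Traits are per-stratum normals: the study
models stratify serum calcium on rs1801725 carrier status and urinary
calcium on rs1042636 carrier status within each group, with the
group-level summaries as fallback for all other traits; age/BMI are
normal and sex Bernoulli per group at the published rates.

What the generator does not emulate: joint genotype structure across
SNPs (the study publishes only per-SNP margins, so fixture genotypes are
independent across loci), measurement error beyond normal noise, and any
recruitment or matching structure. Consequently multi-locus results on
the fixture (combined-carrier ORs, dosage-category ORs and fractions)
exercise the procedures and their parameter-recovery guarantees, not the
study's published joint-genotype values — those are validated instead by
round-trips on cohorts generated with known stratum odds.

## Problem sizes in the test suite

Golden count-table checks are exact and instantaneous. Simulation-based
checks use n = 2000 subjects × 100 replicates for logistic CI coverage,
n = 20 000 per group for allelic-OR recovery, n = 4000–8000 for LD-target
and dosage-monotonicity checks, and 100-subject samples for the EM vs
grid-search comparisons — sizes at which Monte-Carlo error is well inside
the asserted tolerances while the full suite runs in seconds.

## Known limitations

- The EM estimator returns a point estimate only; no standard errors on
  haplotype frequencies (not needed for r² reporting).
- Exact-count mode fixes margins per SNP but cannot simultaneously honor
  r² targets; LD targets require frequency mode.
- The dosage-category OR for a bin with zero controls relies on the
  Haldane-corrected 2×2 and a Fisher p; with very sparse top bins the CI
  is wide and should be read qualitatively.
- No trend (Cochran–Armitage) test, haplotype-block detection, matched
  conditional regression, or meta-analytic layer.
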