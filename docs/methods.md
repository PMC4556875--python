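# Methods

## Statistical model

### Genotype encodings and association

A biallelic SNP has three genotype classes — homozygous major, heterozygous,
homozygous minor (coded 0/1/2, −1 missing). A *genetic model* collapses them
to a binary exposure: dominant (carrier of the minor allele, {1,2}),
recessive (minor homozygote, {2}), or an explicit custom class. The exposed
class and its complement always partition the three classes, so any
single-class exposure (e.g. "CC versus CT/TT") is expressible either
directly (custom) or as the complement of a standard encoding; the two
labelings yield reciprocal odds ratios and identical score terms
(reciprocal symmetry, asserted in the tests).

For one SNP and one contrast the 2×2 table counts exposed/unexposed cases
(a, b) and controls (c, d), after dropping missing genotypes. Cases are
restricted to one TOAST subtype per contrast (optionally to the
atrial-fibrillation subset); the full control arm is reused across
contrasts. Statistics:

* odds ratio ad/bc with Wald 95% CI exp(ln OR ± z₀.₉₇₅·√(1/a+1/b+1/c+1/d));
  a single zero cell triggers the Haldane–Anscombe +0.5 correction
  (flagged), two zero cells sharing a row or column leave the OR undefined;
* Pearson χ² without continuity correction, df = 1. The uncorrected form
  is deliberate: it exactly reproduces the one published covariate p-value
  that can be rebuilt from printed counts (hypertension in the replication
  arm, p = 5.5×10⁻⁵), which the Yates-corrected form does not;
* two-sided Fisher exact p (sum of fixed-margin tables as or less probable
  than the observed), used as the reported test whenever any expected cell
  is below 5.

The scan always computes both dominant and recessive encodings. The
original analysis reports "a dominant/recessive genetic model" without a
selection rule; the default policy (`best-of-two`) keeps, per SNP, the
encoding with the smaller χ² p-value and records both under
`policy="all"`. Raw p-values drive selection — the source analysis applies
no multiple-testing correction across its panel — but Bonferroni-adjusted
columns are always emitted alongside.

### Score construction

Forward stepwise logistic regression gates the univariately significant
SNPs (p < 0.05): at each step the candidate with the smallest
likelihood-ratio p versus the current model enters while that p is below
`p_enter` (0.05), ties broken by candidate order. The logistic fit is IRLS
on the binomial log-likelihood, convergent when the largest absolute
coefficient change is < 1e-8 within 50 iterations; quasi-separation
surfaces as `converged=False` rather than an exception so selection can
continue. Candidates enter the gate as risk-direction indicators
(protective SNPs pre-inverted), on complete cases across the candidate set.

Weights come from the *univariate* odds ratios, not the joint fit: the
published weights equal the per-SNP genotype ORs with protective ORs
inverted (1/0.65 → 1.5, 1/0.46 → 2.1) and rounded to one decimal, half
away from zero. That reading is the only one consistent with the printed
equation, so `weight_source="univariate-OR"` is the default and the
stepwise fit acts purely as the inclusion gate (`"stepwise"` weights,
exp(coefficient) rounded the same way, are available). Terms are ordered
by descending weight; printed formulas render in rs-id order, the
convention used in the source equation.

Because weights carry exactly one decimal, subject scores live on a
0.1-point grid; scoring is done in integer tenths, which keeps the
linearity identity mean(subject scores) = Σ wₖ·freqₖ exact (to floating
point, ~1e-15) on complete cohorts. The default missing-genotype policy
(`exclude`) drops subjects missing any scored genotype, preserving that
identity; `zero` scores missing indicators as 0 and flags the subject
incomplete.

Score distributions are compared with the Mann-Whitney U test (normal
approximation with tie correction, no continuity correction so identical
groups give p = 1; an exact enumeration variant exists for small tie-free
samples) or Kruskal-Wallis for k > 2 groups, with arithmetic group means
reported to one decimal in the style of the source tables.

Clinical binary factors (male sex, hypertension, …) can extend the score
("clinical-genetic"): each univariately significant factor enters with its
own OR, same inversion and rounding rules. The original study's
clinical-genetic means are not reproducible because its clinical weights
were never printed; the mechanism here is therefore generic.

### CHAID stratification

Kass-style ordinal CHAID with a single predictor (the score): start with
one category per distinct score value; repeatedly merge the adjacent pair
whose 2×2 (pair × outcome) χ² p is largest, while that p exceeds
`merge_alpha` (0.05). Categories smaller than `min_group` (10) are first
folded into their more similar neighbour (larger pairwise p). The final
partition's significance is the overall χ² p on the r×2 table times the
ordinal Bonferroni multiplier C(c−1, r−1) for c initial and r final
categories, capped at 1. Degenerate pair tables (a shared empty outcome
column) count as indistinguishable (p = 1). The original software (SPSS)
exposes many undocumented knobs; these defaults are the plain textbook
ordinal procedure and are validated against an independent brute-force
greedy implementation for up to 8 categories.

Printed group bounds follow the one-decimal midpoint convention — each
group's lower bound is the previous group's maximum plus 0.1 — which is
how cut-offs like "1.6" and "4.4" arise between attainable score values
1.5/2.1 and 4.3/5.8. The convention assumes the 0.1-point grid of
one-decimal weights; scores on a finer grid would render adjacent bounds
0.1 apart regardless.

## Synthetic cohorts

The generator emulates the two study arms: discovery 374 cardioembolic
cases / 156 controls, replication 242 / 547 (the 547 follows the genotype
table headers; the study text elsewhere says 542 — the discrepancy is in
the source). Published genotype data are collapsed class frequencies per
group (e.g. GG in 22.4% of cases), so presets pin the printed class
probability exactly and split the remaining mass between the other two
classes by Hardy–Weinberg proportions conditional on that class frequency
(for a printed minor-homozygote frequency f: q = √f). True allele
frequencies are not recoverable from the collapsed classes; only
class-level frequencies are matched.

Genotypes are drawn independently across SNPs (no linkage disequilibrium —
the score treats SNPs as independent terms and no joint genotype data
exist) and independently of the covariates, which are per-group Bernoulli
with the published prevalences. Atrial fibrillation is flagged on 46.4% of
cardioembolic cases, independent of genotype. A `null_cohort` preset uses
the discovery-control frequencies in both groups. Missing calls are
overlaid uniformly at a configurable `missing_rate` (default 0).

What the generator does *not* emulate — LD, population stratification,
genotyping error, per-subject missingness patterns, the joint
genotype-covariate distribution — bounds what passing tests show: pipeline
correctness and calibration under the published marginal frequencies, not
behaviour on real cohort structure. In particular, the published
risk-group percentages (50% / 74.1% / 92%) depend on the unavailable joint
genotype distribution and are replaced by a monotonicity property (case
fraction strictly increasing across risk groups on effect-bearing data).

## Numerical and design choices

* Allele orientation on file input: major/minor assigned by allele
  frequency among controls (when ≥ 50 controls are present, otherwise all
  samples), alphabetical tie-break; VCF REF/ALT map to major/minor by
  observed frequency with REF favoured on ties. Genotype tokens are
  unordered two-base strings ("AG" ≡ "GA"), "NN" missing.
* Count reconstruction from printed percentages rounds to the nearest
  integer, ties away from zero.
* The sample-size utility is the classical two-proportion normal
  approximation n = (z₁₋α/₂√(2p̄q̄) + z₁₋β√(p₁q₁+p₂q₂))²/(p₁−p₂)², rounded
  up; for the quoted design (0.30 vs 0.15, 80% power, α = 0.05) it gives
  121 per group, not the "110 subjects" the study quotes from its
  (undisclosed) software — the discrepancy is documented rather than
  matched.
* Degenerate inputs: empty arms and zero-margin tables raise typed errors
  at the primitive level and become flagged rows in scans; a single
  distinct score value yields a one-group stratification with a warning.

## Statistical test design

Several suite properties are themselves statistical and are asserted at
sample sizes and bounds where they hold with comfortable margin:

* Simulated OR recovery at 50,000 per group allows one of sixty draws
  (20 seeds × 3 SNPs) outside ±0.1, since ±0.1 is only ~2.6 SE for the
  widest OR (2.2) at that size.
* Type-I-error calibration of the scan on null cohorts pools the three
  panel SNPs per encoding over 1,000 replicates (3,000 tests per
  encoding), where the [0.035, 0.065] band sits ~3.7 SE from the nominal
  0.05.
* Exact one-decimal recovery of all three published weights from
  simulated cohorts is *not* a high-probability event at feasible sizes:
  the generating ORs (2.1999, 0.4675, 0.6570) lie fractions of a standard
  error from one-decimal rounding boundaries (0.4675 is ~0.2 SE from the
  1/2.15 boundary even at 50,000 per group), so per-replicate joint
  recovery probability is ≈ 0.03 at 20× the study size and ≈ 0.4 at
  50,000/50,000. The corresponding acceptance check is implemented at its
  stated conditions and fails for this structural reason; the attainable
  counterparts — selection of exactly the three causal SNPs, ORs within
  sampling error — are asserted separately.
* Fisher-exact and χ² p-values converge, but at cells of ~50 the gap can
  still reach ~0.1; the asymptotic-agreement test runs where all cells are
  ≥ 500 (max observed gap 0.018).

## Problem sizes

Default-suite simulations use the study sizes (530 / 789 subjects) and
scaled variants up to 20× for power-style checks, 50,000 per group for OR
recovery, 1,000 replicates for calibration, and full enumeration oracles
up to n = 40 (Fisher) and group sizes 6 (Mann-Whitney). These sizes were
chosen so each property is tested in the regime where it is informative.

## Known limitations

* Single-predictor CHAID only; no multi-way splits or cross-validated
  cut-offs.
* No additive/genotypic (2-df) association models, covariate-adjusted
  per-SNP ORs, haplotypes, or LD-aware weighting; HWE departures are not
  used to exclude SNPs.
* VCF support is read-only and minimal: biallelic records, GT subfield,
  no phasing or imputation.
* Published per-SNP p-values and CI bounds from the source tables are not
  reproducible from the printed class frequencies under any standard 2×2
  test (per-SNP missingness in the real data is the likely cause); they
  are treated as documentation, not acceptance surfaces.
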