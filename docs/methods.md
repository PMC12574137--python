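# Methods

This note documents the models behind each stage, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices and limitations a user should know
about.

## The synthetic cohort generator

The generator is the package's substitute for access-controlled
individual-level cohort data. Its defaults describe a large
developmental-disorder (DD) clinical-sequencing cohort:

| parameter | default | rationale |
|---|---|---|
| `category_probs` | 0.84 / 0.13 / 0.022 / 0.008 | term / moderate / very / extreme frequencies typical of DD cohorts, in which preterm probands are enriched relative to the ~10% population rate |
| `diag_prob_by_category` | 0.42 / 0.36 / 0.31 / 0.22 | diagnostic yield declining with prematurity, the liability-threshold signature the burden analyses probe |
| gestational weeks | uniform over the category's completed-week range (term capped at 42) | only category frequencies are specified; uniform-within-category is the least-informative completion |
| `p_male` | 0.56 | DD cohorts skew male |
| birthweight | log-linear median, ~3550 g at 40 wk and ~1150 g at 28 wk, ±2.5% by sex, multiplicative noise with CV 0.12 | matches the shape of fetal-growth references; the shipped synthetic LMS reference (L = 1, S = 0.12) inverts it exactly |
| milestone medians | smile 3, sit 9, walk 18, words 24 months | delayed relative to population norms, as expected in a DD cohort |
| DNM rates | 100 genes scaled to ~0.30 synonymous / 0.65 missense / 0.08 PTV expected DNMs per proband per generation | realistic exome-wide per-proband totals; per-gene shares are Dirichlet-distributed |

Randomness: a single master seed spawns an independent, named
substream per simulator (`SimConfig.rng("cohort")`,
`rng("dnm_base")`, ...), so adding a simulator never perturbs another's
draws, and every simulator is a pure function of (inputs, seed). The
DNM excess uses its own substream, which makes the baseline —
synonymous counts in particular — bit-identical between zero-excess
and excess runs at the same seed.

Injected effects and their estimators:

* **DNM excess.** Diagnosed probands receive Poisson-distributed extra
  nonsynonymous DNMs in each configured gene set; the gene is uniform
  within the set and the class (missense vs PTV) is proportional to the
  gene's null rates. Synonymous counts are never touched, so the
  calibration factor stays valid under injection.
* **Trios.** Parental genotypes are Binomial(2, f) per variant; each
  parent transmits one allele (Binomial(1, g/2)); the child dosage is
  the sum of transmitted alleles, giving corr(child, each parent) = ½.
  The phenotype is β_direct·PGS_child + β_parental·(PGS_mother +
  PGS_father) + Gaussian noise with all scores standardised, so the
  marginal child-score slope equals β_direct + β_parental — the
  attenuation identity that motivates the trio model.
* **Milestones.** Event times are exponential with rate
  ln2/median × exp(log-HR shifts) per category and diagnosis.
  Censoring is Bernoulli(`censor_prob`) per observation with the
  censoring time uniform on (0, event time): independent of the group
  structure, which is all the log-rank/Cox stages assume.
* **Rare variants.** A fixture generator: each candidate variant passes
  the complete burden-score filter with a configurable probability, and
  a failing variant violates exactly one filter, so the per-proband
  score is Binomial(k, f) by construction.

What the generator does **not** emulate: linkage disequilibrium,
sequence-context mutation-rate variation, genotyping-array error,
ascertainment-driven collider structure, informative censoring, or
correlated phenotype batteries. Passing tests therefore demonstrate
that the estimators recover known truth under their stated model
assumptions — not that those assumptions hold in any real cohort.

## Phenotype derivation

Prematurity classification uses the WHO half-open boundaries on
completed weeks; fractional input floors with a warning, because
gestation is conventionally recorded in completed weeks. Inputs outside
[22, 44] are rejected rather than clamped.

The ontology is a rooted DAG of is_a edges (child → parent, the OBO
orientation); obsolete terms and non-is_a relations are ignored on
read. A term's descendant closure is itself plus everything that can
reach it; closures are cached per graph.

Organ-system counting assigns every term below at least one system
root to exactly one root. The redundancy-avoidance rule in the
literature this mirrors is not published in full, so the package uses a
documented deterministic stand-in: the root with the smallest
descendant closure wins (the most specific system), residual ties break
lexicographically, and an explicit priority list can override the rule
entirely. The proband-level count is then the number of distinct
assigned roots over the proband's terms, so a term and its same-system
ancestor count once.

LMS z-scores use the standard ((x/M)^L − 1)/(L·S) form with the
log-form limit for |L| ≤ 1e-8. Lookup is exact on (sex, completed
week) with no interpolation — growth references are tabulated at that
resolution, and silent interpolation can hide join errors. The shipped
reference is synthetic, matched to the generator's birthweight model.
The outlier filter removes |z| > 5 and logs the count.

## Association battery

Binary outcomes use a binomial GLM (IRLS — chosen over Newton ML for
robustness near separation), continuous outcomes OLS, and counts a
negative-binomial regression with ML dispersion, falling back to
Poisson with a warning when the dispersion estimate pins at zero (the
family is otherwise undefined there). Separation is detected by
diverging coefficients (|β| > 15 on the link scale) and flagged;
empty prematurity cells yield flagged, inestimable terms rather than
silent drops. Antenatal outcomes adjust for maternal age; all others
for proband age at assessment and sex, matching the two displayed model
families; a single optional extra covariate (deprivation index or a
genetic score) supports sensitivity refits.

Continuous-gestation refits standardise gestational weeks to mean 0,
SD 1 within each cohort (sample SD, ddof = 1), so coefficients are per
SD of gestation.

Meta-analysis is fixed-effect IVW only — designed for two cohorts,
where a random-effects variance component is not estimable in any
useful way. The pooled SE is 1/√Σw, which is never larger than the
smallest input SE (asserted in tests).

Survival: Kaplan–Meier product-limit curves, the k-group log-rank test,
and Cox partial likelihood with the Efron tie correction — ties are
common at month resolution. Milestone ages are analysed as entered; a
gestation-correction toggle is deliberately absent from the default
path because source data are typically inconsistently pre-corrected,
and correcting twice is worse than not correcting. Multiplicity ledgers
are explicit: 0.05/4 for the log-rank family and 0.05/24 for Cox terms
(3 prematurity + 3 interaction terms × 4 milestones).

## DNM burden

Expected counts are N × Σ rates over the gene set and classes.
"Nonsynonymous" is the missense + PTV classes of the rate table;
mapping finer consequence vocabularies into those classes is the
caller's responsibility (see `docs/formats.md`).

A single calibration factor λ = O_syn/E_syn is computed over **all**
probands, exome-wide, and reused across strata: synonymous DNMs are
assumed neutral, so λ absorbs any overall misscaling of the null model
without absorbing signal. The excess test is a one-sided exact Poisson
test; by default it runs against λ·E. Caveat: λ is a plug-in estimate,
and treating λ·E as fixed ignores its sampling variance — with small
synonymous expectations this makes the corrected test anticonservative
(measurably so below ~1,000 expected synonymous DNMs). The
`apply_lambda_in_test=False` form tests against the raw expectation
and carries the exact-Poisson conservativeness guarantee; the package's
null-calibration checks use it, since the simulated null is exactly the
rate table.

The attributable fraction AF = (O − λE)/N may be negative and is
reported as computed. Its uncertainty treats O as Poisson with λE
fixed, SE = √O/N, CI = AF ± 1.96·SE; a proband-level bootstrap is
provided as an alternative for users who want λ's and the count
distribution's variability reflected. AF, O, E and (O − λE) are exactly
additive over disjoint gene sets at common N and λ, which the tests
assert to 1e-12. Group comparisons use z = (AF₁ − AF₂)/√(SE₁² + SE₂²)
with a 9-test Bonferroni ledger (3 proband groups × 3 gene sets); the
excess battery carries an 18-test ledger (× 2 gestational groups).

## Diagnostic enrichment

Per-gene tests regress binary prematurity on a gene indicator among
diagnosed probands with single-gene diagnoses, with no covariates (an
optional cohort indicator is exposed); genes qualify at ≥ 30 observed
diagnostic variants, the count at which the Monte-Carlo power
calculation gives ≥ 80% power for OR ≈ 6 at the Bonferroni-corrected
level. Zero cells fall back to the exact test with the conditional-MLE
odds ratio, flagged. A sensitivity rerun restricts to clinically
confirmed P/LP annotations.

Gene-set tests pool very and extremely preterm probands (three groups:
term / moderate / very-or-extreme) and run an exact k×2 Fisher test by
full enumeration of tables with the observed margins (two-sided by
probability mass; exponential in k, intended for k ≤ 4), followed by
pairwise 2×2 exact contrasts of each preterm group vs term. The
multiplicity ledger is 4 tests per gene set (overall + up to 3
pairwise).

The power routine simulates carrier/non-carrier preterm counts and
applies the closed-form Wald test on the 2×2 log odds ratio — the
single-binary-predictor logistic model in closed form — with a Haldane
0.5 correction only on zero cells.

## Genetic scores

PGS scoring matches variants by ID and exact allele pair: a swapped
effect/other pair flips the dosage to 2 − d; a mismatched pair is
dropped with a warning, and no strand flipping is attempted (inputs
are assumed pre-harmonised). Missing dosages are imputed to twice the
effect-allele frequency estimated from non-missing carriers. Scores
are standardised within cohort so regression coefficients read as per
SD of score.

The RVBS counts variants passing all of: autosomal heterozygous,
inherited, (high-confidence PTV) or (missense-like with MPC ≥ 2),
pLI > 0.9, gnomAD MAF < 1e-5 in every super-population, cohort
MAF < 1e-4. "Missense-like" is the expanded class (missense, stop/start
lost, inframe indels, low-confidence LoF); the boundary MPC = 2 is
inclusive. The filter is monotone: relaxing any threshold never
decreases a score.

RINT uses the Blom offset, Φ⁻¹((r − 3/8)/(n + ¼)), with average ranks
for ties and missing values propagated; constant input is rejected.

The trio model regresses the phenotype jointly on standardised child,
maternal and paternal scores (plus covariates). Because
parent = transmitted + non-transmitted and the child score is the sum
of transmitted alleles, regressing on parental full scores is an
affine reparameterisation of regressing on explicitly constructed
non-transmitted scores — the child coefficient (the direct-effect
estimate) is identical; the simulator exposes per-parent transmitted
dosages so either form can be fit. A child score collinear with the
parents (no segregation variance) is rejected.

## Problem sizes and tolerances

Monte-Carlo checks in the test-suite and acceptance script use scaled
cohorts chosen to keep each property estimable in seconds: λ
calibration at N = 20,000 over a 100-gene panel; AF recovery of an
injected 0.15 excess at N = 10,000; the 18-test null battery over 200
replicates of N = 1,500 × 40 genes; Cox hazard-ratio recovery at
N = 5,000; trio recovery at 3,000 trios × 300 variants. Stochastic
recoveries are asserted within 4 estimated SEs; closed-form identities
to 1e-6–1e-12; calibration rates with binomial Monte-Carlo allowances.

## Known limitations

* The organ-system tie-break is a documented stand-in, not a claim
  about the original redundancy rule.
* Fixed-effect meta-analysis only; heterogeneity is reported, not
  modelled.
* The λ-corrected Poisson test ignores λ's sampling variance (above).
* The exact k×2 Fisher enumeration is exponential in k.
* No LD, imputation, ancestry inference, PC computation or
  variant-calling QC: those are upstream of this package's inputs.
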