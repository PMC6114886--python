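# Methods

This document is the package's own account of the statistical methods it
implements, the assumptions baked into its defaults, and the numerical
choices that affect results.

## 1. Models

Both pretest-probability (PTP) models are logistic regressions applied
without refitting:

    η = β₀ + Σⱼ βⱼ xⱼ,   PTP = expit(η) = 1 / (1 + e^(−η))

`ModelSpec` is a frozen, config-driven description of one such model: an
intercept plus coefficient terms drawn from a fixed covariate vocabulary
(linear age in years, male sex, typical/atypical chest-pain indicators
against a nonanginal reference, diabetes, hypertension, hyperlipidaemia,
current smoking, family history of CAD, and one coronary-calcium family —
either `ccs_transform`, β·log_b(ccs + shift), or mutually exclusive
`ccs_category_indicator` terms). A spec may use at most one CCS family;
only the logistic link is supported.

The two packaged example specs have the covariate structure of the
clinical-history score ("confirm" shape: age, sex, chest pain, diabetes,
hypertension, family history, smoking) and of its calcium-extended
counterpart ("gem" shape: drops family history, adds hyperlipidaemia and
β·ln(ccs + 1)). Their coefficient *values* are illustrative, chosen to give
plausible effect directions and magnitudes; validating published models on
real data means supplying the published coefficients in the same JSON/YAML
format. `predict_ptp` uses a sign-branched logistic to avoid overflow at
extreme η and clamps output to the open interval (0, 1) so downstream
log-odds and H-L denominators are always finite.

## 2. Outcome definitions

* **Obstructive CAD**: an explicit adjudicated label wins if present;
  otherwise derived as maximum diameter stenosis ≥ 50% OR any
  non-assessable (typically heavily calcified) segment.
* **PTP categories**: low < 15%, 15% ≤ medium ≤ 85%, high > 85%. Boundary
  values fall in the medium category; cut-offs are arguments everywhere
  (`DEFAULT_CUTOFFS = (0.15, 0.85)`).
* **Strategy map**: low → no further test, medium → noninvasive test,
  high → invasive strategy.
* **MACE composite**: cardiac death, nonfatal myocardial infarction, or
  hospitalization for unstable angina at any time during follow-up;
  coronary revascularization counts only when later than 60 days after the
  index evaluation (`LATE_REVASC_MONTHS = 60 / 30.4375`, using the mean
  Gregorian month length). Individuals without follow-up are excluded from
  MACE rates and counted separately.

## 3. Statistics

### AUC and the DeLong paired test

AUC is the Mann–Whitney statistic with ties counted ½, computed from
midranks. Variance and the paired comparison use DeLong's structural
components (placement values): for individual i,
v10ᵢ = (overall rank − within-positive rank)/n₋ for positives and the
mirrored v01 for negatives. The paired test statistic is

    z = (AUC_b − AUC_a) / sqrt(s²_a + s²_b − 2 s_ab)

with s² the placement-value variances of the difference components.
Identical score vectors return a difference of 0 with p = 1; a nonzero
difference with zero estimated variance raises an error rather than
returning a fabricated p-value. Wald confidence intervals are truncated to
[0, 1]. The test-suite oracle is exhaustive pair counting for the AUC
itself and a 20,000-resample paired bootstrap for the p-value.

### IDI

IDI = (p̄⁺_new − p̄⁺_old) − (p̄⁻_new − p̄⁻_old), the change in
discrimination slope. The z-test uses the standard error of the paired
per-individual differences, pooled across the two outcome groups. A
group-means-only variant (`idi_from_group_means`) supports recomputation
from published summary tables.

### Categorical NRI

Reclassification tables are 3×3 counts with rows = new category,
columns = old, one table per outcome group. "Up" is movement to a higher
category (below the diagonal in this orientation), "down" to a lower one.

    NRI = [P(up|D=1) − P(down|D=1)] + [P(down|D=0) − P(up|D=0)]

Component proportions are computed with exact rational arithmetic
(`fractions.Fraction`) so the overall NRI is exactly the sum of its
components before the final float conversion. The z-test uses the
multinomial variance (p_up + p_down − (p_up − p_down)²)/n per stratum.

### Hosmer–Lemeshow and the degrees-of-freedom choice

Individuals are grouped by interior quantiles of predicted probability
(deciles by default); a value exactly equal to a cut point goes to the
lower group, so grouping is deterministic and order-independent. The
statistic is χ² = Σ (O_g − E_g)² / (E_g (1 − p̄_g)).

The reference distribution depends on where the probabilities came from.
The default df = g − 2 is the convention for a model *fitted on the same
data*. When the probabilities are externally specified — a published model
scored without refitting, or the simulation truth — the group deviations
are g independent standardized sums and the correct reference is χ² with
df = g. We verified this empirically: on Bernoulli(p) data with p the
truth, the statistic has mean ≈ g and the df = g test holds its nominal 5%
size, whereas df = g − 2 over-rejects. The `df` argument makes both
available; the external-validation code paths in this package use df = g
where the probabilities are simulation truth and the report default
(df = g − 2) elsewhere, so users comparing against fitted-model literature
see the familiar convention.

Degenerate groupings (fewer than three populated groups under heavy ties,
or a cell with expected events 0 or n) raise errors instead of returning a
meaningless statistic.

### Strategy impact

Among individuals without obstructive CAD whose *old* category was medium
(noninvasive testing), count those whose *new* category is low (no further
test), per stratum and pooled; report the MACE tally among the moved, with
no-follow-up individuals excluded from the denominator but counted.

## 4. Synthetic cohort generator

The generator emulates the *structure* of a low-risk validation population
in two strata defined by cardiovascular risk-factor burden (smoking,
diabetes, hypertension, hyperlipidaemia — family history is not a counted
risk factor):

* **Stratum sizes and prevalence**: 0 RF n = 1201 at 30% obstructive-CAD
  prevalence; 1 RF n = 2415 at 27%. These and all marginals below are the
  package defaults because they are the conditions the pipeline is meant
  to be exercised under, not tuning dials.
* **Covariates**: age from a truncated normal on [18, 90]
  (0 RF: 56.26 ± 10.61; 1 RF: 57.20 ± 10.56); sex, chest-pain type,
  family history, and (in the 1-RF stratum) which single risk factor is
  present are drawn from fixed categorical marginals.
* **CCS**: zero-inflated lognormal. The point mass at zero is 46%/47% by
  stratum; the lognormal parameters (0 RF: μ = 4.5213, σ = 1.2484;
  1 RF: μ = 4.7015, σ = 1.4683) were solved analytically so the positive
  part reproduces the target fractions in the guideline categories
  1–100, 101–400, > 400.
* **Disease**: obstructive CAD is Bernoulli under a known logistic model
  over the generated covariates (the packaged calcium-extended example
  structure). The intercept is tuned by `scipy.optimize.brentq` on the
  mean predicted probability so realized prevalence matches the stratum
  target in expectation — disease strength comes from the coefficients,
  overall level from the target prevalence.
* **Follow-up and MACE**: follow-up time Uniform(3, 31) months with 3.8%
  lost to follow-up; MACE is Bernoulli with base rate 2.3% and odds ratio
  3.0 for CAD-positives (chosen analytically to give a pooled rate near
  3.5%); event kinds are drawn from fixed proportions (cardiac death,
  nonfatal MI, unstable angina, late revascularization), with a small
  0.5% rate of early (< 60 days) revascularizations that must *not* count
  as MACE.

What the generator does **not** emulate: covariate correlations beyond
those induced by the disease model (e.g. age–CCS correlation exists only
through the categorical marginals, not as an explicit copula), competing
risks or any time-to-event structure (event times are placed uniformly in
the eligible window, not from a hazard model), measurement error in CCS,
and site or referral effects. It is a pipeline-validation instrument, not
an epidemiological simulator.

All randomness flows from one `numpy` `SeedSequence`-derived generator per
cohort; a fixed seed gives byte-identical CSV output.

## 5. Parameter recovery

`parameter_recovery_check` confirms the generator/validator loop is
self-consistent: over seeded replicates (default 50 cohorts of n = 20,000),
the true disease model is compared with a deliberately degraded competitor
(all slopes halved, intercept re-tuned to the same prevalence so only shape
differs). The true model should win on AUC and positive NRI in ≈ all
replicates and pass H-L (at df = g, since its probabilities are the truth)
at near-nominal rates. The replicate count and cohort size were chosen so
the check is decisive yet runs in well under a minute on one CPU.

## 6. Data notes on the packaged published tables

The packaged reclassification tables and group-mean PTPs are transcribed
counts. Two reconciliations worth knowing about:

* Recomputing the overall 0-RF NRI exactly from counts gives 29.844%,
  while summing the separately rounded components (6.34% + 23.51%) gives
  29.85%; the package reports the exact value.
* The 0-RF chest-pain marginal used by the generator takes the atypical
  count as 559, the unique value consistent with both the stratum size
  (433 + 559 + 209 = 1201) and the printed 46% share.

## 7. Limitations

* NRI/IDI inference uses the classical asymptotic variances; both
  statistics are known to be optimistic when the added marker is weak, and
  categorical NRI depends entirely on the chosen cut-offs.
* The DeLong test assumes the same individuals under both models (paired);
  unpaired comparison is out of scope.
* H-L with many tied predictions can collapse groups; the package errors
  out rather than silently merging, which means heavily discretized scores
  may need a smaller g.
* Example coefficient sets are structural placeholders: absolute PTPs,
  calibration statistics, and strategy fractions computed with them
  characterize the pipeline, not any published model's performance.
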