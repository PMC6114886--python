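# ptpvalid

External validation and comparison of pretest-probability (PTP) models for
obstructive coronary artery disease (CAD).

## The problem

Guidelines make the estimated PTP of obstructive CAD the first step in
working up stable chest pain: individuals below 15% need no further testing,
those between 15% and 85% are sent to noninvasive testing, and those above
85% to an invasive strategy. Clinical PTP models built only from history
(age, sex, chest-pain typicality, risk factors) tend to overestimate risk in
low-risk populations and push many disease-free people into unnecessary
noninvasive testing. Adding the Agatston coronary calcium score (CCS) — a
cheap, low-radiation quantification of coronary calcification — promises a
sharper estimate. `ptpvalid` is a pipeline for quantifying exactly how much
sharper, for anyone validating a pair of logistic PTP models head-to-head on
a cohort with a CCTA-adjudicated outcome (obstructive CAD: any ≥50% diameter
stenosis or a non-assessable, heavily calcified segment).

## What it computes

Both models are logistic linear predictors, fully config-driven:

    η = β₀ + Σⱼ βⱼ xⱼ,   PTP = 1 / (1 + e^(−η))

The comparison statistics are:

* **AUC** (Mann–Whitney, ties ½) with DeLong variance, and the **DeLong
  paired test** for ΔAUC on the same individuals:
  z = (AUC_b − AUC_a) / √(v_a + v_b − 2c) from placement values.
* **IDI**, the difference of discrimination slopes:
  (p̄⁺_new − p̄⁺_old) − (p̄⁻_new − p̄⁻_old), with a pooled paired z-test.
* **Categorical NRI** at the guideline 15%/85% cut-offs, with the full 3×3
  reclassification tables by outcome:
  NRI = [P(up|+) − P(down|+)] + [P(down|−) − P(up|−)].
* **Hosmer–Lemeshow** calibration on deciles of PTP, with exportable
  observed-vs-predicted curve data.
* **Diagnostic-strategy impact**: CAD-negative individuals moved from
  noninvasive testing (medium PTP) to no further test (low PTP), and the
  MACE rate among them (cardiac death, nonfatal MI, unstable-angina
  hospitalization, late >60-day revascularization).

A seeded synthetic cohort generator reproduces the structure of the
motivating study population — two strata at the low extreme of risk-factor
burden (0 RF: n=1201, 30% prevalence; 1 RF: n=2415, 27%) with realistic
covariate marginals, a zero-inflated lognormal CCS, and a known logistic
disease model — so the whole pipeline can be exercised and checked for
parameter recovery without patient data.

Coefficient values for the published CONFIRM score and Genders extended
model are not bundled (they belong to the original model publications);
the package ships example coefficient sets with the correct covariate
structure, and scoring a real cohort with the published numbers is purely a
config exercise (`src/ptpvalid/data/*_example.json` shows the format).

## Worked example

Recompute the reclassification statistics from the published 0-RF tables
that ship as package data:

```
$ ptpvalid compare-tables --stratum "0 RF"
{
  ...
  "up_pos": 64, "down_pos": 41, "up_neg": 72, "down_neg": 269,
  "nri_pos_pct": 6.34, "nri_neg_pct": 23.51, "nri_overall_pct": 29.84,
  "idi_pct": 5.0
}
```

Of 838 CAD-negative individuals, 269 were reclassified down and only 72 up
(net +23.51% of negatives correctly moved); among 363 positives, 64 moved up
against 41 down (+6.34%); the overall NRI is 29.84% and the IDI from the
printed group-mean PTPs is 5 percentage points — the calcium-extended model
classifies substantially better.

The same pipeline end-to-end on a synthetic stratum:

```python
from ptpvalid import default_configs, generate_cohort, validate_cohort
from ptpvalid.models import example_confirm_style_spec, example_gem_style_spec
from ptpvalid.report import render_text_report

cfg0, _ = default_configs(seed=1)
cohort = generate_cohort(cfg0)                      # 1201 records, "0 RF"
report = validate_cohort(cohort,
                         example_confirm_style_spec(),
                         example_gem_style_spec())
print(render_text_report(report))
```

```
Stratum 0 RF: n=1201, obstructive CAD 361 (30.06%)
AUC clinical-score-example: 0.699 (0.666 to 0.731)
AUC calcium-extended-example: 0.811 (0.785 to 0.837)
DeLong ΔAUC 0.112, p = 2.42e-15
IDI 10.72% (positives 32% → 39%, negatives 19% → 15%), p = 3.083e-21
NRI overall 19.42% (positives 9.42%, negatives 10.00%; up/down positives 65/31, negatives 106/190), p = 6.507e-09
H-L (old): chi2 = 88.80, df = 8, p = 8.157e-16
H-L (new): chi2 = 66.04, df = 8, p = 3.003e-11
Strategy: 189/394 (48%) negatives move from noninvasive testing to no further test
  among moved: 3 MACE in 184 followed (1.6%; 5 without follow-up)
MACE AUC: old 0.605, new 0.667, DeLong p = 0.07163 (47 MACE / 1161 followed; 40 excluded without follow-up)
```

The calcium-extended model gains 0.112 in AUC, reclassifies a net 19% of the
cohort correctly, and moves about half of the test-bound negatives out of
testing at a 1.6% event rate. (Both models are miscalibrated here by
construction: the example coefficient sets are scored as-is, without
recalibrating their intercepts to this cohort.)

The CLI mirrors this: `ptpvalid generate` writes synthetic cohort/events
CSVs, `ptpvalid validate --cohort ... --model-old ... --model-new ...`
writes a JSON/CSV/text report bundle.

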