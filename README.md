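# genofirst

A tested pipeline for **genotype-first hereditary breast-cancer screening**
analyses: instead of offering germline testing only to people whose family
history (FH) meets clinical criteria, a genotype-first program identifies
carriers of pathogenic variants in breast-cancer genes directly from existing
biobank genomic data and returns the finding through genetic counseling.

The package is written for statistical geneticists and biobank return-of-
results teams who want to reproduce, stress-test, or re-parameterize this
kind of analysis without access to restricted individual-level data.  Every
stage runs on synthetic cohorts with the relevant statistical structure.

## What it implements

* **`genofirst.simulate`** — a synthetic biobank generator: an all-female
  cohort with heterozygous carriers of a 16-variant panel across the 11
  breast-cancer genes (high risk: *BRCA1, BRCA2, TP53, STK11, PTEN, CDH1*;
  moderate: *ATM, PALB2, CHEK2, NBN, NF1*), piecewise-exponential
  breast-cancer onset on the age scale, per-source genotype matrices
  (sequencing / array / imputed) with injected missingness and imputation
  discordance, and Mendelian pedigrees whose relatives develop cancers under
  the same hazard model.
* **`genofirst.qc`** — per-source variant/sample QC: call-rate filters, an
  exact Hardy–Weinberg test (conditional on allele counts, the appropriate
  test for rare variants), and an X-heterozygosity sex check.
* **`genofirst.annotate`** — ClinVar-style assertion lookup, risk
  classification (returnable ⇔ pathogenic / likely pathogenic), gene
  tiering, direct-vs-imputed carrier concordance, the two-rule candidate
  prioritization, and the Sanger confirmation gate.
* **`genofirst.eligibility`** — a data-driven rule engine for FH-based
  testing criteria (a codified 2018-era base rule set plus an adjusted
  version extending to relative prostate/pancreatic cancer and breast-cancer
  onset ≤ 60), with a parser for free-text FH strings
  (`"Mother's side: BC, 38, 46; OC, 56"`).
* **`genofirst.survival`** — Kaplan–Meier cumulative incidence with
  Greenwood variance and log–log confidence bands, and Cox proportional
  hazards (Newton–Raphson on the Efron partial likelihood), both written
  from first principles and verified against an independent reference
  implementation in the test suite.
* **`genofirst.reporting` / `genofirst.fixtures`** — the study's published
  summary tables ship as TSV fixtures, and the reporting layer recomputes
  their headline statistics (participant flow, variant shares, onset
  cross-tabs, surgery uptake, cascade-screening load).

The core survival model: within age band $j$ the baseline hazard is a
constant $h_j$, calibrated once so the non-carrier cumulative incidence
$1 - \exp(-H(70))$ equals 4.3%; a carrier group with hazard ratio $r$ has
onset distribution $S(t) = \exp(-r\,H(t))$, sampled by inversion.  Group
hazard ratios default to 12.1 (*BRCA1/2*) and 4.4 (*CHEK2*).

## Worked example

```python
import numpy as np
from genofirst import CohortConfig, CoxPH, KaplanMeierEstimator
from genofirst import simulate

cfg = CohortConfig(n_participants=20_000, seed=42)
cohort = simulate.simulate_cohort(cfg)
rec = simulate.survival_records(cohort)

X = np.stack([rec.group == "BRCA1/2", rec.group == "CHEK2"], axis=1).astype(float)
fit = CoxPH().fit(rec.exit_age, rec.event, X)
print(f"HR BRCA1/2 {fit.hr_[0]:.1f} (95% CI {fit.ci95_[0][0]:.1f}-{fit.ci95_[0][1]:.1f})")
print(f"HR CHEK2   {fit.hr_[1]:.1f} (95% CI {fit.ci95_[1][0]:.1f}-{fit.ci95_[1][1]:.1f})")

nc = rec[rec.group == "non-carrier"]
inc, ci = KaplanMeierEstimator().fit(nc.exit_age, nc.event).cumulative_incidence_at(70)
print(f"non-carrier incidence at 70: {100*inc:.1f}% ({100*ci[0]:.1f}-{100*ci[1]:.1f})")
```

prints

```
HR BRCA1/2 11.3 (95% CI 8.6-15.0)
HR CHEK2   4.0 (95% CI 2.4-6.8)
non-carrier incidence at 70: 4.4% (4.0-4.8)
```

i.e. on one simulated cohort of 20,000 women (348 carriers, 803 first
breast-cancer events) the Cox fit recovers the generator's hazard ratios of
12.1 and 4.4 within its confidence intervals, and the non-carrier
Kaplan–Meier incidence at age 70 matches the calibrated 4.3% anchor.

A CLI mirrors the pipeline: `genofirst simulate`, `qc`, `eligibility`,
`survival`, `report`, `acceptance`, and `genofirst config --dump` for the
full default configuration.

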