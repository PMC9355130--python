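# Methods

This note documents the models behind `genofirst`, the defaults and why
they were chosen, and what the synthetic cohorts do and do not emulate.

## Breast-cancer onset model

Time is **age from birth**.  The baseline (non-carrier) hazard is piecewise
constant on decade bands with relative weights 0.02 / 0.5 / 1.0 / 1.3 / 1.5
/ 1.6 / 1.6 for ages 0–30, 30–40, …, 80–100, reflecting the age profile of
female breast-cancer incidence (near zero before 30, rising to a plateau).
Because the published anchors are cumulative incidences rather than
hazards, the weights are rescaled once (`hazard.calibrate_baseline`) so
that the non-carrier cumulative incidence at age 70,
1 − exp(−H(70)), equals the configured anchor of **4.3%**.

Carrier groups act proportionally on this baseline: S(t) = exp(−r·H(t))
with default hazard ratios **r = 12.1 for BRCA1/2**, **4.4 for CHEK2**, and
3.0 for the remaining moderate-risk genes (the last is a literature-scale
choice; the source analysis did not estimate it separately).  Event ages
are drawn by exact inversion of the piecewise-exponential survival
function, so the closed form 1 − exp(−r·H(a)) is the generator's ground
truth at every age and serves as the oracle in the tests.

Note an internal tension in the published anchors: under exact proportional
hazards, r = 12.1 on a 4.3% baseline implies a carrier incidence at 70 of
1 − 0.957^12.1 ≈ 41%, while the published Kaplan–Meier point estimate for
carriers is 35.3% (95% CI 24.7–44.4).  The generator calibrates on the
(hazard ratio, non-carrier incidence) pair; the carrier-incidence closed
form is therefore ≈ 41%, inside the published interval but not equal to its
point estimate.  The acceptance outputs report the recovered hazard ratios
and the non-carrier incidence, which are the quantities the model pins
down.

## Cohort structure

Defaults emulate a women-only population biobank:

* **Carrier frequencies.**  Combined BRCA1/2 carrier probability 0.008
  (the published Estonian sequencing-based prevalence, 1/124), split across
  the seven BRCA panel variants in proportion to their case counts.  CHEK2
  0.005 — the published confirmed-carrier count (204/136,043 ≈ 0.15%)
  reflects a confirmed subset, not population prevalence; 0.5% matches the
  Northern/Eastern-European range for c.1100delC plus the two splice
  variants.  ATM 0.003, NBN 0.001, NF1 0.0002 (literature-scale).  Each
  carrier holds exactly one panel variant, matching the one-gene-per-
  participant reporting of the source tables.
* **Follow-up.**  Age at censoring ~ Uniform(40, 90), representing attained
  age at the last registry linkage; recruitment age is censor age minus a
  Uniform(1, 20) gap, floored at 22.  Diagnoses with onset before
  recruitment are labeled *prevalent*, later ones *incident* (the source
  distinguishes the two without stating a rule; this is the natural one).
  Whether prevalent cases contribute to the survival risk set is a
  configuration flag (`include_prevalent`, default true, mirroring the
  apparent use of known-date diagnoses regardless of recruitment).
* **Genotype sources.**  BRCA1/2 variants are observed through array,
  imputed and sequencing data; the non-BRCA panel variants through
  sequencing only — mirroring how carriers were actually found (almost all
  BRCA findings from genotype data, most non-BRCA from sequencing).
  Sequencing/array copies get 2%/1% missingness; the imputed copy retains a
  true carrier call with probability 0.95 and adds spurious carriers at
  5·10⁻⁴ (discordance is injected, not modeled mechanistically — no
  phasing or imputation algorithm is reimplemented).  Twenty synthetic
  X-chromosome markers (MAF 0.1–0.4) support the sex check; reported sex
  carries a 0.2% clerical error rate.

## Pedigrees and family history

Each carrier proband gets mother + father plus Poisson(2.3) additional
relatives drawn from a first/second-degree pool, for a mean pedigree size
of 4.3 (the published mean number of relatives recommended for counseling
per participant).  Relatives inherit the proband's variant with Mendelian
probability 1/2 (first degree) or 1/4 (second degree); relatives of
non-carriers carry at the population frequency.  Female relatives draw
breast-cancer onsets from the same hazard model given their carrier status;
ovarian, prostate, pancreatic, gastric and male-breast cancers occur as
age-distributed Bernoulli events with carrier rate ratios for the
BRCA-associated types.

Two severity scales are calibrated once by `scripts/calibrate_fh.py`
(bisection against the rule engine on 4,000 synthetic carrier pedigrees)
and frozen as defaults:

* `fh_breast_scale = 2.874` multiplies relatives' breast/ovarian risk so
  that the **base** criteria detect ≈ 33% of carriers from FH alone.  The
  scale exceeds 1 because a reported FH aggregates many relatives over full
  lifetimes (including deceased ones), which the simple pedigree model
  otherwise understates.
* `fh_adjacent_scale = 1.09` multiplies prostate/pancreatic rates so the
  **adjusted** criteria detect ≈ 53%.

The published 33% → 53% detection rates rest on unpublished
per-participant histories, so they are reproduced structurally (base rate
in a plausible band, adjusted strictly higher), not exactly.

## Eligibility rules

The clinical guidelines behind the source analysis are not printed in it;
the base rule set is a codified approximation of 2018-era familial
breast-cancer testing criteria, shipped as a versioned TSV
(`data/rules.tsv`) so the rules can be edited without touching the engine:
personal BC ≤ 45; personal BC ≤ 50 with a second BC or any close relative
with breast/ovarian/pancreatic/prostate cancer; personal triple-negative BC
≤ 60; personal ovarian cancer; personal male BC; relative BC ≤ 50; relative
ovarian cancer; relative male BC; and ≥ 3 breast cancers in one lineage
(the participant counts with either side; unknown-side relatives count
toward both).  The adjusted version adds: any relative prostate or
pancreatic cancer, and relative BC ≤ 60 — implemented verbatim from the
one-sentence published definition.  "Close relative" means first or second
degree.  An unknown onset age never satisfies an age-limited rule
(conservative) but does satisfy any-age rules.  Every rule is monotone in
the event list, so the adjusted set is provably a superset of base; both
properties are exercised on 10,000 random histories.

The FH string parser follows the source tables' grammar (side prefixes,
type abbreviations BC/OC/PC/PAC/GC, comma-separated ages); decade tokens
("40-s") and phrases without an age yield unknown onsets, parenthetical
remarks are dropped, and unrecognizable fragments become type *other* with
a warning.  Its output is pinned against a hand-tallied fixture of all 23
table FH strings.

## Quality control

The exact Hardy–Weinberg test enumerates the conditional distribution of
the heterozygote count given the allele counts in log space (log-gamma
form) and sums the probabilities not exceeding the observed one; a 1e-10
log-space tolerance absorbs round-off among tied configurations.
Monomorphic sites give p = 1 by convention.  The test equals an independent
integer-arithmetic enumeration to < 1e-12 for every triple with N ≤ 200,
and its null failure rate at α = 1e-4 over 100,000 simulated
HWE-consistent variants stays below α + 3·SE (the exact test is
conservative).  Default thresholds: sequencing call rate ≥ 0.90 and HWE
p ≥ 1e-9 on all variants; array call rate ≥ 0.95 and HWE p ≥ 1e-4 on
autosomes only; sample call rate ≥ 0.95.  Whether the sequencing HWE filter
was autosomes-only is not stated in the source; the default applies it to
all variants, with a flag to restrict.  Sex-check thresholds (male X-het
≤ 0.05, female ≥ 0.20, ≥ 10 informative calls) are documented defaults,
not published values.  A variant failing both call rate and HWE is counted
once, under call rate.  Upstream caller-internal filters (VQSR) are out of
scope; a VCF FILTER column is honored — only PASS/"." records enter QC.

## Survival estimation

Kaplan–Meier uses the product-limit form with Greenwood variance and a
log–log-transformed 95% band (bounds stay inside [0, 1]); cumulative
incidence is 1 − S(t) evaluated as a step function.  The Cox model
maximizes the Efron-tied partial likelihood (Breslow available; the two
coincide without ties) by Newton–Raphson with step-halving, gradient
tolerance 1e-9 (the step-halving acceptance threshold is relative to |ll|
because round-off in the log-likelihood scales with its magnitude),
maximum 50 iterations, covariates centered for stability, standard errors
from the observed information and Wald intervals.  Monotone-likelihood
divergence (a covariate level with all or no events) is detected — huge
coefficient with exploding standard error — and raised, never silently
returned.  Both estimators are verified against lifelines to 1e-6 on a
tied fixture, and parameter recovery is checked over 200 simulated cohorts
of 20,000 women: mean estimated hazard ratios within 5% of generator
truth, ≥ 93% Wald coverage, and mean KM non-carrier incidence at 70 within
three Monte-Carlo standard errors of the closed form.  The replicate size
(200 × 20,000) keeps the Monte-Carlo error of the means around 1–2% while
the whole experiment runs in well under a minute.

## What the synthetic cohorts do not capture

* No polygenic or non-genetic risk factors; hazards depend on carrier
  group only, and proportional hazards holds exactly by construction —
  real carrier risks are age-varying.
* No male participants, no male breast/prostate cancer risk modeling in
  probands (male relatives appear only as FH sources).
* Pedigrees are independent across probands (no shared founders), relative
  counts and attained ages are stylized, and non-breast cancer onsets use
  simple truncated-normal age distributions.
* Genotype errors are injected at configured rates rather than arising
  from a calling/imputation mechanism; Sanger confirmation is a boolean
  gate.
* Participant personal histories contain breast cancer only; the published
  non-breast personal cancers enter through the fixture tables, not the
  generator.

Passing tests therefore demonstrate the *pipeline's* correctness and
calibration under the stated model, not the realism of any particular
biobank.

## Fixture conventions

The four published summary tables are transcribed verbatim as TSV (RefSeq
thousands-separator artifacts removed, e.g. `NM_007300`).  Known internal
inconsistencies of the source are preserved and documented rather than
reconciled: the per-gene case counts sum to 108 against 109 counseled
participants, and the printed "14.7% CHEK2" share implies 16 carriers
where the table lists 15.  Study-wide surgery totals (16 BSO, 5 MT) exceed
the surgeries listed in the tables because some were performed in carriers
without cancer history who are not tabled; they are therefore supplied as
constants, never derived.  GRCh37 loci for the panel variants are not
published; the packaged loci are synthetic placeholders inside the correct
gene bounds, used only as join keys, and are labelled as such in the data
files.  Percentages are rounded half-up — to integers for the
participation funnel, to one decimal for table shares — matching the
source's printing.
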