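"""Recompute the study's headline quantities from scratch.

Fixture-derived statistics come straight from the packaged tables; the
survival quantities come from the Cox/KM parameter-recovery experiment on
simulated cohorts; the detection rates come from synthetic carrier family
histories under the calibrated severity defaults.  Every value is computed
at call time — nothing is looked up.
"""

from __future__ import annotations

from . import fixtures, reporting
from .annotate import variant_table_summary


def run_acceptance(
    seed: int,
    n_replicates: int = 200,
    n_per_cohort: int = 20_000,
    n_fh_probands: int = 4000,
) -> dict[str, dict]:
    fixtures.validate_fixtures()
    out: dict[str, dict] = {}

    def put(name: str, value, n) -> None:
        out[name] = {"value": float(value), "n": int(n)}

    # ---- personal cancer history (cross-tab)
    ct = reporting.onset_crosstab()
    put("personal_cancers_total", ct["total"], ct["total"])
    put("personal_bc_count", ct["by_type"]["Breast"], ct["total"])

    # ---- breast-cancer case table
    bc = reporting.bc_case_summary()
    put("incident_bc_count", bc["incident"], bc["n_cases"])
    put("bc_under50_pct", bc["under50_pct"], bc["n_cases"])

    # ---- risk-reducing surgery
    surg = reporting.surgery_uptake()
    put("bso_cancer_history_pct", surg["bso_cancer_history_pct"], surg["bso_total"])
    put("mt_contralateral_pct", surg["mt_contralateral_pct"], surg["mt_total"])

    # ---- variant panel shares
    t1 = variant_table_summary(fixtures.load_table1())
    brca1_top = t1[(t1.gene == "BRCA1") & (t1.cds == "c.5329dupC")].share_pct.iloc[0]
    brca2_top = t1[(t1.gene == "BRCA2") & (t1.cds == "c.8572C>T")].share_pct.iloc[0]
    put("brca1_top_variant_share_pct", brca1_top, int(t1[t1.gene == "BRCA1"].gene_total.iloc[0]))
    put("brca2_top_variant_share_pct", brca2_top, int(t1[t1.gene == "BRCA2"].gene_total.iloc[0]))
    shares = reporting.counseled_shares()
    put("brca1_counseled_share_pct", shares["BRCA1"], fixtures.N_COUNSELED)
    put("atm_counseled_share_pct", shares["ATM"], fixtures.N_COUNSELED)
    put("pathogenic_assertion_pct", reporting.pathogenic_share_pct(), int(t1.cases.sum()))

    # ---- participation funnel and cascade screening
    flow = reporting.flow_percentages()
    put("participation_scheduled_pct", flow["scheduled_pct"], 180)
    put("participation_consented_pct", flow["consented_pct"], 180)
    put("second_visit_pct", flow["second_visit_pct"], 109)
    put("oncologist_visit_pct", flow["oncologist_pct"], 109)
    put("cascade_mean_invitations", reporting.cascade_load(), 106)

    # ---- hazard-ratio recovery and non-carrier cumulative incidence
    rec = reporting.hr_recovery_experiment(
        seed, n_replicates=n_replicates, n_per_cohort=n_per_cohort
    )
    put("cox_hr_brca12", rec["hr_mean"]["BRCA1/2"], rec["n_replicates"] * n_per_cohort)
    put("cox_hr_chek2", rec["hr_mean"]["CHEK2"], rec["n_replicates"] * n_per_cohort)
    put(
        "km_noncarrier_incidence_age70_pct",
        100 * rec["km_noncarrier_incidence70_mean"],
        rec["n_replicates"] * n_per_cohort,
    )

    # ---- family-history detection rates
    det = reporting.fh_detection_rates(seed, n_probands=n_fh_probands)
    put("fh_detection_base_pct", 100 * det["base"]["rate"], det["base"]["total"])
    put("fh_detection_adjusted_pct", 100 * det["adjusted"]["rate"], det["adjusted"]["total"])

    return out
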