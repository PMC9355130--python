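"""Table-level study summaries and the acceptance computation.

Pure functions over the packaged fixture tables (participant flow, variant
shares, cancer cross-tabs, surgery uptake) plus the simulation-based
quantities (hazard-ratio recovery, cumulative incidence, family-history
detection rates).  Re-runs are byte-identical for a fixed seed.

Rounding follows the published printing conventions: half-up to integers
for flow percentages, half-up to one decimal for table shares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import eligibility, fixtures, hazard, simulate
from .config import CohortConfig
from .domain import ConvergenceError, PersonalHistory
from .survival import CoxPH, KaplanMeierEstimator


def round_half_up(x: float, decimals: int = 0) -> float:
    scale = 10**decimals
    return math.floor(x * scale + 0.5) / scale


@dataclass
class FlowCounts:
    invited: int = 180
    scheduled: int = 111
    consented: int = 109
    second_visit: int = 101
    oncologist: int = 100

    def __post_init__(self) -> None:
        funnel = [self.invited, self.scheduled, self.consented, self.second_visit,
                  self.oncologist]
        if any(a < b for a, b in zip(funnel, funnel[1:])):
            raise ValueError("participation funnel must be non-increasing")


def flow_percentages(flow: FlowCounts | None = None) -> dict[str, int]:
    """Funnel percentages with the published denominators.

    Scheduled and consented are fractions of invited; later stages are
    fractions of consented (consented is also given relative to responders).
    """
    f = flow or FlowCounts()
    return {
        "scheduled_pct": int(round_half_up(100 * f.scheduled / f.invited)),
        "consented_pct": int(round_half_up(100 * f.consented / f.invited)),
        "consented_of_responders_pct": int(round_half_up(100 * f.consented / f.scheduled)),
        "second_visit_pct": int(round_half_up(100 * f.second_visit / f.consented)),
        "oncologist_pct": int(round_half_up(100 * f.oncologist / f.consented)),
    }


def onset_crosstab(table2: pd.DataFrame | None = None) -> dict:
    """Row, column and grand totals of the cancer-type x onset-band table."""
    t2 = fixtures.load_table2() if table2 is None else table2
    bands = ["lt40", "age40_49", "age50_59", "gt59"]
    if t2.empty:
        return {"by_type": {}, "by_band": {b: 0 for b in bands}, "total": 0}
    by_type = {
        row.cancer_location: int(sum(getattr(row, b) for b in bands))
        for row in t2.itertuples()
    }
    by_band = {b: int(t2[b].sum()) for b in bands}
    return {"by_type": by_type, "by_band": by_band, "total": int(sum(by_type.values()))}


def bc_case_summary(table4: pd.DataFrame | None = None) -> dict:
    """Incident/prevalent counts, under-50 fraction and per-gene counts."""
    t4 = fixtures.load_table4() if table4 is None else table4
    status = t4.status.str.strip()
    bad = set(status) - {"I", "P"}
    if bad:
        raise ValueError(f"malformed status token(s): {sorted(bad)}")
    n = len(t4)
    under50 = int((t4.age_at_dx < 50).sum())
    return {
        "n_cases": n,
        "incident": int((status == "I").sum()),
        "prevalent": int((status == "P").sum()),
        "under50": under50,
        "under50_pct": round_half_up(100 * under50 / n) if n else 0.0,
        "per_gene": t4.gene.value_counts().to_dict(),
    }


def _count_surgeries(frames: list[pd.DataFrame], token: str) -> int:
    import logging

    n = 0
    for df in frames:
        for s in df.surgery:
            text = str(s).upper()
            known = {"BSO", "MT", "NO", "YES"}
            tokens = set(
                t for t in text.replace("(", " ").replace(")", " ")
                .replace("+", " ").replace(",", " ").split()
                if t.isalpha()
            )
            unknown = tokens - known
            if unknown:
                logging.getLogger(__name__).warning(
                    "unknown surgery token(s) %s in %r", sorted(unknown), s
                )
            if token in tokens:
                n += 1
    return n


def surgery_uptake(
    table4: pd.DataFrame | None = None,
    table5: pd.DataFrame | None = None,
    bso_total: int = 16,
    mt_total: int = 5,
) -> dict:
    """Risk-reducing surgeries among tabled (cancer-history) participants.

    ``bso_total`` / ``mt_total`` are the study-wide counts (some surgeries
    were in carriers without cancer history, who are not tabled), so the
    fractions are tabled-count / study total.
    """
    t4 = fixtures.load_table4() if table4 is None else table4
    t5 = fixtures.load_table5() if table5 is None else table5
    bso = _count_surgeries([t4, t5], "BSO")
    mt = _count_surgeries([t4], "MT")
    return {
        "bso_cancer_history": bso,
        "bso_total": bso_total,
        "bso_cancer_history_pct": round_half_up(100 * bso / bso_total, 1),
        "mt_contralateral": mt,
        "mt_total": mt_total,
        "mt_contralateral_pct": round_half_up(100 * mt / mt_total, 1),
    }


def cascade_load(invitations: int = 453, participants: int = 106) -> float:
    """Mean cascade-screening invitations per participant, one decimal."""
    if participants <= 0:
        raise ValueError("participants must be positive")
    return round_half_up(invitations / participants, 1)


def counseled_shares(table1: pd.DataFrame | None = None) -> dict[str, float]:
    """Per-gene carrier shares of the counseled cohort (denominator 109)."""
    t1 = fixtures.load_table1() if table1 is None else table1
    sums = t1.groupby("gene")["cases"].sum()
    return {
        g: round_half_up(100 * c / fixtures.N_COUNSELED, 1) for g, c in sums.items()
    }


def pathogenic_share_pct(table1: pd.DataFrame | None = None) -> float:
    """Percent of tabled carrier cases whose variant is pathogenic (vs LP)."""
    t1 = fixtures.load_table1() if table1 is None else table1
    total = t1.cases.sum()
    kp = t1.loc[t1.clinvar_class == "KP", "cases"].sum()
    return round_half_up(100 * kp / total)


# ----------------------------------------------------- simulation summaries


def hr_recovery_experiment(
    seed: int,
    n_replicates: int = 200,
    n_per_cohort: int = 20_000,
    config: CohortConfig | None = None,
) -> dict:
    """Parameter-recovery check for the Cox estimator on simulated cohorts.

    For each replicate, participants are assigned to the BRCA1/2, CHEK2 or
    non-carrier group at the configured frequencies, onset ages are drawn
    from the piecewise-exponential model, and a two-covariate Cox model is
    fit.  Reports mean estimated hazard ratios, 95%-CI coverage of the
    generator truth, and the mean Kaplan-Meier non-carrier incidence at 70.
    """
    config = config or CohortConfig()
    bands = config.baseline_hazard
    hr_true = {
        "BRCA1/2": config.group_hr["BRCA1/2"],
        "CHEK2": config.group_hr["CHEK2"],
    }
    f_brca = sum(
        f for v, f in config.variant_freqs.items() if _gene_of(v) in ("BRCA1", "BRCA2")
    )
    f_chek2 = sum(f for v, f in config.variant_freqs.items() if _gene_of(v) == "CHEK2")
    root = np.random.SeedSequence(seed)
    hrs = {k: [] for k in hr_true}
    cover = {k: 0 for k in hr_true}
    km70 = []
    n_fit = 0
    lo, hi = config.censor_age_range
    for child in root.spawn(n_replicates):
        rng = np.random.default_rng(child)
        group = rng.choice(
            3, size=n_per_cohort, p=[f_brca, f_chek2, 1 - f_brca - f_chek2]
        )
        hr_vec = np.where(group == 0, hr_true["BRCA1/2"],
                          np.where(group == 1, hr_true["CHEK2"], 1.0))
        u = rng.uniform(size=n_per_cohort)
        onset = hazard.inverse_cumulative_hazard(bands, -np.log(u) / hr_vec)
        censor = rng.uniform(lo, hi, size=n_per_cohort)
        event = onset <= censor
        exit_age = np.where(event, onset, censor)
        X = np.stack([group == 0, group == 1], axis=1).astype(float)
        try:
            fit = CoxPH().fit(exit_age, event, X)
        except ConvergenceError:
            continue
        n_fit += 1
        for j, k in enumerate(hr_true):
            hrs[k].append(fit.hr_[j])
            lo_j, hi_j = fit.ci95_[j]
            if lo_j <= hr_true[k] <= hi_j:
                cover[k] += 1
        nc = group == 2
        km = KaplanMeierEstimator().fit(exit_age[nc], event[nc])
        km70.append(km.cumulative_incidence_at(70.0)[0])

    km70 = np.asarray(km70)
    return {
        "n_replicates": n_fit,
        "hr_true": hr_true,
        "hr_mean": {k: float(np.mean(v)) for k, v in hrs.items()},
        "ci_coverage": {k: cover[k] / n_fit for k in hr_true},
        "km_noncarrier_incidence70_mean": float(km70.mean()),
        "km_noncarrier_incidence70_se": float(km70.std(ddof=1) / np.sqrt(len(km70))),
        "closed_form_noncarrier_incidence70": hazard.closed_form_incidence(
            bands, 1.0, 70.0
        ),
    }


_GENE_CACHE: dict[str, str] | None = None


def _gene_of(rsid: str) -> str:
    global _GENE_CACHE
    if _GENE_CACHE is None:
        t1 = fixtures.load_table1()
        _GENE_CACHE = dict(zip(t1.rsid, t1.gene))
    return _GENE_CACHE.get(rsid, "-")


def fh_detection_rates(
    seed: int, n_probands: int = 1000, config: CohortConfig | None = None
) -> dict:
    """Base- and adjusted-criteria detection rates on synthetic carrier FHs.

    Family history only (no personal-history rules), matching the published
    evaluation of whether carriers' FHs alone met the testing criteria.
    """
    config = config or CohortConfig()
    peds = simulate.simulate_carrier_pedigrees(config, n_probands, seed)
    empty_personal = PersonalHistory()
    results = {"base": [], "adjusted": []}
    for _, members in peds:
        fam = simulate.family_events(members)
        for version in results:
            results[version].append(
                eligibility.evaluate_eligibility(
                    empty_personal, fam, version=version, include_personal=False
                )
            )
    out = {}
    for version, res in results.items():
        frac, n_el, n_tot = eligibility.detection_rate(res)
        out[version] = {"rate": frac, "eligible": n_el, "total": n_tot}
    return out
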