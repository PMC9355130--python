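"""Synthetic biobank cohort generator.

Generates cohorts with the statistical structure the downstream analysis
assumes, so every stage is testable without access to restricted biobank
data: carrier assignment at configured frequencies, piecewise-exponential
breast-cancer onset ages on the age scale, per-source genotype matrices with
injected missingness and imputation discordance, and Mendelian pedigrees
whose relatives experience cancers under the same hazard model.

All randomness flows from one root seed through independent per-stage
streams (`config.rng_for`), so identical (config, seed) pairs give
byte-identical output and stages can be re-run in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fixtures, hazard
from .config import CohortConfig, GENE_GROUP, rng_for
from .domain import (
    CancerType,
    FamilyCancerEvent,
    GenotypeMatrix,
    PedigreeMember,
)

_RELATION_POOL = (
    # relation, sex, degree, side
    ("sister", "female", 1, "unknown"),
    ("brother", "male", 1, "unknown"),
    ("daughter", "female", 1, "unknown"),
    ("son", "male", 1, "unknown"),
    ("grandmother", "female", 2, "maternal"),
    ("grandmother", "female", 2, "paternal"),
    ("grandfather", "male", 2, "maternal"),
    ("grandfather", "male", 2, "paternal"),
    ("aunt", "female", 2, "maternal"),
    ("aunt", "female", 2, "paternal"),
    ("uncle", "male", 2, "maternal"),
    ("uncle", "male", 2, "paternal"),
)

_MENDELIAN_P = {1: 0.5, 2: 0.25}


@dataclass
class SyntheticCohort:
    config: CohortConfig
    participants: pd.DataFrame
    diagnoses: pd.DataFrame
    variant_table: pd.DataFrame
    truth: GenotypeMatrix
    sources: dict[str, GenotypeMatrix]
    reported_sex: dict[str, str]
    pedigrees: dict[str, list[PedigreeMember]] = field(default_factory=dict)


def simulate_event_times(bands, hr: float, n: int, seed: int) -> np.ndarray:
    """Breast-cancer onset ages by inversion of S(t) = exp(-hr * H(t)).

    Bands must cover ages 0-100 contiguously; ages past the coverage come
    back as +inf (no event within the modeled lifespan).
    """
    hazard.validate_bands(bands)
    rng = rng_for(seed, "events")
    return hazard.sample_event_ages(bands, hr, n, rng)


def _variant_table(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    loci = fixtures.load_panel_loci()
    panel = loci[loci.rsid.isin(config.variant_freqs)].copy()
    panel = panel.rename(columns={"rsid": "variant_id"})
    panel["freq"] = panel.variant_id.map(config.variant_freqs)
    rows = [panel]
    if config.n_x_variants > 0:
        lo, hi = config.x_maf_range
        xrows = pd.DataFrame(
            {
                "variant_id": [f"xqc_{i:03d}" for i in range(config.n_x_variants)],
                "gene": "X_QC",
                "chrom": "X",
                "pos": np.arange(config.n_x_variants) * 100_000 + 3_000_000,
                "ref": "A",
                "alt": "G",
                "freq": rng.uniform(lo, hi, size=config.n_x_variants),
            }
        )
        rows.append(xrows)
    return pd.concat(rows, ignore_index=True)


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort (participants, genotypes, pedigrees).

    Carriers hold exactly one panel variant each (the study reported a
    single gene per participant); pedigrees are generated for carriers,
    which is the population the family-history analyses evaluate.
    """
    config.validate()
    seed = config.seed
    rng = rng_for(seed, "cohort")
    n = config.n_participants
    ids = [f"P{i:06d}" for i in range(n)]

    # --- carrier assignment: at most one panel variant per participant
    vids = sorted(config.variant_freqs)
    freqs = np.array([config.variant_freqs[v] for v in vids])
    p = np.concatenate([freqs, [1.0 - freqs.sum()]])
    draw = rng.choice(len(vids) + 1, size=n, p=p)
    carrier = draw < len(vids)
    variant_id = np.where(carrier, np.array(vids + ["-"], dtype=object)[draw], "-")

    var_table = _variant_table(config, rng_for(seed, "x"))
    gene_of = dict(zip(var_table.variant_id, var_table.gene))
    genes = np.array([gene_of.get(v, "-") for v in variant_id], dtype=object)
    groups = np.array(
        [GENE_GROUP[g] if g in GENE_GROUP else "non-carrier" for g in genes], dtype=object
    )

    # --- follow-up window
    lo, hi = config.censor_age_range
    censor_age = rng.uniform(lo, hi, size=n)
    gap = rng.uniform(*config.recruitment_gap_range, size=n)
    recruitment_age = np.maximum(config.recruitment_age_min, censor_age - gap)
    birth_year = (2020 - np.round(censor_age)).astype(int)

    # --- breast-cancer onset under proportional hazards
    hrs = np.ones(n)
    for grp, mult in config.group_hr.items():
        hrs[groups == grp] = mult
    u = rng_for(seed, "events").uniform(size=n)
    with np.errstate(divide="ignore"):
        event_age = hazard.inverse_cumulative_hazard(
            config.baseline_hazard, -np.log(u) / hrs
        )

    has_event = event_age <= censor_age
    status = np.where(event_age < recruitment_age, "prevalent", "incident")

    participants = pd.DataFrame(
        {
            "id": ids,
            "sex": "female",
            "birth_year": birth_year,
            "recruitment_age": recruitment_age,
            "censor_age": censor_age,
            "carrier": carrier,
            "variant_id": variant_id,
            "gene": genes,
            "group": groups,
            "event_age": np.where(has_event, event_age, np.nan),
        }
    )
    diagnoses = pd.DataFrame(
        {
            "participant_id": np.array(ids, dtype=object)[has_event],
            "icd10": "C50",
            "onset_age": event_age[has_event],
            "status": status[has_event],
        }
    )

    # --- genotype truth and degraded per-source copies
    truth = _truth_matrix(var_table, participants, rng_for(seed, "x"))
    sources = degrade_genotypes(truth, config, seed, variant_table=var_table)

    # --- reported sex with rare clerical errors (all participants female)
    err = rng.uniform(size=n) < config.sex_error_rate
    reported_sex = {i: ("male" if e else "female") for i, e in zip(ids, err)}

    # --- pedigrees for carriers
    ped_rng = rng_for(seed, "pedigree")
    pedigrees = {}
    for pid, gene in zip(participants.id[carrier], genes[carrier]):
        pedigrees[pid] = _pedigree(gene, True, config, ped_rng)

    return SyntheticCohort(
        config=config,
        participants=participants,
        diagnoses=diagnoses,
        variant_table=var_table,
        truth=truth,
        sources=sources,
        reported_sex=reported_sex,
        pedigrees=pedigrees,
    )


def _truth_matrix(
    var_table: pd.DataFrame, participants: pd.DataFrame, rng: np.random.Generator
) -> GenotypeMatrix:
    n = len(participants)
    geno = np.zeros((len(var_table), n), dtype=np.int8)
    vid_row = {v: i for i, v in enumerate(var_table.variant_id)}
    for i, v in enumerate(participants.variant_id):
        if v != "-":
            geno[vid_row[v], i] = 1
    # X-chromosome QC variants: Hardy-Weinberg genotypes (female cohort)
    for _, row in var_table[var_table.chrom == "X"].iterrows():
        q = row.freq
        g = rng.choice(3, size=n, p=[(1 - q) ** 2, 2 * q * (1 - q), q**2])
        geno[vid_row[row.variant_id], :] = g
    return GenotypeMatrix(
        source="truth",
        variant_ids=list(var_table.variant_id),
        chroms=list(var_table.chrom.astype(str)),
        sample_ids=list(participants.id),
        genotypes=geno,
    )


def degrade_genotypes(
    truth: GenotypeMatrix,
    config: CohortConfig,
    seed: int,
    variant_table: pd.DataFrame | None = None,
) -> dict[str, GenotypeMatrix]:
    """Derive the three observed-source matrices from the complete truth.

    Sequencing and array copies get configured missingness; the imputed copy
    retains a true carrier call with probability ``imputation_concordance``
    and introduces spurious carrier calls at ``imputed_false_positive_rate``.
    Each source carries only the variants observed through it (by default
    BRCA1/2 through array+imputed+sequencing, other panel genes through
    sequencing only), mirroring how the published carriers were found.
    """
    rng = rng_for(seed, "degrade")
    gene_of = (
        dict(zip(variant_table.variant_id, variant_table.gene))
        if variant_table is not None
        else {}
    )

    def gene_for(vid: str, chrom: str) -> str:
        if vid in gene_of:
            return gene_of[vid]
        return "X_QC" if chrom in ("X", "chrX") else "-"

    out: dict[str, GenotypeMatrix] = {}
    for source in ("sequencing", "array", "imputed"):
        keep = []
        for vid, chrom in zip(truth.variant_ids, truth.chroms):
            gene = gene_for(vid, chrom)
            if gene == "X_QC":
                present = source in ("sequencing", "array")
            else:
                present = source in config.gene_sources(gene)
            if present:
                keep.append(vid)
        sub = truth.subset_variants(keep)
        geno = sub.genotypes.copy()
        if source == "imputed":
            c = config.imputation_concordance
            fp = config.imputed_false_positive_rate
            u = rng.uniform(size=geno.shape)
            is_carrier = geno > 0
            geno[is_carrier & (u >= c)] = 0
            geno[(~is_carrier) & (u < fp)] = 1
        miss = config.missingness.get(source, 0.0)
        if miss > 0:
            geno[rng.uniform(size=geno.shape) < miss] = -1
        out[source] = GenotypeMatrix(
            source=source,
            variant_ids=sub.variant_ids,
            chroms=sub.chroms,
            sample_ids=sub.sample_ids,
            genotypes=geno,
        )
    return out


# ---------------------------------------------------------------- pedigrees


def simulate_pedigree(
    gene: str, proband_carrier: bool, config: CohortConfig, seed: int
) -> list[PedigreeMember]:
    """Relatives of one proband with Mendelian variant transmission.

    First-degree relatives of a carrier proband carry the variant with
    probability 1/2, second-degree with 1/4; relatives of a non-carrier
    carry it at the population frequency.  Each relative's cancer events
    are drawn from the same hazard model given their carrier status.
    """
    return _pedigree(gene, proband_carrier, config, rng_for(seed, "pedigree"))


def _pedigree(
    gene: str, proband_carrier: bool, config: CohortConfig, rng: np.random.Generator
) -> list[PedigreeMember]:
    members: list[tuple[str, str, int, str]] = [
        ("mother", "female", 1, "maternal"),
        ("father", "male", 1, "paternal"),
    ]
    n_extra = rng.poisson(max(0.0, config.n_relatives_mean - 2.0))
    for _ in range(n_extra):
        members.append(_RELATION_POOL[rng.integers(len(_RELATION_POOL))])

    pop_freq = sum(config.variant_freqs.values())
    out = []
    for relation, sex, degree, side in members:
        if proband_carrier:
            p_carry = _MENDELIAN_P[degree]
        else:
            p_carry = pop_freq
        carrier = bool(rng.uniform() < p_carry)
        attained = _attained_age(relation, config, rng)
        events = _relative_events(sex, gene, carrier, attained, degree, side, config, rng)
        out.append(
            PedigreeMember(
                relation=relation,
                degree=degree,
                side=side,
                sex=sex,
                carrier=carrier,
                attained_age=attained,
                events=events,
            )
        )
    return out


def _attained_age(relation: str, config: CohortConfig, rng) -> float:
    if relation in ("mother", "father"):
        lo, hi = config.relative_attained_age_range
    elif relation in ("grandmother", "grandfather"):
        lo, hi = 70.0, 95.0
    elif relation in ("daughter", "son"):
        lo, hi = 20.0, 50.0
    else:
        lo, hi = 45.0, 85.0
    return float(rng.uniform(lo, hi))


def _bounded_onset(mean: float, sd: float, attained: float, rng) -> float | None:
    onset = float(rng.normal(mean, sd))
    if onset < 25.0:
        onset = 25.0 + abs(rng.normal(0, 5))
    return onset if onset <= attained else None


def _relative_events(
    sex: str,
    gene: str,
    carrier: bool,
    attained: float,
    degree: int,
    side: str,
    config: CohortConfig,
    rng,
) -> list[FamilyCancerEvent]:
    events: list[FamilyCancerEvent] = []
    brca = gene in ("BRCA1", "BRCA2")

    def add(ct: CancerType, onset):
        events.append(
            FamilyCancerEvent(degree=degree, side=side, cancer_type=ct, onset_age=onset)
        )

    if sex == "female":
        hr = config.hr_for_gene(gene) if carrier else 1.0
        age = hazard.sample_event_ages(
            config.baseline_hazard, hr * config.fh_breast_scale, 1, rng
        )[0]
        if age <= attained:
            add(CancerType.BREAST, float(age))
        p_oc = config.fh_ovarian_rate * (
            config.fh_ovarian_rr if (carrier and brca) else 1.0
        ) * config.fh_breast_scale
        if rng.uniform() < min(p_oc, 0.9):
            onset = _bounded_onset(58.0, 10.0, attained, rng)
            if onset is not None:
                add(CancerType.OVARIAN, onset)
    else:
        p_pc = config.fh_prostate_rate * (
            config.fh_prostate_rr if (carrier and brca) else 1.0
        ) * config.fh_adjacent_scale
        if rng.uniform() < min(p_pc, 0.9):
            onset = _bounded_onset(70.0, 8.0, attained, rng)
            if onset is not None:
                add(CancerType.PROSTATE, onset)
        p_mbc = config.fh_male_bc_rate * (
            config.fh_male_bc_rr_brca2 if (carrier and gene == "BRCA2") else 1.0
        )
        if rng.uniform() < min(p_mbc, 0.5):
            onset = _bounded_onset(65.0, 10.0, attained, rng)
            if onset is not None:
                add(CancerType.MALE_BREAST, onset)

    p_pac = config.fh_pancreatic_rate * (
        config.fh_pancreatic_rr if (carrier and brca) else 1.0
    ) * config.fh_adjacent_scale
    if rng.uniform() < min(p_pac, 0.9):
        onset = _bounded_onset(68.0, 9.0, attained, rng)
        if onset is not None:
            add(CancerType.PANCREATIC, onset)
    if rng.uniform() < config.fh_gastric_rate:
        onset = _bounded_onset(65.0, 12.0, attained, rng)
        if onset is not None:
            add(CancerType.GASTRIC, onset)
    return events


def simulate_carrier_pedigrees(
    config: CohortConfig, n_probands: int, seed: int
) -> list[tuple[str, list[PedigreeMember]]]:
    """Pedigrees for synthetic carrier probands, genes drawn at panel frequencies.

    Cheaper than a full cohort when only the family-history analyses are
    needed (detection-rate evaluation and its calibration).
    """
    t1 = fixtures.load_table1()
    gene_of = dict(zip(t1.rsid, t1.gene))
    vids = sorted(config.variant_freqs)
    freqs = np.array([config.variant_freqs[v] for v in vids])
    rng = rng_for(seed, "fh")
    draws = rng.choice(len(vids), size=n_probands, p=freqs / freqs.sum())
    ped_rng = rng_for(seed, "fh", extra=1)
    out = []
    for k in draws:
        gene = gene_of[vids[k]]
        out.append((gene, _pedigree(gene, True, config, ped_rng)))
    return out


def family_events(members: list[PedigreeMember]) -> list[FamilyCancerEvent]:
    """Flatten a pedigree into the event list the eligibility engine consumes."""
    ev: list[FamilyCancerEvent] = []
    for m in members:
        ev.extend(m.events)
    return ev


# ------------------------------------------------------------------ output


def survival_records(cohort: SyntheticCohort, include_prevalent: bool | None = None) -> pd.DataFrame:
    """Age-scale time-to-first-breast-cancer records for the survival module.

    With ``include_prevalent`` (default from config) diagnoses made before
    recruitment contribute as events at their onset age; otherwise prevalent
    cases are dropped from the risk set entirely.
    """
    if include_prevalent is None:
        include_prevalent = cohort.config.include_prevalent
    p = cohort.participants
    event = ~p.event_age.isna()
    exit_age = np.where(event, p.event_age, p.censor_age)
    rec = pd.DataFrame(
        {
            "id": p.id,
            "entry_age": 0.0,
            "exit_age": exit_age,
            "event": event,
            "group": p.group,
        }
    )
    if not include_prevalent:
        prevalent = event & (p.event_age < p.recruitment_age)
        rec = rec[~prevalent.to_numpy()]
    return rec.reset_index(drop=True)


def write_participants_tsv(cohort: SyntheticCohort, path) -> None:
    cohort.participants.to_csv(path, sep="\t", index=False)


def write_diagnoses_tsv(cohort: SyntheticCohort, path) -> None:
    cohort.diagnoses.to_csv(path, sep="\t", index=False)


def write_pedigrees_tsv(cohort: SyntheticCohort, path) -> None:
    rows = []
    for pid, members in cohort.pedigrees.items():
        for j, m in enumerate(members):
            if not m.events:
                rows.append((pid, f"{pid}_R{j}", m.relation, m.degree, m.side,
                             m.carrier, "", ""))
            for e in m.events:
                rows.append(
                    (pid, f"{pid}_R{j}", m.relation, m.degree, m.side, m.carrier,
                     e.cancer_type.value, "" if e.onset_age is None else e.onset_age)
                )
    pd.DataFrame(
        rows,
        columns=["proband_id", "member_id", "relation", "degree", "side",
                 "carrier", "cancer_type", "onset_age"],
    ).to_csv(path, sep="\t", index=False)
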