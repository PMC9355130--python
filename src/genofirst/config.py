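"""Cohort-generator configuration.

Every calibration constant of the synthetic biobank lives here rather than
in code: carrier frequencies, the baseline hazard anchor, group hazard
ratios, genotype-degradation rates, pedigree structure and the
family-history severity scales.  Defaults emulate the Estonian Biobank
structure the analysis assumes: ~0.8% combined BRCA1/2 carrier frequency,
group hazard ratios of 12.1 (BRCA1/2) and 4.4 (CHEK2) on a baseline
calibrated to 4.3% cumulative breast-cancer incidence by age 70.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import fixtures, hazard
from .domain import ConfigError, SOURCES

#: Default per-gene-group carrier frequencies (probability a woman carries a
#: P/LP variant in the group).  BRCA1/2 combined 0.8% is the published
#: Estonian sequencing-based prevalence (1/124); CHEK2 0.5% reflects the
#: Northern/Eastern European range for c.1100delC plus the two splice
#: variants; the remaining moderate genes use literature-scale values.
DEFAULT_GROUP_FREQS = {
    "BRCA1": None,  # split from the 0.008 BRCA1/2 mass by panel-table proportions
    "BRCA2": None,
    "CHEK2": 0.005,
    "ATM": 0.003,
    "NBN": 0.001,
    "NF1": 0.0002,
}
BRCA_COMBINED_FREQ = 0.008

DEFAULT_GROUP_HR = {"BRCA1/2": 12.1, "CHEK2": 4.4, "moderate_other": 3.0}

#: Hazard-ratio group of each panel gene (proportional-hazards multiplier
#: applied to the baseline).
GENE_GROUP = {
    "BRCA1": "BRCA1/2",
    "BRCA2": "BRCA1/2",
    "CHEK2": "CHEK2",
    "ATM": "moderate_other",
    "NBN": "moderate_other",
    "NF1": "moderate_other",
    "TP53": "moderate_other",
    "STK11": "moderate_other",
    "PTEN": "moderate_other",
    "CDH1": "moderate_other",
    "PALB2": "moderate_other",
}

#: Which observation sources carry each gene's variants by default: BRCA1/2
#: variants surface in genotyping-array + imputed data (and sequencing),
#: the non-BRCA panel variants only in sequencing data - mirroring how the
#: carriers were actually found.
DEFAULT_VARIANT_SOURCES = {
    "BRCA1": ("sequencing", "array", "imputed"),
    "BRCA2": ("sequencing", "array", "imputed"),
}
DEFAULT_OTHER_SOURCES = ("sequencing",)


def default_variant_freqs() -> dict[str, float]:
    """Per-variant carrier probabilities.

    Group-level frequencies are split across the group's panel variants in
    proportion to the published per-variant case counts.
    """
    t1 = fixtures.load_table1()
    brca = t1[t1.gene.isin(["BRCA1", "BRCA2"])]
    freqs: dict[str, float] = {}
    brca_total = brca.cases.sum()
    for _, row in brca.iterrows():
        freqs[row.rsid] = float(BRCA_COMBINED_FREQ * row.cases / brca_total)
    for gene, gfreq in DEFAULT_GROUP_FREQS.items():
        if gfreq is None:
            continue
        sub = t1[t1.gene == gene]
        for _, row in sub.iterrows():
            freqs[row.rsid] = float(gfreq * row.cases / sub.cases.sum())
    return freqs


@dataclass
class CohortConfig:
    n_participants: int = 20_000
    seed: int = 0

    # genetics
    variant_freqs: dict[str, float] = field(default_factory=default_variant_freqs)
    variant_sources: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_VARIANT_SOURCES)
    )
    n_x_variants: int = 20
    x_maf_range: tuple[float, float] = (0.1, 0.4)

    # breast-cancer onset model
    baseline_hazard: tuple = field(
        default_factory=lambda: hazard.calibrate_baseline(0.043, 70.0)
    )
    group_hr: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GROUP_HR))

    # follow-up
    censor_age_range: tuple[float, float] = (40.0, 90.0)
    recruitment_gap_range: tuple[float, float] = (1.0, 20.0)
    recruitment_age_min: float = 22.0
    include_prevalent: bool = True

    # genotype degradation
    missingness: dict[str, float] = field(
        default_factory=lambda: {"sequencing": 0.02, "array": 0.01, "imputed": 0.0}
    )
    imputation_concordance: float = 0.95
    imputed_false_positive_rate: float = 0.0005
    sex_error_rate: float = 0.002

    # pedigree / family-history model
    n_relatives_mean: float = 4.3
    relative_attained_age_range: tuple[float, float] = (55.0, 90.0)
    # severity scales set once by scripts/calibrate_fh.py so that base-criteria
    # detection among carriers is ~1/3 and adjusted ~1/2 (see docs/methods.md)
    fh_breast_scale: float = 2.874
    fh_adjacent_scale: float = 1.09
    fh_ovarian_rate: float = 0.012
    fh_ovarian_rr: float = 12.0
    fh_prostate_rate: float = 0.10
    fh_prostate_rr: float = 2.0
    fh_pancreatic_rate: float = 0.015
    fh_pancreatic_rr: float = 2.5
    fh_gastric_rate: float = 0.03
    fh_male_bc_rate: float = 0.001
    fh_male_bc_rr_brca2: float = 30.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_participants <= 0:
            raise ConfigError("n_participants must be positive")
        for vid, f in self.variant_freqs.items():
            if not (0.0 <= f < 0.5):
                raise ConfigError(f"variant_freqs[{vid}] must be in [0, 0.5)")
        hazard.validate_bands(self.baseline_hazard)
        for grp, hr in self.group_hr.items():
            if hr <= 0:
                raise ConfigError(f"group_hr[{grp}] must be positive")
        for src, m in self.missingness.items():
            if src not in SOURCES:
                raise ConfigError(f"missingness has unknown source {src!r}")
            if not (0.0 <= m <= 1.0):
                raise ConfigError(f"missingness[{src}] must be in [0, 1]")
        if not (0.0 <= self.imputation_concordance <= 1.0):
            raise ConfigError("imputation_concordance must be in [0, 1]")
        if not (0.0 <= self.imputed_false_positive_rate <= 1.0):
            raise ConfigError("imputed_false_positive_rate must be in [0, 1]")
        if self.n_relatives_mean < 2.0:
            raise ConfigError("n_relatives_mean must be at least 2 (both parents)")
        lo, hi = self.censor_age_range
        if not (0 < lo < hi <= 100):
            raise ConfigError("censor_age_range must be an increasing pair in (0, 100]")

    # ------------------------------------------------------------------ io
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["baseline_hazard"] = [list(b) for b in self.baseline_hazard]
        d["variant_sources"] = {g: list(s) for g, s in self.variant_sources.items()}
        for key in ("censor_age_range", "recruitment_gap_range", "x_maf_range",
                    "relative_attained_age_range"):
            d[key] = list(d[key])
        return d

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        if "baseline_hazard" in d:
            d["baseline_hazard"] = tuple(tuple(b) for b in d["baseline_hazard"])
        if "variant_sources" in d:
            d["variant_sources"] = {g: tuple(s) for g, s in d["variant_sources"].items()}
        for key in ("censor_age_range", "recruitment_gap_range", "x_maf_range",
                    "relative_attained_age_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    # ------------------------------------------------------------- helpers
    def gene_sources(self, gene: str) -> tuple[str, ...]:
        return self.variant_sources.get(gene, DEFAULT_OTHER_SOURCES)

    def hr_for_gene(self, gene: str) -> float:
        return self.group_hr[GENE_GROUP[gene]]


_STAGE_IDS = {
    "cohort": 1,
    "events": 2,
    "pedigree": 3,
    "degrade": 4,
    "fh": 5,
    "x": 6,
}


def rng_for(seed: int, stage: str, extra: int = 0) -> np.random.Generator:
    """Independent, reproducible stream per pipeline stage.

    One root seed; each stage draws from its own child SeedSequence so a
    stage can be re-run in isolation without perturbing the others.
    """
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(_STAGE_IDS[stage], extra))
    return np.random.default_rng(ss)
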