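"""Shared domain types for the genotype-first screening pipeline.

The vocabulary follows clinical cancer-genetics usage: *carriers* hold a
heterozygous pathogenic/likely-pathogenic (P/LP) variant in one of the 11
breast-cancer panel genes; *prevalent* diagnoses precede biobank recruitment,
*incident* ones occur during follow-up; genotype *sources* are the three ways
a biobank observes a genotype (direct sequencing, genotyping array, or
imputation from an array scaffold).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

GENOTYPE_CODES = {"hom_ref": 0, "het": 1, "hom_alt": 2, "missing": -1}

SOURCES = ("sequencing", "array", "imputed")

HIGH_RISK_GENES = frozenset({"BRCA1", "BRCA2", "TP53", "STK11", "PTEN", "CDH1"})
MODERATE_RISK_GENES = frozenset({"ATM", "PALB2", "CHEK2", "NBN", "NF1"})
PANEL_GENES = HIGH_RISK_GENES | MODERATE_RISK_GENES

#: Genes whose sequencing-detected P/LP carriers were eligible for
#: confirmation directly from sequencing data (prioritization rule 2).
SEQUENCING_SUBSET_GENES = frozenset({"BRCA1", "BRCA2", "CHEK2", "ATM", "NBN", "NF1"})


class CancerType(str, enum.Enum):
    BREAST = "breast"
    OVARIAN = "ovarian"
    PROSTATE = "prostate"
    PANCREATIC = "pancreatic"
    GASTRIC = "gastric"
    MALE_BREAST = "male_breast"
    OTHER = "other"


class ClinVarAssertion(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    UNCERTAIN = "uncertain_significance"
    BENIGN = "benign"
    LIKELY_BENIGN = "likely_benign"
    CONFLICTING = "conflicting"


RETURNABLE_ASSERTIONS = frozenset(
    {ClinVarAssertion.PATHOGENIC, ClinVarAssertion.LIKELY_PATHOGENIC}
)


class GenofirstError(Exception):
    """Base class for package errors."""


class ConfigError(GenofirstError):
    """Invalid configuration; the message names the offending field."""


class ConvergenceError(GenofirstError):
    """An iterative fit diverged or hit a monotone-likelihood boundary."""


@dataclass
class GenotypeMatrix:
    """Genotype calls for one source, coded 0/1/2 with -1 for missing.

    ``genotypes`` has shape (n_variants, n_samples).  Chromosome labels are
    kept per variant because the array-data HWE filter applies to autosomes
    only.
    """

    source: str
    variant_ids: list[str]
    chroms: list[str]
    sample_ids: list[str]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        nv, ns = self.genotypes.shape
        if nv != len(self.variant_ids) or nv != len(self.chroms):
            raise ValueError("variant dimension mismatch")
        if ns != len(self.sample_ids):
            raise ValueError("sample dimension mismatch")

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def variant_index(self, variant_id: str) -> int:
        try:
            return self.variant_ids.index(variant_id)
        except ValueError:
            raise KeyError(f"unknown variant id: {variant_id}") from None

    def subset_variants(self, keep: list[str]) -> "GenotypeMatrix":
        idx = [self.variant_index(v) for v in keep]
        return GenotypeMatrix(
            source=self.source,
            variant_ids=[self.variant_ids[i] for i in idx],
            chroms=[self.chroms[i] for i in idx],
            sample_ids=list(self.sample_ids),
            genotypes=self.genotypes[idx, :].copy(),
        )


@dataclass
class Diagnosis:
    icd10: str
    onset_age: float
    status: str  # "prevalent" | "incident"


@dataclass
class Participant:
    id: str
    sex: str
    birth_year: int
    recruitment_age: float
    censor_age: float
    diagnoses: list[Diagnosis] = field(default_factory=list)


@dataclass
class FamilyCancerEvent:
    """One cancer in a close (first- or second-degree) blood relative."""

    degree: int
    side: str  # "maternal" | "paternal" | "unknown"
    cancer_type: CancerType
    onset_age: float | None  # None when the age of onset is not known


@dataclass
class PersonalCancer:
    cancer_type: CancerType
    onset_age: float
    triple_negative: bool = False


@dataclass
class PersonalHistory:
    cancers: list[PersonalCancer] = field(default_factory=list)


@dataclass
class PedigreeMember:
    relation: str
    degree: int
    side: str
    sex: str
    carrier: bool
    attained_age: float
    events: list[FamilyCancerEvent] = field(default_factory=list)
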