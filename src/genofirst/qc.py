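"""Per-source variant and sample quality control.

Implements the filters applied to each genotype source before carrier
identification: per-variant call rate, an exact Hardy-Weinberg equilibrium
test (conditional on allele counts, as is standard for rare variants where
the chi-square approximation breaks down), per-sample call rate, and an
X-heterozygosity sex check against the reported phenotype sex.

Default thresholds per source:
  sequencing  call rate >= 0.90, HWE p >= 1e-9 (all variants)
  array       call rate >= 0.95, HWE p >= 1e-4 (autosomal variants only)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import gammaln, logsumexp

from .domain import GenotypeMatrix

_LN2 = math.log(2.0)

X_CHROMS = frozenset({"X", "chrX", "23"})
Y_CHROMS = frozenset({"Y", "chrY", "24"})


@dataclass
class QcThresholds:
    call_rate_min: float = 0.90
    hwe_p_min: float = 1e-9
    autosomes_only_hwe: bool = False
    sample_call_rate_min: float = 0.95

    def __post_init__(self) -> None:
        for name in ("call_rate_min", "hwe_p_min", "sample_call_rate_min"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")

    @classmethod
    def for_source(cls, source: str) -> "QcThresholds":
        if source == "sequencing":
            return cls(call_rate_min=0.90, hwe_p_min=1e-9, autosomes_only_hwe=False)
        if source in ("array", "imputed"):
            return cls(call_rate_min=0.95, hwe_p_min=1e-4, autosomes_only_hwe=True)
        raise ValueError(f"unknown source: {source!r}")


@dataclass
class HweResult:
    n_hom_ref: int
    n_het: int
    n_hom_alt: int
    p_value: float


@dataclass
class QcReport:
    source: str = ""
    variants_tested: int = 0
    variants_failed_call_rate: int = 0
    variants_failed_hwe: int = 0
    samples_excluded: list[tuple[str, str]] = field(default_factory=list)

    @property
    def variants_passed(self) -> int:
        return (
            self.variants_tested
            - self.variants_failed_call_rate
            - self.variants_failed_hwe
        )


# ------------------------------------------------------------------- HWE


@lru_cache(maxsize=200_000)
def _het_log_probs(n: int, n_minor: int) -> tuple[np.ndarray, np.ndarray]:
    """Log conditional probabilities of every feasible heterozygote count.

    Conditional distribution of the het count given n diploid individuals
    and n_minor copies of the minor allele; feasible counts share the
    parity of n_minor.  Returned normalized.
    """
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    n_rare_hom = (n_minor - hets) // 2
    n_common_hom = n - hets - n_rare_hom
    lg = math.lgamma
    base = lg(n + 1) + lg(n_minor + 1) + lg(2 * n - n_minor + 1) - lg(2 * n + 1)
    lp = (
        base
        - gammaln(n_rare_hom + 1)
        - gammaln(hets + 1)
        - gammaln(n_common_hom + 1)
        + hets * _LN2
    )
    lp -= logsumexp(lp)
    return hets, lp


@lru_cache(maxsize=200_000)
def hwe_pvalue_table(n: int, n_minor: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact two-sided p-value for every feasible heterozygote count.

    p(h) is the total conditional probability of heterozygote counts whose
    probability does not exceed that of h (a small log-space tolerance
    absorbs round-off in tied probabilities).
    """
    hets, lp = _het_log_probs(n, n_minor)
    order = np.argsort(lp, kind="stable")
    cum = np.cumsum(np.exp(lp[order]))
    idx = np.searchsorted(lp[order], lp + 1e-10, side="right")
    return hets, np.minimum(cum[idx - 1], 1.0)


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> HweResult:
    """Two-sided exact Hardy-Weinberg test.

    The p-value is the total conditional probability of heterozygote counts
    whose probability does not exceed that of the observed count, given the
    allele counts.  Monomorphic input gives p = 1 by convention.  Invariant
    under swapping the two homozygote counts.
    """
    for name, v in (("n_hom_ref", n_hom_ref), ("n_het", n_het), ("n_hom_alt", n_hom_alt)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("total genotype count must be positive")
    n_minor = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if n_minor == 0:
        return HweResult(n_hom_ref, n_het, n_hom_alt, 1.0)
    hets, pvals = hwe_pvalue_table(n, n_minor)
    p = float(pvals[np.searchsorted(hets, n_het)])
    return HweResult(n_hom_ref, n_het, n_hom_alt, p)


# --------------------------------------------------------------- variants


def genotype_counts(matrix: GenotypeMatrix, variant_id: str) -> tuple[int, int, int]:
    g = matrix.genotypes[matrix.variant_index(variant_id)]
    return int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())


def variant_call_rate(matrix: GenotypeMatrix, variant_id: str) -> float:
    """Fraction of non-missing calls for one variant."""
    g = matrix.genotypes[matrix.variant_index(variant_id)]
    if g.size == 0:
        return 0.0
    return float((g >= 0).sum() / g.size)


def filter_variants(
    matrix: GenotypeMatrix, thresholds: QcThresholds | None = None
) -> tuple[list[str], QcReport]:
    """Apply call-rate then HWE filters; first-failure attribution.

    A variant passes iff call rate >= call_rate_min and (exempt from HWE or
    HWE p >= hwe_p_min).  Sex-chromosome variants are HWE-exempt when
    ``autosomes_only_hwe`` is set.  A variant failing both filters is
    counted once, under call rate.
    """
    if thresholds is None:
        thresholds = QcThresholds.for_source(matrix.source)
    report = QcReport(source=matrix.source, variants_tested=matrix.n_variants)
    passing: list[str] = []
    for vid, chrom in zip(matrix.variant_ids, matrix.chroms):
        if variant_call_rate(matrix, vid) < thresholds.call_rate_min:
            report.variants_failed_call_rate += 1
            continue
        exempt = thresholds.autosomes_only_hwe and chrom in (X_CHROMS | Y_CHROMS)
        if not exempt:
            aa, ab, bb = genotype_counts(matrix, vid)
            if aa + ab + bb > 0 and hwe_exact_test(aa, ab, bb).p_value < thresholds.hwe_p_min:
                report.variants_failed_hwe += 1
                continue
        passing.append(vid)
    return passing, report


# ---------------------------------------------------------------- samples


def infer_sex_from_x_het(
    matrix: GenotypeMatrix,
    sample_id: str,
    male_max: float = 0.05,
    female_min: float = 0.20,
    min_calls: int = 10,
) -> str:
    """Sex from the X-chromosome heterozygosity rate.

    Males are hemizygous on X, so their called X genotypes are (nearly)
    never heterozygous; rates between the two thresholds, or too few
    non-missing X calls, give ``undetermined``.
    """
    j = matrix.sample_ids.index(sample_id)
    on_x = np.array([c in X_CHROMS for c in matrix.chroms])
    g = matrix.genotypes[on_x, j]
    called = g >= 0
    if called.sum() < min_calls:
        return "undetermined"
    het_rate = (g[called] == 1).mean()
    if het_rate >= female_min:
        return "female"
    if het_rate <= male_max:
        return "male"
    return "undetermined"


def sample_call_rate(matrix: GenotypeMatrix, sample_id: str) -> float:
    j = matrix.sample_ids.index(sample_id)
    g = matrix.genotypes[:, j]
    return float((g >= 0).sum() / g.size) if g.size else 0.0


def sample_qc(
    matrix: GenotypeMatrix,
    reported_sex: dict[str, str],
    thresholds: QcThresholds | None = None,
) -> QcReport:
    """Exclude samples for low call rate or reported-vs-inferred sex mismatch.

    Call rate is checked first and is the primary reason when both fail; an
    undetermined inferred sex never excludes.
    """
    if thresholds is None:
        thresholds = QcThresholds.for_source(matrix.source)
    missing = [s for s in matrix.sample_ids if s not in reported_sex]
    if missing:
        raise KeyError(f"reported_sex missing entries, e.g. {missing[0]!r}")
    report = QcReport(source=matrix.source)
    call_rates = (matrix.genotypes >= 0).mean(axis=0)
    on_x = np.array([c in X_CHROMS for c in matrix.chroms])
    gx = matrix.genotypes[on_x, :]
    n_called = (gx >= 0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        het_rate = np.where(n_called > 0, (gx == 1).sum(axis=0) / n_called, np.nan)
    for j, sid in enumerate(matrix.sample_ids):
        if call_rates[j] < thresholds.sample_call_rate_min:
            report.samples_excluded.append((sid, "call_rate"))
            continue
        if n_called[j] < 10:
            continue  # undetermined never excludes
        if het_rate[j] >= 0.20:
            inferred = "female"
        elif het_rate[j] <= 0.05:
            inferred = "male"
        else:
            continue
        if inferred != reported_sex[sid]:
            report.samples_excluded.append((sid, "sex_mismatch"))
    return report
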