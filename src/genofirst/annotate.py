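"""ClinVar cross-referencing, risk classification and carrier prioritization.

The return-of-results framework: every panel variant is matched against a
ClinVar-style assertion table on its (chrom, pos, ref, alt) key; carriers of
pathogenic / likely pathogenic variants are prioritized for Sanger
confirmation by two rules -

  rule 1  carrier status present in BOTH array and imputed data and the gene
          is in the high-risk list (BRCA1, BRCA2, TP53, STK11, PTEN, CDH1);
  rule 2  carrier status present in sequencing data and the gene is in the
          sequencing-validation subset (BRCA1, BRCA2, CHEK2, ATM, NBN, NF1).

Only Sanger-confirmed candidates are returnable; unconfirmed ones are kept
in an audit list, never silently dropped.

Two tiering schemes coexist: the primary gene-list tier (high vs moderate
gene) drives rule 1; the assertion-based tier (pathogenic -> high, likely
pathogenic -> moderate) is reported alongside for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .domain import (
    ClinVarAssertion,
    GenotypeMatrix,
    HIGH_RISK_GENES,
    MODERATE_RISK_GENES,
    PANEL_GENES,
    RETURNABLE_ASSERTIONS,
    SEQUENCING_SUBSET_GENES,
)

logger = logging.getLogger(__name__)

_SIGNIFICANCE_MAP = {
    "pathogenic": ClinVarAssertion.PATHOGENIC,
    "likely pathogenic": ClinVarAssertion.LIKELY_PATHOGENIC,
    "uncertain significance": ClinVarAssertion.UNCERTAIN,
    "benign": ClinVarAssertion.BENIGN,
    "likely benign": ClinVarAssertion.LIKELY_BENIGN,
    "conflicting interpretations of pathogenicity": ClinVarAssertion.CONFLICTING,
    # study-table shorthand
    "kp": ClinVarAssertion.PATHOGENIC,
    "lp": ClinVarAssertion.LIKELY_PATHOGENIC,
}


def gene_tier(gene: str) -> str:
    """Gene-list tier: high or moderate; total and exclusive over the panel."""
    if gene in HIGH_RISK_GENES:
        return "high"
    if gene in MODERATE_RISK_GENES:
        return "moderate"
    raise ValueError(f"gene {gene!r} is outside the 11-gene panel")


def parse_significance(text: str) -> ClinVarAssertion | None:
    key = str(text).strip().lower()
    if key.startswith("conflicting"):
        return ClinVarAssertion.CONFLICTING
    return _SIGNIFICANCE_MAP.get(key)


def annotate_clinvar(
    variants: pd.DataFrame, clinvar: pd.DataFrame
) -> dict[str, ClinVarAssertion]:
    """Assign one assertion per panel variant by (chrom, pos, ref, alt) join.

    Unmatched variants default to uncertain significance with a warning;
    malformed assertion rows are skipped with a warning, never silently.
    """
    table: dict[tuple, ClinVarAssertion] = {}
    for _, row in clinvar.iterrows():
        assertion = parse_significance(row.get("clinical_significance", ""))
        try:
            key = (str(row["chrom"]), int(row["pos"]), str(row["ref"]), str(row["alt"]))
        except (KeyError, TypeError, ValueError):
            assertion = None
            key = None
        if assertion is None or key is None:
            logger.warning("skipping malformed ClinVar row: %s", dict(row))
            continue
        table[key] = assertion

    out: dict[str, ClinVarAssertion] = {}
    for _, v in variants.iterrows():
        key = (str(v["chrom"]), int(v["pos"]), str(v["ref"]), str(v["alt"]))
        if key in table:
            out[v["variant_id"]] = table[key]
        else:
            logger.warning(
                "variant %s not found in ClinVar table; defaulting to VUS",
                v["variant_id"],
            )
            out[v["variant_id"]] = ClinVarAssertion.UNCERTAIN
    return out


def classify_risk(gene: str, assertion: ClinVarAssertion) -> tuple[bool, str, str | None]:
    """(returnable, gene_tier, assertion_tier).

    Returnable iff the assertion is pathogenic or likely pathogenic.  The
    assertion tier (P -> high, LP -> moderate) is None for non-returnable
    assertions.
    """
    if gene not in PANEL_GENES:
        raise ValueError(f"gene {gene!r} is outside the 11-gene panel")
    returnable = assertion in RETURNABLE_ASSERTIONS
    assertion_tier = None
    if assertion is ClinVarAssertion.PATHOGENIC:
        assertion_tier = "high"
    elif assertion is ClinVarAssertion.LIKELY_PATHOGENIC:
        assertion_tier = "moderate"
    return returnable, gene_tier(gene), assertion_tier


# ------------------------------------------------------------- concordance


@dataclass
class ConcordanceResult:
    variant_id: str
    both_carrier: int
    direct_only: int
    imputed_only: int
    neither: int
    single_source: bool
    summary: float | None
    per_sample: pd.DataFrame


def genotype_concordance(
    direct: GenotypeMatrix, imputed: GenotypeMatrix, variant_id: str
) -> ConcordanceResult:
    """Carrier-status agreement between directly genotyped and imputed data.

    summary = both / (both + direct_only + imputed_only); None when the
    carrier union is empty.  A variant absent from either matrix yields a
    defined result flagged single_source.
    """
    if direct.sample_ids != imputed.sample_ids:
        raise ValueError("matrices must share sample ordering")
    n = len(direct.sample_ids)
    in_direct = variant_id in direct.variant_ids
    in_imputed = variant_id in imputed.variant_ids
    d = (
        direct.genotypes[direct.variant_index(variant_id)] > 0
        if in_direct
        else np.zeros(n, dtype=bool)
    )
    m = (
        imputed.genotypes[imputed.variant_index(variant_id)] > 0
        if in_imputed
        else np.zeros(n, dtype=bool)
    )
    both = int((d & m).sum())
    donly = int((d & ~m).sum())
    ionly = int((~d & m).sum())
    union = both + donly + ionly
    per_sample = pd.DataFrame(
        {
            "sample_id": direct.sample_ids,
            "flag": np.select(
                [d & m, d & ~m, ~d & m],
                ["both_carrier", "direct_only", "imputed_only"],
                default="neither",
            ),
        }
    )
    return ConcordanceResult(
        variant_id=variant_id,
        both_carrier=both,
        direct_only=donly,
        imputed_only=ionly,
        neither=n - union,
        single_source=not (in_direct and in_imputed),
        summary=(both / union) if union else None,
        per_sample=per_sample,
    )


# ----------------------------------------------------------- prioritization


@dataclass
class CarrierCall:
    participant_id: str
    variant_id: str
    gene: str
    cds: str = ""
    in_sequencing: bool = False
    in_array: bool = False
    in_imputed: bool = False
    confirmed: bool | None = None


@dataclass
class ReturnCandidate:
    call: CarrierCall
    assertion: ClinVarAssertion
    tier: str
    selection_reason: str


def carrier_calls_from_sources(
    sources: dict[str, GenotypeMatrix], variant_genes: dict[str, str],
    variant_cds: dict[str, str] | None = None,
) -> list[CarrierCall]:
    """Collect per-participant carrier calls across the three sources."""
    calls: dict[tuple[str, str], CarrierCall] = {}
    for source, matrix in sources.items():
        flag = {"sequencing": "in_sequencing", "array": "in_array", "imputed": "in_imputed"}
        if source not in flag:
            continue
        for i, vid in enumerate(matrix.variant_ids):
            if vid not in variant_genes or variant_genes[vid] not in PANEL_GENES:
                continue
            hits = np.nonzero(matrix.genotypes[i] > 0)[0]
            for j in hits:
                key = (matrix.sample_ids[j], vid)
                if key not in calls:
                    calls[key] = CarrierCall(
                        participant_id=key[0],
                        variant_id=vid,
                        gene=variant_genes[vid],
                        cds=(variant_cds or {}).get(vid, ""),
                    )
                setattr(calls[key], flag[source], True)
    return sorted(calls.values(), key=lambda c: (c.participant_id, c.gene, c.cds, c.variant_id))


def prioritize_candidates(
    calls: list[CarrierCall],
    annotations: dict[str, ClinVarAssertion],
) -> list[ReturnCandidate]:
    """Select confirmation candidates by the two-rule scheme.

    Only P/LP variants can be selected; output is deduplicated per
    (participant, variant), rule 1 winning ties, and deterministically
    ordered by (participant, gene, cds).
    """
    selected: dict[tuple[str, str], ReturnCandidate] = {}
    for call in calls:
        assertion = annotations.get(call.variant_id, ClinVarAssertion.UNCERTAIN)
        returnable, tier, _ = classify_risk(call.gene, assertion)
        if not returnable:
            continue
        reason = None
        if call.in_array and call.in_imputed and tier == "high":
            reason = "both_sources_high_risk_gene"
        elif call.in_sequencing and call.gene in SEQUENCING_SUBSET_GENES:
            reason = "sequencing_subset"
        if reason is None:
            continue
        key = (call.participant_id, call.variant_id)
        if key in selected and selected[key].selection_reason == "both_sources_high_risk_gene":
            continue
        selected[key] = ReturnCandidate(
            call=call, assertion=assertion, tier=tier, selection_reason=reason
        )
    return sorted(
        selected.values(),
        key=lambda c: (c.call.participant_id, c.call.gene, c.call.cds, c.call.variant_id),
    )


def confirmation_gate(
    candidates: list[ReturnCandidate], confirmations: dict[str, bool]
) -> tuple[list[ReturnCandidate], list[ReturnCandidate], list[ReturnCandidate]]:
    """Sanger gate: (returnable, unconfirmed_audit, pending).

    ``confirmations`` maps participant id -> confirmation outcome; a missing
    entry holds the candidate in the pending list.
    """
    returned, audit, pending = [], [], []
    for cand in candidates:
        pid = cand.call.participant_id
        if pid not in confirmations:
            pending.append(cand)
        elif confirmations[pid]:
            cand.call.confirmed = True
            returned.append(cand)
        else:
            cand.call.confirmed = False
            audit.append(cand)
    return returned, audit, pending


# ------------------------------------------------------------- summaries


def variant_table_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-variant case counts with within-gene percentage shares.

    Shares are cases / gene total, rounded half-up to one decimal, matching
    the published table's convention.
    """
    out = table.copy()
    totals = out.groupby("gene")["cases"].transform("sum")
    out["gene_total"] = totals
    share = 100.0 * out.cases / totals
    out["share_pct"] = np.floor(share * 10 + 0.5) / 10
    return out
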