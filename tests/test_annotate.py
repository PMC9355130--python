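import numpy as np
import pandas as pd
import pytest

from genofirst import fixtures
from genofirst.annotate import (
    CarrierCall,
    annotate_clinvar,
    carrier_calls_from_sources,
    classify_risk,
    confirmation_gate,
    gene_tier,
    genotype_concordance,
    prioritize_candidates,
    variant_table_summary,
)
from genofirst.domain import ClinVarAssertion, GenotypeMatrix


@pytest.fixture(scope="module")
def panel_variants():
    loci = fixtures.load_panel_loci()
    return loci.rename(columns={"rsid": "variant_id"})


@pytest.fixture(scope="module")
def annotations(panel_variants):
    return annotate_clinvar(panel_variants, fixtures.load_clinvar())


class TestClinVarAnnotation:
    def test_panel_assertions_from_fixture(self, annotations):
        t1 = fixtures.load_table1()
        top_brca1 = t1[(t1.gene == "BRCA1") & (t1.cds == "c.5329dupC")].rsid.iloc[0]
        assert annotations[top_brca1] is ClinVarAssertion.PATHOGENIC
        chek2_splice = t1[t1.cds == "c.319+2T>A"].rsid.iloc[0]
        assert annotations[chek2_splice] is ClinVarAssertion.LIKELY_PATHOGENIC
        assert len(annotations) == 16

    def test_unmatched_variant_defaults_to_vus(self, panel_variants):
        extra = pd.DataFrame(
            [{"variant_id": "rsX", "gene": "BRCA1", "chrom": "17",
              "pos": 41_200_000, "ref": "A", "alt": "G"}]
        )
        ann = annotate_clinvar(extra, fixtures.load_clinvar())
        assert ann["rsX"] is ClinVarAssertion.UNCERTAIN

    def test_malformed_row_skipped_not_silent(self, panel_variants, caplog):
        bad = fixtures.load_clinvar().copy()
        bad["pos"] = bad["pos"].astype(object)
        bad.loc[0, "pos"] = "not-a-number"
        with caplog.at_level("WARNING"):
            ann = annotate_clinvar(panel_variants, bad)
        assert "malformed" in caplog.text
        # the corrupted row's variant falls back to VUS
        assert ClinVarAssertion.UNCERTAIN in ann.values()


class TestRiskClassification:
    def test_gene_tier_total_and_exclusive(self):
        high = {"BRCA1", "BRCA2", "TP53", "STK11", "PTEN", "CDH1"}
        moderate = {"ATM", "PALB2", "CHEK2", "NBN", "NF1"}
        for g in high:
            assert gene_tier(g) == "high"
        for g in moderate:
            assert gene_tier(g) == "moderate"
        with pytest.raises(ValueError, match="panel"):
            gene_tier("MLH1")

    @pytest.mark.parametrize(
        "gene,assertion,returnable,gtier,atier",
        [
            ("NF1", ClinVarAssertion.PATHOGENIC, True, "moderate", "high"),
            ("ATM", ClinVarAssertion.LIKELY_PATHOGENIC, True, "moderate", "moderate"),
            ("BRCA1", ClinVarAssertion.PATHOGENIC, True, "high", "high"),
            ("BRCA1", ClinVarAssertion.BENIGN, False, "high", None),
            ("CHEK2", ClinVarAssertion.CONFLICTING, False, "moderate", None),
            ("BRCA2", ClinVarAssertion.UNCERTAIN, False, "high", None),
        ],
    )
    def test_returnability_and_tiers(self, gene, assertion, returnable, gtier, atier):
        assert classify_risk(gene, assertion) == (returnable, gtier, atier)


def _matrix(source, carriers, samples, variant="v1", chrom="17"):
    geno = np.zeros((1, len(samples)), dtype=np.int8)
    for s in carriers:
        geno[0, samples.index(s)] = 1
    return GenotypeMatrix(source, [variant], [chrom], list(samples), geno)


class TestConcordance:
    def test_identical_matrices_summary_one(self):
        samples = list("ABCD")
        d = _matrix("array", ["A", "B"], samples)
        m = _matrix("imputed", ["A", "B"], samples)
        assert genotype_concordance(d, m, "v1").summary == 1.0

    def test_set_arithmetic(self):
        samples = list("ABCDE")
        d = _matrix("array", ["A", "B", "C"], samples)
        m = _matrix("imputed", ["B", "C", "D"], samples)
        c = genotype_concordance(d, m, "v1")
        assert (c.both_carrier, c.direct_only, c.imputed_only) == (2, 1, 1)
        assert c.summary == 0.5
        flags = dict(zip(c.per_sample.sample_id, c.per_sample.flag))
        assert flags == {
            "A": "direct_only", "B": "both_carrier", "C": "both_carrier",
            "D": "imputed_only", "E": "neither",
        }

    def test_single_source_flag(self):
        samples = list("AB")
        d = _matrix("array", ["A"], samples)
        m = GenotypeMatrix("imputed", [], [], samples, np.empty((0, 2), dtype=np.int8))
        c = genotype_concordance(d, m, "v1")
        assert c.single_source and c.summary == 0.0


class TestPrioritization:
    def _ann(self, **kw):
        base = {"v_brca1": ClinVarAssertion.PATHOGENIC,
                "v_palb2": ClinVarAssertion.PATHOGENIC,
                "v_chek2": ClinVarAssertion.LIKELY_PATHOGENIC,
                "v_benign": ClinVarAssertion.BENIGN}
        base.update(kw)
        return base

    def test_rule1_array_plus_imputed_high_risk(self):
        calls = [CarrierCall("P1", "v_brca1", "BRCA1", in_array=True, in_imputed=True)]
        out = prioritize_candidates(calls, self._ann())
        assert len(out) == 1
        assert out[0].selection_reason == "both_sources_high_risk_gene"

    def test_rule2_sequencing_subset(self):
        calls = [CarrierCall("P1", "v_chek2", "CHEK2", in_sequencing=True)]
        out = prioritize_candidates(calls, self._ann())
        assert out[0].selection_reason == "sequencing_subset"

    def test_palb2_sequencing_only_not_selected(self):
        calls = [CarrierCall("P1", "v_palb2", "PALB2", in_sequencing=True)]
        assert prioritize_candidates(calls, self._ann()) == []

    def test_benign_never_selected(self):
        calls = [
            CarrierCall("P1", "v_benign", "BRCA1", in_sequencing=True,
                        in_array=True, in_imputed=True)
        ]
        assert prioritize_candidates(calls, self._ann()) == []

    def test_array_only_high_risk_not_selected(self):
        calls = [CarrierCall("P1", "v_brca1", "BRCA1", in_array=True)]
        assert prioritize_candidates(calls, self._ann()) == []

    def test_order_insensitive_and_deduplicated(self):
        calls = [
            CarrierCall("P2", "v_chek2", "CHEK2", in_sequencing=True),
            CarrierCall("P1", "v_brca1", "BRCA1", in_array=True, in_imputed=True,
                        in_sequencing=True),
        ]
        a = prioritize_candidates(calls, self._ann())
        b = prioritize_candidates(list(reversed(calls)), self._ann())
        assert [c.call.participant_id for c in a] == ["P1", "P2"]
        assert a == b
        # rule 1 wins when both rules could apply
        assert a[0].selection_reason == "both_sources_high_risk_gene"

    def test_recall_on_synthetic_truth(self, small_cohort, annotations):
        genes = dict(zip(small_cohort.variant_table.variant_id,
                         small_cohort.variant_table.gene))
        calls = carrier_calls_from_sources(small_cohort.sources, genes)
        out = prioritize_candidates(calls, annotations)
        selected = {c.call.participant_id for c in out}
        p = small_cohort.participants
        # every true BRCA carrier seen in both array and imputed is selected
        arr, imp = small_cohort.sources["array"], small_cohort.sources["imputed"]
        for _, row in p[p.gene.isin(["BRCA1", "BRCA2"])].iterrows():
            j = arr.sample_ids.index(row.id)
            vi_a = arr.variant_index(row.variant_id)
            vi_i = imp.variant_index(row.variant_id)
            if arr.genotypes[vi_a, j] > 0 and imp.genotypes[vi_i, j] > 0:
                assert row.id in selected


class TestConfirmationGate:
    def _cands(self):
        calls = [
            CarrierCall("P1", "v_brca1", "BRCA1", in_array=True, in_imputed=True),
            CarrierCall("P2", "v_brca1", "BRCA1", in_array=True, in_imputed=True),
        ]
        return prioritize_candidates(
            calls, {"v_brca1": ClinVarAssertion.PATHOGENIC}
        )

    def test_all_confirmed_identity(self):
        cands = self._cands()
        ret, audit, pending = confirmation_gate(cands, {"P1": True, "P2": True})
        assert ret == cands and audit == [] and pending == []

    def test_unconfirmed_goes_to_audit(self):
        ret, audit, pending = confirmation_gate(self._cands(), {"P1": True, "P2": False})
        assert [c.call.participant_id for c in ret] == ["P1"]
        assert [c.call.participant_id for c in audit] == ["P2"]

    def test_missing_confirmation_pending(self):
        ret, audit, pending = confirmation_gate(self._cands(), {"P1": True})
        assert [c.call.participant_id for c in pending] == ["P2"]

    def test_empty_input(self):
        assert confirmation_gate([], {}) == ([], [], [])


class TestVariantTableSummary:
    def test_shares_match_published_printing(self):
        t1 = variant_table_summary(fixtures.load_table1())
        by_cds = t1.set_index("cds")
        assert by_cds.loc["c.5329dupC"].share_pct == 52.5
        assert by_cds.loc["c.8572C>T"].share_pct == 88.0
        assert by_cds.loc["c.657_661delACAAA"].share_pct == 100.0
        # every computed share equals the printed column
        assert (t1.share_pct == t1.share_printed.astype(float)).all()

    def test_shares_sum_to_100_within_rounding(self):
        t1 = variant_table_summary(fixtures.load_table1())
        for _, sub in t1.groupby("gene"):
            assert sub.share_pct.sum() == pytest.approx(100.0, abs=0.2)
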