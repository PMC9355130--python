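import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from genofirst import hazard, simulate
from genofirst.config import CohortConfig, rng_for
from genofirst.domain import ConfigError


class TestEventTimes:
    def test_zero_hazard_means_no_events(self):
        bands = ((0.0, 100.0, 0.0),)
        ages = simulate.simulate_event_times(bands, 1.0, 500, seed=1)
        assert np.all(np.isinf(ages))

    def test_constant_hazard_matches_closed_form(self):
        h, n = 0.01, 100_000
        ages = simulate.simulate_event_times(((0.0, 100.0, h),), 1.0, n, seed=2)
        for a in (10, 30, 60):
            expected = 1 - np.exp(-h * a)
            observed = (ages <= a).mean()
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(observed - expected) < 3 * se

    def test_carrier_incidence_matches_piecewise_closed_form(self):
        cfg = CohortConfig()
        hr = cfg.group_hr["BRCA1/2"]
        n = 100_000
        ages = simulate.simulate_event_times(cfg.baseline_hazard, hr, n, seed=3)
        expected = hazard.closed_form_incidence(cfg.baseline_hazard, hr, 70.0)
        observed = (ages <= 70).mean()
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) < 3 * se
        # the exact piecewise value, not the single-band approximation
        assert expected == pytest.approx(1 - (1 - 0.043) ** hr, rel=1e-10)

    def test_non_contiguous_bands_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            simulate.simulate_event_times(
                ((0.0, 40.0, 0.01), (50.0, 100.0, 0.01)), 1.0, 10, seed=0
            )

    def test_baseline_calibration_hits_anchor(self):
        bands = hazard.calibrate_baseline(0.043, 70.0)
        assert hazard.closed_form_incidence(bands, 1.0, 70.0) == pytest.approx(0.043)


class TestCohort:
    def test_deterministic_for_same_seed(self, small_config, small_cohort):
        again = simulate.simulate_cohort(dataclasses.replace(small_config))
        pd.testing.assert_frame_equal(small_cohort.participants, again.participants)
        pd.testing.assert_frame_equal(small_cohort.diagnoses, again.diagnoses)
        for src in small_cohort.sources:
            np.testing.assert_array_equal(
                small_cohort.sources[src].genotypes, again.sources[src].genotypes
            )
        assert small_cohort.pedigrees == again.pedigrees

    def test_zero_frequencies_give_zero_carriers(self):
        cfg = CohortConfig(n_participants=500, seed=9, n_x_variants=0,
                           imputed_false_positive_rate=0.0)
        cfg.variant_freqs = {v: 0.0 for v in cfg.variant_freqs}
        cohort = simulate.simulate_cohort(cfg)
        assert not cohort.participants.carrier.any()
        for m in cohort.sources.values():
            assert not (m.genotypes > 0).any()

    def test_carrier_fraction_within_binomial_envelope(self):
        cfg = CohortConfig(n_participants=50_000, seed=21, n_x_variants=0)
        cohort = simulate.simulate_cohort(cfg)
        brca = cohort.participants.gene.isin(["BRCA1", "BRCA2"]).mean()
        p = 0.008
        se = np.sqrt(p * (1 - p) / cfg.n_participants)
        assert abs(brca - p) < 3 * se

    def test_prevalent_incident_split_by_recruitment_age(self, small_cohort):
        merged = small_cohort.diagnoses.merge(
            small_cohort.participants, left_on="participant_id", right_on="id"
        )
        prev = merged.status == "prevalent"
        assert (merged.onset_age[prev] < merged.recruitment_age[prev]).all()
        assert (merged.onset_age[~prev] >= merged.recruitment_age[~prev]).all()
        assert (merged.onset_age <= merged.censor_age).all()
        assert merged.icd10.eq("C50").all()

    def test_null_hazard_ratio_removes_group_difference(self):
        cfg = CohortConfig(n_participants=30_000, seed=33, n_x_variants=0)
        cfg.group_hr = {k: 1.0 for k in cfg.group_hr}
        cohort = simulate.simulate_cohort(cfg)
        p = cohort.participants
        carrier_ages = p.event_age[p.carrier & p.event_age.notna()]
        other_ages = p.event_age[~p.carrier & p.event_age.notna()]
        if len(carrier_ages) >= 5:
            ks = stats.ks_2samp(carrier_ages, other_ages)
            assert ks.pvalue > 0.01


class TestDegradation:
    def test_identity_when_no_degradation(self):
        cfg = CohortConfig(
            n_participants=400, seed=6, n_x_variants=4,
            missingness={"sequencing": 0.0, "array": 0.0, "imputed": 0.0},
            imputation_concordance=1.0, imputed_false_positive_rate=0.0,
        )
        cohort = simulate.simulate_cohort(cfg)
        truth = cohort.truth
        for src, m in cohort.sources.items():
            sub = truth.subset_variants(m.variant_ids)
            np.testing.assert_array_equal(m.genotypes, sub.genotypes)

    def test_missingness_rate_recovered(self):
        cfg = CohortConfig(
            n_participants=2000, seed=7, n_x_variants=10,
            missingness={"sequencing": 0.1, "array": 0.0, "imputed": 0.0},
        )
        cohort = simulate.simulate_cohort(cfg)
        g = cohort.sources["sequencing"].genotypes
        miss = (g == -1).mean()
        se = np.sqrt(0.1 * 0.9 / g.size)
        assert abs(miss - 0.1) < 3 * se

    def test_imputation_concordance_recovered(self):
        cfg = CohortConfig(n_participants=60_000, seed=8, n_x_variants=0,
                           imputation_concordance=0.8, imputed_false_positive_rate=0.0,
                           missingness={"sequencing": 0.0, "array": 0.0, "imputed": 0.0})
        cohort = simulate.simulate_cohort(cfg)
        from genofirst.annotate import genotype_concordance

        both = donly = ionly = 0
        for vid in cohort.sources["imputed"].variant_ids:
            c = genotype_concordance(cohort.sources["array"], cohort.sources["imputed"], vid)
            both += c.both_carrier
            donly += c.direct_only
            ionly += c.imputed_only
        union = both + donly + ionly
        se = np.sqrt(0.8 * 0.2 / union)
        assert abs(both / union - 0.8) < 3 * se

    def test_source_restriction(self, small_cohort):
        # non-BRCA panel variants are sequencing-only by default
        chek2 = [v for v, g in zip(small_cohort.variant_table.variant_id,
                                   small_cohort.variant_table.gene) if g == "CHEK2"]
        assert set(chek2) <= set(small_cohort.sources["sequencing"].variant_ids)
        assert not set(chek2) & set(small_cohort.sources["array"].variant_ids)
        assert not set(chek2) & set(small_cohort.sources["imputed"].variant_ids)


class TestPedigrees:
    def test_mendelian_first_degree_rate(self):
        cfg = CohortConfig()
        peds = simulate.simulate_carrier_pedigrees(cfg, 3000, seed=10)
        first = [m.carrier for _, members in peds for m in members if m.degree == 1]
        frac = np.mean(first)
        se = np.sqrt(0.25 / len(first))
        assert len(first) > 5000
        assert abs(frac - 0.5) < 3 * se

    def test_non_carrier_proband_zero_freq_no_carrier_relatives(self):
        cfg = CohortConfig()
        cfg.variant_freqs = {v: 0.0 for v in cfg.variant_freqs}
        members = simulate.simulate_pedigree("BRCA1", False, cfg, seed=12)
        assert not any(m.carrier for m in members)

    def test_mean_pedigree_size(self):
        cfg = CohortConfig()
        peds = simulate.simulate_carrier_pedigrees(cfg, 4000, seed=13)
        sizes = [len(members) for _, members in peds]
        se = np.sqrt(cfg.n_relatives_mean / len(sizes))  # Poisson spread
        assert abs(np.mean(sizes) - 4.3) < 3 * se

    def test_relative_events_respect_attained_age(self):
        cfg = CohortConfig()
        peds = simulate.simulate_carrier_pedigrees(cfg, 500, seed=14)
        for _, members in peds:
            for m in members:
                for e in m.events:
                    assert e.onset_age is None or e.onset_age <= m.attained_age
                    assert e.degree == m.degree and e.side == m.side


class TestConfig:
    def test_invalid_frequency_names_field(self):
        with pytest.raises(ConfigError, match="variant_freqs"):
            CohortConfig(variant_freqs={"rs1": 0.7})

    def test_invalid_concordance(self):
        with pytest.raises(ConfigError, match="imputation_concordance"):
            CohortConfig(imputation_concordance=1.5)

    def test_yaml_round_trip(self, tmp_path):
        cfg = CohortConfig(n_participants=123, seed=5)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        back = CohortConfig.from_yaml(path)
        assert back == cfg

    def test_stage_streams_independent(self):
        a = rng_for(1, "cohort").uniform(size=3)
        b = rng_for(1, "events").uniform(size=3)
        assert not np.allclose(a, b)
        np.testing.assert_array_equal(a, rng_for(1, "cohort").uniform(size=3))
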