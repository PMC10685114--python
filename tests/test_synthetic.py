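import numpy as np
import pytest
from scipy import stats

import vmtopics as v
from vmtopics.data_model import DataError
from vmtopics.synthetic import (
    GeneratorConfig,
    LACTOBACILLUS_TAXA,
    SYNONYM_GENERA,
    default_centroids,
    make_reference_topics,
    simulate_assays,
    simulate_bleeding_diary,
    simulate_cohort,
    simulate_transition_cohort,
)


class TestReferenceTopics:
    def test_point_mass_template_echo(self):
        beta = make_reference_topics(GeneratorConfig())
        row = beta.values[beta.row_ids.index("I")]
        assert row[beta.taxon_ids.index("Lactobacillus_crispatus")] == pytest.approx(0.95)

    def test_synonym_topic_equal_share(self):
        """Background 0.4 → each of the four genera gets (1 − 0.4)/4 = 0.15."""
        beta = make_reference_topics(GeneratorConfig())
        row = beta.values[beta.row_ids.index("IV-C")]
        for g in SYNONYM_GENERA:
            assert row[beta.taxon_ids.index(g)] == pytest.approx(0.15)

    def test_all_rows_sum_to_one(self):
        beta = make_reference_topics(GeneratorConfig())
        np.testing.assert_allclose(beta.values.sum(1), 1.0, atol=1e-8)

    def test_bad_template_rejected(self):
        cfg = GeneratorConfig()
        cfg.templates = {"A": {cfg.taxa[0]: 0.5}, "B": {cfg.taxa[1]: 1.0}}
        with pytest.raises(DataError, match="sums to"):
            make_reference_topics(cfg)


class TestBleedingDiary:
    def test_deterministic_cycle_without_noise(self):
        """sd = 0 and no spotting: onsets every 28 days, 4 bleeding days per cycle."""
        cfg = GeneratorConfig(cycle_sd=0.0, menses_sd=0.0, spotting_rate=0.0,
                              mean_cycle_length=28, menses_length=4, initial_phase=0)
        diary, onsets = simulate_bleeding_diary(cfg, 70, seed=0)
        assert onsets == [0, 28, 56]
        assert int((diary >= 1).sum()) == 4 * 3
        assert all(diary[o:o + 4].min() >= 1 for o in onsets)

    def test_single_day_diary(self):
        diary, _ = simulate_bleeding_diary(GeneratorConfig(), 1, seed=1)
        assert diary.shape == (1,)

    def test_seed_reproducibility(self):
        cfg = GeneratorConfig()
        d1, o1 = simulate_bleeding_diary(cfg, 70, seed=5)
        d2, o2 = simulate_bleeding_diary(cfg, 70, seed=5)
        np.testing.assert_array_equal(d1, d2)
        assert o1 == o2

    def test_invalid_length_rejected(self):
        with pytest.raises(DataError):
            simulate_bleeding_diary(GeneratorConfig(), 0, seed=0)


class TestCohort:
    def test_law_of_large_numbers_recovery(self):
        """No drift, no menses effect, huge concentration: empirical taxon
        frequencies match γβ within multinomial error at large library size."""
        cfg = GeneratorConfig(
            n_participants=4, samples_per_participant=6, rho=0.0, sigma=1e-6,
            menses_effect=0.0, baseline_concentration=5e4, anchor_boost=0.0,
            synonym_baseline_damping=1.0, library_mu=np.log(1e6), library_sigma=1e-9,
            fraction_pregnant=1.0, seed=0)
        co = simulate_cohort(cfg)
        rel = co.counts.counts / co.counts.library_sizes[:, None]
        for i in range(co.counts.n_samples):
            pid = co.meta.iloc[i]["participant"]
            beta = co.true_beta.values.copy()
            # apply this participant's synonym variant to the expected row
            syn = co.true_beta.row_ids.index("IV-C")
            keep = co.synonym_choice[pid]
            niche = sum(beta[syn, co.true_beta.taxon_ids.index(g)] for g in SYNONYM_GENERA)
            for g in SYNONYM_GENERA:
                beta[syn, co.true_beta.taxon_ids.index(g)] = niche if g == keep else 0.0
            expected = co.true_gamma.iloc[i].to_numpy() @ beta
            assert np.abs(rel[i] - expected).max() < 0.01

    def test_menses_effect_raises_menses_topics(self):
        """Mean γ of the menses topic is higher on menses days (Monte Carlo)."""
        cfg = GeneratorConfig(n_participants=30, samples_per_participant=30,
                              fraction_pregnant=0.0, menses_effect=3.0, seed=3)
        co = simulate_cohort(cfg)
        on, off = [], []
        for i, (sid, row) in enumerate(co.meta.iterrows()):
            g = co.true_gamma.iloc[i]["IV-C"]
            days = co.true_menses_days[row["participant"]]
            (on if int(row["day"]) in days else off).append(g)
        assert np.mean(on) > np.mean(off) + 0.03

    def test_synonym_variants_never_cooccur(self):
        """Construction: only a participant's chosen genus can reach substantial
        abundance — other genera appear only as trace spread from other topics."""
        co = simulate_cohort(GeneratorConfig(seed=4))
        rel = co.counts.counts / co.counts.library_sizes[:, None]
        cols = [co.counts.taxon_ids.index(g) for g in SYNONYM_GENERA]
        for i, sid in enumerate(co.counts.sample_ids):
            substantial = rel[i, cols] > 0.05
            assert substantial.sum() <= 1
            if substantial.any():
                pid = co.meta.iloc[i]["participant"]
                genus = SYNONYM_GENERA[int(np.argmax(substantial))]
                assert co.synonym_choice[pid] == genus

    def test_gamma_exchangeable_without_menses_effect(self):
        """menses_effect = 0: γ distribution identical on and off menses days."""
        cfg = GeneratorConfig(n_participants=30, samples_per_participant=40,
                              fraction_pregnant=0.0, menses_effect=0.0, seed=6)
        co = simulate_cohort(cfg)
        on, off = [], []
        for i, (sid, row) in enumerate(co.meta.iterrows()):
            g = co.true_gamma.iloc[i]["IV-C"]
            days = co.true_menses_days[row["participant"]]
            (on if int(row["day"]) in days else off).append(g)
        _, p = stats.ks_2samp(on, off)
        assert p > 0.01

    def test_seed_reproducibility_bit_identical(self):
        cfg = GeneratorConfig(n_participants=4, samples_per_participant=5, seed=11)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        np.testing.assert_array_equal(a.counts.counts, b.counts.counts)
        np.testing.assert_array_equal(a.true_gamma.to_numpy(), b.true_gamma.to_numpy())
        assert a.true_cycle_onsets == b.true_cycle_onsets

    def test_metadata_contract(self, small_cohort):
        from vmtopics.data_model import validate_sample_table

        validate_sample_table(small_cohort.meta, small_cohort.counts)
        np_rows = small_cohort.meta[~small_cohort.meta["pregnant"]]
        assert np_rows["bleeding"].notna().all()
        assert small_cohort.meta[small_cohort.meta["pregnant"]]["preterm"].notna().all()


class TestAssays:
    def test_zero_amplitude_feature_constant_mean(self, rng):
        cfg = GeneratorConfig(assay_amplitude=0.0, assay_missing_rate=0.0,
                              assay_lloq_quantile=0.0, assay_uloq_quantile=1.0)
        cds = rng.integers(-18, 8, size=400)
        assay, truth = simulate_assays(cfg, cds, seed=1)
        j = 0
        early = assay.values[cds < -9, j].mean()
        late = assay.values[cds >= -9, j].mean()
        assert abs(early - late) < 0.3

    def test_phase_structure_of_cyclic_features(self):
        """Amplitude 2, peak day 0: mean at day 0 exceeds mean at day −13."""
        cfg = GeneratorConfig(assay_amplitude=2.0, assay_fraction_cyclic=1.0,
                              assay_missing_rate=0.0, assay_lloq_quantile=0.0,
                              assay_uloq_quantile=1.0, seed=0)
        cds = np.tile([0, -13], 250)
        assay, truth = simulate_assays(cfg, cds, seed=2)
        peak0 = truth[truth.peak_day == truth.peak_day].index[truth.peak_day.abs().idxmin()]
        j = int(truth.peak_day.abs().idxmin())
        m0 = assay.values[cds == 0, j].mean()
        m13 = assay.values[cds == -13, j].mean()
        # feature j peaks nearest day 0 → opposite-phase day is lower
        if truth.loc[j, "cyclic"]:
            assert m0 > m13

    def test_full_missingness(self):
        cfg = GeneratorConfig(assay_missing_rate=1.0)
        assay, _ = simulate_assays(cfg, np.zeros(10, int), seed=3)
        assert np.isnan(assay.values).all()

    def test_out_of_range_cycledays_rejected(self):
        with pytest.raises(DataError):
            simulate_assays(GeneratorConfig(), np.array([9]), seed=0)


def test_default_centroids_are_valid_compositions():
    cents = default_centroids()
    np.testing.assert_allclose(cents.values.sum(1), 1.0, atol=1e-6)
    assert "IV-C1" in cents.labels and "I-A" in cents.labels


def test_transition_cohort_hazard_direction():
    df = simulate_transition_cohort(n_participants=20, pairs_per_participant=10, seed=0)
    dom = df[df.current_lacto >= 0.5]
    loss = dom.next_lacto < 0.5
    # pairs with more anaerobe membership lose dominance more often
    risky = dom["gamma_IV-B"] + dom["gamma_IV-C"] + dom["gamma_III"]
    assert risky[loss].mean() > risky[~loss].mean()
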