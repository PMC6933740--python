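import numpy as np
import pytest
from scipy import stats

from petscreen import (
    Cohort,
    Provenance,
    Subject,
    cohort_moments,
    default_config,
    simulate_cohort,
)
from petscreen.cohort_sim import TABLE_CALIBRATED_OFFSETS


class TestDefaultConfig:
    def test_class_pet_rates_match_published_counts(self):
        cfg = default_config()
        assert cfg.pet_rate_by_class["e4_carrier"] == pytest.approx(0.857, abs=5e-4)
        assert cfg.pet_rate_by_class["e2_only"] == 0.0
        assert cfg.pet_rate_by_class["e3e3"] == pytest.approx(10 / 31)

    def test_marker_params_match_published_moments(self):
        cfg = default_config()
        assert cfg.marker_params["pet_pos"]["abeta42"] == (16.3, 2.3)
        assert cfg.marker_params["pet_neg"]["abeta42"] == (17.6, 3.3)
        assert cfg.marker_params["pet_pos"]["tau"] == (18.4, 8.5)

    def test_genotype_probs_normalized_and_class_exact(self):
        cfg = default_config()
        probs = cfg.genotype_probs
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-15)
        carrier = probs["e2e4"] + probs["e3e4"] + probs["e4e4"]
        assert carrier == pytest.approx(14 / 52, abs=1e-12)
        e2_only = probs["e2e2"] + probs["e2e3"]
        assert e2_only == pytest.approx(7 / 52, abs=1e-12)

    def test_correlation_targets(self):
        cfg = default_config()
        assert cfg.suvr_params["pet_neg"][2] == 0.387
        assert cfg.suvr_params["pet_pos"][2] == -0.068

    def test_validation_rejects_bad_configs(self):
        cfg = default_config()
        with pytest.raises(ValueError, match="n_subjects"):
            cfg.with_(n_subjects=0).validate()
        bad_probs = dict(cfg.genotype_probs)
        bad_probs["e3e3"] += 0.1
        with pytest.raises(ValueError, match="sum to 1"):
            cfg.with_(genotype_probs=bad_probs).validate()
        with pytest.raises(ValueError, match=r"\[0,1\]"):
            cfg.with_(
                pet_rate_by_class={**cfg.pet_rate_by_class, "e3e3": 1.2}
            ).validate()
        with pytest.raises(ValueError, match="marker_floor"):
            cfg.with_(marker_floor=0.0).validate()


class TestSimulate:
    def test_zero_subjects_is_an_error(self):
        with pytest.raises(ValueError, match="n_subjects"):
            simulate_cohort(default_config(n_subjects=0))

    def test_determinism(self):
        cfg = default_config(n_subjects=200, seed=7)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        assert a.to_frame().equals(b.to_frame())
        assert a.provenance.config_digest == b.provenance.config_digest

    def test_seed_changes_cohort(self):
        a = simulate_cohort(default_config(n_subjects=200, seed=7))
        b = simulate_cohort(default_config(n_subjects=200, seed=8))
        assert not a.to_frame()["abeta42"].equals(b.to_frame()["abeta42"])

    def test_e2_only_subjects_never_pet_positive_by_default(self):
        cohort = simulate_cohort(default_config(n_subjects=2000, seed=3))
        df = cohort.to_frame()
        assert not df.loc[df["e2_only"], "pet_positive"].any()

    def test_markers_respect_floor(self):
        cohort = simulate_cohort(default_config(n_subjects=2000, seed=3))
        df = cohort.to_frame()
        for marker in ("abeta40", "abeta42", "tau"):
            assert (df[marker] >= 1.0).all()


class TestParameterRecovery:
    """Moments of a large simulated cohort recover the generator inputs."""

    def test_pet_rates_within_three_binomial_se(self, large_default_cohort,
                                                large_default_moments):
        df = large_default_cohort.to_frame()
        for cls, rate in (("e4_carrier", 12 / 14), ("e3e3", 10 / 31),
                          ("e2_only", 0.0)):
            n_cls = (df["genotype_class"] == cls).sum()
            se = np.sqrt(max(rate * (1 - rate), 1e-12) / n_cls)
            got = large_default_moments.pet_rate_by_class[cls]
            assert abs(got - rate) <= max(3 * se, 1e-9)

    def test_abeta_means_within_three_se(self, large_default_moments):
        m = large_default_moments.marker_by_pet
        for pet, marker, mean, sd in [
            ("pet_pos", "abeta42", 16.3, 2.3),
            ("pet_neg", "abeta42", 17.6, 3.3),
            ("pet_pos", "abeta40", 50.9, 7.7),
            ("pet_neg", "abeta40", 49.1, 7.3),
        ]:
            n = m.loc[pet, (marker, "n")]
            got = m.loc[pet, (marker, "mean")]
            assert abs(got - mean) <= 3 * sd / np.sqrt(n)

    def test_tau_means_match_truncated_distribution(self, large_default_moments):
        """tau's floor sits ~2 SD below the mean, so the sampled mean matches
        the *truncated*-normal mean (the distribution actually drawn), not
        the nominal location parameter."""
        m = large_default_moments.marker_by_pet
        for pet, mean, sd in [("pet_pos", 18.4, 8.5), ("pet_neg", 22.5, 10.4)]:
            a = (1.0 - mean) / sd
            trunc_mean, trunc_var = stats.truncnorm.stats(
                a, np.inf, loc=mean, scale=sd, moments="mv"
            )
            n = m.loc[pet, ("tau", "n")]
            got = m.loc[pet, ("tau", "mean")]
            assert abs(got - float(trunc_mean)) <= 3 * np.sqrt(trunc_var / n)
            # and the nominal parameter is visibly biased upward
            assert float(trunc_mean) > mean + 0.2

    def test_suvr_correlations_recovered(self, large_default_moments):
        corr = large_default_moments.suvr_correlation_by_pet
        assert corr["pet_neg"] == pytest.approx(0.387, abs=0.03)
        assert corr["pet_pos"] == pytest.approx(-0.068, abs=0.03)

    def test_truncation_bias_negligible_for_abeta(self):
        """With the calibrated moments and floor 1 pg/ml, truncation moves
        the Abeta means by < 0.01 pg/ml (floor > 6 SD below both means)."""
        for mean, sd in [(16.3, 2.3), (17.6, 3.3), (50.9, 7.7), (49.1, 7.3)]:
            a = (1.0 - mean) / sd
            trunc_mean = float(
                stats.truncnorm.stats(a, np.inf, loc=mean, scale=sd, moments="m")
            )
            assert abs(trunc_mean - mean) < 0.01

    def test_genotype_class_frequencies(self, large_default_cohort):
        df = large_default_cohort.to_frame()
        n = len(df)
        frac = (df["genotype_class"] == "e4_carrier").mean()
        p = 14 / 52
        assert abs(frac - p) <= 3 * np.sqrt(p * (1 - p) / n)


class TestGenotypeEffects:
    def test_offsets_shift_class_means(self):
        cfg = default_config(n_subjects=20_000, seed=5, genotype_effects=True)
        assert cfg.genotype_marker_offsets == TABLE_CALIBRATED_OFFSETS
        moments = cohort_moments(simulate_cohort(cfg))
        by_class = moments.marker_by_class
        # carriers end up with *higher* plasma Abeta1-42 despite being
        # mostly PET+ (the published carrier/non-carrier pattern)
        assert (
            by_class.loc["e4_carrier", ("abeta42", "mean")]
            > by_class.loc["e3e3", ("abeta42", "mean")]
        )
        assert (
            by_class.loc["e4_carrier", ("tau", "mean")]
            > by_class.loc["e3e3", ("tau", "mean")]
        )


class TestMoments:
    def test_hand_computed_mean_and_sd(self):
        subjects = [
            Subject(subject_id="a", genotype="e3e3", pet_positive=False,
                    abeta40=50.0, abeta42=16.0, tau=20.0),
            Subject(subject_id="b", genotype="e3e3", pet_positive=False,
                    abeta40=50.0, abeta42=18.0, tau=20.0),
        ]
        cohort = Cohort(subjects=subjects, provenance=Provenance(source="external file"))
        m = cohort_moments(cohort).marker_by_pet
        assert m.loc["pet_neg", ("abeta42", "mean")] == pytest.approx(17.0)
        assert m.loc["pet_neg", ("abeta42", "sd")] == pytest.approx(np.sqrt(2.0))

    def test_singleton_group_sd_is_undefined_not_zero(self):
        subjects = [
            Subject(subject_id="a", genotype="e3e3", pet_positive=True,
                    abeta40=50.0, abeta42=16.0, tau=20.0),
            Subject(subject_id="b", genotype="e3e3", pet_positive=False,
                    abeta40=50.0, abeta42=18.0, tau=20.0),
        ]
        cohort = Cohort(subjects=subjects, provenance=Provenance(source="external file"))
        m = cohort_moments(cohort).marker_by_pet
        assert np.isnan(m.loc["pet_pos", ("abeta42", "sd")])

    def test_moments_deterministic_across_regeneration(self):
        cfg = default_config(n_subjects=500, seed=11)
        m1 = cohort_moments(simulate_cohort(cfg))
        m2 = cohort_moments(simulate_cohort(cfg))
        assert m1.marker_by_pet.equals(m2.marker_by_pet)
        assert m1.pet_rate_by_class.equals(m2.pet_rate_by_class)


class TestCohortValidation:
    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            Cohort(subjects=[], provenance=Provenance(source="external file"))

    def test_duplicate_ids_rejected(self):
        s = Subject(subject_id="a", genotype="e3e3", pet_positive=False,
                    abeta40=50.0, abeta42=16.0, tau=20.0)
        with pytest.raises(ValueError, match="unique"):
            Cohort(subjects=[s, s], provenance=Provenance(source="external file"))

    def test_bad_genotype_rejected(self):
        with pytest.raises(ValueError, match="genotype"):
            Subject(subject_id="a", genotype="e5e4", pet_positive=False,
                    abeta40=50.0, abeta42=16.0, tau=20.0)

    def test_nonpositive_marker_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            Subject(subject_id="a", genotype="e3e3", pet_positive=False,
                    abeta40=50.0, abeta42=0.0, tau=20.0)
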