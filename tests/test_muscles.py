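"""Reduction model: CSA-proportional distribution, co-contraction balance,
ligament resolution, and the generator/reducer round trip."""

import numpy as np
import pytest

from kneeload.config import MUSCLES, default_model_config
from kneeload.muscles import (
    MomentArmModel,
    distribute_moment,
    height_scale_factor,
    ligament_forces,
    quadriceps_force,
    reduce_trial,
)
from kneeload.signals import filter_trial
from kneeload.synthetic import GaitTrialSpec, generate_gait_trial


class TestHeightScale:
    @pytest.mark.parametrize(
        "group, grand, expected",
        [
            (1.75, 1.69, 1.0355),  # male group over cohort grand mean
            (1.69, 1.69, 1.0),
            (1.628, 1.6895, 0.9636),  # female group over cohort grand mean
        ],
    )
    def test_ratio(self, group, grand, expected):
        assert height_scale_factor(group, grand) == pytest.approx(expected, abs=5e-5)

    def test_non_positive_height_rejected(self):
        with pytest.raises(ValueError):
            height_scale_factor(0.0, 1.69)


class TestDistributeMoment:
    def test_single_muscle(self):
        forces = distribute_moment(50.0, {"soleus": 0.05}, {"soleus": 60.0})
        assert forces["soleus"] == pytest.approx(1000.0)

    def test_two_muscles_share_by_csa(self):
        forces = distribute_moment(
            50.0,
            {"gastrocnemius": 0.05, "soleus": 0.05},
            {"gastrocnemius": 60.0, "soleus": 40.0},
        )
        assert forces["gastrocnemius"] == pytest.approx(600.0)
        assert forces["soleus"] == pytest.approx(400.0)

    def test_antagonist_moment_gives_zero(self):
        forces = distribute_moment(-10.0, {"soleus": 0.05}, {"soleus": 60.0})
        assert forces["soleus"] == 0.0

    def test_moment_closure_for_unequal_arms(self):
        arms = {"gastrocnemius": 0.048, "soleus": 0.041}
        csa = {"gastrocnemius": 30.0, "soleus": 51.0}
        forces = distribute_moment(73.0, arms, csa)
        total = sum(arms[m] * forces[m] for m in arms)
        assert total == pytest.approx(73.0, rel=1e-12)

    def test_zero_arm_with_nonzero_moment_is_error(self):
        with pytest.raises(ValueError, match="zero moment arm"):
            distribute_moment(10.0, {"soleus": 0.0}, {"soleus": 60.0})


class TestQuadriceps:
    def test_reduces_to_single_muscle_without_biarticulars(self):
        assert quadriceps_force(40.0, {}, 0.04) == pytest.approx(1000.0)

    def test_cocontraction_balance(self):
        f = quadriceps_force(40.0, {"hamstrings": (500.0, 0.03)}, 0.04)
        assert f == pytest.approx((40.0 + 15.0) / 0.04)  # 1375 N

    def test_clamped_at_zero(self):
        assert quadriceps_force(-50.0, {"hamstrings": (100.0, 0.03)}, 0.04) == 0.0

    def test_zero_arm_is_error(self):
        with pytest.raises(ValueError):
            quadriceps_force(40.0, {}, 0.0)


class TestLigaments:
    def test_zero_residuals_zero_forces(self, male_model):
        out = ligament_forces(0.0, 0.0, 0.5, male_model)
        assert all(v == 0.0 for v in out.values())

    def test_anterior_shear_excludes_pcl(self, male_model):
        out = ligament_forces(100.0, 0.0, 0.5, male_model)
        phi = male_model.orientation("acl", 0.5)
        assert out["acl"] == pytest.approx(100.0 / np.cos(phi))
        assert out["pcl"] == 0.0

    def test_planted_residuals_match_hand_resolution(self, male_model):
        # oracle: direct evaluation of the configured resolution rule
        shear, frontal, angle = -80.0, 45.0, 0.7
        out = ligament_forces(shear, frontal, angle, male_model)
        assert out["pcl"] == pytest.approx(80.0 / np.cos(male_model.orientation("pcl", angle)))
        assert out["mcl"] == pytest.approx(45.0 / np.cos(male_model.orientation("mcl", angle)))
        assert out["acl"] == 0.0 and out["lcl"] == 0.0

    def test_forces_non_negative_over_random_residuals(self, male_model, rng):
        shear = rng.normal(0, 200, 50)
        frontal = rng.normal(0, 100, 50)
        out = ligament_forces(shear, frontal, np.full(50, 0.4), male_model)
        for v in out.values():
            assert np.all(v >= 0)


class TestRoundTrip:
    def test_noise_free_force_recovery(self, clean_walk):
        """The reduction inverts the generator exactly at zero noise."""
        (trial, truth), spec = clean_walk
        model = MomentArmModel.for_subject(spec.subject)
        recovered = reduce_trial(trial, model)
        for muscle in MUSCLES:
            planted = truth.forces[muscle]
            scale = max(1.0, np.abs(planted).max())
            assert np.abs(recovered[muscle] - planted).max() / scale < 1e-9

    def test_moment_closure_every_sample(self, clean_walk):
        (trial, truth), spec = clean_walk
        model = MomentArmModel.for_subject(spec.subject)
        th = trial["ankle_flex_angle"]
        reconstructed = model.arm("gastrocnemius", "ankle", th) * truth.forces[
            "gastrocnemius"
        ] + model.arm("soleus", "ankle", th) * truth.forces["soleus"]
        assert np.allclose(reconstructed, trial["ankle_pf_moment"], atol=1e-9)

    def test_gender_variants_differ(self, male_subject, female_subject):
        male = MomentArmModel.for_subject(male_subject)
        female = MomentArmModel.for_subject(female_subject)
        angle = 0.6
        assert male.arm("quadriceps", "knee", angle) != female.arm("quadriceps", "knee", angle)
        f_m = quadriceps_force(40.0, {}, male.arm("quadriceps", "knee", angle))
        f_f = quadriceps_force(40.0, {}, female.arm("quadriceps", "knee", angle))
        assert f_m != f_f

    def test_all_forces_non_negative(self, clean_walk):
        (trial, truth), spec = clean_walk
        recovered = reduce_trial(trial, MomentArmModel.for_subject(spec.subject))
        assert (recovered.forces.to_numpy() >= -1e-12).all()


class TestNoisyRecovery:
    def test_mean_peak_quadriceps_within_two_percent(self, male_subject):
        """Monte-Carlo over 50 seeds at 5 N·m moment noise: the mean
        recovered quadriceps peak stays within 2% of the planted peak."""
        peaks = []
        planted_peak = None
        for seed in range(50):
            spec = GaitTrialSpec(
                subject=male_subject,
                noise_sd={"grf": 0.0, "moments": 5.0, "angles": 0.0, "pelvis_vz": 0.0},
                seed=seed,
            )
            trial, truth = generate_gait_trial(spec)
            filtered = filter_trial(trial, 45.0, 6.0)
            recovered = reduce_trial(filtered, MomentArmModel.for_subject(male_subject))
            peaks.append(recovered["quadriceps"].max())
            planted_peak = truth.forces["quadriceps"].max()
        assert abs(np.mean(peaks) - planted_peak) / planted_peak < 0.02


class TestAngleRangeClamping:
    def test_out_of_range_angle_warns_and_clamps(self, male_model):
        with pytest.warns(RuntimeWarning, match="clamped"):
            r = male_model.arm("quadriceps", "knee", 3.0)
        assert r == pytest.approx(male_model.arm("quadriceps", "knee", 2.1))


def test_config_schema_rejects_missing_blocks():
    from kneeload.config import ConfigError, validate_model_config

    config = default_model_config()
    del config["csa_cm2"]["quadriceps"]
    with pytest.raises(ConfigError):
        validate_model_config(config)
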