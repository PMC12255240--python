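"""Generator contracts: determinism, construction invariants, planted-truth
consistency, and validation of malformed specifications."""

import numpy as np
import pandas as pd
import pytest

from kneeload.reliability import icc_2k
from kneeload.synthetic import (
    GaitTrialSpec,
    StsTrialSpec,
    TileSetSpec,
    generate_gait_trial,
    generate_rating_table,
    generate_sts_trace,
    generate_tile_set,
    make_speckle_master,
    rating_grid,
)


class TestDeterminism:
    def test_gait_trials_bit_identical_under_fixed_seed(self, male_subject):
        spec = GaitTrialSpec(subject=male_subject, seed=42)
        t1, g1 = generate_gait_trial(spec)
        t2, g2 = generate_gait_trial(GaitTrialSpec(subject=male_subject, seed=42))
        pd.testing.assert_frame_equal(t1.data, t2.data)
        assert np.array_equal(g1.heel_strikes, g2.heel_strikes)

    def test_different_seeds_differ(self, male_subject):
        t1, _ = generate_gait_trial(GaitTrialSpec(subject=male_subject, seed=1))
        t2, _ = generate_gait_trial(GaitTrialSpec(subject=male_subject, seed=2))
        assert not np.array_equal(t1["fz"], t2["fz"])

    def test_sts_trace_deterministic(self):
        t1, g1 = generate_sts_trace(StsTrialSpec(noise_sd=5.0, seed=9))
        t2, g2 = generate_sts_trace(StsTrialSpec(noise_sd=5.0, seed=9))
        pd.testing.assert_frame_equal(t1.data, t2.data)
        assert g1.events == g2.events


class TestGaitConstruction:
    def test_heel_strike_crossings_planted_at_20_newtons(self, clean_walk):
        (trial, truth), spec = clean_walk
        fz = trial["fz"]
        for idx in truth.heel_strikes:
            assert fz[idx] >= 20.0
            assert fz[idx - 1] < 20.0

    def test_boundary_ordering(self, clean_walk):
        (trial, truth), _ = clean_walk
        assert np.all(np.diff(truth.heel_strikes) > 0)

    def test_invalid_specs_rejected(self, male_subject):
        with pytest.raises(ValueError, match="movement_class"):
            GaitTrialSpec(movement_class="hop", subject=male_subject)
        with pytest.raises(ValueError, match="positive"):
            GaitTrialSpec(stride_duration_s=-1.0, subject=male_subject)
        with pytest.raises(ValueError, match="noise"):
            GaitTrialSpec(noise_sd={"grf": -5.0}, subject=male_subject)

    def test_trial_tsv_round_trip(self, clean_walk, tmp_path):
        (trial, _), _ = clean_walk
        path = tmp_path / "walk_00.tsv"
        trial.to_tsv(path)
        header = path.read_text().splitlines()[0]
        assert header == "\t".join(
            [
                "time", "fx", "fy", "fz",
                "hip_flex_angle", "knee_flex_angle", "knee_add_angle", "ankle_flex_angle",
                "hip_ext_moment", "knee_flex_moment", "knee_add_moment", "ankle_pf_moment",
                "pelvis_vz",
            ]
        )
        from kneeload.trial import TrialTimeSeries

        back = TrialTimeSeries.from_tsv(path)
        assert back.rate_hz == pytest.approx(trial.rate_hz)
        assert np.allclose(back["fz"], trial["fz"], rtol=1e-6, atol=1e-5)


class TestStsConstruction:
    def test_boundaries_strictly_increasing_required(self):
        with pytest.raises(ValueError, match="increasing"):
            StsTrialSpec(phase_boundaries=(100, 90, 200, 300, 400))

    def test_true_events_ordered_and_inside_trace(self, clean_sts):
        (trial, truth), spec = clean_sts
        sts = truth.events["sit_to_stand"]
        s2s = truth.events["stand_to_sit"]
        assert sts[0] < sts[1] <= s2s[0] < s2s[1] < len(trial)
        # events sit inside the construction knots they refine
        assert spec.phase_boundaries[1] <= sts[0] < spec.phase_boundaries[2]
        assert spec.phase_boundaries[3] <= s2s[0] < spec.phase_boundaries[4]

    def test_quiet_standing_level(self, clean_sts):
        (trial, truth), spec = clean_sts
        b2, b3 = spec.phase_boundaries[2], spec.phase_boundaries[3]
        seg = trial["fz"][b2:b3]
        assert np.all(np.abs(seg - truth.bodyweight_n) < 0.005 * truth.bodyweight_n)


class TestTileSets:
    def test_true_distance_is_calibrated_euclidean(self):
        master, _ = make_speckle_master(width_px=1000, seed=0)
        spec = TileSetSpec(
            master=master,
            tile_width_px=512,
            offsets_px=(0, 300),
            landmark_pair_px=((100, 50), (500, 50)),
            px_per_cm=80.0,
        )
        tiles, true_cm = generate_tile_set(spec)
        assert true_cm == pytest.approx(5.0)
        assert len(tiles) == 2 and tiles[0].shape[1] == 512

    def test_tiles_are_exact_crops(self):
        master, lm = make_speckle_master(width_px=1200, seed=1)
        spec = TileSetSpec(master, 512, (0, 300, 600), lm, 80.0)
        tiles, _ = generate_tile_set(spec)
        for off, tile in zip(spec.offsets_px, tiles):
            assert np.array_equal(tile, master[:, off : off + 512])

    def test_insufficient_overlap_rejected(self):
        master, lm = make_speckle_master(width_px=1400, seed=2)
        with pytest.raises(ValueError, match="overlap"):
            TileSetSpec(master, 500, (0, 450), lm, 80.0)

    def test_landmark_outside_master_rejected(self):
        master, _ = make_speckle_master(width_px=800, seed=3)
        with pytest.raises(ValueError, match="landmarks"):
            TileSetSpec(master, 512, (0, 250), ((100, 50), (2000, 50)), 80.0)


class TestRatingTables:
    def test_no_disagreement_gives_icc_one(self):
        table, theory = generate_rating_table(10, 2, 3, 4.0, 0.0, 0.0, seed=0)
        assert theory == 1.0
        res = icc_2k(rating_grid(table, "rater"))
        assert res.icc == pytest.approx(1.0)
        assert res.sem == pytest.approx(0.0, abs=1e-9)

    def test_no_subject_variance_estimates_near_zero(self):
        """Monte-Carlo mean of the estimate over 200 seeds is ~0 when all
        variance is measurement error.  The table must be large enough for
        the ratio estimator's tails to be tame (it diverges at tiny n)."""
        estimates = []
        for seed in range(200):
            table, _ = generate_rating_table(50, 3, 1, 0.0, 0.0, 25.0, seed=seed)
            estimates.append(icc_2k(rating_grid(table, "rater")).icc)
        assert abs(float(np.mean(estimates))) < 0.1

    def test_estimates_concentrate_on_planted_value(self):
        """n=200 subjects, planted variances 9/0/1, k=3 repeats: the ICC(2,3)
        estimate should sit within Monte-Carlo error of the closed-form
        planted-component value."""
        table, theory = generate_rating_table(200, 1, 3, 9.0, 0.0, 1.0, seed=7)
        grid = rating_grid(table, "repeat", rater="r0")
        res = icc_2k(grid)
        assert theory == pytest.approx(9.0 / (9.0 + 1.0 / 3.0))
        assert res.icc == pytest.approx(theory, abs=0.02)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            generate_rating_table(1, 2, 3, 1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            generate_rating_table(5, 2, 3, -1.0, 1.0, 1.0)
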