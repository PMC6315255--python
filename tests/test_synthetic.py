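import numpy as np
import pandas as pd
import pytest

from funcprofile import io_epoch
from funcprofile.synthetic import (
    DAY_MINUTES,
    SimulationConfig,
    adversarial_config,
    class_ranks,
    dwell_probabilities,
    null_config,
    simulate_capacity,
    simulate_cohort,
    simulate_subject_day,
)
from funcprofile.wear import detect_nonwear, valid_day


class TestSubjectDay:
    def test_degenerate_single_class_day(self):
        cfg = SimulationConfig(
            class_templates=((500.0, 0.0),),
            base_weights=(0.0,),
            effect_size=0.0,
            wear_minutes_range=(600, 600),
            midday_nonwear_prob=0.0,
        )
        rng = np.random.default_rng(0)
        day = simulate_subject_day(0.0, cfg, rng)
        assert day.shape[0] == DAY_MINUTES
        wear_values = day[day > 0]
        assert wear_values.shape[0] == 600
        assert (wear_values == 500).all()

    def test_day_is_deterministic_in_seed(self):
        cfg = SimulationConfig()
        d1 = simulate_subject_day(0.3, cfg, np.random.default_rng(5))
        d2 = simulate_subject_day(0.3, cfg, np.random.default_rng(5))
        np.testing.assert_array_equal(d1, d2)

    def test_every_day_is_valid_and_nonwear_recovered(self):
        # lowest class well above the interruption threshold so the
        # wear-time rule recovers exactly the inserted zero blocks
        cfg = SimulationConfig(
            class_templates=((300.0, 30.0), (1500.0, 200.0)),
            base_weights=(0.5, -0.5),
        )
        rng = np.random.default_rng(11)
        for _ in range(10):
            day = simulate_subject_day(0.0, cfg, rng)
            wear = detect_nonwear(day)
            assert valid_day(wear)
            assert 600 <= wear.sum() <= 840
            assert (day[~wear] == 0).all()
            assert (day[wear] > 0).all()

    def test_high_phi_tilts_toward_intense_classes(self):
        cfg = SimulationConfig(effect_size=0.8)
        top_mean = cfg.class_templates[-1][0]
        minutes = {}
        for phi in (-1.5, 1.5):
            rng = np.random.default_rng(77)
            total = 0
            for _ in range(40):
                day = simulate_subject_day(phi, cfg, rng)
                total += (day > top_mean - 2000).sum()
            minutes[phi] = total
        assert minutes[1.5] > minutes[-1.5]

    def test_dwell_proportions_converge_to_softmax(self):
        # zero SDs make every minute's class identifiable by its value
        cfg = SimulationConfig(
            class_templates=((100.0, 0.0), (1000.0, 0.0), (3000.0, 0.0)),
            base_weights=(0.5, 0.0, -0.5),
            effect_size=0.8,
            midday_nonwear_prob=0.0,
        )
        phi = 0.7
        probs = dwell_probabilities(phi, cfg)
        rng = np.random.default_rng(123)
        counts = np.zeros(3)
        for _ in range(400):
            day = simulate_subject_day(phi, cfg, rng)
            wear_vals = day[day > 0]
            for j, (m, _s) in enumerate(cfg.class_templates):
                counts[j] += (wear_vals == m).sum()
        np.testing.assert_allclose(counts / counts.sum(), probs, atol=0.02)


class TestAdversarialNonwear:
    def test_interruptions_stay_inside_flagged_blocks(self):
        cfg = adversarial_config(
            class_templates=((300.0, 30.0),), base_weights=(0.0,)
        )
        rng = np.random.default_rng(3)
        saw_interruption = False
        for _ in range(10):
            day = simulate_subject_day(0.0, cfg, rng)
            wear = detect_nonwear(day)
            assert valid_day(wear)
            nonwear_vals = day[~wear]
            assert (nonwear_vals < 100).all()
            saw_interruption |= (nonwear_vals > 0).any()
        assert saw_interruption


class TestCapacity:
    def test_noiseless_capacity_is_monotone_and_rank_consistent(self):
        cfg = SimulationConfig(
            capacity_params={
                name: {**params, "noise_sd": 0.0}
                for name, params in SimulationConfig().capacity_params.items()
            }
        )
        rng = np.random.default_rng(0)
        phis = np.linspace(-2, 2, 9)
        vals = {name: [] for name in cfg.capacity_params}
        for phi in phis:
            cap = simulate_capacity(phi, cfg, rng)
            for name, v in cap.items():
                vals[name].append(v)
        assert (np.diff(vals["walk400_time"]) < 0).all()
        assert (np.diff(vals["walk20_pace"]) > 0).all()
        assert (np.diff(vals["sitstand_rate"]) > 0).all()

    def test_null_preset_detaches_activity_from_phi(self):
        cfg = null_config()
        assert dwell_probabilities(-2.0, cfg) == pytest.approx(
            dwell_probabilities(2.0, cfg)
        )

    def test_capacity_deterministic_in_seed(self):
        cfg = SimulationConfig()
        a = simulate_capacity(0.4, cfg, np.random.default_rng(9))
        b = simulate_capacity(0.4, cfg, np.random.default_rng(9))
        assert a == b


class TestCohort:
    def test_files_round_trip_through_io(self, small_sim, tmp_path):
        io_epoch.write_table(
            small_sim.epochs[["subject_id", "timestamp", "count"]],
            tmp_path / "epochs.csv",
        )
        io_epoch.write_table(small_sim.covariates, tmp_path / "cov.csv")
        io_epoch.write_table(small_sim.capacity, tmp_path / "cap.csv")
        ep = io_epoch.read_epochs(tmp_path / "epochs.csv")
        cov = io_epoch.read_covariates(tmp_path / "cov.csv")
        cap = io_epoch.read_capacity(tmp_path / "cap.csv")
        assert ep["subject_id"].nunique() == 20
        assert len(cov) == len(cap) == 20
        assert (ep.groupby(["subject_id", "day"]).size() == DAY_MINUTES).all()

    def test_cohort_reproducible(self):
        cfg = SimulationConfig(n_subjects=5, n_days=1, seed=4)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        pd.testing.assert_frame_equal(a.epochs, b.epochs)
        pd.testing.assert_frame_equal(a.capacity, b.capacity)

    def test_ground_truth_categories_follow_quartile_rule(self, small_sim):
        gt = small_sim.ground_truth
        cats = gt["true_category_walk400_time"]
        assert set(cats) <= {1, 2, 3}
        # noiseless 400-m time decreases in phi given covariates; the
        # quartile rule on its values must mark both tails
        assert (cats == 1).sum() >= 1 and (cats == 3).sum() >= 1

    def test_covariates_echo_cohort_descriptives(self):
        # BMI mean 28.52 (SD 4.87), ~44.5% male at full cohort size
        cfg = SimulationConfig(n_subjects=2001, n_days=1, seed=2)
        cohort = simulate_cohort(cfg)
        bmi = cohort.covariates["bmi"]
        assert abs(bmi.mean() - 28.52) < 0.5
        male = (cohort.covariates["sex"] == "M").mean()
        assert abs(male - 0.4453) < 0.05


def test_class_ranks_are_centered():
    r = class_ranks(6)
    assert r[0] == -1.0 and r[-1] == 1.0
    assert np.allclose(r.mean(), 0.0)
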