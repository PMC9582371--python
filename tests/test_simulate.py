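"""Synthetic-data generator: stimulus statistics, timing, BOLD forward model."""

import numpy as np
import pandas as pd
import pytest

from selfcontrol_fmri import behavior, glm, simulate
from selfcontrol_fmri.config import SimConfig

from conftest import TEST_KW


class TestStimuli:
    def test_discretized_moments_match_task_statistics(self, small_config):
        """Across many draws, the 5-point ratings have the calibrated
        mean/SD: health near -0.35 (SD 1.41), taste near 0.57 (SD 1.10)."""
        rng = np.random.default_rng(0)
        cfg = small_config.with_(n_stimuli=50)
        h, t = [], []
        for _ in range(200):
            s = simulate.simulate_stimuli(cfg, rng)
            h.append(simulate.discretize_rating(s["h_latent"]))
            t.append(simulate.discretize_rating(s["t_latent"]))
        h, t = np.concatenate(h), np.concatenate(t)
        assert abs(h.mean() - (-0.35)) < 0.05
        assert abs(t.mean() - 0.57) < 0.05
        assert abs(h.std(ddof=1) - 1.41) < 0.05
        assert abs(t.std(ddof=1) - 1.10) < 0.05

    def test_zero_correlation_parameter(self, small_config):
        rng = np.random.default_rng(1)
        cfg = small_config.with_(n_stimuli=4000)
        s = simulate.simulate_stimuli(cfg, rng)
        r = np.corrcoef(s["h_latent"], s["t_latent"])[0, 1]
        assert abs(r) < 0.05

    def test_correlation_parameter_is_honored(self, small_config):
        rng = np.random.default_rng(1)
        cfg = small_config.with_(n_stimuli=4000, stim_ht_correlation=0.6)
        s = simulate.simulate_stimuli(cfg, rng)
        r = np.corrcoef(s["h_latent"], s["t_latent"])[0, 1]
        assert abs(r - 0.6) < 0.05

    def test_fixed_seed_reproduces_table(self, small_config):
        a = simulate.simulate_stimuli(small_config, np.random.default_rng(3))
        b = simulate.simulate_stimuli(small_config, np.random.default_rng(3))
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_correlation_rejected(self):
        with pytest.raises(ValueError, match="correlation"):
            SimConfig(stim_ht_correlation=1.5)


class TestSubjects:
    def test_degenerate_weights_follow_health_sign(self, stimuli):
        cfg = SimConfig(w_health_sc=1.0, w_taste_sc=0.0, rating_noise_sd=0.0,
                        decision_noise=0.0, missing_prob=0.0, **TEST_KW)
        prof = simulate.simulate_subject(cfg, stimuli, "SC",
                                         np.random.default_rng(0))
        nonneutral = prof["health"] != 0
        assert (np.sign(prof.loc[nonneutral, "gv"])
                == np.sign(prof.loc[nonneutral, "health"])).all()

    def test_noise_free_sc_truth_classified_sc(self, noisefree_config, stimuli):
        """Closure with the classifier: noise-free health-weighted subjects
        pass all three criteria."""
        rng = np.random.default_rng(5)
        for _ in range(5):
            prof = simulate.simulate_subject(noisefree_config, stimuli, "SC",
                                             rng)
            for mode in ("three_criteria", "one_criterion"):
                assert behavior.classify_participant(prof, mode).label == "SC"

    def test_sc_truth_declines_liked_unhealthy_more(self, small_config,
                                                    stimuli):
        rng = np.random.default_rng(6)
        sc, nsc = [], []
        for i in range(30):
            for cls, acc in (("SC", sc), ("NSC", nsc)):
                prof = simulate.simulate_subject(small_config, stimuli, cls,
                                                 rng)
                acc.append(behavior._yes_proportion(prof, 1, -1))
        assert np.nanmean(sc) < np.nanmean(nsc)

    def test_unknown_class_rejected(self, small_config, stimuli):
        with pytest.raises(ValueError, match="true_class"):
            simulate.simulate_subject(small_config, stimuli, "XX",
                                      np.random.default_rng(0))


class TestTiming:
    def test_iti_bounds_and_mean(self, small_config):
        rng = np.random.default_rng(0)
        itis = np.concatenate([
            simulate.simulate_timing(10, rng, small_config)["iti"]
            for _ in range(1000)])
        assert itis.min() >= 4.0 and itis.max() <= 15.0
        assert abs(itis.mean() - 9.5) < 0.1  # mean of U(4, 15)

    def test_single_trial_starts_at_run_start(self, small_config):
        t = simulate.simulate_timing(1, np.random.default_rng(0), small_config)
        assert t["onset"].iloc[0] == small_config.t_start

    def test_onsets_increase_and_rts_bounded(self, small_config):
        t = simulate.simulate_timing(16, np.random.default_rng(1),
                                     small_config)
        assert (np.diff(t["onset"]) > 0).all()
        assert ((t["rt"] > 0) & (t["rt"] <= 4.0)).all()

    def test_overflow_names_trial(self, small_config):
        cfg = small_config.with_(n_volumes_per_run=30)
        with pytest.raises(ValueError, match=r"trial \d+"):
            simulate.simulate_timing(20, np.random.default_rng(0), cfg)


class TestBold:
    def test_null_amplitudes_leave_noise_variance(self, stimuli, labels):
        cfg = SimConfig(effect_size_map="null", drift_amplitude=0.0,
                        noise_sd=1.0, ar1_rho=0.0, neural_fluct_sd=0.0,
                        missing_prob=0.0, **TEST_KW)
        rng = np.random.default_rng(0)
        sub = simulate.simulate_subject_dataset(cfg, stimuli, 0, "NSC", rng,
                                                labels, blocks=("decision",))
        data = sub.runs["decision"].data
        var = data.var(axis=-1).mean()
        assert abs(var - 1.0) < 0.05

    def test_rho_zero_gives_white_noise(self, stimuli, labels):
        cfg = SimConfig(effect_size_map="null", drift_amplitude=0.0,
                        ar1_rho=0.0, neural_fluct_sd=0.0, missing_prob=0.0,
                        **TEST_KW)
        rng = np.random.default_rng(1)
        sub = simulate.simulate_subject_dataset(cfg, stimuli, 0, "NSC", rng,
                                                labels, blocks=("decision",))
        x = sub.runs["decision"].data.reshape(-1, cfg.n_volumes_per_run)
        x = x - x.mean(axis=1, keepdims=True)
        lag1 = np.mean(np.sum(x[:, 1:] * x[:, :-1], axis=1)
                       / np.sum(x[:, :-1] ** 2, axis=1))
        assert abs(lag1) < 0.02

    def test_white_matter_carries_no_task_signal(self, stimuli, labels,
                                                 noisefree_config):
        sub = simulate.simulate_subject_dataset(
            noisefree_config, stimuli, 0, "SC", np.random.default_rng(2),
            labels, blocks=("decision",))
        wm = sub.runs["decision"].data[labels == 5]
        assert np.allclose(wm, noisefree_config.baseline)

    def test_first_level_recovers_amplitude(self, stimuli, labels,
                                            noisefree_config):
        """Forward model and design construction agree: with noise off the
        fitted goal-value beta equals the simulated vmPFC amplitude."""
        cfg = noisefree_config.with_(effect_size_map="strong")
        sub = simulate.simulate_subject_dataset(
            cfg, stimuli, 0, "SC", np.random.default_rng(3), labels,
            blocks=("decision",))
        run = sub.runs["decision"]
        design = glm.build_design({"decision": sub.events["decision"]}, "1",
                                  run.motion, cfg.tr, cfg.n_volumes_per_run,
                                  sub.profile)
        fit = glm.fit_first_level(run.data, design)
        beta = fit.beta_map("decision_trials_x_gv").values
        assert np.allclose(beta[labels == 1], 2.0, atol=1e-8)
        assert np.allclose(beta[labels == 5], 0.0, atol=1e-8)

    def test_unknown_region_in_effect_map_rejected(self):
        with pytest.raises(ValueError, match="cerebellum"):
            SimConfig(effect_size_map={"cerebellum": {"task": 1.0}})

    def test_white_matter_amplitudes_rejected(self):
        with pytest.raises(ValueError, match="white_matter"):
            SimConfig(effect_size_map={"white_matter": {"task": 0.5}})


class TestDataset:
    def test_tree_layout_and_counterbalancing(self, dataset_dir, small_config):
        subs = sorted(p.name for p in dataset_dir.glob("sub-*"))
        assert len(subs) == small_config.n_subjects
        participants = pd.read_csv(dataset_dir / "participants.tsv", sep="\t")
        first = participants["first_block"].value_counts()
        assert first["health"] == first["taste"] == small_config.n_subjects // 2

    def test_same_seed_byte_identical_events(self, small_config, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        cfg = small_config.with_(n_subjects=2)
        simulate.generate_dataset(cfg, a, with_bold=False)
        simulate.generate_dataset(cfg, b, with_bold=False)
        for pa in sorted(a.rglob("*_events.tsv")):
            pb = b / pa.relative_to(a)
            assert pa.read_bytes() == pb.read_bytes()

    def test_refuses_nonempty_output(self, dataset_dir, small_config):
        with pytest.raises(FileExistsError):
            simulate.generate_dataset(small_config, dataset_dir)
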