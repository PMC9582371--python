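"""Design construction, orthogonalization, first-level fits, group inference."""

import warnings

import numpy as np
import pandas as pd
import pytest

from selfcontrol_fmri import glm, simulate
from selfcontrol_fmri.config import SimConfig
from selfcontrol_fmri.volumes import VolumeMap

from conftest import TEST_KW


def simple_events(n_trials=12, duration=2.0, spacing=14.0, start=10.0,
                  gv=None, h=None, t=None):
    ids = [f"stim{i:03d}" for i in range(n_trials)]
    rng = np.random.default_rng(99)
    gv = rng.integers(-2, 3, n_trials).astype(float) if gv is None else gv
    h = rng.integers(-2, 3, n_trials).astype(float) if h is None else h
    t = rng.integers(-2, 3, n_trials).astype(float) if t is None else t
    events = pd.DataFrame({
        "onset": start + np.arange(n_trials) * spacing,
        "duration": np.full(n_trials, duration),
        "trial_type": "decision",
        "stimulus_id": ids,
        "response": gv,
    })
    profile = pd.DataFrame({"stimulus_id": ids, "health": h, "taste": t,
                            "gv": gv})
    return events, profile


class TestHRF:
    def test_zero_at_onset_and_truncation(self):
        t = np.arange(0.0, 40.0, 0.1)
        h = glm.canonical_hrf(t)
        assert h[0] == 0.0
        assert np.all(h[t > 32.0] == 0.0)
        assert h.max() == pytest.approx(1.0)

    def test_peak_near_five_seconds(self):
        # mode of the response gamma (shape 6, scale 1) is 5 s; the small
        # undershoot subtraction shifts the argmax only slightly
        t = np.arange(0.0, 32.0, 0.1)
        h = glm.canonical_hrf(t)
        assert abs(t[np.argmax(h)] - 5.0) <= 0.3

    def test_matches_independent_canonical_model(self):
        """Agrees with nilearn's SPM-style canonical HRF (independent oracle)."""
        from nilearn.glm.first_level import spm_hrf
        t = np.arange(0.0, 32.0, 0.1)
        ours = glm.canonical_hrf(t)
        theirs = np.asarray(spm_hrf(0.1, oversampling=1, time_length=32.0))
        theirs = theirs[: len(ours)] / theirs.max()
        # nilearn samples on a slightly offset grid; shape must agree
        assert np.corrcoef(ours, theirs)[0, 1] > 0.999
        assert abs(t[np.argmax(ours)] - t[np.argmax(theirs)]) <= 0.2

    def test_negative_grid_rejected(self):
        with pytest.raises(ValueError):
            glm.canonical_hrf(np.array([-1.0, 0.0, 1.0]))


class TestOrthogonalization:
    def test_identical_modulators_second_zero(self):
        rng = np.random.default_rng(0)
        col = rng.standard_normal(100)
        out = glm.orthogonalize_modulators([col, col.copy()])
        assert np.allclose(out[1], 0.0, atol=1e-12)

    def test_orthogonal_inputs_unchanged(self):
        a = np.array([1.0, 0.0, 0.0, 1.0])
        b = np.array([0.0, 1.0, -1.0, 0.0])
        out = glm.orthogonalize_modulators([a, b])
        assert np.allclose(out[0], a, atol=1e-12)
        assert np.allclose(out[1], b, atol=1e-12)

    def test_projection_oracle(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal(200)
        m1 = rng.standard_normal(200)
        m2 = rng.standard_normal(200)
        out = glm.orthogonalize_modulators([base, m1, m2])
        assert abs(out[1] @ out[0]) < 1e-10
        assert abs(out[2] @ out[0]) < 1e-10
        assert abs(out[2] @ out[1]) < 1e-10
        # explicit least-squares residual oracle
        X = np.column_stack([base, m1])
        oracle = m2 - X @ np.linalg.lstsq(X, m2, rcond=None)[0]
        assert np.allclose(out[2], oracle, atol=1e-8)

    def test_zero_column_rejected(self):
        with pytest.raises(ValueError, match="zero norm"):
            glm.orthogonalize_modulators([np.zeros(10)])


class TestDesign:
    def test_single_trial_column_is_convolved_pulse(self):
        events, profile = simple_events(n_trials=1)
        motion = np.random.default_rng(0).standard_normal((130, 6)) * 0.1
        design = glm.build_design({"decision": events}, "2", motion, 2.0, 130,
                                  profile)
        pulse = glm.convolved_regressor(events["onset"].to_numpy(),
                                        events["duration"].to_numpy(),
                                        2.0, 130)
        level = {2.0: "strong_yes", 1.0: "yes", 0.0: "neutral",
                 -1.0: "no", -2.0: "strong_no"}[events["response"].iloc[0]]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert np.allclose(design.column(level), pulse)

    def test_glm1_column_roster(self, dataset):
        subject = dataset.subjects[0]
        design = glm.build_design(subject.events, "1", subject.motion,
                                  dataset.tr, dataset.n_volumes_per_run,
                                  subject.profile)
        boxcars = [n for n in design.names if n.endswith("_trials")]
        mods = [n for n in design.names if "_x_gv" in n]
        constants = [n for n in design.names if n.startswith("constant")]
        motion = [n for n in design.names if n.startswith("motion")]
        assert sorted(boxcars) == ["decision_trials", "health_trials",
                                   "taste_trials"]
        assert len(mods) == 3
        assert len(motion) == 6
        assert len(constants) == 3

    def test_zero_trial_condition_dropped_with_warning(self):
        events, profile = simple_events(gv=np.full(12, 2.0))
        motion = np.random.default_rng(0).standard_normal((130, 6)) * 0.1
        with pytest.warns(UserWarning, match="zero trials"):
            design = glm.build_design({"decision": events}, "2", motion, 2.0,
                                      130, profile)
        assert "strong_yes" in design.names
        assert "no" not in design.names
        assert any(s.name == "no" for s in design.dropped)

    def test_unknown_glm_id(self, dataset):
        subject = dataset.subjects[0]
        with pytest.raises(ValueError, match="unknown GLM id"):
            glm.build_design(subject.events, "9", subject.motion, dataset.tr,
                             dataset.n_volumes_per_run, subject.profile)

    def test_order_invariance_with_orthogonal_modulators(self):
        """With duration-weighted-orthogonal health/taste modulators the
        3a and 3b fits attribute identical betas to each modulator."""
        rng = np.random.default_rng(2)
        h = rng.standard_normal(14)
        t = rng.standard_normal(14)
        h = h - h.mean()
        t = t - t.mean() - (h @ t) / (h @ h) * h
        events, profile = simple_events(n_trials=14, h=np.clip(h, -2, 2),
                                        t=np.clip(t * 0 + t, -2, 2))
        profile["health"], profile["taste"] = h, t  # keep exact orthogonality
        motion = rng.standard_normal((130, 6)) * 0.1
        y = rng.standard_normal((130, 4))
        betas = {}
        for gid in ("3a", "3b"):
            design = glm.build_design({"decision": events}, gid, motion, 2.0,
                                      130, profile)
            fit = glm.fit_first_level(y, design)
            betas[gid] = {n: fit.betas[fit.names.index(n)]
                          for n in fit.names if "_x_" in n}
        for name, vals in betas["3a"].items():
            assert np.allclose(vals, betas["3b"][name], atol=1e-6)

    def test_correlated_modulators_shift_attribution(self):
        """With correlated modulators the first-entered one absorbs the
        shared signal: its beta is larger when entered first."""
        rng = np.random.default_rng(3)
        shared = rng.standard_normal(14)
        h = shared + 0.3 * rng.standard_normal(14)
        t = shared + 0.3 * rng.standard_normal(14)
        events, profile = simple_events(n_trials=14)
        profile["health"], profile["taste"] = h, t
        motion = rng.standard_normal((130, 6)) * 0.1
        signal = glm.convolved_regressor(
            events["onset"].to_numpy(), events["duration"].to_numpy(), 2.0,
            130, shared - shared.mean())
        y = (signal + 0.01 * rng.standard_normal(130))[:, None]
        out = {}
        for gid in ("3a", "3b"):
            design = glm.build_design({"decision": events}, gid, motion, 2.0,
                                      130, profile)
            fit = glm.fit_first_level(y, design)
            out[gid] = {n.split("_x_")[1]: fit.betas[fit.names.index(n), 0]
                        for n in fit.names if "_x_" in n}
        assert out["3a"]["health"] > out["3b"]["health"]
        assert out["3b"]["taste"] > out["3a"]["taste"]
        assert out["3a"]["health"] > 0 and out["3b"]["taste"] > 0

    def test_total_fit_unchanged_by_order(self):
        """Sequential orthogonalization reshuffles attribution but spans the
        same model space: 3a and 3b have identical residuals."""
        rng = np.random.default_rng(4)
        events, profile = simple_events(n_trials=14)
        motion = rng.standard_normal((130, 6)) * 0.1
        y = rng.standard_normal((130, 3))
        resid = {}
        for gid in ("3a", "3b"):
            design = glm.build_design({"decision": events}, gid, motion, 2.0,
                                      130, profile)
            fit = glm.fit_first_level(y, design, whiten=False)
            proj, _ = glm._highpass_projector(design)
            X = proj @ design.matrix
            resid[gid] = proj @ y - X @ fit.betas
        assert np.allclose(resid["3a"], resid["3b"], atol=1e-8)


class TestFirstLevel:
    def test_ar1_estimate_recovers_rho(self, stimuli, labels):
        cfg = SimConfig(effect_size_map="null", drift_amplitude=0.0,
                        ar1_rho=0.3, neural_fluct_sd=0.0, missing_prob=0.0,
                        **TEST_KW)
        rng = np.random.default_rng(0)
        rhos = []
        for i in range(5):
            sub = simulate.simulate_subject_dataset(
                cfg, stimuli, i, "NSC", rng, labels, blocks=("decision",))
            run = sub.runs["decision"]
            design = glm.build_design({"decision": sub.events["decision"]},
                                      "1", run.motion, cfg.tr,
                                      cfg.n_volumes_per_run, sub.profile)
            fit = glm.fit_first_level(run.data, design)
            rhos.append(fit.rho)
        assert abs(np.mean(rhos) - 0.3) < 0.05

    def test_whitened_residuals_are_white(self, stimuli, labels):
        cfg = SimConfig(effect_size_map="null", drift_amplitude=0.0,
                        ar1_rho=0.4, neural_fluct_sd=0.0, missing_prob=0.0,
                        **TEST_KW)
        rng = np.random.default_rng(1)
        sub = simulate.simulate_subject_dataset(
            cfg, stimuli, 0, "NSC", rng, labels, blocks=("decision",))
        run = sub.runs["decision"]
        design = glm.build_design({"decision": sub.events["decision"]}, "1",
                                  run.motion, cfg.tr, cfg.n_volumes_per_run,
                                  sub.profile)
        fit = glm.fit_first_level(run.data, design)
        # refit the whitened model by hand and check residual autocorrelation
        proj, _ = glm._highpass_projector(design)
        Y = proj @ run.data.reshape(-1, cfg.n_volumes_per_run).T
        X = proj @ design.matrix
        rho = fit.rho
        Yw = Y[1:] - rho * Y[:-1]
        Xw = X[1:] - rho * X[:-1]
        resid = Yw - Xw @ np.linalg.lstsq(Xw, Yw, rcond=None)[0]
        lag1 = np.mean(np.sum(resid[1:] * resid[:-1], axis=0)
                       / np.sum(resid[:-1] ** 2, axis=0))
        # residual-forming projection pushes the lag-1 ratio slightly
        # negative even at the true rho; near-zero is the expectation
        assert abs(lag1) < 0.1

    def test_rank_deficiency_reported(self):
        events, profile = simple_events()
        motion = np.zeros((130, 6))
        with pytest.raises(ValueError, match="rank deficient"):
            design = glm.build_design({"decision": events}, "2", motion, 2.0,
                                      130, profile)
            glm.fit_first_level(np.zeros((130, 2)), design)


@pytest.fixture(scope="module")
def fit():
    rng = np.random.default_rng(0)
    events, profile = simple_events()
    motion = rng.standard_normal((130, 6)) * 0.1
    design = glm.build_design({"decision": events}, "1", motion, 2.0, 130,
                              profile)
    return glm.fit_first_level(rng.standard_normal((130, 6)), design)


class TestContrasts:

    def test_unit_weight_returns_beta(self, fit):
        idx = fit.names.index("decision_trials_x_gv")
        _, beta_map = glm.contrast_map(fit, {"decision_trials_x_gv": 1.0})
        assert np.allclose(beta_map.flat, fit.betas[idx])

    def test_negation(self, fit):
        t1, _ = glm.contrast_map(fit, {"decision_trials_x_gv": 1.0})
        t2, _ = glm.contrast_map(fit, {"decision_trials_x_gv": -1.0})
        assert np.allclose(t1.flat, -t2.flat)

    def test_linearity(self, fit):
        _, b1 = glm.contrast_map(fit, {"decision_trials": 1.0})
        _, b2 = glm.contrast_map(fit, {"decision_trials_x_gv": 1.0})
        _, b12 = glm.contrast_map(fit, {"decision_trials": 1.0,
                                        "decision_trials_x_gv": 1.0})
        assert np.allclose(b12.flat, b1.flat + b2.flat)

    def test_unknown_regressor_rejected(self, fit):
        with pytest.raises(ValueError, match="unknown regressor"):
            glm.contrast_map(fit, {"nonexistent": 1.0})


def _maps(rng, n, mask_shape=(5, 5, 2), offset=0.0):
    mask = np.ones(mask_shape, dtype=bool)
    return [VolumeMap(offset + rng.standard_normal(mask_shape), np.eye(4),
                      mask, "beta") for _ in range(n)]


class TestGroupInference:
    def test_degenerate_constant_maps_flagged(self):
        mask = np.ones((3, 3, 1), dtype=bool)
        maps = [VolumeMap(np.full((3, 3, 1), 2.0), np.eye(4), mask, "beta")
                for _ in range(4)]
        t_map, p_map, _ = glm.group_ttest(maps)
        assert np.isnan(t_map.flat).all()

    def test_two_sample_df(self):
        rng = np.random.default_rng(0)
        _, _, df = glm.group_ttest(_maps(rng, 15), _maps(rng, 65))
        assert df == 78

    def test_null_type_one_error(self):
        rng = np.random.default_rng(1)
        rates = []
        for _ in range(30):
            _, p_map, _ = glm.group_ttest(_maps(rng, 8), _maps(rng, 8))
            rates.append(np.mean(p_map.flat < 0.05))
        assert abs(np.mean(rates) - 0.05) < 0.02

    def test_mask_mismatch_rejected(self):
        rng = np.random.default_rng(2)
        a = _maps(rng, 3)
        b = _maps(rng, 3, mask_shape=(4, 4, 2))
        with pytest.raises(ValueError, match="common grid"):
            glm.group_ttest(a, b)


class TestThresholding:
    def _p_map(self, p_values, shape=(4, 4, 2)):
        mask = np.ones(shape, dtype=bool)
        vol = np.asarray(p_values, dtype=float).reshape(shape)
        return VolumeMap(vol, np.diag([3.0, 3.0, 3.0, 1.0]), mask, "p")

    def test_all_ones_no_clusters(self):
        table, binary = glm.threshold_map(self._p_map(np.ones(32)), "unc_001")
        assert len(table) == 0
        assert binary.values.sum() == 0

    def test_single_voxel_cluster(self):
        p = np.ones(32)
        p[5] = 1e-6
        table, _ = glm.threshold_map(self._p_map(p), "unc_001")
        assert len(table) == 1
        assert table["extent"].iloc[0] == 1

    def test_peak_coordinates_in_mm(self):
        p = np.ones(32)
        p[0] = 1e-6
        table, _ = glm.threshold_map(self._p_map(p), "unc_005")
        assert (table[["peak_x_mm", "peak_y_mm", "peak_z_mm"]].iloc[0]
                == 0.0).all()

    def test_fdr_null_controls_discoveries(self):
        rng = np.random.default_rng(0)
        any_hit = 0
        for _ in range(200):
            p = rng.random(32)
            table, _ = glm.threshold_map(self._p_map(p), "fdr_05")
            any_hit += int(len(table) > 0)
        # on full-null maps the BH family-wise false-discovery proportion
        # is the rejection indicator; its mean stays near q = .05
        assert any_hit / 200 < 0.1

    def test_empty_mask_rejected(self):
        mask = np.zeros((2, 2, 2), dtype=bool)
        vm = VolumeMap(np.full((2, 2, 2), np.nan), np.eye(4), mask, "p")
        with pytest.raises(ValueError, match="empty"):
            glm.threshold_map(vm, "unc_001")
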