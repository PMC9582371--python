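"""Verification experiments exercising the pipeline against known truth.

Each function runs a self-contained simulation experiment at desk scale and
returns the scalar quantities that characterize the pipeline's statistical
behavior: classifier closure, OLS fidelity, modulator-order effects,
amplitude recovery and null calibration, circular peak-voxel selection bias,
FDR control, PPI coupling recovery, and deconvolution accuracy. The
analysis scripts and the acceptance harness both drive these functions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from . import behavior, glm, ppi, roi, simulate
from .config import SimConfig
from .volumes import RegionMask

# Desk-scale study conditions used throughout: 16 stimuli per run keeps the
# task's 4-15 s ITIs inside a 130-volume (260 s) run with wide margin, and a
# 12^3 grid keeps all labeled regions multi-voxel.
DESK_KW = dict(n_stimuli=16, n_volumes_per_run=130, grid_shape=(12, 12, 12))


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed % 2**31, stream]))


# --------------------------------------------------------------------------
# Behavior
# --------------------------------------------------------------------------

def boundary_profile() -> pd.DataFrame:
    """A participant succeeding on exactly half of the conflict trials."""
    return pd.DataFrame({
        "stimulus_id": [f"stim{i:03d}" for i in range(8)],
        "health": [-1.0, -1, -1, -1, 2, 1, 0, -2],
        "taste": [1.0, 1, 2, 2, 1, 0, 0, -2],
        "gv": [-1.0, 1, -2, 2, 2, -1, 0, -2],
    })


def classification_closure(n_subjects: int = 50, seed: int = 0) -> dict:
    """Noise-free SC-truth subjects must classify as SC under both rules;
    a boundary subject (rate exactly .5) separates the two rules."""
    cfg = SimConfig(noise_sd=0.0, rating_noise_sd=0.0, decision_noise=0.0,
                    missing_prob=0.0, **DESK_KW)
    rng = _rng(seed, 1)
    hits = {"three_criteria": 0, "one_criterion": 0}
    for i in range(n_subjects):
        stim = simulate.simulate_stimuli(cfg, rng)
        prof = simulate.simulate_subject(cfg, stim, "SC", rng)
        for mode in hits:
            hits[mode] += int(
                behavior.classify_participant(prof, mode).label == "SC")
    bound = boundary_profile()
    one = behavior.classify_participant(bound, "one_criterion")
    three = behavior.classify_participant(bound, "three_criteria")
    return {
        "rate_three_criteria": hits["three_criteria"] / n_subjects,
        "rate_one_criterion": hits["one_criterion"] / n_subjects,
        "boundary_rate": one.criterion1_rate,
        "boundary_one_criterion_sc": one.label == "SC",
        "boundary_three_criteria_sc": three.label == "SC",
        "n": n_subjects,
    }


def ols_oracle_check(n_instances: int = 100, seed: int = 0) -> dict:
    """Worst-case deviation of choice_regressions from the closed-form
    normal-equation solution over random instances."""
    rng = _rng(seed, 2)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(5, 40))
        prof = pd.DataFrame({
            "stimulus_id": [f"s{i}" for i in range(n)],
            "health": np.clip(rng.standard_normal(n), -2, 2),
            "taste": np.clip(rng.standard_normal(n), -2, 2),
            "gv": np.clip(rng.standard_normal(n), -2, 2),
        })
        b_h, b_t, _, _ = behavior.choice_regressions(prof)
        X = np.column_stack([np.ones(n), prof["health"], prof["taste"]])
        y = prof["gv"].to_numpy()
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        worst = max(worst, abs(b_h - oracle[1]), abs(b_t - oracle[2]))
    return {"max_abs_diff": worst, "n": n_instances}


# --------------------------------------------------------------------------
# Design algebra
# --------------------------------------------------------------------------

def _modulator_design_data(rng, corr: float, n_trials: int = 14,
                           n_volumes: int = 130):
    h = rng.standard_normal(n_trials)
    t_raw = rng.standard_normal(n_trials)
    h = h - h.mean()
    t_orth = t_raw - t_raw.mean() - (h @ t_raw) / (h @ h) * h
    if corr == 0.0:
        t = t_orth
    else:
        t = corr * h / h.std() + np.sqrt(1 - corr**2) * t_orth / t_orth.std()
    ids = [f"stim{i:03d}" for i in range(n_trials)]
    events = pd.DataFrame({
        "onset": 10.0 + np.arange(n_trials) * 14.0,
        "duration": np.full(n_trials, 2.0),
        "trial_type": "decision",
        "stimulus_id": ids,
        "response": np.sign(h),
    })
    profile = pd.DataFrame({"stimulus_id": ids, "health": h, "taste": t,
                            "gv": np.sign(h)})
    motion = rng.standard_normal((n_volumes, 6)) * 0.1
    return events, profile, motion


def orthogonalization_order_check(seed: int = 0) -> dict:
    """Order effects of sequential modulator orthogonalization.

    With duration-weighted-orthogonal modulators, entering health or taste
    first leaves every modulator beta unchanged. With correlation 0.6 the
    first-entered modulator absorbs the shared signal, so its beta exceeds
    the beta it gets when entered second.
    """
    rng = _rng(seed, 3)
    n_volumes = 130
    # exact-orthogonality branch
    events, profile, motion = _modulator_design_data(rng, corr=0.0)
    y = rng.standard_normal((n_volumes, 4))
    betas = {}
    for gid in ("3a", "3b"):
        design = glm.build_design({"decision": events}, gid, motion, 2.0,
                                  n_volumes, profile)
        fit = glm.fit_first_level(y, design)
        betas[gid] = {n: fit.betas[fit.names.index(n)]
                      for n in fit.names if "_x_" in n}
    max_diff = max(float(np.max(np.abs(betas["3a"][n] - betas["3b"][n])))
                   for n in betas["3a"])

    # correlated branch: data carry the shared component
    events, profile, motion = _modulator_design_data(rng, corr=0.6)
    shared = (profile["health"] / profile["health"].std()
              + profile["taste"] / profile["taste"].std()).to_numpy() / 2
    signal = glm.convolved_regressor(
        events["onset"].to_numpy(), events["duration"].to_numpy(), 2.0,
        n_volumes, shared - shared.mean())
    y = (signal + 0.01 * rng.standard_normal(n_volumes))[:, None]
    out = {}
    for gid in ("3a", "3b"):
        design = glm.build_design({"decision": events}, gid, motion, 2.0,
                                  n_volumes, profile)
        fit = glm.fit_first_level(y, design)
        out[gid] = {n.split("_x_")[1]: float(fit.betas[fit.names.index(n), 0])
                    for n in fit.names if "_x_" in n}
    return {
        "orthogonal_max_beta_diff": max_diff,
        "health_beta_entered_first": out["3a"]["health"],
        "health_beta_entered_second": out["3b"]["health"],
        "taste_beta_entered_first": out["3b"]["taste"],
        "taste_beta_entered_second": out["3a"]["taste"],
        "first_absorbs_shared": (out["3a"]["health"] > out["3b"]["health"]
                                 and out["3b"]["taste"] > out["3a"]["taste"]
                                 and out["3a"]["health"] > 0
                                 and out["3b"]["taste"] > 0),
    }


# --------------------------------------------------------------------------
# Recovery and calibration
# --------------------------------------------------------------------------

def recovery_experiment(n_subjects: int = 30, n_reps: int = 20,
                        seed: int = 0) -> dict:
    """Group-level recovery of the vmPFC goal-value amplitude.

    For each repetition, simulate ``n_subjects`` SC subjects at the strong
    single-channel preset (vmPFC goal value only), fit GLM1 per subject
    (unsmoothed), and run the one-sample group t test on the per-subject
    vmPFC mask-mean beta (significance at p < .001) and per-voxel tests on
    the null white-matter region (alpha = .05).
    """
    cfg = SimConfig(effect_size_map="strong", missing_prob=0.0, **DESK_KW)
    labels = simulate.make_region_labels(cfg.grid_shape)
    vm, wm = labels == 1, labels == 5
    rng = _rng(seed, 4)
    significant = 0
    wm_rejections = 0
    wm_tests = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep in range(n_reps):
            stim = simulate.simulate_stimuli(cfg, rng)
            vm_means, maps = [], []
            for i in range(n_subjects):
                sub = simulate.simulate_subject_dataset(
                    cfg, stim, i, "SC", rng, labels, blocks=("decision",))
                run = sub.runs["decision"]
                design = glm.build_design(
                    {"decision": sub.events["decision"]}, "1", run.motion,
                    cfg.tr, cfg.n_volumes_per_run, sub.profile)
                fit = glm.fit_first_level(run.data, design)
                beta = fit.beta_map("decision_trials_x_gv")
                vm_means.append(float(np.nanmean(beta.values[vm])))
                maps.append(beta)
            _, p = stats.ttest_1samp(vm_means, 0.0)
            significant += int(p < 0.001 and np.mean(vm_means) > 0)
            _, p_map, _ = glm.group_ttest(maps)
            wm_p = p_map.values[wm]
            wm_rejections += int(np.sum(wm_p < 0.05))
            wm_tests += wm_p.size
    return {
        "significant_fraction": significant / n_reps,
        "white_matter_fpr": wm_rejections / wm_tests,
        "n_wm_tests": wm_tests,
        "n": n_subjects * n_reps,
    }


def circularity_experiment(n_subjects: int = 20, mask_size: int = 50,
                           n_sim: int = 1000, seed: int = 0) -> dict:
    """Peak-voxel vs mean-over-mask rejection rates on a null region."""
    rng = _rng(seed, 5)
    return roi.selection_bias_experiment(n_subjects, mask_size, n_sim, rng)


def fdr_calibration(n_sim: int = 500, n_voxels: int = 400,
                    n_subjects: int = 12, seed: int = 0) -> dict:
    """Empirical false-discovery proportion of BH at q=.05 on null maps."""
    rng = _rng(seed, 6)
    mask = np.ones((n_voxels, 1, 1), dtype=bool)
    affine = np.eye(4)
    fdp = []
    from .volumes import VolumeMap
    for _ in range(n_sim):
        maps = [VolumeMap(rng.standard_normal((n_voxels, 1, 1)), affine,
                          mask, "beta") for _ in range(n_subjects)]
        _, p_map, _ = glm.group_ttest(maps)
        table, binary = glm.threshold_map(p_map, "fdr_05")
        n_disc = int(binary.values.sum())
        fdp.append(1.0 if n_disc > 0 else 0.0)  # all discoveries are false
    return {"empirical_fdr": float(np.mean(fdp)), "n_sim": n_sim}


def ppi_recovery(n_sim: int = 20, n_subjects: int = 6, seed: int = 0,
                 null: bool = False) -> dict:
    """Sign recovery of the IFG coupling modulation (or null calibration).

    Each simulation is a small group study: per subject, localize the dlPFC
    seed, run the PPI regression, and average the interaction beta over the
    IFG region; the group-level one-sample t decides recovery (one-sided
    positive at p < .05) or, under the null (coupling amplitude 0),
    a two-sided false positive at alpha = .05.
    """
    effects = {"vmpfc": {"decision_gv": 1.0},
               "dlpfc": {"unhealthy": 1.2, "healthy": 0.3}}
    if not null:
        effects["ifg"] = {"ppi_unhealthy": 0.8}
    cfg = SimConfig(effect_size_map=effects, missing_prob=0.0, **DESK_KW)
    labels = simulate.make_region_labels(cfg.grid_shape)
    dlpfc = RegionMask(labels == 3, "dlpfc", cfg.affine, "meta_analytic")
    ifg = labels == 4
    rng = _rng(seed, 7)
    positive = 0
    rejections = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for sim in range(n_sim):
            stim = simulate.simulate_stimuli(cfg, rng)
            means = []
            for i in range(n_subjects):
                sub = simulate.simulate_subject_dataset(
                    cfg, stim, i, "NSC", rng, labels, blocks=("decision",))
                run = sub.runs["decision"]
                seed_ts = ppi.extract_seed(
                    run.data, sub.events["decision"], sub.profile,
                    run.motion, dlpfc, cfg.tr)
                _, beta = ppi.run_ppi(
                    run.data, seed_ts, sub.events["decision"], sub.profile,
                    run.motion, cfg.tr, mask=ifg, affine=cfg.affine)
                means.append(float(np.nanmean(beta.flat)))
            t, p = stats.ttest_1samp(means, 0.0)
            positive += int(np.mean(means) > 0 and p / 2 < 0.05)
            rejections += int(p < 0.05)
    if null:
        return {"rejection_rate": rejections / n_sim, "n_sim": n_sim}
    return {"sign_recovery_rate": positive / n_sim, "n_sim": n_sim}


def deconvolution_roundtrip(n_volumes: int = 200, tr: float = 2.0) -> dict:
    """Round-trip error of ridge deconvolution on a band-limited signal."""
    t = np.arange(n_volumes) * tr
    x = np.sin(2 * np.pi * t / 60.0) + 0.5 * np.cos(2 * np.pi * t / 45.0)
    err = ppi.roundtrip_relative_error(x, tr)
    return {"relative_error": err, "n": n_volumes}
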