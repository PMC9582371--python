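"""Synthetic dataset generator for the food self-control experiment.

The generator produces a BIDS-like dataset — per-subject events tables for
the three task blocks (health rating, taste rating, decision), 4D BOLD
volumes on a common 3 mm grid, motion traces, region masks, and a
ground-truth sidecar — whose statistical structure embodies the hypotheses
the downstream analyses test:

* food stimuli carry latent healthiness and tastiness traits, approximately
  uncorrelated, calibrated so the 5-point (-2..+2) discretized ratings have
  mean health near -0.35 (SD 1.41) and mean taste near 0.57 (SD 1.10);
* each subject decides via a weighted utility u = w_h * H + w_t * T with
  ordered-logistic noise; self-controllers (SC) weight health over taste and
  non-self-controllers (NSC) the reverse;
* vmPFC carries an integrated goal-value BOLD signal during decisions (plus
  group-dependent health/taste attribute signals), caudate a weaker value
  signal, dlPFC responds to unhealthy foods and serves as the PPI seed, IFG
  couples to the dlPFC seed specifically on unhealthy trials, and white
  matter carries no task signal at all (the circularity control);
* BOLD noise is AR(1) Gaussian plus low-frequency cosine drift entirely
  below the 1/128 Hz high-pass cutoff, so filtering removes it exactly.

Trial timing follows the task: a response-limited 4 s stimulus window
(reaction times truncated log-normal), 0.5 s feedback (recorded but never
modeled), and a uniform 4-15 s inter-trial interval.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from functools import lru_cache
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import optimize, signal, stats

from . import glm
from .config import CHANNELS, REGIONS, SimConfig

FEEDBACK_S = 0.5
ITI_LOW_S, ITI_HIGH_S = 4.0, 15.0
MAX_RT_S = 4.0
RATING_CUTS = np.array([-1.5, -0.5, 0.5, 1.5])

BLOCKS = ("health", "taste", "decision")

# Fractional bounding boxes of the labeled regions on the common grid
# (lo/hi fractions per axis). Blocks are disjoint by construction.
_REGION_BOXES = {
    "vmpfc": ((0.35, 0.55), (0.60, 0.80), (0.15, 0.35)),
    "caudate": ((0.40, 0.55), (0.40, 0.55), (0.40, 0.55)),
    "dlpfc": ((0.10, 0.30), (0.60, 0.80), (0.60, 0.80)),
    "ifg": ((0.10, 0.25), (0.75, 0.90), (0.40, 0.55)),
    "white_matter": ((0.65, 0.90), (0.15, 0.45), (0.40, 0.60)),
}
REGION_CODES = {"background": 0, "vmpfc": 1, "caudate": 2, "dlpfc": 3,
                "ifg": 4, "white_matter": 5}


def discretize_rating(x: np.ndarray) -> np.ndarray:
    """Map a continuous latent value onto the -2..+2 five-point scale.

    Fixed symmetric cut points at +-0.5 and +-1.5 on the latent scale.
    """
    return (np.digitize(np.asarray(x, dtype=float), RATING_CUTS) - 2).astype(float)


def _discrete_moments(mu: float, sigma: float) -> tuple[float, float]:
    """Mean and SD of a discretized N(mu, sigma) latent rating."""
    edges = np.concatenate([[-np.inf], RATING_CUTS, [np.inf]])
    cdf = stats.norm.cdf(edges, mu, sigma)
    p = np.diff(cdf)
    levels = np.arange(-2, 3)
    mean = float(p @ levels)
    var = float(p @ (levels - mean) ** 2)
    return mean, np.sqrt(var)


@lru_cache(maxsize=None)
def latent_normal_for_discrete(target_mean: float,
                               target_sd: float) -> tuple[float, float]:
    """Latent-normal (mu, sigma) whose discretized ratings match target moments."""

    def loss(theta):
        mu, log_sigma = theta
        m, s = _discrete_moments(mu, np.exp(log_sigma))
        return [m - target_mean, s - target_sd]

    sol = optimize.least_squares(loss, x0=[target_mean, np.log(target_sd)],
                                 xtol=1e-12, ftol=1e-12)
    mu, sigma = sol.x[0], float(np.exp(sol.x[1]))
    m, s = _discrete_moments(mu, sigma)
    if abs(m - target_mean) > 0.02 or abs(s - target_sd) > 0.02:
        raise RuntimeError(
            f"latent moment matching failed: got ({m:.3f}, {s:.3f}) for "
            f"target ({target_mean}, {target_sd})"
        )
    return float(mu), sigma


# --------------------------------------------------------------------------
# Stimuli and behavior
# --------------------------------------------------------------------------

def simulate_stimuli(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-stimulus latent healthiness and tastiness traits.

    Latents are bivariate normal with the configured correlation; marginal
    moments are calibrated so that discretized ratings match the stimulus
    statistics of the task (wide, slightly unhealthy health range; mildly
    positive taste).
    """
    if config.n_stimuli < 2:
        raise ValueError("need at least two stimuli")
    rho = config.stim_ht_correlation
    mu_h, sd_h = latent_normal_for_discrete(config.stim_health_mean,
                                            config.stim_health_sd)
    mu_t, sd_t = latent_normal_for_discrete(config.stim_taste_mean,
                                            config.stim_taste_sd)
    z = rng.standard_normal((config.n_stimuli, 2))
    h = mu_h + sd_h * z[:, 0]
    t = mu_t + sd_t * (rho * z[:, 0] + np.sqrt(1 - rho ** 2) * z[:, 1])
    return pd.DataFrame({
        "stimulus_id": [f"stim{i:03d}" for i in range(config.n_stimuli)],
        "h_latent": h,
        "t_latent": t,
    })


def simulate_subject(
    config: SimConfig,
    stimuli: pd.DataFrame,
    true_class: str,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate one subject's ratings and decisions.

    Health and taste ratings are the stimulus latents plus subject-level
    normal noise, discretized to -2..+2. The decision follows an
    ordered-choice model on u = w_h * H + w_t * T + eps with logistic noise,
    mapped through the same fixed cut points. Each response is independently
    missing with the configured probability.
    """
    if true_class not in ("SC", "NSC"):
        raise ValueError(f"true_class must be 'SC' or 'NSC', got {true_class!r}")
    if true_class == "SC":
        w_h, w_t = config.w_health_sc, config.w_taste_sc
    else:
        w_h, w_t = config.w_health_nsc, config.w_taste_nsc
    if not (np.isfinite(w_h) and np.isfinite(w_t)):
        raise ValueError("choice weights must be finite")

    n = len(stimuli)
    h = discretize_rating(
        stimuli["h_latent"].to_numpy()
        + config.rating_noise_sd * rng.standard_normal(n))
    t = discretize_rating(
        stimuli["t_latent"].to_numpy()
        + config.rating_noise_sd * rng.standard_normal(n))
    eps = (rng.logistic(0.0, config.decision_noise, n)
           if config.decision_noise > 0 else np.zeros(n))
    u = w_h * h + w_t * t + eps
    gv = discretize_rating(u)

    profile = pd.DataFrame({
        "stimulus_id": stimuli["stimulus_id"].to_numpy(),
        "health": h,
        "taste": t,
        "gv": gv,
    })
    if config.missing_prob > 0:
        for col in ("health", "taste", "gv"):
            miss = rng.random(n) < config.missing_prob
            profile.loc[miss, col] = np.nan
    profile.attrs["true_class"] = true_class
    profile.attrs["w_health"] = w_h
    profile.attrs["w_taste"] = w_t
    return profile


def simulate_timing(
    n_trials: int,
    rng: np.random.Generator,
    config: SimConfig,
) -> pd.DataFrame:
    """Trial onsets, reaction times, and inter-trial intervals for one run.

    Onsets are strictly increasing; each trial occupies a response-limited
    stimulus window (RT in (0, 4] s, truncated log-normal), followed by
    0.5 s feedback and a uniform 4-15 s ITI. Raises if a trial would run
    past the end of the run.
    """
    if n_trials < 1:
        raise ValueError("need at least one trial")
    run_length = config.n_volumes_per_run * config.tr
    rts = np.empty(n_trials)
    for i in range(n_trials):
        rt = np.inf
        while rt > MAX_RT_S:
            rt = rng.lognormal(config.rt_log_mean, config.rt_log_sd)
        rts[i] = rt
    itis = rng.uniform(ITI_LOW_S, ITI_HIGH_S, n_trials)
    onsets = np.empty(n_trials)
    t = config.t_start
    for i in range(n_trials):
        onsets[i] = t
        end = t + rts[i] + FEEDBACK_S
        if end > run_length:
            raise ValueError(
                f"trial {i} ends at {end:.1f} s, past the run length "
                f"{run_length:.1f} s"
            )
        t = end + itis[i]
    return pd.DataFrame({
        "onset": onsets,
        "rt": rts,
        "feedback_onset": onsets + rts,
        "iti": itis,
    })


def simulate_motion(n_volumes: int, rng: np.random.Generator,
                    scale: float = 0.2) -> np.ndarray:
    """Six autocorrelated motion traces (AR(1) excursions, amplitude <= 1)."""
    rho = 0.97
    innovations = rng.standard_normal((n_volumes, 6))
    m = signal.lfilter([1.0], [1.0, -rho], innovations, axis=0)
    m *= scale * np.sqrt(1 - rho ** 2)
    return np.clip(m, -1.0, 1.0)


# --------------------------------------------------------------------------
# Geometry and ground truth
# --------------------------------------------------------------------------

def make_region_labels(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Integer region-label volume on the grid (codes in REGION_CODES)."""
    labels = np.zeros(grid_shape, dtype=np.int16)
    for name, box in _REGION_BOXES.items():
        slices = []
        for dim, (lo, hi) in zip(grid_shape, box):
            a, b = int(round(lo * dim)), int(round(hi * dim))
            slices.append(slice(a, max(b, a + 1)))
        region = labels[tuple(slices)]
        if (region != 0).any():
            raise RuntimeError(f"region {name} overlaps an earlier region")
        labels[tuple(slices)] = REGION_CODES[name]
    return labels


@dataclass
class GroundTruth:
    """True generative quantities of a simulated dataset."""

    classes: dict[str, str]                 # subject id -> SC | NSC
    weights: dict[str, tuple[float, float]]  # subject id -> (w_h, w_t)
    stimuli: dict[str, tuple[float, float]]  # stimulus id -> (H*, T*)
    amplitudes: dict[str, dict[str, dict[str, float]]]  # group->region->channel
    region_codes: dict[str, int]
    seed: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _resolved_amplitudes(config: SimConfig) -> dict[str, dict[str, dict[str, float]]]:
    out: dict[str, dict[str, dict[str, float]]] = {}
    for group in ("SC", "NSC"):
        out[group] = {}
        for region in REGIONS:
            amps = {
                ch: config.amplitude(region, ch, group)
                for ch in CHANNELS
                if config.amplitude(region, ch, group) != 0.0
            }
            if amps:
                out[group][region] = amps
    return out


# --------------------------------------------------------------------------
# BOLD forward model
# --------------------------------------------------------------------------

def _stationary_ar1(n: int, rho: float, sd: float,
                    rng: np.random.Generator, shape: tuple = ()) -> np.ndarray:
    """Stationary AR(1) noise: x_0 ~ N(0, sd^2), x_t = rho x_{t-1} + w_t."""
    x = np.empty(shape + (n,))
    x[..., 0] = rng.standard_normal(shape) * sd
    if n > 1:
        w = rng.standard_normal(shape + (n - 1,)) * sd * np.sqrt(1 - rho ** 2)
        if rho == 0:
            x[..., 1:] = w
        else:
            rest = signal.lfilter([1.0], [1.0, -rho], w, axis=-1,
                                  zi=(rho * x[..., 0])[..., None])[0]
            x[..., 1:] = rest
    return x


def _hrf_convolve_tr(series: np.ndarray, tr: float) -> np.ndarray:
    """HRF convolution of a TR-resolution series."""
    kernel = glm.canonical_hrf(np.arange(0.0, glm.HRF_LENGTH_S + tr, tr))
    return np.convolve(series, kernel)[: len(series)] * tr


def _truth_channels(
    block: str,
    events: pd.DataFrame,
    profile: pd.DataFrame,
    config: SimConfig,
) -> dict[str, np.ndarray]:
    """Unconvolved microtime signal channels for one run."""
    tr, n_vol = config.tr, config.n_volumes_per_run
    onsets = events["onset"].to_numpy()
    durs = events["duration"].to_numpy()
    prof = profile.set_index("stimulus_id")
    gv = prof["gv"].reindex(events["stimulus_id"]).to_numpy(dtype=float)
    h = prof["health"].reindex(events["stimulus_id"]).to_numpy(dtype=float)
    t = prof["taste"].reindex(events["stimulus_id"]).to_numpy(dtype=float)

    channels: dict[str, np.ndarray] = {}

    def boxcar(rows):
        return glm.fine_grid_column(onsets[rows], durs[rows], tr, n_vol)

    def modulated(rows, values):
        centered = values[rows] - values[rows].mean()
        return glm.fine_grid_column(onsets[rows], durs[rows], tr, n_vol,
                                    centered)

    channels["task"] = boxcar(np.ones(len(events), dtype=bool))
    gv_ok = ~np.isnan(gv)
    if block == "decision" and gv_ok.any():
        channels["decision_gv"] = modulated(gv_ok, gv)
    if block == "taste" and gv_ok.any():
        channels["taste_gv"] = modulated(gv_ok, gv)
    if block == "health" and gv_ok.any():
        channels["health_gv"] = modulated(gv_ok, gv)
    if block == "decision":
        ht_ok = ~np.isnan(h) & ~np.isnan(t)
        if ht_ok.any():
            channels["decision_health"] = modulated(ht_ok, h)
            channels["decision_taste"] = modulated(ht_ok, t)
        channels["unhealthy"] = boxcar(h < 0)
        channels["healthy"] = boxcar(h > 0)
        conds = glm._glm_conditions("4", {"decision": events}, profile)
        for cond in conds:
            if cond["name"] in ("sc_success", "sc_failure") and cond["rows"].any():
                channels[cond["name"]] = boxcar(cond["rows"])
    return {k: v for k, v in channels.items() if np.any(v)}


@dataclass
class BoldRun:
    """One simulated functional run."""

    block: str
    data: np.ndarray            # 4D (x, y, z, t)
    motion: np.ndarray          # (t, 6)
    affine: np.ndarray
    seed_neural: np.ndarray     # dlPFC neural series at TR resolution


def simulate_bold(
    block: str,
    events: pd.DataFrame,
    profile: pd.DataFrame,
    config: SimConfig,
    group: str,
    labels: np.ndarray,
    rng: np.random.Generator,
) -> BoldRun:
    """Forward-model one run of BOLD data on the labeled grid.

    Signal per region is the sum over ground-truth channels of amplitude
    times the HRF-convolved channel regressor; the dlPFC region additionally
    carries an intrinsic AR(1) neural fluctuation (shared across its voxels),
    and regions with a ``ppi_unhealthy`` amplitude receive the convolved
    product of the (centered) dlPFC neural series with the unhealthy-trial
    indicator. White matter has zero amplitude on every channel by
    construction. Drift is a low-frequency cosine sum below the 1/128 Hz
    high-pass cutoff with per-voxel random coefficients; noise is stationary
    AR(1) Gaussian per voxel. Motion traces are pure nuisance (no coupling
    into the signal).
    """
    tr, n_vol = config.tr, config.n_volumes_per_run
    os_ = glm.OVERSAMPLING
    fine = _truth_channels(block, events, profile, config)
    conv = {name: glm.convolve_fine(col, tr, n_vol) for name, col in fine.items()}
    neural_tr = {name: col.reshape(n_vol, os_).mean(axis=1)
                 for name, col in fine.items()}

    # dlPFC neural series: its task channels plus intrinsic fluctuation.
    fluct = _stationary_ar1(n_vol, 0.5, config.neural_fluct_sd, rng)
    seed_neural = fluct.copy()
    for name, series in neural_tr.items():
        seed_neural = seed_neural + config.amplitude("dlpfc", name, group) * series
    ppi_base = None
    if "unhealthy" in neural_tr:
        inter = (seed_neural - seed_neural.mean()) * neural_tr["unhealthy"]
        ppi_base = _hrf_convolve_tr(inter, tr)

    n_vox = int(np.prod(config.grid_shape))
    flat_labels = labels.reshape(-1)
    data = np.zeros((n_vox, n_vol))

    code_to_name = {v: k for k, v in REGION_CODES.items()}
    for code in np.unique(flat_labels):
        region = code_to_name[int(code)]
        sig = np.zeros(n_vol)
        for name, series in conv.items():
            sig += config.amplitude(region, name, group) * series
        if region == "dlpfc":
            sig = sig + _hrf_convolve_tr(fluct, tr)
        g = config.amplitude(region, "ppi_unhealthy", group)
        if g != 0.0 and ppi_base is not None:
            sig = sig + g * ppi_base
        data[flat_labels == code] = sig

    # Drift: cosines strictly below the high-pass cutoff, random per voxel.
    basis = glm.dct_highpass_basis(n_vol, tr)
    if basis.shape[1]:
        coeffs = rng.standard_normal((n_vox, basis.shape[1]))
        data += config.drift_amplitude * coeffs @ basis.T
    if config.noise_sd > 0:
        data += _stationary_ar1(n_vol, config.ar1_rho, config.noise_sd, rng,
                                shape=(n_vox,))
    data += config.baseline
    motion = simulate_motion(n_vol, rng, config.motion_scale)
    return BoldRun(block, data.reshape(config.grid_shape + (n_vol,)),
                   motion, config.affine, seed_neural)


# --------------------------------------------------------------------------
# Subject- and dataset-level generation
# --------------------------------------------------------------------------

def block_order(subject_index: int) -> tuple[str, str, str]:
    """Counterbalanced block order: rating blocks first, decisions last.

    Even-indexed subjects start with the health block, odd-indexed subjects
    with the taste block, so half of any even-sized sample has each order.
    """
    if subject_index % 2 == 0:
        return ("health", "taste", "decision")
    return ("taste", "health", "decision")


def subject_events(
    profile: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
    blocks: tuple[str, ...] = BLOCKS,
) -> dict[str, pd.DataFrame]:
    """Per-block events tables (onset, duration, trial_type, stimulus, response).

    Stimulus order is shuffled independently per block; the duration equals
    the reaction time (4 s when the response is missing). The response column
    repeats the block's rating for that stimulus.
    """
    events = {}
    response_col = {"health": "health", "taste": "taste", "decision": "gv"}
    for block in blocks:
        order = rng.permutation(len(profile))
        timing = simulate_timing(len(profile), rng, config)
        prof = profile.iloc[order].reset_index(drop=True)
        responses = prof[response_col[block]].to_numpy(dtype=float)
        durations = np.where(np.isnan(responses), MAX_RT_S,
                             timing["rt"].to_numpy())
        events[block] = pd.DataFrame({
            "onset": timing["onset"].to_numpy(),
            "duration": durations,
            "trial_type": block,
            "stimulus_id": prof["stimulus_id"].to_numpy(),
            "response": responses,
        })
    return events


@dataclass
class SubjectData:
    """Everything simulated for one subject."""

    subject_id: str
    true_class: str
    profile: pd.DataFrame
    events: dict[str, pd.DataFrame]
    runs: dict[str, BoldRun]
    motion: np.ndarray          # concatenated over runs in block order


def simulate_subject_dataset(
    config: SimConfig,
    stimuli: pd.DataFrame,
    subject_index: int,
    true_class: str,
    rng: np.random.Generator,
    labels: np.ndarray | None = None,
    blocks: tuple[str, ...] | None = None,
    with_bold: bool = True,
) -> SubjectData:
    """Simulate one subject end to end (behavior, events, optionally BOLD)."""
    if labels is None:
        labels = make_region_labels(config.grid_shape)
    profile = simulate_subject(config, stimuli, true_class, rng)
    order = block_order(subject_index) if blocks is None else blocks
    events = subject_events(profile, config, rng, order)
    runs: dict[str, BoldRun] = {}
    motions = []
    for block in order:
        if with_bold:
            run = simulate_bold(block, events[block], profile, config,
                                true_class, labels, rng)
            runs[block] = run
            motions.append(run.motion)
        else:
            motions.append(simulate_motion(config.n_volumes_per_run, rng,
                                           config.motion_scale))
    return SubjectData(
        subject_id=f"sub-{subject_index + 1:03d}",
        true_class=true_class,
        profile=profile,
        events=events,
        runs=runs,
        motion=np.vstack(motions),
    )


def assign_classes(config: SimConfig) -> list[str]:
    """Deterministic SC/NSC assignment: the first round(frac_sc * n) are SC."""
    n_sc = int(round(config.frac_sc * config.n_subjects))
    return ["SC"] * n_sc + ["NSC"] * (config.n_subjects - n_sc)


def subject_rngs(config: SimConfig) -> tuple[np.random.Generator, list[np.random.Generator]]:
    """One generator for dataset-level draws plus one per subject."""
    seq = np.random.SeedSequence(config.seed)
    children = seq.spawn(config.n_subjects + 1)
    return (np.random.default_rng(children[0]),
            [np.random.default_rng(c) for c in children[1:]])


def generate_dataset(config: SimConfig, path: str | Path,
                     overwrite: bool = False,
                     with_bold: bool = True) -> GroundTruth:
    """Write a full BIDS-like synthetic dataset to ``path``.

    Layout: ``participants.tsv``; ``masks/`` with the integer label volume,
    one binary NIfTI per region, and ``labels.json``; ``ground_truth.json``;
    and per subject ``sub-XXX/func/`` with one events TSV, motion TSV, and
    (optionally) BOLD NIfTI per run. Runs are named run-01..run-03 in the
    subject's counterbalanced block order. Fully reproducible from
    (config, seed).
    """
    path = Path(path)
    if path.exists() and any(path.iterdir()) and not overwrite:
        raise FileExistsError(
            f"output directory {path} is not empty; pass overwrite=True")
    path.mkdir(parents=True, exist_ok=True)

    (path / "dataset_description.json").write_text(json.dumps({
        "name": "synthetic food self-control task",
        "tr": config.tr,
        "n_volumes_per_run": config.n_volumes_per_run,
        "grid_shape": list(config.grid_shape),
        "voxel_size_mm": config.voxel_size_mm,
        "n_subjects": config.n_subjects,
        "n_stimuli": config.n_stimuli,
        "seed": config.seed,
    }, indent=2))

    dataset_rng, per_subject = subject_rngs(config)
    stimuli = simulate_stimuli(config, dataset_rng)
    labels = make_region_labels(config.grid_shape)
    classes = assign_classes(config)

    masks_dir = path / "masks"
    masks_dir.mkdir(exist_ok=True)
    nib.save(nib.Nifti1Image(labels.astype(np.int16), config.affine),
             str(masks_dir / "region_labels.nii.gz"))
    for name, code in REGION_CODES.items():
        if code == 0:
            continue
        nib.save(
            nib.Nifti1Image((labels == code).astype(np.uint8), config.affine),
            str(masks_dir / f"mask-{name}.nii.gz"))
    (masks_dir / "labels.json").write_text(json.dumps(REGION_CODES, indent=2))

    participants = []
    truth_classes, truth_weights = {}, {}
    for i, (true_class, rng) in enumerate(zip(classes, per_subject)):
        sub = simulate_subject_dataset(config, stimuli, i, true_class, rng,
                                       labels, with_bold=with_bold)
        func = path / sub.subject_id / "func"
        func.mkdir(parents=True, exist_ok=True)
        order = block_order(i)
        for run_idx, block in enumerate(order, start=1):
            stem = f"{sub.subject_id}_task-food_run-{run_idx:02d}"
            ev = sub.events[block].copy()
            ev["response"] = ev["response"].map(
                lambda v: "n/a" if np.isnan(v) else f"{v:.0f}")
            ev.to_csv(func / f"{stem}_events.tsv", sep="\t", index=False,
                      float_format="%.4f")
            sl = slice((run_idx - 1) * config.n_volumes_per_run,
                       run_idx * config.n_volumes_per_run)
            pd.DataFrame(
                sub.motion[sl],
                columns=["trans_x", "trans_y", "trans_z",
                         "rot_x", "rot_y", "rot_z"],
            ).to_csv(func / f"{stem}_motion.tsv", sep="\t", index=False,
                     float_format="%.6f")
            if with_bold:
                nib.save(
                    nib.Nifti1Image(
                        sub.runs[block].data.astype(np.float32), config.affine),
                    str(func / f"{stem}_bold.nii.gz"))
        gender = "F" if dataset_rng.random() < 0.5 else "M"
        participants.append({
            "participant_id": sub.subject_id,
            "gender": gender,
            "age": int(dataset_rng.integers(18, 44)),
            "bmi": round(float(dataset_rng.normal(22.5, 2.5)), 1),
            "first_block": order[0],
        })
        truth_classes[sub.subject_id] = true_class
        truth_weights[sub.subject_id] = (
            float(sub.profile.attrs["w_health"]),
            float(sub.profile.attrs["w_taste"]))

    pd.DataFrame(participants).to_csv(path / "participants.tsv", sep="\t",
                                      index=False)
    truth = GroundTruth(
        classes=truth_classes,
        weights=truth_weights,
        stimuli={row.stimulus_id: (float(row.h_latent), float(row.t_latent))
                 for row in stimuli.itertuples()},
        amplitudes=_resolved_amplitudes(config),
        region_codes=REGION_CODES,
        seed=config.seed,
    )
    (path / "ground_truth.json").write_text(truth.to_json())
    return truth
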