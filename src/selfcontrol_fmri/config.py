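"""Simulation configuration and ground-truth effect presets.

Amplitudes are expressed in the same arbitrary units as the BOLD noise
standard deviation (``noise_sd``); with the default ``noise_sd = 1`` an
amplitude of 1 means the condition regressor (unit-peak HRF convolution)
enters the voxel time series at one noise SD per unit of regressor height.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

#: Canonical ground-truth signal channels understood by the BOLD simulator.
#: Boxcar channels are indicator regressors over the named trials of the run;
#: modulator channels are the (mean-centered) rating times the boxcar.
CHANNELS = (
    "task",             # boxcar over all trials of the run
    "decision_gv",      # goal-value modulator, decision run
    "decision_health",  # health-rating modulator, decision run
    "decision_taste",   # taste-rating modulator, decision run
    "taste_gv",         # goal-value modulator during the taste-rating run
    "health_gv",        # goal-value modulator during the health-rating run
    "unhealthy",        # boxcar over unhealthy-food decision trials (H < 0)
    "healthy",          # boxcar over healthy-food decision trials (H > 0)
    "sc_success",       # boxcar over successful self-control decision trials
    "sc_failure",       # boxcar over failed self-control decision trials
    "ppi_unhealthy",    # seed-neural x unhealthy-indicator interaction
)

REGIONS = ("vmpfc", "caudate", "dlpfc", "ifg", "white_matter", "background")

# Amplitudes may be a scalar (same for every subject) or a {"SC": a, "NSC": b}
# mapping. White matter is a guaranteed null region and accepts no entries.
EFFECT_PRESETS: dict[str, dict[str, dict[str, object]]] = {
    # Rich truth used by the end-to-end pipeline: vmPFC carries an integrated
    # goal-value signal during decisions plus attribute signals whose balance
    # differs between SC (health-weighted) and NSC (taste-weighted) subjects;
    # caudate carries a weaker value signal; dlPFC responds to unhealthy foods
    # (seeding the PPI); IFG couples to the dlPFC seed on unhealthy trials.
    "default": {
        "vmpfc": {
            "task": 0.3,
            "decision_gv": 1.0,
            "decision_health": {"SC": 0.8, "NSC": 0.0},
            "decision_taste": {"SC": 0.4, "NSC": 0.8},
        },
        "caudate": {"decision_gv": 0.5},
        "dlpfc": {"unhealthy": 1.2, "healthy": 0.3},
        "ifg": {"ppi_unhealthy": 0.8},
    },
    # Clean single-channel truth for parameter-recovery experiments: only the
    # vmPFC goal-value amplitude is nonzero, at a level giving a comfortably
    # suprathreshold group effect with ~30 subjects.
    "strong": {
        "vmpfc": {"decision_gv": 2.0},
    },
    # Same shape at half the amplitude.
    "moderate": {
        "vmpfc": {"decision_gv": 1.0},
    },
    # Null truth: no region carries any task signal.
    "null": {},
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic experiment.

    Defaults reproduce the study conditions: 50 food stimuli rated on 5-point
    scales coded -2..+2, three task blocks (health, taste, decision) of one
    run each, TR 2.0 s with 343 volumes per run, 3 mm isotropic voxels, a
    4 s response-limited stimulus window followed by 0.5 s feedback and a
    uniform 4-15 s inter-trial interval, and an SC fraction of 15/80.
    """

    n_subjects: int = 80
    n_stimuli: int = 50
    frac_sc: float = 15 / 80
    # Decision utility weights u = w_h * H + w_t * T (+ noise): SC subjects
    # weight health more than taste, NSC the reverse. The SC taste weight is
    # kept below 0.25 so that with noise switched off the decision sign
    # follows health on every self-control trial (|H| >= 1 beats w_t * 2).
    w_health_sc: float = 1.0
    w_taste_sc: float = 0.2
    w_health_nsc: float = 0.3
    w_taste_nsc: float = 0.9
    tr: float = 2.0
    n_volumes_per_run: int = 343
    grid_shape: tuple[int, int, int] = (20, 20, 20)
    voxel_size_mm: float = 3.0
    effect_size_map: Mapping[str, Mapping[str, object]] | str = "default"
    ar1_rho: float = 0.3
    noise_sd: float = 1.0
    seed: int = 0

    # Stimulus statistics targeted after discretization to the -2..+2 scale.
    stim_health_mean: float = -0.35
    stim_health_sd: float = 1.41
    stim_taste_mean: float = 0.57
    stim_taste_sd: float = 1.10
    stim_ht_correlation: float = 0.0

    # Behavioral noise: subject-level rating noise on the latent attribute
    # scale, logistic noise scale of the ordered decision model, and the
    # probability that a response is missing.
    rating_noise_sd: float = 0.3
    decision_noise: float = 0.6
    missing_prob: float = 0.01

    # Timing. Trials start after ``t_start`` seconds of rest; reaction times
    # follow a log-normal truncated to (0, 4] s.
    t_start: float = 10.0
    rt_log_mean: float = 0.35
    rt_log_sd: float = 0.35

    # BOLD nuisance structure: low-frequency cosine drift (below the 128 s
    # high-pass cutoff), AR(1) motion excursions, baseline level, and the SD
    # of the seed region's intrinsic neural fluctuation (what makes the PPI
    # interaction identifiable).
    drift_amplitude: float = 2.0
    motion_scale: float = 0.2
    baseline: float = 100.0
    neural_fluct_sd: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_sc <= 1.0:
            raise ValueError(f"frac_sc must lie in [0, 1], got {self.frac_sc}")
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if not 0.0 <= self.ar1_rho < 1.0:
            raise ValueError(f"ar1_rho must lie in [0, 1), got {self.ar1_rho}")
        if not -1.0 < self.stim_ht_correlation < 1.0:
            raise ValueError(
                "stim_ht_correlation must lie in (-1, 1), "
                f"got {self.stim_ht_correlation}"
            )
        if self.n_stimuli < 2:
            raise ValueError("n_stimuli must be at least 2")
        effects = self.resolved_effects()
        for region, channels in effects.items():
            if region not in REGIONS:
                raise ValueError(f"unknown region label {region!r}")
            if region == "white_matter" and channels:
                raise ValueError(
                    "white_matter is a null control region and accepts no "
                    "effect amplitudes"
                )
            for channel, amp in channels.items():
                if channel not in CHANNELS:
                    raise ValueError(f"unknown signal channel {channel!r}")
                vals = (
                    list(amp.values()) if isinstance(amp, Mapping) else [amp]
                )
                if not all(np.isfinite(v) for v in vals):
                    raise ValueError(
                        f"non-finite amplitude for {region}/{channel}"
                    )

    def resolved_effects(self) -> dict[str, dict[str, object]]:
        """The effect-size map with a named preset resolved to its dict."""
        if isinstance(self.effect_size_map, str):
            try:
                return EFFECT_PRESETS[self.effect_size_map]
            except KeyError:
                raise ValueError(
                    f"unknown effect preset {self.effect_size_map!r}; "
                    f"choose from {sorted(EFFECT_PRESETS)}"
                ) from None
        return {k: dict(v) for k, v in self.effect_size_map.items()}

    def amplitude(self, region: str, channel: str, group: str) -> float:
        """True amplitude of ``channel`` in ``region`` for a subject group."""
        amp = self.resolved_effects().get(region, {}).get(channel, 0.0)
        if isinstance(amp, Mapping):
            return float(amp.get(group, 0.0))
        return float(amp)

    def with_(self, **kwargs) -> "SimConfig":
        """A copy of the config with the given fields replaced."""
        return replace(self, **kwargs)

    @property
    def affine(self) -> np.ndarray:
        """RAS affine of the common grid (3 mm isotropic, origin at corner)."""
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        return aff
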