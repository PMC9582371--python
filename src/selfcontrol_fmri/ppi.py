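"""Two-stage psychophysiological-interaction (PPI) connectivity analysis.

Stage 1 (PPI1): a seed-localizer GLM on the decision run (healthy-food and
unhealthy-food boxcars plus motion) finds, per subject, the voxel with the
strongest positive unhealthy-food response inside a supplied mask; the BOLD
time series averaged over a 4 mm sphere around that peak is cleaned of
motion variance, deconvolved to an estimated neural series, and enters a
per-voxel regression with (a) the HRF-convolved interaction of the neural
series with an unhealthy-trial indicator, (b) the HRF-convolved indicator
itself, and (c) the seed series — plus motion and a constant. The
interaction beta map is the connectivity-modulation estimate. Stage 2
(PPI2) repeats the regression with a sphere seed placed at a cluster found
in the stage-1 group map.

Deconvolution is a ridge-regularized inversion of the HRF convolution
operator at TR resolution with the penalty chosen by generalized
cross-validation (fallback lambda = 1 when GCV is degenerate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import toeplitz

from . import glm, roi
from .volumes import RegionMask, VolumeMap, voxel_to_mm


@dataclass
class SeedTimeseries:
    """Averaged, motion-cleaned seed BOLD series and its provenance."""

    values: np.ndarray
    sphere: RegionMask
    peak_ijk: tuple[int, int, int] | None = None
    motion_residualized: bool = False
    neural: np.ndarray | None = None
    ridge_lambda: float | None = None


def _residualize(y: np.ndarray, nuisance: np.ndarray) -> np.ndarray:
    """Residual of y after regressing out nuisance columns plus an intercept."""
    X = np.column_stack([np.ones(len(y)), nuisance])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def sphere_series(bold: np.ndarray, sphere: RegionMask,
                  motion: np.ndarray | None = None) -> SeedTimeseries:
    """Average BOLD over a sphere, optionally removing motion variance."""
    series = bold[sphere.mask].mean(axis=0)
    cleaned = series
    if motion is not None:
        cleaned = _residualize(series, np.asarray(motion, dtype=float))
    return SeedTimeseries(cleaned, sphere,
                          motion_residualized=motion is not None)


def extract_seed(
    bold: np.ndarray,
    events_decision: pd.DataFrame,
    profile: pd.DataFrame,
    motion: np.ndarray,
    mask: RegionMask,
    tr: float,
    radius_mm: float = 4.0,
) -> SeedTimeseries:
    """Locate the subject's seed and extract its cleaned sphere time series.

    The localizer GLM (decision run only) models healthy-food and
    unhealthy-food boxcars with motion nuisance; the peak is the voxel with
    the strongest positive unhealthy-food beta inside ``mask``, and the seed
    series is the motion-residualized average over a 4 mm sphere around it.
    """
    n_volumes = bold.shape[-1]
    design = glm.build_design({"decision": events_decision}, "ppi_seed",
                              motion, tr, n_volumes, profile)
    fit = glm.fit_first_level(bold, design, mask=mask.mask,
                              affine=mask.affine)
    beta_map = fit.beta_map("unhealthy_food")
    peak = roi.select_peak_voxel(beta_map, mask)
    center_mm = voxel_to_mm(np.array(peak), mask.affine)
    sphere = roi.make_sphere_mask(center_mm, radius_mm, mask.mask.shape,
                                  mask.affine, label="seed_sphere")
    seed = sphere_series(bold, sphere, motion)
    seed.peak_ijk = peak
    return seed


def deconvolve_neural(
    seed: SeedTimeseries | np.ndarray,
    tr: float,
    ridge_lambda: float | None = None,
) -> tuple[np.ndarray, float]:
    """Estimate the neural series underlying a BOLD series.

    Solves min ||H n - y||^2 + lambda ||n||^2 where H is the Toeplitz
    operator of the canonical HRF at TR resolution. The penalty is chosen by
    generalized cross-validation over a log grid unless given; if GCV is
    degenerate the documented fallback is lambda = 1.
    """
    y = seed.values if isinstance(seed, SeedTimeseries) else np.asarray(seed)
    y = np.asarray(y, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("seed series contains non-finite values")
    n = len(y)
    y_c = y - y.mean()
    kernel = glm.canonical_hrf(np.arange(0.0, glm.HRF_LENGTH_S + tr, tr)) * tr
    col = np.zeros(n)
    col[: min(len(kernel), n)] = kernel[:n]
    H = toeplitz(col, np.zeros(n))
    U, s, Vt = np.linalg.svd(H, full_matrices=False)
    uty = U.T @ y_c
    if ridge_lambda is None:
        grid = np.logspace(-8, 2, 40)
        best, best_score = 1.0, np.inf
        for lam in grid:
            shrink = s ** 2 / (s ** 2 + lam)
            resid2 = float(np.sum(((1 - shrink) * uty) ** 2))
            denom = (n - np.sum(shrink)) ** 2
            score = n * resid2 / denom if denom > 0 else np.inf
            if np.isfinite(score) and score < best_score:
                best, best_score = lam, score
        ridge_lambda = best if np.isfinite(best_score) else 1.0
    coef = s / (s ** 2 + ridge_lambda)
    neural = Vt.T @ (coef * uty)
    if isinstance(seed, SeedTimeseries):
        seed.neural = neural
        seed.ridge_lambda = float(ridge_lambda)
    return neural, float(ridge_lambda)


#: Causal dead time of the deconvolution: neural activity within the final
#: ~8 s of a run (the HRF rise time) produces almost no BOLD signal inside
#: the run, so those trailing samples are structurally unidentified.
HRF_DEAD_TIME_S = 8.0


def roundtrip_relative_error(x: np.ndarray, tr: float,
                             ridge_lambda: float = 1e-8) -> float:
    """Relative error of deconvolve(convolve(x)) over the identified range.

    The final ``HRF_DEAD_TIME_S`` seconds are excluded: a causal HRF has not
    yet transduced that neural activity into in-run BOLD, so no deconvolution
    can recover it. Signals are compared after mean removal.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    kernel = glm.canonical_hrf(np.arange(0.0, glm.HRF_LENGTH_S + tr, tr)) * tr
    y = np.convolve(x, kernel)[:n]
    neural, _ = deconvolve_neural(y, tr, ridge_lambda)
    keep = n - int(np.ceil(HRF_DEAD_TIME_S / tr))
    xc = x - x.mean()
    resid = neural[:keep] - xc[:keep]
    return float(np.linalg.norm(resid) / np.linalg.norm(xc[:keep]))


def psych_indicators(events_decision: pd.DataFrame, profile: pd.DataFrame,
                     tr: float, n_volumes: int,
                     include_neutral: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """TR-resolution unhealthy-trial and any-trial indicator functions.

    By default stimuli with a neutral health rating (H = 0) are excluded
    from the unhealthy indicator (they are neither healthy nor unhealthy);
    ``include_neutral`` folds them in.
    """
    prof = profile.set_index("stimulus_id")
    h = prof["health"].reindex(events_decision["stimulus_id"]).to_numpy(float)
    unhealthy_rows = (h < 0) | (include_neutral & (h == 0))
    os_ = glm.OVERSAMPLING

    def tr_indicator(rows):
        fine = glm.fine_grid_column(
            events_decision["onset"].to_numpy()[rows],
            events_decision["duration"].to_numpy()[rows], tr, n_volumes)
        return fine.reshape(n_volumes, os_).mean(axis=1)

    return tr_indicator(unhealthy_rows), tr_indicator(np.ones(len(h), bool))


@dataclass
class PPIDesign:
    matrix: np.ndarray
    names: list[str]
    vif: dict[str, float] = field(default_factory=dict)


def build_ppi_design(
    neural: np.ndarray,
    psych_unhealthy: np.ndarray,
    psych_any: np.ndarray,
    seed_series: np.ndarray,
    motion: np.ndarray,
    tr: float,
) -> PPIDesign:
    """Assemble the PPI regression design.

    The psychological variable is centered to -1/2 / +1/2 within trial
    windows (+1/2 during unhealthy trials, -1/2 during other trials, 0 at
    rest); the interaction is the centered psych times the neural series.
    The interaction and psych main effect are HRF-convolved; the seed main
    effect enters as the observed seed series. A collinearity warning with
    variance-inflation factors is raised when the interaction is nearly
    spanned by the main effects.
    """
    psych_c = psych_unhealthy - 0.5 * psych_any
    kernel = glm.canonical_hrf(np.arange(0.0, glm.HRF_LENGTH_S + tr, tr))

    def conv(x):
        return np.convolve(x, kernel)[: len(x)] * tr

    cols = [
        conv(neural * psych_c),
        conv(psych_unhealthy),
        conv(psych_any),
        seed_series - seed_series.mean(),
    ]
    names = ["ppi_interaction", "psych_unhealthy", "psych_task", "seed"]
    motion = np.asarray(motion, dtype=float)
    for j in range(motion.shape[1]):
        cols.append(motion[:, j])
        names.append(f"motion_{j}")
    cols.append(np.ones(len(neural)))
    names.append("constant")
    X = np.column_stack(cols)

    # VIF of the interaction against the other regressors.
    vif = {}
    for j, name in enumerate(names[:4]):
        others = np.delete(X, j, axis=1)
        beta, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
        resid = X[:, j] - others @ beta
        total = np.sum((X[:, j] - X[:, j].mean()) ** 2)
        r2 = 1 - np.sum(resid ** 2) / total if total > 0 else 1.0
        vif[name] = float(1.0 / max(1 - r2, 1e-12))
    if vif["ppi_interaction"] > 100:
        warnings.warn(
            "PPI interaction is nearly collinear with the main effects; "
            f"VIFs: { {k: round(v, 1) for k, v in vif.items()} }",
            stacklevel=2,
        )
    return PPIDesign(X, names, vif)


def run_ppi(
    bold: np.ndarray,
    seed: SeedTimeseries,
    events_decision: pd.DataFrame,
    profile: pd.DataFrame,
    motion: np.ndarray,
    tr: float,
    mask: np.ndarray | None = None,
    affine: np.ndarray | None = None,
    include_neutral: bool = False,
) -> tuple[VolumeMap, VolumeMap]:
    """Per-subject PPI regression; returns (t map, beta map) of the interaction.

    Estimated on the decision run only. Group inference over subjects'
    interaction beta maps goes through ``glm.group_ttest``.
    """
    n_volumes = bold.shape[-1]
    if seed.neural is None:
        deconvolve_neural(seed, tr)
    psych_u, psych_a = psych_indicators(events_decision, profile, tr,
                                        n_volumes, include_neutral)
    if np.allclose(psych_u, psych_u[0]):
        raise ValueError("psychological indicator is constant")
    ppi_design = build_ppi_design(seed.neural, psych_u, psych_a, seed.values,
                                  motion, tr)
    design = glm.DesignMatrix(
        matrix=ppi_design.matrix,
        names=ppi_design.names,
        specs=[glm.RegressorSpec(n, "nuisance") for n in ppi_design.names],
        tr=tr,
        run_slices=[slice(0, n_volumes)],
        glm_id="ppi",
    )
    fit = glm.fit_first_level(bold, design, mask=mask, affine=affine)
    t_map, beta_map = glm.contrast_map(fit, {"ppi_interaction": 1.0})
    return t_map, beta_map


def reseed_from_cluster(
    cluster_row: pd.Series,
    grid_shape: tuple[int, int, int],
    affine: np.ndarray,
    radius_mm: float = 4.0,
) -> RegionMask:
    """Sphere seed mask at a cluster peak from a group PPI cluster table."""
    center = np.array([cluster_row["peak_x_mm"], cluster_row["peak_y_mm"],
                       cluster_row["peak_z_mm"]])
    return roi.make_sphere_mask(center, radius_mm, grid_shape, affine,
                                label="ppi2_seed")
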