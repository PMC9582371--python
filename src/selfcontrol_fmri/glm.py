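"""First- and second-level GLMs for the food self-control task.

Implements the five task GLMs plus the PPI seed-localizer model: boxcar
regressors with duration equal to the reaction time, parametric value
modulators mean-centered within condition and sequentially orthogonalized
before convolution with a canonical double-gamma HRF, AR(1) prewhitened
first-level fits, voxelwise one- and two-sample group t tests, and map
thresholding (uncorrected and Benjamini-Hochberg FDR) with cluster tables.

High-pass filtering uses a per-run discrete-cosine basis below 1/128 Hz and is
applied identically to data and design by projection at fit time; the
residual degrees of freedom are reduced accordingly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import gamma as gamma_dist
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from .volumes import VolumeMap, voxel_to_mm
from . import behavior

GLM_IDS = ("1", "2", "3a", "3b", "4", "5", "ppi_seed")

HP_CUTOFF_S = 128.0
OVERSAMPLING = 16
HRF_LENGTH_S = 32.0


# --------------------------------------------------------------------------
# Hemodynamic response and regressor construction
# --------------------------------------------------------------------------

def canonical_hrf(t_grid: np.ndarray) -> np.ndarray:
    """Canonical double-gamma HRF sampled on ``t_grid`` (seconds).

    Response gamma peaks at 6 s, undershoot at 16 s (both dispersion 1), with
    a 1:6 undershoot ratio; the kernel is truncated at 32 s and scaled to
    unit peak.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or (t < 0).any():
        raise ValueError("t_grid must be a 1D nonnegative time grid")
    h = gamma_dist.pdf(t, 6.0) - gamma_dist.pdf(t, 16.0) / 6.0
    h[t > HRF_LENGTH_S] = 0.0
    peak = h.max()
    if peak > 0:
        h = h / peak
    return h


def convolved_regressor(
    onsets: np.ndarray,
    durations: np.ndarray,
    tr: float,
    n_volumes: int,
    amplitudes: np.ndarray | None = None,
    oversampling: int = OVERSAMPLING,
) -> np.ndarray:
    """HRF-convolved boxcar regressor sampled at the frame times.

    Events are laid out on a microtime grid of ``oversampling`` bins per TR,
    convolved with the canonical HRF, and sampled at the middle bin of each
    TR. The convolution approximates the continuous integral (kernel scaled
    by the microtime step).
    """
    fine = fine_grid_column(onsets, durations, tr, n_volumes, amplitudes,
                            oversampling)
    return convolve_fine(fine, tr, n_volumes, oversampling)


def fine_grid_column(
    onsets, durations, tr, n_volumes, amplitudes=None,
    oversampling: int = OVERSAMPLING,
) -> np.ndarray:
    """Unconvolved boxcar (optionally amplitude-modulated) on the microtime grid."""
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    durations = np.atleast_1d(np.asarray(durations, dtype=float))
    if amplitudes is None:
        amplitudes = np.ones_like(onsets)
    amplitudes = np.atleast_1d(np.asarray(amplitudes, dtype=float))
    dt = tr / oversampling
    n_fine = n_volumes * oversampling
    col = np.zeros(n_fine)
    for onset, dur, amp in zip(onsets, durations, amplitudes):
        i0 = int(round(onset / dt))
        i1 = max(int(round((onset + dur) / dt)), i0 + 1)
        if i0 >= n_fine:
            continue
        col[i0:min(i1, n_fine)] += amp
    return col


def convolve_fine(fine: np.ndarray, tr: float, n_volumes: int,
                  oversampling: int = OVERSAMPLING) -> np.ndarray:
    """Convolve a microtime column with the HRF and sample frame times."""
    dt = tr / oversampling
    kernel = canonical_hrf(np.arange(0.0, HRF_LENGTH_S + dt, dt))
    conv = np.convolve(fine, kernel)[: len(fine)] * dt
    idx = np.arange(n_volumes) * oversampling + oversampling // 2
    return conv[idx]


def orthogonalize_modulators(columns: list[np.ndarray]) -> list[np.ndarray]:
    """Sequential Gram-Schmidt orthogonalization.

    The first column is left untouched; each subsequent column is
    residualized against all earlier (already-orthogonalized) columns. This
    shifts variance shared between parametric modulators onto the
    earlier-entered regressor, mirroring the SPM default.
    """
    if not columns:
        raise ValueError("need at least one column")
    out: list[np.ndarray] = []
    for i, col in enumerate(columns):
        col = np.asarray(col, dtype=float).copy()
        if np.linalg.norm(col) == 0:
            raise ValueError(f"column {i} has zero norm")
        for prev in out:
            denom = prev @ prev
            if denom > 0:
                col -= (prev @ col) / denom * prev
        out.append(col)
    return out


# --------------------------------------------------------------------------
# Design matrices
# --------------------------------------------------------------------------

@dataclass
class RegressorSpec:
    name: str
    kind: str  # boxcar | parametric | nuisance | constant
    condition: str | None = None
    n_trials: int = 0
    dropped: bool = False


@dataclass
class DesignMatrix:
    matrix: np.ndarray          # n_total_volumes x n_regressors
    names: list[str]
    specs: list[RegressorSpec]
    tr: float
    run_slices: list[slice]     # volume ranges of each run
    high_pass_cutoff: float = HP_CUTOFF_S
    glm_id: str = ""
    dropped: list[RegressorSpec] = field(default_factory=list)

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.matrix.shape[0]) * self.tr + self.tr / 2

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def validate(self) -> None:
        if not np.isfinite(self.matrix).all():
            raise ValueError("design matrix contains non-finite entries")
        for name, spec in zip(self.names, self.specs):
            if spec.kind in ("boxcar", "parametric") and not spec.dropped:
                if np.allclose(self.column(name), 0):
                    raise ValueError(f"task column {name!r} is all zero")


def dct_highpass_basis(n_volumes: int, tr: float,
                       cutoff: float = HP_CUTOFF_S) -> np.ndarray:
    """Discrete-cosine drift basis with all periods above ``cutoff`` seconds.

    Returns an (n, K) orthonormal matrix with K = floor(2 * n * tr / cutoff)
    cosines (the constant is excluded; run constants are separate columns).
    """
    k_max = int(np.floor(2.0 * n_volumes * tr / cutoff))
    t = np.arange(n_volumes)
    basis = np.empty((n_volumes, k_max))
    for k in range(1, k_max + 1):
        basis[:, k - 1] = np.cos(np.pi * k * (2 * t + 1) / (2 * n_volumes))
    if k_max > 0:
        basis /= np.linalg.norm(basis, axis=0, keepdims=True)
    return basis


def _categorize(profile: pd.DataFrame) -> pd.DataFrame:
    cats = behavior.categorize_trials(profile)
    return cats.set_index("stimulus_id")


def _trial_modulators(events: pd.DataFrame, profile: pd.DataFrame,
                      column: str) -> np.ndarray:
    prof = profile.set_index("stimulus_id")[column]
    return prof.reindex(events["stimulus_id"]).to_numpy(dtype=float)


def _glm_conditions(glm_id: str, events_by_run: dict[str, pd.DataFrame],
                    profile: pd.DataFrame,
                    decision_trials_only: bool = True) -> list[dict]:
    """Expand a GLM id into condition definitions.

    Each condition is a dict with keys ``name``, ``run``, ``rows`` (boolean
    mask into the run's events), and ``modulators`` (ordered list of
    (name, values) pairs, already restricted to the condition's trials).
    """
    prof = profile.set_index("stimulus_id")
    conds: list[dict] = []

    def ratings(ev: pd.DataFrame, col: str) -> pd.Series:
        return prof[col].reindex(ev["stimulus_id"]).reset_index(drop=True)

    if glm_id in ("1", "3a", "3b"):
        missing_rows: dict[str, np.ndarray] = {}
        for block, ev in events_by_run.items():
            gv = ratings(ev, "gv")
            own = ev["response"].astype(float)
            h, t = ratings(ev, "health"), ratings(ev, "taste")
            if glm_id == "1":
                miss = gv.isna() | own.isna()
            else:
                miss = h.isna() | t.isna()
            missing_rows[block] = miss.to_numpy()
            ok = ~miss.to_numpy()
            if glm_id == "1":
                mods = [("gv", gv.to_numpy()[ok])]
            else:
                order = (
                    [("health", h.to_numpy()[ok]), ("taste", t.to_numpy()[ok])]
                    if glm_id == "3a"
                    else [("taste", t.to_numpy()[ok]), ("health", h.to_numpy()[ok])]
                )
                mods = order
            conds.append({
                "name": f"{block}_trials", "run": block, "rows": ok,
                "modulators": mods,
            })
        any_missing = np.concatenate([m for m in missing_rows.values()])
        if any_missing.any():
            for block, miss in missing_rows.items():
                if miss.any():
                    conds.append({
                        "name": "missing", "run": block, "rows": miss,
                        "modulators": [],
                    })
        return conds

    # Decision-run models.
    ev = events_by_run["decision"]
    gv = ratings(ev, "gv")
    h, t = ratings(ev, "health"), ratings(ev, "taste")

    if glm_id == "2":
        labels = {2: "strong_yes", 1: "yes", 0: "neutral",
                  -1: "no", -2: "strong_no"}
        miss = gv.isna().to_numpy()
        for level, name in labels.items():
            rows = (~miss) & (gv.to_numpy() == level)
            conds.append({"name": name, "run": "decision", "rows": rows,
                          "modulators": []})
        if miss.any():
            conds.append({"name": "missing", "run": "decision", "rows": miss,
                          "modulators": []})
        return conds

    if glm_id in ("4", "5"):
        cats = _categorize(profile)
        miss = (gv.isna() | h.isna() | t.isna()).to_numpy()
        neutral = (~miss) & (gv.to_numpy() == 0)
        req = cats["requires_self_control"].reindex(
            ev["stimulus_id"]).to_numpy(dtype=bool)
        liked_unhealthy = cats["liked"].reindex(ev["stimulus_id"]).to_numpy(
            dtype=bool) & cats["unhealthy"].reindex(
            ev["stimulus_id"]).to_numpy(dtype=bool)
        active = (~miss) & (~neutral)
        success = active & req & (
            (liked_unhealthy & (gv.to_numpy() < 0))
            | (~liked_unhealthy & (gv.to_numpy() > 0))
        )
        if glm_id == "4":
            groups = {
                "sc_success": success,
                "sc_failure": active & req & ~success,
                "no_sc_required": active & ~req,
                "neutral_response": neutral,
            }
        else:
            groups = {
                "liked_unhealthy": active & req & liked_unhealthy,
                "disliked_healthy": active & req & ~liked_unhealthy,
                "no_sc_required": active & ~req,
                "neutral_response": neutral,
            }
        for name, rows in groups.items():
            conds.append({"name": name, "run": "decision", "rows": rows,
                          "modulators": []})
        if miss.any():
            conds.append({"name": "missing", "run": "decision", "rows": miss,
                          "modulators": []})
        return conds

    if glm_id == "ppi_seed":
        hv = h.to_numpy()
        conds.append({"name": "healthy_food", "run": "decision",
                      "rows": hv > 0, "modulators": []})
        conds.append({"name": "unhealthy_food", "run": "decision",
                      "rows": hv < 0, "modulators": []})
        return conds

    raise ValueError(f"unknown GLM id {glm_id!r}; choose from {GLM_IDS}")


def build_design(
    events_by_run: dict[str, pd.DataFrame],
    glm_id: str,
    motion: pd.DataFrame | np.ndarray,
    tr: float,
    n_volumes_per_run: int,
    profile: pd.DataFrame | None = None,
    oversampling: int = OVERSAMPLING,
) -> DesignMatrix:
    """Build the design matrix for one subject and one of the task GLMs.

    ``events_by_run`` maps block name (run) to its events table with columns
    onset, duration, stimulus_id, response. ``profile`` is the subject's
    per-stimulus rating table (stimulus_id, health, taste, gv) needed for
    parametric modulators and trial categorization. GLMs 2, 4, 5 and the PPI
    seed model use the decision run only; GLMs 1 and 3 use all supplied runs.
    Feedback periods are not modeled. Parametric modulators are mean-centered
    within condition and sequentially orthogonalized (after the condition
    boxcar) on the microtime grid before convolution.
    """
    if glm_id not in GLM_IDS:
        raise ValueError(f"unknown GLM id {glm_id!r}; choose from {GLM_IDS}")
    if profile is None:
        raise ValueError("a subject rating profile is required")
    decision_only = glm_id in ("2", "4", "5", "ppi_seed")
    runs = (["decision"] if decision_only
            else list(events_by_run.keys()))
    for run in runs:
        if run not in events_by_run:
            raise ValueError(f"events for run {run!r} are missing")
        ev = events_by_run[run]
        if (ev["onset"] + ev["duration"]).max() > n_volumes_per_run * tr:
            raise ValueError(f"events in run {run!r} exceed the run length")

    conds = _glm_conditions(glm_id, {r: events_by_run[r] for r in runs},
                            profile)
    n_total = n_volumes_per_run * len(runs)
    run_slices = [slice(i * n_volumes_per_run, (i + 1) * n_volumes_per_run)
                  for i in range(len(runs))]
    run_offset = {r: i for i, r in enumerate(runs)}

    columns: list[np.ndarray] = []
    names: list[str] = []
    specs: list[RegressorSpec] = []

    # Merge same-named conditions across runs (the missing-trial boxcar).
    merged: dict[str, list[dict]] = {}
    for cond in conds:
        merged.setdefault(cond["name"], []).append(cond)

    for name, parts in merged.items():
        n_trials = int(sum(p["rows"].sum() for p in parts))
        if n_trials == 0:
            warnings.warn(
                f"condition {name!r} has zero trials and is dropped",
                stacklevel=2,
            )
            specs.append(RegressorSpec(name, "boxcar", name, 0, dropped=True))
            continue
        fine_parts: dict[str, np.ndarray] = {}
        mod_fine: dict[str, dict[str, np.ndarray]] = {}
        mod_order: list[str] = []
        for part in parts:
            ev = events_by_run[part["run"]]
            rows = part["rows"]
            onsets = ev["onset"].to_numpy()[rows]
            durs = ev["duration"].to_numpy()[rows]
            box = fine_grid_column(onsets, durs, tr, n_volumes_per_run,
                                   oversampling=oversampling)
            fine_parts[part["run"]] = box
            for mod_name, values in part["modulators"]:
                centered = values - values.mean()
                mod = fine_grid_column(onsets, durs, tr, n_volumes_per_run,
                                       centered, oversampling=oversampling)
                mod_fine.setdefault(part["run"], {})[mod_name] = mod
                if mod_name not in mod_order:
                    mod_order.append(mod_name)

        def place(run: str, sampled: np.ndarray) -> np.ndarray:
            col = np.zeros(n_total)
            col[run_slices[run_offset[run]]] = sampled
            return col

        box_col = np.zeros(n_total)
        for run, fine in fine_parts.items():
            box_col += place(run, convolve_fine(fine, tr, n_volumes_per_run,
                                                oversampling))
        columns.append(box_col)
        names.append(name)
        specs.append(RegressorSpec(name, "boxcar", name, n_trials))

        if mod_order:
            # Sequential orthogonalization on the microtime grid, per run,
            # against the condition boxcar and earlier modulators.
            per_run_orth = {
                run: orthogonalize_modulators(
                    [fine_parts[run]] + [mods[m] for m in mod_order]
                )[1:]
                for run, mods in mod_fine.items()
            }
            for j, mod_name in enumerate(mod_order):
                col = np.zeros(n_total)
                for run in mod_fine:
                    col += place(run, convolve_fine(
                        per_run_orth[run][j], tr, n_volumes_per_run,
                        oversampling))
                columns.append(col)
                names.append(f"{name}_x_{mod_name}")
                specs.append(RegressorSpec(f"{name}_x_{mod_name}",
                                           "parametric", name, n_trials))

    # Motion nuisance (six columns, concatenated over runs).
    motion = np.asarray(motion, dtype=float)
    if motion.shape != (n_total, 6):
        raise ValueError(
            f"motion must be ({n_total}, 6), got {motion.shape}"
        )
    for j in range(6):
        columns.append(motion[:, j])
        names.append(f"motion_{j}")
        specs.append(RegressorSpec(f"motion_{j}", "nuisance"))

    # Session constants, one per run.
    for i, run in enumerate(runs):
        col = np.zeros(n_total)
        col[run_slices[i]] = 1.0
        columns.append(col)
        names.append(f"constant_{run}")
        specs.append(RegressorSpec(f"constant_{run}", "constant"))

    design = DesignMatrix(
        matrix=np.column_stack(columns),
        names=names,
        specs=[s for s in specs if not s.dropped],
        tr=tr,
        run_slices=run_slices,
        glm_id=glm_id,
        dropped=[s for s in specs if s.dropped],
    )
    design.validate()
    return design


# --------------------------------------------------------------------------
# First-level fitting
# --------------------------------------------------------------------------

@dataclass
class FirstLevelFit:
    betas: np.ndarray           # n_regressors x n_voxels
    sigma2: np.ndarray          # n_voxels
    df: float
    rho: float
    design: DesignMatrix
    mask: np.ndarray            # bool 3D (or 1D for abstract fits)
    affine: np.ndarray
    xtx_inv: np.ndarray

    @property
    def names(self) -> list[str]:
        return self.design.names

    def beta_map(self, name: str) -> VolumeMap:
        return VolumeMap.from_flat(self.betas[self.names.index(name)],
                                   self.mask, self.affine, "beta",
                                   regressor=name)


def _highpass_projector(design: DesignMatrix) -> np.ndarray:
    """Residual-forming matrix of the per-run DCT drift basis."""
    n = design.matrix.shape[0]
    proj = np.eye(n)
    n_dct = 0
    for sl in design.run_slices:
        basis = dct_highpass_basis(sl.stop - sl.start, design.tr,
                                   design.high_pass_cutoff)
        n_dct += basis.shape[1]
        if basis.shape[1]:
            proj[sl, sl] -= basis @ basis.T
    return proj, n_dct


def fit_first_level(
    bold: np.ndarray,
    design: DesignMatrix,
    mask: np.ndarray | None = None,
    affine: np.ndarray | None = None,
    whiten: bool = True,
) -> FirstLevelFit:
    """Fit a first-level GLM with a pooled AR(1) prewhitening pass.

    ``bold`` is a 4D array (x, y, z, t) or a 2D (t, voxels) array. The data
    and design are high-pass filtered by projecting out the per-run DCT
    basis; an initial OLS pass estimates a single lag-1 residual
    autocorrelation pooled over the analysis mask; data and design are then
    prewhitened with the (1, -rho) difference filter per run and refit by
    least squares. Degrees of freedom are n - rank(design) - #DCT columns.
    """
    if bold.ndim == 4:
        if mask is None:
            mask = np.ones(bold.shape[:3], dtype=bool)
        Y = bold[mask].T.astype(float)          # t x voxels
    elif bold.ndim == 2:
        Y = bold.astype(float)
        if mask is None:
            mask = np.ones(Y.shape[1], dtype=bool)
    else:
        raise ValueError("bold must be 4D (x,y,z,t) or 2D (t,voxels)")
    if affine is None:
        affine = np.eye(4)

    X = design.matrix
    if Y.shape[0] != X.shape[0]:
        raise ValueError(
            f"bold has {Y.shape[0]} volumes but design has {X.shape[0]}"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # Report which columns are collinear with the rest.
        bad = []
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(X):
                bad.append(design.names[j])
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")

    proj, n_dct = _highpass_projector(design)
    Xf = proj @ X
    Yf = proj @ Y

    def lstsq_fit(Xw, Yw):
        xtx = Xw.T @ Xw
        xtx_inv = np.linalg.pinv(xtx)
        betas = xtx_inv @ Xw.T @ Yw
        resid = Yw - Xw @ betas
        return betas, resid, xtx_inv

    betas, resid, xtx_inv = lstsq_fit(Xf, Yf)
    rho = 0.0
    if whiten:
        num = den = 0.0
        for sl in design.run_slices:
            r = resid[sl]
            num += float(np.sum(r[1:] * r[:-1]))
            den += float(np.sum(r[:-1] ** 2))
        if den > 0 and np.mean(resid ** 2) > 1e-20:
            observed = num / den
            rho = _debias_ar1(observed, X, design)
        rho = float(np.clip(rho, -0.95, 0.95))
        Xw = Xf.copy()
        Yw = Yf.copy()
        scale = np.sqrt(1.0 - rho ** 2)
        for sl in design.run_slices:
            Xw[sl.start + 1:sl.stop] = (
                Xf[sl.start + 1:sl.stop] - rho * Xf[sl.start:sl.stop - 1])
            Yw[sl.start + 1:sl.stop] = (
                Yf[sl.start + 1:sl.stop] - rho * Yf[sl.start:sl.stop - 1])
            Xw[sl.start] = Xf[sl.start] * scale
            Yw[sl.start] = Yf[sl.start] * scale
        betas, resid, xtx_inv = lstsq_fit(Xw, Yw)

    df = Y.shape[0] - rank - n_dct
    if df <= 0:
        raise ValueError(f"nonpositive degrees of freedom ({df})")
    sigma2 = np.sum(resid ** 2, axis=0) / df
    return FirstLevelFit(betas, sigma2, float(df), rho, design, mask,
                         np.asarray(affine), xtx_inv)


def _debias_ar1(observed: float, X: np.ndarray,
                design: DesignMatrix) -> float:
    """Bias-corrected pooled AR(1) coefficient.

    Residualizing against the design and drift basis attenuates the lag-1
    autocorrelation of the residuals relative to that of the noise. With the
    combined projector P onto span(design, DCT), the expected residual lag-1
    ratio under AR(1) noise with coefficient rho is

        g(rho) = tr((I-P) S (I-P) L) / tr((I-P) S (I-P) D),

    where S is the (per-run block) AR(1) covariance, L the symmetrized
    within-run lag-1 indicator, and D the within-run lag-0 indicator. The
    returned value solves g(rho) = observed by fixed-point iteration.
    """
    n = X.shape[0]
    dct_cols = []
    for sl in design.run_slices:
        basis = dct_highpass_basis(sl.stop - sl.start, design.tr,
                                   design.high_pass_cutoff)
        for k in range(basis.shape[1]):
            col = np.zeros(n)
            col[sl] = basis[:, k]
            dct_cols.append(col)
    Z = np.column_stack([X] + dct_cols) if dct_cols else X
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    Q = U[:, s > s.max() * 1e-10]

    L = np.zeros((n, n))
    D = np.zeros((n, n))
    for sl in design.run_slices:
        for t in range(sl.start + 1, sl.stop):
            L[t, t - 1] = L[t - 1, t] = 0.5
        for t in range(sl.start, sl.stop - 1):
            D[t, t] = 1.0

    def g(rho):
        Sigma = np.zeros((n, n))
        for sl in design.run_slices:
            m = sl.stop - sl.start
            idx = np.arange(m)
            Sigma[sl, sl] = rho ** np.abs(idx[:, None] - idx[None, :])
        QtSQ = Q.T @ Sigma @ Q

        def trace_term(M):
            t_full = float(np.sum(Sigma * M))
            MQ = M @ Q
            t_cross = float(np.trace(Q.T @ (Sigma @ MQ)))
            t_both = float(np.trace(QtSQ @ (Q.T @ MQ)))
            return t_full - 2.0 * t_cross + t_both

        den = trace_term(D)
        return trace_term(L) / den if den > 0 else 0.0

    rho = float(np.clip(observed, -0.9, 0.9))
    for _ in range(4):
        rho = float(np.clip(rho + (observed - g(rho)), -0.95, 0.95))
    return rho


def contrast_map(fit: FirstLevelFit, weights) -> tuple[VolumeMap, VolumeMap]:
    """Contrast effect and t maps for a weight vector or {name: weight} dict.

    Weights referencing a column dropped from the design raise.
    """
    names = fit.names
    if isinstance(weights, dict):
        dropped_names = {s.name for s in fit.design.dropped}
        w = np.zeros(len(names))
        for name, value in weights.items():
            if name in dropped_names:
                raise ValueError(
                    f"contrast references dropped column {name!r}")
            if name not in names:
                raise ValueError(f"unknown regressor {name!r}")
            w[names.index(name)] = value
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(names),):
            raise ValueError(
                f"weight vector must have length {len(names)}, got {w.shape}"
            )
    effect = w @ fit.betas
    var = fit.sigma2 * float(w @ fit.xtx_inv @ w)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(var)
    beta_map = VolumeMap.from_flat(effect, fit.mask, fit.affine, "beta",
                                   df=fit.df)
    t_map = VolumeMap.from_flat(t, fit.mask, fit.affine, "t", df=fit.df)
    return t_map, beta_map


# --------------------------------------------------------------------------
# Second level
# --------------------------------------------------------------------------

def group_ttest(
    maps_a: list[VolumeMap],
    maps_b: list[VolumeMap] | None = None,
) -> tuple[VolumeMap, VolumeMap, float]:
    """Voxelwise one-sample (vs 0) or pooled two-sample group t test.

    Two-sample df is n_a + n_b - 2 (pooled variance). Voxels with zero
    variance are flagged as NaN. Returns (t map, two-sided p map, df).
    """
    if len(maps_a) < 2:
        raise ValueError("need at least two maps per group")
    ref = maps_a[0]
    for m in maps_a + (maps_b or []):
        if not m.same_grid(ref) or not np.array_equal(m.mask, ref.mask):
            raise ValueError("maps are not on a common grid/mask")
    A = np.stack([m.flat for m in maps_a])
    if maps_b is None:
        n = A.shape[0]
        df = n - 1
        mean = A.mean(axis=0)
        sd = A.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / (sd / np.sqrt(n))
        t[sd == 0] = np.nan
    else:
        if len(maps_b) < 2:
            raise ValueError("need at least two maps per group")
        B = np.stack([m.flat for m in maps_b])
        na, nb = A.shape[0], B.shape[0]
        df = na + nb - 2
        sp2 = ((na - 1) * A.var(axis=0, ddof=1)
               + (nb - 1) * B.var(axis=0, ddof=1)) / df
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (A.mean(axis=0) - B.mean(axis=0)) / np.sqrt(
                sp2 * (1 / na + 1 / nb))
        t[sp2 == 0] = np.nan
    p = 2 * t_dist.sf(np.abs(t), df)
    t_map = VolumeMap.from_flat(t, ref.mask, ref.affine, "t", df=df)
    p_map = VolumeMap.from_flat(p, ref.mask, ref.affine, "p", df=df)
    return t_map, p_map, float(df)


THRESHOLDS = {"unc_001": 0.001, "unc_005": 0.005, "fdr_05": 0.05}


def threshold_map(
    p_map: VolumeMap,
    method: str = "unc_001",
    t_map: VolumeMap | None = None,
    connectivity: int = 18,
) -> tuple[pd.DataFrame, VolumeMap]:
    """Threshold a p map and extract connected clusters.

    ``unc_001``/``unc_005`` threshold the uncorrected p values; ``fdr_05``
    applies Benjamini-Hochberg over in-mask voxels at q = .05. Clusters use
    18-connectivity by default; the table lists peak mm coordinates (from the
    affine), peak |t| (when a t map is given), and extent.
    """
    if method not in THRESHOLDS:
        raise ValueError(f"unknown method {method!r}")
    if not p_map.mask.any():
        raise ValueError("empty analysis mask")
    p = p_map.flat
    finite = np.isfinite(p)
    sig = np.zeros_like(p, dtype=bool)
    if method == "fdr_05":
        if finite.any():
            rej, _, _, _ = multipletests(p[finite], alpha=0.05, method="fdr_bh")
            sig[finite] = rej
    else:
        sig[finite] = p[finite] < THRESHOLDS[method]

    binary = np.zeros(p_map.mask.shape, dtype=bool)
    binary[p_map.mask] = sig

    structure = {6: ndimage.generate_binary_structure(3, 1),
                 18: ndimage.generate_binary_structure(3, 2),
                 26: ndimage.generate_binary_structure(3, 3)}[connectivity]
    labels, n_clusters = ndimage.label(binary, structure=structure)
    rows = []
    t_vals = t_map.values if t_map is not None else -np.log10(p_map.values)
    for lab in range(1, n_clusters + 1):
        vox = np.argwhere(labels == lab)
        stat = np.abs(t_vals[tuple(vox.T)])
        peak_idx = vox[np.nanargmax(stat)]
        peak_mm = voxel_to_mm(peak_idx, p_map.affine)
        rows.append({
            "label": lab,
            "peak_x_mm": float(np.atleast_1d(peak_mm)[0]),
            "peak_y_mm": float(np.atleast_1d(peak_mm)[1]),
            "peak_z_mm": float(np.atleast_1d(peak_mm)[2]),
            "peak_stat": float(np.nanmax(stat)),
            "extent": int(len(vox)),
            "p_peak": float(np.nanmin(p_map.values[tuple(vox.T)])),
        })
    table = pd.DataFrame(
        rows, columns=["label", "peak_x_mm", "peak_y_mm", "peak_z_mm",
                       "peak_stat", "extent", "p_peak"])
    binary_map = VolumeMap(binary.astype(float), p_map.affine, p_map.mask,
                           "p", {"method": method})
    return table, binary_map


def smooth_volumes(bold: np.ndarray, fwhm_mm: float,
                   voxel_mm: float) -> np.ndarray:
    """Isotropic Gaussian smoothing of a 4D series (no smoothing over time)."""
    if fwhm_mm <= 0:
        return bold
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_mm
    return ndimage.gaussian_filter(
        bold, sigma=(sigma_vox, sigma_vox, sigma_vox, 0.0))
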