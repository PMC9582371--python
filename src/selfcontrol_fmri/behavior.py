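"""Trial categorization, SC/NSC classification, and behavioral statistics.

A subject's profile is a DataFrame with one row per food stimulus and columns
``stimulus_id``, ``health``, ``taste``, ``gv`` — the health rating, taste
rating, and decision ("goal value") rating, each on the -2..+2 scale with NaN
for missing responses.

Self-control is operationalized through the stimulus categories: a trial
requires self-control when the food is liked-but-unhealthy (taste > 0,
health < 0) or disliked-but-healthy (taste < 0, health > 0); self-control
succeeds when the participant declines the former (decision < 0) or chooses
the latter (decision > 0). Ratings of exactly 0 belong to neither side of a
category axis, and a neutral decision on a self-control trial counts as a
failure (it is neither a decline nor a choice).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

REQUIRED_COLUMNS = ("stimulus_id", "health", "taste", "gv")

CHOICE_CATEGORIES = {
    "liked_healthy": (1, 1),
    "liked_unhealthy": (1, -1),
    "disliked_healthy": (-1, 1),
    "disliked_unhealthy": (-1, -1),
}


def _check_profile(profile: pd.DataFrame) -> pd.DataFrame:
    for col in REQUIRED_COLUMNS:
        if col not in profile.columns:
            raise ValueError(f"profile is missing column {col!r}")
    vals = profile[["health", "taste", "gv"]].to_numpy(dtype=float)
    ok = np.isnan(vals) | ((vals >= -2) & (vals <= 2))
    if not ok.all():
        raise ValueError("ratings must lie in -2..+2 or be missing")
    # canonical stimulus order makes every downstream statistic (including
    # floating-point tie cases) independent of the input row order
    return profile.sort_values("stimulus_id", kind="stable").reset_index(
        drop=True)


def categorize_trials(profile: pd.DataFrame) -> pd.DataFrame:
    """Per-stimulus trial categories.

    Stimuli with a missing health or taste rating are excluded from
    ``requires_self_control``; success is defined only where self-control is
    required and the decision is observed.
    """
    profile = _check_profile(profile)
    h = profile["health"].to_numpy(dtype=float)
    t = profile["taste"].to_numpy(dtype=float)
    gv = profile["gv"].to_numpy(dtype=float)
    rated = ~np.isnan(h) & ~np.isnan(t)
    liked = rated & (t > 0)
    disliked = rated & (t < 0)
    healthy = rated & (h > 0)
    unhealthy = rated & (h < 0)
    requires = (liked & unhealthy) | (disliked & healthy)
    decided = ~np.isnan(gv)
    success = requires & decided & (
        ((liked & unhealthy) & (gv < 0)) | ((disliked & healthy) & (gv > 0))
    )
    return pd.DataFrame({
        "stimulus_id": profile["stimulus_id"].to_numpy(),
        "liked": liked,
        "disliked": disliked,
        "healthy": healthy,
        "unhealthy": unhealthy,
        "requires_self_control": requires,
        "self_control_success": success,
        "neutral_decision": decided & (gv == 0),
        "decision_missing": ~decided,
    })


@dataclass
class ClassificationResult:
    label: str                      # SC | NSC | unclassified
    criterion1_rate: float
    criterion2_pass: bool
    criterion3_pass: bool
    b_health: float
    b_taste: float
    r2_health: float
    r2_taste: float
    mode: str
    n_required: int
    diagnostics: str = ""


def choice_regressions(profile: pd.DataFrame) -> tuple[float, float, float, float]:
    """Individual-level choice regressions.

    OLS of the decision rating on health and taste ratings jointly
    (returning both coefficients) and on each rating alone (returning the
    two R-squared values). Stimuli with any missing rating are excluded.
    """
    profile = _check_profile(profile)
    data = profile[["health", "taste", "gv"]].dropna()
    if len(data) < 3:
        raise ValueError(
            f"need at least 3 fully rated stimuli, got {len(data)}")
    for col in ("health", "taste"):
        if data[col].nunique() == 1:
            raise ValueError(f"regressor {col!r} is constant")
    y = data["gv"].to_numpy(dtype=float)
    X = sm.add_constant(data[["health", "taste"]].to_numpy(dtype=float))
    multi = sm.OLS(y, X).fit()
    b_health, b_taste = multi.params[1], multi.params[2]
    r2 = {}
    for col in ("health", "taste"):
        simple = sm.OLS(y, sm.add_constant(
            data[col].to_numpy(dtype=float))).fit()
        r2[col] = simple.rsquared
    return float(b_health), float(b_taste), float(r2["health"]), float(r2["taste"])


def classify_participant(profile: pd.DataFrame,
                         mode: str = "three_criteria") -> ClassificationResult:
    """Classify a participant as SC, NSC, or unclassified.

    Three-criteria rule: (1) self-control succeeded on more than 50% of the
    trials requiring it (missing decisions excluded from both numerator and
    denominator; neutral decisions count as failures); (2) in the joint
    choice regression the standardized health coefficient exceeds the
    standardized taste coefficient in magnitude; (3) the simple-regression
    R-squared of health exceeds that of taste. All three -> SC; none -> NSC;
    otherwise unclassified. One-criterion rule: SC iff the success rate is
    at least 50%, else NSC.
    """
    if mode not in ("three_criteria", "one_criterion"):
        raise ValueError(f"unknown mode {mode!r}")
    cats = categorize_trials(profile)
    required = cats["requires_self_control"] & ~cats["decision_missing"]
    n_required = int(required.sum())
    if n_required == 0:
        return ClassificationResult(
            "unclassified", np.nan, False, False, np.nan, np.nan,
            np.nan, np.nan, mode, 0,
            "no trials requiring self-control with an observed decision",
        )
    rate = float(cats.loc[required, "self_control_success"].mean())

    b_health, b_taste, r2_h, r2_t = choice_regressions(profile)
    data = profile[["health", "taste", "gv"]].dropna()
    sd_y = data["gv"].std(ddof=1)
    std_bh = b_health * data["health"].std(ddof=1) / sd_y if sd_y > 0 else np.nan
    std_bt = b_taste * data["taste"].std(ddof=1) / sd_y if sd_y > 0 else np.nan
    c2 = bool(np.abs(std_bh) > np.abs(std_bt)) if np.isfinite(std_bh) else False
    c3 = bool(r2_h > r2_t)

    if mode == "one_criterion":
        label = "SC" if rate >= 0.5 else "NSC"
    else:
        c1 = rate > 0.5
        if c1 and c2 and c3:
            label = "SC"
        elif not (c1 or c2 or c3):
            label = "NSC"
        else:
            label = "unclassified"
    return ClassificationResult(label, rate, c2, c3, b_health, b_taste,
                                r2_h, r2_t, mode, n_required)


def _yes_proportion(profile: pd.DataFrame, liked_sign: int,
                    healthy_sign: int) -> float:
    """Fraction of yes/strong-yes decisions in one taste/health category."""
    cats = categorize_trials(profile).set_index("stimulus_id")
    prof = profile.set_index("stimulus_id")
    taste_flag = cats["liked"] if liked_sign > 0 else cats["disliked"]
    health_flag = cats["healthy"] if healthy_sign > 0 else cats["unhealthy"]
    rows = taste_flag & health_flag & ~cats["decision_missing"]
    if rows.sum() == 0:
        return np.nan
    return float((prof.loc[rows[rows].index, "gv"] > 0).mean())


def group_choice_table(
    profiles: list[pd.DataFrame],
    labels: list[str],
) -> dict[str, pd.DataFrame]:
    """Group comparison of choice behavior between SC and NSC participants.

    For each taste-by-health category, the per-subject proportion of yes /
    strong-yes decisions is compared between groups with a pooled-variance
    two-sample t test (df = n_SC + n_NSC - 2). Per-stimulus mean health and
    taste ratings of the two groups are correlated (Pearson, with Fisher-z
    95% CI). Subjects with an empty category cell are excluded from that
    cell's test.
    """
    labels = list(labels)
    sc = [p for p, l in zip(profiles, labels) if l == "SC"]
    nsc = [p for p, l in zip(profiles, labels) if l == "NSC"]
    if not sc or not nsc:
        raise ValueError("both groups must be non-empty")

    rows = []
    for name, (ls, hs) in CHOICE_CATEGORIES.items():
        a = np.array([_yes_proportion(p, ls, hs) for p in sc])
        b = np.array([_yes_proportion(p, ls, hs) for p in nsc])
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if len(a) >= 2 and len(b) >= 2:
            t, p = stats.ttest_ind(a, b, equal_var=True)
        else:
            t, p = np.nan, np.nan
        rows.append({
            "category": name,
            "mean_sc": a.mean(), "se_sc": a.std(ddof=1) / np.sqrt(len(a)),
            "mean_nsc": b.mean(), "se_nsc": b.std(ddof=1) / np.sqrt(len(b)),
            "t": float(t), "df": len(a) + len(b) - 2, "p": float(p),
            "n_sc": len(a), "n_nsc": len(b),
        })
    proportions = pd.DataFrame(rows)

    corr_rows = []
    for col in ("health", "taste"):
        mean_sc = pd.concat(sc).groupby("stimulus_id")[col].mean()
        mean_nsc = pd.concat(nsc).groupby("stimulus_id")[col].mean()
        common = mean_sc.index.intersection(mean_nsc.index)
        x, y = mean_sc.loc[common], mean_nsc.loc[common]
        r, p = stats.pearsonr(x, y)
        n = len(common)
        if abs(r) < 1 and n > 3:
            z = np.arctanh(r)
            half = 1.959964 / np.sqrt(n - 3)
            ci = (np.tanh(z - half), np.tanh(z + half))
        else:
            ci = (r, r)
        corr_rows.append({
            "rating": col, "r": float(r), "ci_low": float(ci[0]),
            "ci_high": float(ci[1]), "df": n - 2, "p": float(p), "n": n,
        })
    correlations = pd.DataFrame(corr_rows)
    return {"proportions": proportions, "correlations": correlations}


def robust_regression(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    tuning: float = 1.345,
    tol: float = 1e-8,
    maxiter: int = 50,
) -> pd.DataFrame:
    """Huber-weighted robust regression of y on x (plus optional covariates).

    Iteratively reweighted least squares with the Huber psi (tuning 1.345).
    Returns a table of coefficients, robust standard errors, t and p values,
    with rows const, x, then covariates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be one-dimensional")
    if np.ptp(x) == 0:
        raise ValueError("regressor x is constant")
    cols = [x]
    names = ["const", "x"]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] == len(y) and cov.shape[1] != len(y):
            cov = cov.T
        for i, c in enumerate(cov):
            cols.append(c)
            names.append(f"cov{i}")
    X = sm.add_constant(np.column_stack(cols))
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more observations than parameters")
    model = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=tuning))
    res = model.fit(maxiter=maxiter, tol=tol, conv="coefs")
    if not getattr(res, "converged", True) and res.fit_history["iteration"] >= maxiter:
        raise RuntimeError(
            f"robust regression did not converge; last params {res.params}")
    return pd.DataFrame({
        "coef": res.params,
        "se": res.bse,
        "t": res.tvalues,
        "p": res.pvalues,
    }, index=names)
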