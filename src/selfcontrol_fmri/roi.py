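"""ROI construction and signal extraction: peak voxel versus mean-over-mask.

The two extraction strategies mirror the competing analysis choices the
pipeline is designed to compare. The *peak* strategy picks, per subject, the
voxel with the strongest selection-contrast effect inside a mask and reads
the test-contrast effects at that voxel; the *mean* strategy averages the
test-contrast effects over the whole mask. When the voxel used to select is
not independent of the test (circular selection), the peak strategy inflates
effects — ``selection_bias_experiment`` quantifies that inflation on a
guaranteed-null region via Monte Carlo simulation of the max statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .volumes import RegionMask, VolumeMap, mm_to_voxel, voxel_to_mm


def make_sphere_mask(
    center_mm: np.ndarray,
    radius_mm: float,
    grid_shape: tuple[int, int, int],
    affine: np.ndarray,
    label: str = "sphere",
) -> RegionMask:
    """Spherical mask of voxels whose centers lie within ``radius_mm``."""
    center_ijk = mm_to_voxel(center_mm, affine)
    if (np.any(center_ijk < 0)
            or np.any(center_ijk >= np.asarray(grid_shape))):
        raise ValueError(
            f"sphere center {center_mm} (voxel {center_ijk}) is outside the grid")
    ijk = np.indices(grid_shape).reshape(3, -1).T
    xyz = voxel_to_mm(ijk, affine)
    dist = np.linalg.norm(xyz - np.asarray(center_mm, dtype=float), axis=1)
    mask = (dist <= radius_mm).reshape(grid_shape)
    if not mask.any():
        raise ValueError(
            f"sphere of radius {radius_mm} mm at {center_mm} contains no voxels")
    return RegionMask(mask, label, affine, "sphere")


def intersect_masks(a: RegionMask, b: RegionMask,
                    label: str | None = None) -> RegionMask:
    """Voxelwise AND of two masks on the same grid."""
    if a.mask.shape != b.mask.shape or not np.allclose(a.affine, b.affine):
        raise ValueError("masks are not on the same grid")
    both = a.mask & b.mask
    if not both.any():
        raise ValueError(
            f"empty intersection of {a.label!r} ({a.size} voxels) and "
            f"{b.label!r} ({b.size} voxels)")
    return RegionMask(both, label or f"{a.label}_and_{b.label}", a.affine,
                      a.provenance)


def select_peak_voxel(
    subject_map: VolumeMap,
    mask: RegionMask,
    direction: str = "max",
) -> tuple[int, int, int]:
    """Voxel index of the extreme selection statistic within a mask.

    Ties are broken by the smallest linear (C-order) voxel index. Raises if
    the map is all-NaN inside the mask.
    """
    if subject_map.values.shape != mask.mask.shape:
        raise ValueError("map and mask are not on the same grid")
    vals = subject_map.values[mask.mask]
    if np.all(np.isnan(vals)):
        raise ValueError("selection map is all-NaN within the mask")
    if direction == "min":
        vals = -vals
    elif direction != "max":
        raise ValueError(f"direction must be 'max' or 'min', got {direction!r}")
    flat_pick = np.nanargmax(vals)
    return tuple(mask.indices()[flat_pick])


@dataclass
class ExtractionResult:
    """Per-subject ROI values for one extraction strategy."""

    table: pd.DataFrame         # subject, contrast, value, peak i/j/k (peak only)
    strategy: str
    selection_contrast: str | None
    test_contrasts: list[str] = field(default_factory=list)

    def values(self, contrast: str) -> np.ndarray:
        rows = self.table[self.table["contrast"] == contrast]
        return rows.sort_values("subject")["value"].to_numpy()


def extract_roi_signal(
    subject_maps: list[dict[str, VolumeMap]],
    mask: RegionMask,
    strategy: str,
    selection_contrast: str | None,
    test_contrasts: list[str],
) -> ExtractionResult:
    """Extract per-subject effects from a mask by peak or mean strategy.

    ``subject_maps`` holds, per subject, contrast-name -> beta VolumeMap.
    Peak strategy: select each subject's peak voxel on the selection
    contrast, read the test-contrast betas at that voxel. Mean strategy:
    average test-contrast betas over the mask (selection contrast unused).
    Subject-level selection and test statistics are both betas.
    """
    if strategy not in ("peak", "mean"):
        raise ValueError(f"strategy must be 'peak' or 'mean', got {strategy!r}")
    if strategy == "peak" and selection_contrast is None:
        raise ValueError("peak strategy requires a selection contrast")
    rows = []
    for subj_idx, maps in enumerate(subject_maps):
        for contrast in test_contrasts:
            if contrast not in maps:
                raise ValueError(
                    f"subject {subj_idx} lacks test contrast {contrast!r}")
        if strategy == "peak":
            if selection_contrast not in maps:
                raise ValueError(
                    f"subject {subj_idx} lacks selection contrast "
                    f"{selection_contrast!r}")
            peak = select_peak_voxel(maps[selection_contrast], mask)
            for contrast in test_contrasts:
                rows.append({
                    "subject": subj_idx, "contrast": contrast,
                    "value": float(maps[contrast].values[peak]),
                    "peak_i": peak[0], "peak_j": peak[1], "peak_k": peak[2],
                })
        else:
            for contrast in test_contrasts:
                vals = maps[contrast].values[mask.mask]
                rows.append({
                    "subject": subj_idx, "contrast": contrast,
                    "value": float(np.nanmean(vals)),
                })
    return ExtractionResult(pd.DataFrame(rows), strategy, selection_contrast,
                            list(test_contrasts))


def goal_value_profile(result: ExtractionResult,
                       levels: list[str]) -> pd.DataFrame:
    """Group mean and SE per goal-value level from an extraction result."""
    rows = []
    for level in levels:
        vals = result.values(level)
        rows.append({
            "level": level,
            "mean": float(np.mean(vals)),
            "se": float(np.std(vals, ddof=1) / np.sqrt(len(vals))),
            "n": len(vals),
        })
    return pd.DataFrame(rows)


def selection_bias_experiment(
    n_subjects: int,
    mask_size: int,
    n_sim: int,
    rng: np.random.Generator,
    noise_sd: float = 1.0,
    beta_sampler=None,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Quantify circular peak-voxel selection bias on a null region.

    Each simulation draws per-subject, per-voxel beta estimates for two
    conditions (successful / unsuccessful self-control) from a null model
    with no true difference. The *peak* strategy selects, per subject, the
    voxel maximizing the (successful - unsuccessful) contrast and then runs a
    paired t test on the same contrast at those self-selected voxels — a
    non-independent (circular) analysis. The *mean* strategy tests the
    mask-mean contrast. Returns rejection rates at ``alpha`` and the mean
    spurious effects.

    ``beta_sampler(rng) -> (S, U)`` may supply (n_subjects, mask_size)
    condition betas from a fitted noise model; the default is iid
    N(0, noise_sd) for both conditions.
    """
    if n_sim < 2:
        raise ValueError("need at least two simulations")
    if beta_sampler is None:
        def beta_sampler(r):
            return (r.standard_normal((n_subjects, mask_size)) * noise_sd,
                    r.standard_normal((n_subjects, mask_size)) * noise_sd)

    reject = {"peak": 0, "mean": 0}
    effect_sum = {"peak": 0.0, "mean": 0.0}
    for _ in range(n_sim):
        S, U = beta_sampler(rng)
        diff = S - U
        peak_idx = np.argmax(diff, axis=1)
        peak_diff = diff[np.arange(diff.shape[0]), peak_idx]
        mean_diff = diff.mean(axis=1)
        for name, vals in (("peak", peak_diff), ("mean", mean_diff)):
            t, p = stats.ttest_1samp(vals, 0.0)
            reject[name] += int(p < alpha)
            effect_sum[name] += float(vals.mean())
    return {
        "peak_rejection_rate": reject["peak"] / n_sim,
        "mean_rejection_rate": reject["mean"] / n_sim,
        "peak_mean_effect": effect_sum["peak"] / n_sim,
        "mean_mean_effect": effect_sum["mean"] / n_sim,
        "n_sim": n_sim,
        "alpha": alpha,
    }
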