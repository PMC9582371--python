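"""End-to-end analysis driver reproducing the study's analysis sequence.

The pipeline runs, in order: participant classification (one- and
three-criteria), behavioral group statistics, the GLM1 goal-value group map,
GLM2 goal-value level profiles (peak vs mean extraction), GLM3a/3b
health/taste attribute encoding by group with the order-robustness branch
and the decision-weight regression, the GLM4 SC-vs-NSC comparison with the
white-matter circularity control, and the two-stage PPI. Each stage writes
tidy tables under the output directory; a manifest records configuration
and file hashes so a rerun with the same dataset and config is
byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, glm, ppi, roi
from .datasets import Dataset, SubjectRecord, read_dataset
from .volumes import RegionMask, VolumeMap

GV_LEVELS = ["strong_no", "no", "neutral", "yes", "strong_yes"]


@dataclass
class PipelineConfig:
    dataset_path: str
    out_path: str
    classification_mode: str = "one_criterion"
    glms: tuple[str, ...] = ("1", "2", "3a", "3b", "4", "5")
    thresholds: tuple[str, ...] = ("unc_001", "unc_005", "fdr_05")
    roi_strategies: tuple[str, ...] = ("peak", "mean")
    run_ppi: bool = True
    include_all_self_controllers: bool = True
    smooth_fwhm: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        for thr in self.thresholds:
            if thr not in glm.THRESHOLDS:
                raise ValueError(f"unknown threshold {thr!r}")
        if self.classification_mode not in ("one_criterion", "three_criteria"):
            raise ValueError(
                f"unknown classification mode {self.classification_mode!r}")


# --------------------------------------------------------------------------
# First-level helpers
# --------------------------------------------------------------------------

def fit_subject_glm(
    subject: SubjectRecord,
    glm_id: str,
    dataset: Dataset,
    smooth_fwhm: float = 8.0,
) -> glm.FirstLevelFit:
    """Fit one of the task GLMs for a subject from the on-disk dataset."""
    profile = subject.profile
    n_vol = dataset.n_volumes_per_run
    voxel_mm = float(dataset.affine[0, 0])
    if glm_id in ("1", "3a", "3b"):
        blocks = subject.block_order
        motion = subject.motion
    else:
        blocks = ["decision"]
        motion = subject.run_motion("decision", n_vol)
    bold = np.concatenate(
        [glm.smooth_volumes(subject.load_bold(b), smooth_fwhm, voxel_mm)
         for b in blocks], axis=-1)
    events = {b: subject.events[b] for b in blocks}
    design = glm.build_design(events, glm_id, motion, dataset.tr, n_vol,
                              profile)
    return glm.fit_first_level(bold, design, affine=dataset.affine)


def classify_all(dataset: Dataset) -> pd.DataFrame:
    """Classification table with both rule sets for every participant."""
    rows = []
    for subject in dataset.subjects:
        profile = subject.profile
        for mode in ("three_criteria", "one_criterion"):
            res = behavior.classify_participant(profile, mode)
            rows.append({
                "participant_id": subject.subject_id,
                "mode": mode,
                "label": res.label,
                "success_rate": res.criterion1_rate,
                "criterion2_pass": res.criterion2_pass,
                "criterion3_pass": res.criterion3_pass,
                "b_health": res.b_health,
                "b_taste": res.b_taste,
                "r2_health": res.r2_health,
                "r2_taste": res.r2_taste,
                "n_required": res.n_required,
            })
    return pd.DataFrame(rows)


def labels_for_mode(classification: pd.DataFrame, mode: str) -> dict[str, str]:
    rows = classification[classification["mode"] == mode]
    return dict(zip(rows["participant_id"], rows["label"]))


# --------------------------------------------------------------------------
# Pipeline
# --------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    config: dict
    stages: dict[str, dict] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(
            {"config": self.config, "stages": self.stages,
             "outputs": self.outputs}, indent=2, default=str))


class PipelineRun:
    """Stateful execution of the analysis sequence."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = Path(config.out_path)
        self.out.mkdir(parents=True, exist_ok=True)
        cfg_dict = asdict(config)
        self.manifest = RunManifest(config=cfg_dict)
        self.results: dict[str, object] = {}
        self._hypotheses: dict[str, dict] = {}

    # -- plumbing ---------------------------------------------------------

    def _write(self, name: str, frame: pd.DataFrame) -> None:
        path = self.out / name
        frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
        self.manifest.outputs[name] = _sha256(path)

    def _stage(self, name: str, func, *deps: str):
        t0 = time.perf_counter()
        for dep in deps:
            status = self.manifest.stages.get(dep, {}).get("status")
            if status != "ok":
                self.manifest.stages[name] = {
                    "status": "skipped", "reason": f"dependency {dep} {status}"}
                return
        try:
            func()
            self.manifest.stages[name] = {
                "status": "ok", "seconds": round(time.perf_counter() - t0, 2)}
        except Exception as exc:  # log and let dependents skip
            self.manifest.stages[name] = {
                "status": "failed", "error": f"{type(exc).__name__}: {exc}",
                "seconds": round(time.perf_counter() - t0, 2)}
            warnings.warn(f"stage {name} failed: {exc}", stacklevel=2)

    # -- stages -----------------------------------------------------------

    def load(self) -> None:
        self.dataset = read_dataset(self.config.dataset_path)

    def classify(self) -> None:
        table = classify_all(self.dataset)
        self._write("classification.tsv", table)
        self.results["classification"] = table
        self.labels = labels_for_mode(table, self.config.classification_mode)

    def behavioral(self) -> None:
        profiles, labels = [], []
        for subject in self.dataset.subjects:
            label = self.labels[subject.subject_id]
            if label in ("SC", "NSC"):
                profiles.append(subject.profile)
                labels.append(label)
        tables = behavior.group_choice_table(profiles, labels)
        self._write("choice_proportions.tsv", tables["proportions"])
        self._write("rating_correlations.tsv", tables["correlations"])
        self.results["choice_proportions"] = tables["proportions"]
        self.results["rating_correlations"] = tables["correlations"]

    def _first_level(self, glm_id: str) -> dict[str, glm.FirstLevelFit]:
        key = f"fits_{glm_id}"
        if key not in self.results:
            fits = {}
            for subject in self.dataset.subjects:
                fits[subject.subject_id] = fit_subject_glm(
                    subject, glm_id, self.dataset, self.config.smooth_fwhm)
            self.results[key] = fits
        return self.results[key]

    def _beta_maps(self, glm_id: str, contrast) -> dict[str, VolumeMap]:
        fits = self._first_level(glm_id)
        out = {}
        for sub_id, fit in fits.items():
            _, beta = glm.contrast_map(fit, contrast)
            out[sub_id] = beta
        return out

    def glm1_group(self) -> None:
        contrast = {"decision_trials_x_gv": 1.0, "taste_trials_x_gv": -1.0}
        maps = self._beta_maps("1", contrast)
        t_map, p_map, df = glm.group_ttest(list(maps.values()))
        self.results["glm1_group_t"] = t_map
        tables = []
        for thr in self.config.thresholds:
            table, _ = glm.threshold_map(p_map, thr, t_map)
            table.insert(0, "threshold", thr)
            tables.append(table)
        clusters = pd.concat(tables, ignore_index=True)
        self._write("glm1_clusters.tsv", clusters)
        vmpfc = self.dataset.masks["vmpfc"]
        in_vmpfc = t_map.values[vmpfc.mask]
        p_vm = p_map.values[vmpfc.mask]
        supported = bool(np.any((p_vm < 0.001) & (in_vmpfc > 0)))
        self._hypotheses["H1"] = {
            "statement": "vmPFC activity correlates with goal value",
            "supported": supported,
            "evidence": f"{int(np.sum((p_vm < 0.001) & (in_vmpfc > 0)))} "
                        f"vmPFC voxels positive at p<.001",
        }
        self.results["glm1_subject_maps"] = maps

    def glm2_profiles(self) -> None:
        fits = self._first_level("2")
        selection = self.results["glm1_subject_maps"]
        vmpfc = self.dataset.masks["vmpfc"]
        subject_maps = []
        for sub_id, fit in fits.items():
            maps = {"selection": selection[sub_id]}
            for level in GV_LEVELS:
                if level in fit.names:
                    maps[level] = fit.beta_map(level)
            subject_maps.append(maps)
        levels = [l for l in GV_LEVELS
                  if all(l in m for m in subject_maps)]
        tables = []
        for strategy in self.config.roi_strategies:
            res = roi.extract_roi_signal(subject_maps, vmpfc, strategy,
                                         "selection", levels)
            prof = roi.goal_value_profile(res, levels)
            prof.insert(0, "strategy", strategy)
            tables.append(prof)
        table = pd.concat(tables, ignore_index=True)
        self._write("goal_value_profiles.tsv", table)
        self.results["goal_value_profiles"] = table

    def glm3_encoding(self) -> None:
        vmpfc = self.dataset.masks["vmpfc"]
        rows = []
        extract_cache = {}
        for order in ("3a", "3b"):
            health_maps = self._beta_maps(
                order, {"decision_trials_x_health": 1.0})
            taste_maps = self._beta_maps(
                order, {"decision_trials_x_taste": 1.0})
            subject_ids = list(health_maps)
            subject_maps = [
                {"health": health_maps[s], "taste": taste_maps[s],
                 "selection": self.results["glm1_subject_maps"][s]}
                for s in subject_ids
            ]
            for strategy in self.config.roi_strategies:
                res = roi.extract_roi_signal(subject_maps, vmpfc, strategy,
                                             "selection", ["health", "taste"])
                for contrast in ("health", "taste"):
                    vals = {
                        s: v for s, v in zip(
                            subject_ids,
                            res.table[res.table["contrast"] == contrast]
                            .sort_values("subject")["value"])
                    }
                    extract_cache[(order, strategy, contrast)] = vals
                    for group in ("SC", "NSC"):
                        gv = np.array([v for s, v in vals.items()
                                       if self.labels[s] == group])
                        if len(gv) < 2:
                            continue
                        from scipy import stats as sstats
                        t, p = sstats.ttest_1samp(gv, 0.0)
                        rows.append({
                            "order": order, "strategy": strategy,
                            "modulator": contrast, "group": group,
                            "mean": gv.mean(),
                            "se": gv.std(ddof=1) / np.sqrt(len(gv)),
                            "t": float(t), "df": len(gv) - 1, "p": float(p),
                            "n": len(gv),
                        })
        table = pd.DataFrame(rows)
        self._write("attribute_encoding.tsv", table)
        self.results["attribute_encoding"] = table
        self.results["attribute_extractions"] = extract_cache

        sc_mean = table.query(
            "order == '3a' and strategy == 'peak' and modulator == 'health' "
            "and group == 'SC'")
        nsc_mean = table.query(
            "order == '3a' and strategy == 'peak' and modulator == 'health' "
            "and group == 'NSC'")
        # supported when SC show significant positive health encoding and
        # NSC show none (a negative NSC attribution does not count against)
        supported = (not sc_mean.empty and not nsc_mean.empty
                     and sc_mean["p"].iloc[0] < 0.05
                     and sc_mean["mean"].iloc[0] > 0
                     and not (nsc_mean["p"].iloc[0] < 0.05
                              and nsc_mean["mean"].iloc[0] > 0))
        self._hypotheses["H2"] = {
            "statement": "vmPFC reflects health ratings in SC but not NSC",
            "supported": bool(supported),
            "evidence": "peak-strategy one-sample tests on the GLM3a health "
                        "modulator",
        }

        # Decision-weight regression: behavioral health weight on neural
        # health encoding (peak strategy, order 3a).
        vals = extract_cache[("3a", "peak", "health")]
        classification = self.results["classification"]
        beh = classification[classification["mode"] == "three_criteria"]
        b_health = dict(zip(beh["participant_id"], beh["b_health"]))
        x = np.array([vals[s] for s in vals])
        y = np.array([b_health[s] for s in vals])
        reg = behavior.robust_regression(x, y)
        reg = reg.reset_index().rename(columns={"index": "term"})
        self._write("decision_weight_regression.tsv", reg)
        self.results["decision_weight_regression"] = reg

    def glm4_group(self) -> None:
        # Subjects with no successful (or no failed) self-control trial have
        # that column dropped and cannot contribute to this comparison.
        fits = self._first_level("4")
        usable = {s: f for s, f in fits.items() if "sc_success" in f.names}
        dropped = sorted(set(fits) - set(usable))
        if dropped:
            warnings.warn(
                f"subjects without successful self-control trials are "
                f"excluded from the GLM4 group stage: {dropped}", stacklevel=2)
        self.results["glm4_usable"] = {
            s: f for s, f in usable.items() if "sc_failure" in f.names}
        maps = {}
        for sub_id, fit in usable.items():
            _, beta = glm.contrast_map(fit, {"sc_success": 1.0})
            maps[sub_id] = beta
        sc_maps = [m for s, m in maps.items() if self.labels[s] == "SC"]
        nsc_maps = [m for s, m in maps.items() if self.labels[s] == "NSC"]
        t_map, p_map, df = glm.group_ttest(sc_maps, nsc_maps)
        tables = []
        for thr in self.config.thresholds:
            table, _ = glm.threshold_map(p_map, thr, t_map)
            table.insert(0, "threshold", thr)
            tables.append(table)
        self._write("glm4_clusters.tsv", pd.concat(tables, ignore_index=True))
        dlpfc = self.dataset.masks["dlpfc"]
        p_dl = p_map.values[dlpfc.mask]
        t_dl = t_map.values[dlpfc.mask]
        supported = bool(np.any((p_dl < 0.001) & (t_dl > 0)))
        self._hypotheses["H3"] = {
            "statement": "dlPFC more active in SC than NSC during successful "
                         "self-control",
            "supported": supported,
            "evidence": f"two-sample t({int(df)}) map in dlPFC at p<.001",
        }
        self.results["glm4_maps"] = maps

    def circularity_control(self) -> None:
        fits = self.results.get("glm4_usable") or self._first_level("4")
        rows = []
        for mask_name in ("dlpfc", "white_matter"):
            mask = self.dataset.masks[mask_name]
            subject_maps = []
            for sub_id, fit in fits.items():
                succ = fit.beta_map("sc_success")
                fail = fit.beta_map("sc_failure")
                _, diff = glm.contrast_map(
                    fit, {"sc_success": 1.0, "sc_failure": -1.0})
                subject_maps.append({"success": succ, "failure": fail,
                                     "diff": diff})
            for strategy in self.config.roi_strategies:
                res = roi.extract_roi_signal(subject_maps, mask, strategy,
                                             "diff", ["success", "failure"])
                s_vals = res.values("success")
                f_vals = res.values("failure")
                from scipy import stats as sstats
                t, p = sstats.ttest_rel(s_vals, f_vals)
                rows.append({
                    "mask": mask_name, "strategy": strategy,
                    "mean_success": s_vals.mean(),
                    "mean_failure": f_vals.mean(),
                    "mean_diff": (s_vals - f_vals).mean(),
                    "t": float(t), "df": len(s_vals) - 1, "p": float(p),
                })
        table = pd.DataFrame(rows)
        self._write("circularity_control.tsv", table)
        self.results["circularity_control"] = table

    def ppi_stage(self) -> None:
        dataset = self.dataset
        if self.config.include_all_self_controllers:
            classification = self.results["classification"]
            one = classification[classification["mode"] == "one_criterion"]
            rates = dict(zip(one["participant_id"], one["success_rate"]))
            eligible = [s for s in dataset.subjects
                        if rates.get(s.subject_id, 0) > 0]
        else:
            eligible = [s for s in dataset.subjects
                        if self.labels[s.subject_id] == "SC"]
        if len(eligible) < 2:
            raise RuntimeError("not enough eligible subjects for PPI")
        dlpfc = dataset.masks["dlpfc"]
        beta_maps = []
        for subject in eligible:
            bold = subject.load_bold("decision")
            motion = subject.run_motion("decision", dataset.n_volumes_per_run)
            profile = subject.profile
            seed = ppi.extract_seed(bold, subject.events["decision"], profile,
                                    motion, dlpfc, dataset.tr)
            _, beta = ppi.run_ppi(bold, seed, subject.events["decision"],
                                  profile, motion, dataset.tr,
                                  affine=dataset.affine)
            beta_maps.append(beta)
        t_map, p_map, df = glm.group_ttest(beta_maps)
        table, _ = glm.threshold_map(p_map, "unc_005", t_map)
        table.insert(0, "analysis", "ppi1")
        self._write("ppi1_clusters.tsv", table)
        self.results["ppi1_clusters"] = table
        self.results["ppi1_t"] = t_map

        supported = False
        evidence = "no suprathreshold PPI1 cluster"
        ppi2_rows = []
        if len(table):
            top = table.sort_values("peak_stat", ascending=False).iloc[0]
            sphere = ppi.reseed_from_cluster(top, dataset.labels.shape,
                                             dataset.affine)
            beta_maps2 = []
            for subject in eligible:
                bold = subject.load_bold("decision")
                motion = subject.run_motion("decision",
                                            dataset.n_volumes_per_run)
                profile = subject.profile
                seed = ppi.sphere_series(bold, sphere, motion)
                _, beta = ppi.run_ppi(bold, seed, subject.events["decision"],
                                      profile, motion, dataset.tr,
                                      affine=dataset.affine)
                beta_maps2.append(beta)
            t2, p2, _ = glm.group_ttest(beta_maps2)
            table2, _ = glm.threshold_map(p2, "unc_005", t2)
            table2.insert(0, "analysis", "ppi2")
            ppi2_rows = table2
            self._write("ppi2_clusters.tsv", table2)
            self.results["ppi2_clusters"] = table2
            ifg = dataset.masks["ifg"]
            p_ifg = p_map.values[ifg.mask]
            supported = bool(np.any(p_ifg < 0.005))
            evidence = (f"PPI1 suprathreshold in IFG: {supported}; "
                        f"{len(table2)} PPI2 clusters")
        self._hypotheses["H4"] = {
            "statement": "dlPFC and vmPFC exhibit functional connectivity "
                         "during self-control",
            "supported": supported,
            "evidence": evidence,
        }

    def write_report(self) -> None:
        truth = self.dataset.ground_truth or {}
        amplitudes = truth.get("amplitudes", {})
        lines = ["# Hypothesis overview", "",
                 "| Hypothesis | Finding | Ground truth | Evidence |",
                 "|---|---|---|---|"]
        truth_map = {
            "H1": bool(amplitudes.get("SC", {}).get("vmpfc", {})
                       .get("decision_gv")),
            "H2": bool(amplitudes.get("SC", {}).get("vmpfc", {})
                       .get("decision_health")),
            "H3": bool(amplitudes.get("SC", {}).get("dlpfc", {})
                       .get("sc_success")),
            "H4": bool(amplitudes.get("SC", {}).get("ifg", {})
                       .get("ppi_unhealthy")),
        }
        rows = []
        for hyp in ("H1", "H2", "H3", "H4"):
            info = self._hypotheses.get(
                hyp, {"statement": "(stage skipped)", "supported": None,
                      "evidence": ""})
            verdict = {True: "supported", False: "not supported",
                       None: "not evaluated"}[info["supported"]]
            lines.append(
                f"| {hyp}: {info['statement']} | {verdict} | "
                f"{'effect simulated' if truth_map.get(hyp) else 'null'} | "
                f"{info['evidence']} |")
            rows.append({"hypothesis": hyp, "finding": verdict,
                         "truth": truth_map.get(hyp), **info})
        if not self._hypotheses:
            lines.append("| (no results) | | | |")
            warnings.warn("report generated from empty results", stacklevel=2)
        report_path = self.out / "report.md"
        report_path.write_text("\n".join(lines) + "\n")
        self.manifest.outputs["report.md"] = _sha256(report_path)
        self._write("hypotheses.tsv", pd.DataFrame(rows))

    # -- driver -----------------------------------------------------------

    def run(self) -> RunManifest:
        self._stage("load", self.load)
        self._stage("classify", self.classify, "load")
        self._stage("behavioral", self.behavioral, "classify")
        if "1" in self.config.glms:
            self._stage("glm1", self.glm1_group, "classify")
        if "2" in self.config.glms:
            self._stage("glm2", self.glm2_profiles, "glm1")
        if {"3a", "3b"} & set(self.config.glms):
            self._stage("glm3", self.glm3_encoding, "glm1")
        if "4" in self.config.glms:
            self._stage("glm4", self.glm4_group, "classify")
            self._stage("circularity", self.circularity_control, "glm4")
        if self.config.run_ppi:
            self._stage("ppi", self.ppi_stage, "classify")
        else:
            self.manifest.stages["ppi"] = {"status": "skipped",
                                           "reason": "disabled in config"}
        self._stage("report", self.write_report, "load")
        self.manifest.save(self.out / "manifest.json")
        return self.manifest


def run_pipeline(config: PipelineConfig) -> PipelineRun:
    """Execute the full analysis sequence; returns the run with its results."""
    run = PipelineRun(config)
    run.run()
    return run


def report(run: PipelineRun) -> str:
    """The hypothesis-overview report of a completed run."""
    path = Path(run.config.out_path) / "report.md"
    if not path.exists():
        warnings.warn("no report found; results may be empty", stacklevel=2)
        return ""
    return path.read_text()
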