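"""Readers for the BIDS-like dataset tree written by the generator."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .volumes import RegionMask

EVENTS_COLUMNS = ("onset", "duration", "trial_type", "stimulus_id", "response")
MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")


@dataclass
class SubjectRecord:
    """File handles and tables for one subject."""

    subject_id: str
    events: dict[str, pd.DataFrame]     # block -> events table
    bold_paths: dict[str, Path]         # block -> NIfTI path
    motion: np.ndarray                  # concatenated (3 runs) x 6
    block_order: list[str]
    issues: list[str] = field(default_factory=list)

    def load_bold(self, block: str) -> np.ndarray:
        return np.asarray(nib.load(str(self.bold_paths[block])).dataobj,
                          dtype=float)

    @property
    def profile(self) -> pd.DataFrame:
        return profile_from_events(self.events)

    def run_motion(self, block: str, n_volumes: int) -> np.ndarray:
        idx = self.block_order.index(block)
        return self.motion[idx * n_volumes:(idx + 1) * n_volumes]


@dataclass
class Dataset:
    path: Path
    participants: pd.DataFrame
    subjects: list[SubjectRecord]
    masks: dict[str, RegionMask]
    labels: np.ndarray
    affine: np.ndarray
    tr: float
    n_volumes_per_run: int
    ground_truth: dict | None = None

    def subject(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)


def profile_from_events(events: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Reassemble the per-stimulus rating profile from the three blocks."""
    cols = {}
    for block, rating in (("health", "health"), ("taste", "taste"),
                          ("decision", "gv")):
        ev = events[block]
        cols[rating] = ev.set_index("stimulus_id")["response"]
    frame = pd.DataFrame(cols)
    frame.index.name = "stimulus_id"
    return frame.reset_index()


def _read_events(path: Path) -> pd.DataFrame:
    ev = pd.read_csv(path, sep="\t", na_values=["n/a"])
    for col in EVENTS_COLUMNS:
        if col not in ev.columns:
            raise ValueError(f"events file {path} is missing column {col!r}")
    ev["response"] = ev["response"].astype(float)
    return ev


def read_dataset(path: str | Path, load_ground_truth: bool = True) -> Dataset:
    """Load a generated dataset, validating its structure.

    Malformed events tables raise naming the file and column; a subject's
    missing motion or BOLD files are recorded in the subject's ``issues``
    list rather than raising, so behavioral-only analyses still run.
    """
    path = Path(path)
    desc = json.loads((path / "dataset_description.json").read_text())
    participants = pd.read_csv(path / "participants.tsv", sep="\t")

    labels_img = nib.load(str(path / "masks" / "region_labels.nii.gz"))
    labels = np.asarray(labels_img.dataobj).astype(int)
    affine = labels_img.affine
    codes = json.loads((path / "masks" / "labels.json").read_text())
    masks = {}
    for name, code in codes.items():
        if code == 0:
            continue
        provenance = "white_matter" if name == "white_matter" else "anatomical"
        masks[name] = RegionMask(labels == code, name, affine, provenance)

    subjects = []
    for row in participants.itertuples():
        sub_id = row.participant_id
        func = path / sub_id / "func"
        first = row.first_block
        order = ([first, "taste" if first == "health" else "health",
                  "decision"])
        events: dict[str, pd.DataFrame] = {}
        bold_paths: dict[str, Path] = {}
        motions = []
        issues: list[str] = []
        for run_idx, block in enumerate(order, start=1):
            stem = f"{sub_id}_task-food_run-{run_idx:02d}"
            events_path = func / f"{stem}_events.tsv"
            if not events_path.exists():
                raise FileNotFoundError(f"missing events file {events_path}")
            ev = _read_events(events_path)
            if not (ev["trial_type"] == block).all():
                raise ValueError(
                    f"events file {events_path} mixes trial types; expected "
                    f"block {block!r}")
            events[block] = ev
            motion_path = func / f"{stem}_motion.tsv"
            if motion_path.exists():
                mot = pd.read_csv(motion_path, sep="\t")
                missing = [c for c in MOTION_COLUMNS if c not in mot.columns]
                if missing:
                    raise ValueError(
                        f"motion file {motion_path} is missing columns "
                        f"{missing}")
                motions.append(mot[list(MOTION_COLUMNS)].to_numpy())
            else:
                issues.append(f"missing motion for run {run_idx}")
                motions.append(np.zeros((desc["n_volumes_per_run"], 6)))
            bold_path = func / f"{stem}_bold.nii.gz"
            if bold_path.exists():
                bold_paths[block] = bold_path
            else:
                issues.append(f"missing BOLD for run {run_idx}")
        subjects.append(SubjectRecord(sub_id, events, bold_paths,
                                      np.vstack(motions), order, issues))

    truth = None
    truth_path = path / "ground_truth.json"
    if load_ground_truth and truth_path.exists():
        truth = json.loads(truth_path.read_text())
    return Dataset(path, participants, subjects, masks, labels, affine,
                   float(desc["tr"]), int(desc["n_volumes_per_run"]), truth)
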