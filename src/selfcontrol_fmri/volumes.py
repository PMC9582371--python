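"""Volume containers: statistical maps and region masks on the common grid."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np


@dataclass
class VolumeMap:
    """A 3D statistic or beta image defined on an analysis mask.

    Values outside the mask are NaN. ``kind`` is one of ``beta``, ``t``, ``p``.
    """

    values: np.ndarray
    affine: np.ndarray
    mask: np.ndarray
    kind: str = "beta"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match mask shape "
                f"{self.mask.shape}"
            )

    @classmethod
    def from_flat(cls, flat: np.ndarray, mask: np.ndarray, affine: np.ndarray,
                  kind: str = "beta", **meta) -> "VolumeMap":
        """Build a map from values listed in C order over the mask voxels."""
        mask = np.asarray(mask, dtype=bool)
        vol = np.full(mask.shape, np.nan)
        vol[mask] = np.asarray(flat, dtype=float)
        return cls(vol, np.asarray(affine), mask, kind, dict(meta))

    @property
    def flat(self) -> np.ndarray:
        """Values over the mask, in C voxel order."""
        return self.values[self.mask]

    def same_grid(self, other: "VolumeMap") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.allclose(self.affine, other.affine)
        )

    def save(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.values.astype(np.float32), self.affine)
        nib.save(img, str(path))
        meta = {"kind": self.kind, **self.meta}
        Path(str(path).replace(".nii.gz", "").replace(".nii", "") + ".json").write_text(
            json.dumps(meta, indent=2, default=str)
        )


@dataclass
class RegionMask:
    """Binary region mask on the common grid."""

    mask: np.ndarray
    label: str
    affine: np.ndarray
    provenance: str = "anatomical"

    _PROVENANCES = (
        "functional", "meta_analytic", "anatomical", "white_matter", "sphere",
    )

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.provenance not in self._PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if not self.mask.any():
            raise ValueError(f"mask {self.label!r} is empty")

    @property
    def size(self) -> int:
        return int(self.mask.sum())

    def indices(self) -> np.ndarray:
        """(n, 3) voxel indices of the mask, in C order."""
        return np.argwhere(self.mask)

    def save(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.mask.astype(np.uint8), self.affine)
        nib.save(img, str(path))

    @classmethod
    def load(cls, path: str | Path, label: str,
             provenance: str = "anatomical") -> "RegionMask":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj) > 0, label, img.affine, provenance)


def voxel_to_mm(ijk: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """World (mm) coordinates of voxel indices under an affine."""
    ijk = np.atleast_2d(ijk)
    xyz = affine[:3, :3] @ ijk.T + affine[:3, 3:4]
    return xyz.T.squeeze()


def mm_to_voxel(xyz: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Nearest voxel indices of world coordinates (mm)."""
    xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
    ijk = np.linalg.inv(affine[:3, :3]) @ (xyz.T - affine[:3, 3:4])
    return np.rint(ijk.T.squeeze()).astype(int)
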