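"""ROI masks and per-subject condition t-value patterns.

Masks are built from second-level cluster tables and applied to each
subject's (non-smoothed) first-level fit, extracting the condition-versus-
baseline t statistic at every ROI voxel in a fixed lexicographic voxel
order shared across subjects and conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .glm import Cluster, GLMResult
from .synth import CONDITIONS


@dataclass
class ROIMask:
    name: str
    mask: np.ndarray  # 3D boolean
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")
        if not self.mask.any():
            raise ValueError(f"ROI {self.name!r} is empty")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def voxel_indices(self) -> np.ndarray:
        """(N, 3) coordinates in deterministic lexicographic order."""
        return np.argwhere(self.mask)

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.mask.astype(np.uint8), self.affine)


def mask_from_cluster(cluster: Cluster, shape: tuple[int, int, int],
                      affine: np.ndarray, name: str) -> ROIMask:
    """Boolean mask with exactly the cluster's voxels set."""
    if cluster.size == 0 or len(cluster.voxels) == 0:
        raise ValueError("cannot build an ROI from an empty cluster")
    voxels = np.asarray(cluster.voxels)
    if (voxels < 0).any() or (voxels >= np.asarray(shape)).any():
        raise ValueError("cluster voxels fall outside the grid")
    mask = np.zeros(shape, dtype=bool)
    mask[tuple(voxels.T)] = True
    return ROIMask(name=name, mask=mask, affine=affine)


def save_mask(mask: ROIMask, path) -> None:
    nib.save(mask.to_nifti(), str(path))


def load_mask(path, name: str | None = None) -> ROIMask:
    img = nib.load(str(path))
    return ROIMask(name=name or str(path),
                   mask=np.asarray(img.dataobj) > 0.5,
                   affine=img.affine)


def save_map(arr: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine), str(path))


def load_map(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine


@dataclass
class PatternMatrix:
    """subjects x conditions x voxels t-values inside one ROI."""

    data: np.ndarray
    subjects: list
    condition_order: tuple[str, ...]
    roi: ROIMask

    def __post_init__(self) -> None:
        s, c, v = self.data.shape
        if c != len(self.condition_order):
            raise ValueError("condition dimension mismatch")
        if v != self.roi.voxel_count:
            raise ValueError("voxel dimension must equal the ROI voxel count")
        if np.isnan(self.data).any():
            raise ValueError("pattern matrix contains missing entries")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    def to_tidy(self) -> pd.DataFrame:
        s, c, v = self.data.shape
        return pd.DataFrame({
            "subject": np.repeat(self.subjects, c * v),
            "condition": np.tile(np.repeat(self.condition_order, v), s),
            "voxel_index": np.tile(np.arange(v), s * c),
            "t": self.data.ravel(),
        })


def extract_patterns(first_level_results: Mapping[object, GLMResult],
                     roi: ROIMask,
                     conditions: Sequence[str] = CONDITIONS) -> PatternMatrix:
    """Extract condition-vs-baseline t values at each ROI voxel for every
    subject, from non-smoothed first-level fits.

    Voxel order is lexicographic by index and identical across subjects and
    conditions. Zero-variance voxels inside the ROI contribute t = 0 (with a
    warning) so the voxel alignment is preserved.
    """
    subjects = list(first_level_results)
    if not subjects:
        raise ValueError("no first-level results supplied")
    idx = tuple(roi.voxel_indices.T)
    data = np.empty((len(subjects), len(conditions), roi.voxel_count))
    for s, subject in enumerate(subjects):
        res = first_level_results[subject]
        if res.shape != roi.mask.shape:
            raise ValueError(f"subject {subject!r} grid {res.shape} does not "
                             f"match ROI grid {roi.mask.shape}")
        for c, cond in enumerate(conditions):
            try:
                tmap = res.t_map(cond)
            except KeyError:
                raise KeyError(f"condition {cond!r} missing for subject "
                               f"{subject!r}") from None
            data[s, c] = tmap[idx]
        if res.degenerate[idx].any():
            warnings.warn(f"subject {subject!r}: zero-variance voxel(s) inside "
                          f"ROI {roi.name!r} imputed with t = 0", stacklevel=2)
    return PatternMatrix(data=data, subjects=subjects,
                         condition_order=tuple(conditions), roi=roi)


def patterns_to_tsv(patterns: PatternMatrix, path) -> None:
    patterns.to_tidy().to_csv(path, sep="\t", index=False)
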