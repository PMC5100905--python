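"""Lesion volumetrics: total and per-tract WMH volumes, prevalence maps.

Volumes are computed in template space ("normalized volumes"): voxel count
times the voxel volume implied by the affine, reported in millilitres.
Overlapping tract ROIs each receive the full contribution of a shared
voxel, so per-ROI volumes may sum to more than the total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CohortGridError, LesionMap, TractROISet

__all__ = [
    "PrevalenceMap",
    "lesion_volume_ml",
    "regional_volume_table",
    "prevalence_map",
    "tested_voxel_mask",
]


@dataclass
class PrevalenceMap:
    """Per-voxel count of subjects with a lesion there."""

    counts: np.ndarray
    n_subjects: int
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.min() < 0 or self.counts.max() > self.n_subjects:
            raise ValueError("prevalence counts out of [0, n_subjects]")


def lesion_volume_ml(lesion: LesionMap, mask: np.ndarray | None = None) -> float:
    """WMH volume in ml, optionally restricted to a binary mask."""
    if mask is None:
        count = lesion.n_lesioned
    else:
        mask = np.asarray(mask)
        if mask.shape != lesion.shape:
            raise CohortGridError(
                f"mask shape {mask.shape} does not match lesion map {lesion.shape}"
            )
        count = int((lesion.data.astype(bool) & mask.astype(bool)).sum())
    return count * lesion.voxel_volume_mm3 / 1000.0


def regional_volume_table(maps: Sequence[LesionMap], rois: TractROISet) -> pd.DataFrame:
    """Per-subject total and per-ROI WMH volumes (ml), one row per subject."""
    if len(maps) == 0:
        raise ValueError("no lesion maps given")
    if rois.shape != maps[0].shape:
        raise CohortGridError("ROI grid does not match lesion-map grid")
    for m in maps:
        if m.shape != maps[0].shape:
            raise CohortGridError(f"subject {m.subject_id}: grid mismatch")
    # voxel counts via one matrix product: subjects x voxels @ voxels x ROIs
    lesions = np.stack([m.data.ravel() for m in maps]).astype(np.float32)
    roi_mat = np.stack(
        [rois[name].ravel() for name in rois.roi_names], axis=1
    ).astype(np.float32)
    counts = lesions @ roi_mat
    ml = np.array([m.voxel_volume_mm3 for m in maps])[:, None] / 1000.0
    table = pd.DataFrame(
        counts * ml, columns=[f"wmh_{name}_ml" for name in rois.roi_names]
    )
    table.insert(0, "total_wmh_ml", lesions.sum(axis=1) * ml[:, 0])
    table.insert(0, "subject_id", [m.subject_id for m in maps])
    return table


def prevalence_map(maps: Sequence[LesionMap]) -> PrevalenceMap:
    """Voxelwise count of lesioned subjects across the cohort."""
    if len(maps) == 0:
        raise ValueError("prevalence map requires at least one lesion map")
    ref = maps[0]
    counts = np.zeros(ref.shape, dtype=np.int32)
    for m in maps:
        if m.shape != ref.shape or not np.allclose(m.affine, ref.affine, atol=1e-4):
            raise CohortGridError(f"subject {m.subject_id}: grid mismatch")
        counts += m.data
    return PrevalenceMap(counts=counts, n_subjects=len(maps), affine=ref.affine)


def tested_voxel_mask(prev: PrevalenceMap, min_subjects: int = 10) -> np.ndarray:
    """Voxels lesioned in at least ``min_subjects`` subjects.

    Voxels below the cutoff are excluded from voxelwise testing: with very
    few lesioned subjects the two-sample comparison at that voxel has no
    power and inflates the multiple-testing family.
    """
    if min_subjects < 1:
        raise ValueError("min_subjects must be >= 1")
    return prev.counts >= min_subjects
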