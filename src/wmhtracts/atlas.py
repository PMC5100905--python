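"""Probabilistic tract atlas -> binary bilateral-merged ROIs.

The tract-screening analyses use 11 major white-matter tracts (JHU-style
atlas), thresholded at 10% probability and with left/right homologues
merged into one region of interest each.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import yaml

from .io import ProbabilisticAtlas, TractROISet

__all__ = [
    "CANONICAL_TRACTS",
    "threshold_atlas",
    "merge_bilateral",
    "load_pairing",
]

#: The 11 bilateral-merged tract ROIs, in canonical reporting order.
CANONICAL_TRACTS = (
    "forceps_minor",
    "anterior_thalamic_radiation",
    "uncinate_fasciculus",
    "inferior_fronto_occipital_fasciculus",
    "cingulum_cingulate_gyrus",
    "inferior_longitudinal_fasciculus",
    "corticospinal_tract",
    "forceps_major",
    "superior_longitudinal_fasciculus",
    "superior_longitudinal_fasciculus_temporal",
    "cingulum_hippocampus",
)

#: Tracts that run through the midline and exist as a single atlas volume.
MIDLINE_TRACTS = ("forceps_minor", "forceps_major")


def threshold_atlas(atlas: ProbabilisticAtlas, threshold_pct: float = 10.0) -> TractROISet:
    """Binarize each tract's probability volume at ``threshold_pct`` percent.

    A voxel belongs to a tract ROI iff its probability is **at or above**
    the threshold (inclusive boundary). The atlas probability scale
    (fraction vs percent) is auto-detected.
    """
    if not 0 < threshold_pct < 100:
        raise ValueError("threshold_pct must be in (0, 100)")
    cut = threshold_pct * atlas.max_scale / 100.0
    masks = {}
    for i, name in enumerate(atlas.tract_names):
        mask = atlas.data[..., i] >= cut
        if not mask.any():
            warnings.warn(
                f"tract {name!r} has no voxel at or above {threshold_pct}%; "
                "empty ROI retained",
                stacklevel=2,
            )
        masks[name] = mask
    return TractROISet(
        roi_names=list(atlas.tract_names),
        masks=masks,
        affine=atlas.affine,
        threshold_pct=float(threshold_pct),
    )


def merge_bilateral(
    roi_set: TractROISet,
    pairing: Mapping[str, Sequence[str]] | None = None,
) -> TractROISet:
    """Merge left/right tract masks into single bilateral ROIs.

    ``pairing`` maps each merged name to the constituent mask names — two
    for bilateral tracts, one for midline tracts (forceps minor/major).
    The merged mask is the voxelwise union. With the default pairing, the
    output carries the 11 canonical tract ROIs in canonical order.
    """
    if pairing is None:
        pairing = default_pairing(roi_set.roi_names)
    masks = {}
    for merged, parts in pairing.items():
        if isinstance(parts, str):
            parts = [parts]
        unknown = [p for p in parts if p not in roi_set.masks]
        if unknown:
            raise KeyError(
                f"pairing for {merged!r} references unknown tract(s) {unknown}; "
                f"available: {sorted(roi_set.roi_names)}"
            )
        union = np.zeros(roi_set.shape, dtype=bool)
        for p in parts:
            union |= roi_set.masks[p]
        masks[merged] = union
    return TractROISet(
        roi_names=list(pairing.keys()),
        masks=masks,
        affine=roi_set.affine,
        threshold_pct=roi_set.threshold_pct,
    )


def default_pairing(available: Sequence[str]) -> dict[str, list[str]]:
    """Canonical pairing for masks named ``<tract>_l`` / ``<tract>_r``."""
    pairing: dict[str, list[str]] = {}
    for tract in CANONICAL_TRACTS:
        if tract in MIDLINE_TRACTS:
            parts = [tract]
        else:
            parts = [f"{tract}_l", f"{tract}_r"]
        missing = [p for p in parts if p not in available]
        if missing:
            raise KeyError(
                f"cannot build default pairing: {missing} not among atlas tracts"
            )
        pairing[tract] = parts
    return pairing


def load_pairing(path) -> dict[str, list[str]]:
    with open(path) as fh:
        pairing = yaml.safe_load(fh)
    return {k: ([v] if isinstance(v, str) else list(v)) for k, v in pairing.items()}
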