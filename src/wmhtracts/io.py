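"""Domain containers and NIfTI / tabular readers.

All volumetric analysis happens on binary lesion maps that have already been
registered to a common template space (MNI-152 in the motivating cohort).
The containers here enforce the two invariants everything downstream relies
on: lesion maps are strictly {0,1}, and every map in a cohort lives on the
same voxel grid (shape + affine).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LesionMap",
    "ProbabilisticAtlas",
    "TractROISet",
    "CohortGridError",
    "read_lesion_map",
    "read_lesion_maps",
    "write_lesion_map",
    "read_atlas",
    "read_cohort_table",
    "load_variable_map",
]

#: Canonical subject-table fields the analyses may require.
CANONICAL_FIELDS = (
    "subject_id",
    "age",
    "sex",
    "education",
    "lacunes_present",
    "microbleeds_present",
    "fazekas",
    "bpf",
    "diagnosis",
)


class CohortGridError(ValueError):
    """Raised when volumes in one cohort disagree on shape or affine."""


def _voxel_volume_mm3(affine: np.ndarray) -> float:
    vol = float(abs(np.linalg.det(np.asarray(affine)[:3, :3])))
    if vol <= 0:
        raise ValueError("affine has a singular 3x3 block; voxel volume undefined")
    return vol


@dataclass
class LesionMap:
    """One subject's binary lesion map in template space.

    ``data`` holds uint8 values in {0, 1}; ``affine`` is the voxel-to-world
    (mm) transform carried over from the NIfTI header.
    """

    subject_id: str
    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"lesion map must be 3-D, got ndim={self.data.ndim}")
        if not np.isin(self.data, (0, 1)).all():
            raise ValueError("lesion map contains values outside {0,1}")
        self.data = self.data.astype(np.uint8)
        _voxel_volume_mm3(self.affine)  # validates

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return _voxel_volume_mm3(self.affine)

    @property
    def n_lesioned(self) -> int:
        return int(self.data.sum())


@dataclass
class ProbabilisticAtlas:
    """A stack of per-tract probability volumes on one grid.

    Probabilities may be stored as fractions (0-1) or percent (0-100); the
    scale is auto-detected from the data maximum and exposed via
    ``max_scale`` so thresholding can be expressed in percent regardless.
    """

    tract_names: list[str]
    data: np.ndarray  # 4-D, last axis indexes tracts
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("atlas data must be 4-D (x, y, z, tract)")
        if self.data.shape[-1] != len(self.tract_names):
            raise ValueError("number of tract names does not match 4th axis")
        if len(set(self.tract_names)) != len(self.tract_names):
            raise ValueError("tract names must be unique")
        if not np.isfinite(self.data).all():
            raise ValueError("atlas contains non-finite probabilities")
        if self.data.min() < 0:
            raise ValueError("atlas contains negative probabilities")

    @property
    def max_scale(self) -> float:
        """100.0 when probabilities are stored in percent, 1.0 for fractions."""
        return 1.0 if self.data.max() <= 1.0 else 100.0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class TractROISet:
    """Named binary ROI masks on one grid; ROIs may overlap."""

    roi_names: list[str]
    masks: dict[str, np.ndarray] = field(repr=False)
    affine: np.ndarray = field(repr=False, default=None)
    threshold_pct: float = 10.0

    def __post_init__(self) -> None:
        if len(set(self.roi_names)) != len(self.roi_names):
            raise ValueError("ROI names must be unique")
        for name in self.roi_names:
            m = np.asarray(self.masks[name])
            if not np.isin(m, (0, 1)).all():
                raise ValueError(f"ROI mask {name!r} is not binary")
            self.masks[name] = m.astype(bool)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __iter__(self):
        return iter(self.roi_names)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.masks[self.roi_names[0]].shape


def _check_grid(shape, affine, ref_shape, ref_affine, label: str) -> None:
    if ref_shape is not None and (
        tuple(shape) != tuple(ref_shape) or not np.allclose(affine, ref_affine, atol=1e-4)
    ):
        raise CohortGridError(
            f"{label}: shape/affine mismatch with the cohort grid "
            f"(got shape {tuple(shape)}, expected {tuple(ref_shape)})"
        )


def read_lesion_map(path: str | Path, subject_id: str | None = None) -> LesionMap:
    """Read one NIfTI lesion volume and binarize it at > 0.5.

    The > 0.5 rule makes the reader robust to interpolation dust left behind
    by resampling of genuinely binary segmentations.
    """
    path = Path(path)
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj, dtype=float)
    if arr.ndim == 4 and arr.shape[3] == 1:
        arr = arr[..., 0]
    if not np.isfinite(arr).all():
        raise ValueError(f"{path}: non-finite voxel values")
    sid = subject_id if subject_id is not None else path.name.split(".")[0]
    return LesionMap(subject_id=sid, data=(arr > 0.5).astype(np.uint8), affine=img.affine)


def read_lesion_maps(paths: Sequence[str | Path]) -> list[LesionMap]:
    """Read a cohort of lesion maps, enforcing a shared grid."""
    maps: list[LesionMap] = []
    ref_shape = ref_affine = None
    for p in paths:
        m = read_lesion_map(p)
        _check_grid(m.shape, m.affine, ref_shape, ref_affine, str(p))
        if ref_shape is None:
            ref_shape, ref_affine = m.shape, m.affine
        maps.append(m)
    return maps


def write_lesion_map(m: LesionMap, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(m.data.astype(np.uint8), m.affine), str(path))


def read_atlas(source: str | Path, tract_names: Sequence[str] | None = None) -> ProbabilisticAtlas:
    """Read a probabilistic tract atlas.

    ``source`` is either a 4-D NIfTI file (``tract_names`` then names the
    volumes along the 4th axis) or a directory of per-tract 3-D NIfTI files,
    in which case the file stems are the tract names.
    """
    source = Path(source)
    if source.is_dir():
        files = sorted(
            [p for p in source.iterdir() if p.name.endswith((".nii", ".nii.gz"))]
        )
        if not files:
            raise FileNotFoundError(f"no NIfTI files in atlas directory {source}")
        vols, names, affine = [], [], None
        for f in files:
            img = nib.load(str(f))
            arr = np.asanyarray(img.dataobj, dtype=float)
            if affine is None:
                affine = img.affine
            else:
                _check_grid(arr.shape, img.affine, vols[0].shape, affine, str(f))
            vols.append(arr)
            names.append(f.name.split(".")[0])
        return ProbabilisticAtlas(names, np.stack(vols, axis=-1), affine)
    img = nib.load(str(source))
    arr = np.asanyarray(img.dataobj, dtype=float)
    if arr.ndim != 4:
        raise ValueError("single-file atlas must be 4-D")
    if tract_names is None:
        tract_names = [f"tract_{i:02d}" for i in range(arr.shape[-1])]
    return ProbabilisticAtlas(list(tract_names), arr, img.affine)


def write_atlas(atlas: ProbabilisticAtlas, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(atlas.data.astype(np.float32), atlas.affine), str(path))


def load_variable_map(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


# Values treated as missing in subject tables on top of genuine NaN.
_MISSING_CODES = {"", "NA", "N/A", "na", "nan", "-999", -999, 999, "999"}


def _coerce_binary(series: pd.Series, recode: Mapping | None = None) -> pd.Series:
    s = series.copy()
    if recode:
        s = s.map(lambda v: recode.get(v, recode.get(str(v), v)) if pd.notna(v) else v)
    out = pd.to_numeric(s, errors="coerce")
    bad = out.dropna()[~out.dropna().isin([0, 1])]
    if len(bad):
        raise ValueError(
            f"column {series.name!r}: values {sorted(set(bad))} are not 0/1; "
            "provide a 'recode' mapping in the variable map"
        )
    return out


def read_cohort_table(
    path: str | Path,
    variable_map: Mapping | None = None,
    required: Sequence[str] = ("subject_id", "age", "sex", "education"),
) -> pd.DataFrame:
    """Read a subject table (CSV or SPSS .sav) into canonical columns.

    ``variable_map`` maps canonical names (see :data:`CANONICAL_FIELDS`) to
    the file's column names; entries may instead be ``{"column": name,
    "recode": {raw: 0/1}}`` for labelled categorical columns. Missing-value
    codes are normalised to NaN; sex and lesion-presence flags are coerced
    to 0/1.
    """
    path = Path(path)
    if path.suffix.lower() == ".sav":
        try:
            raw = pd.read_spss(str(path))
        except ImportError as exc:  # pragma: no cover - depends on env
            raise ImportError(
                "reading SPSS .sav files requires the optional dependency "
                "'pyreadstat'; export the table to CSV instead"
            ) from exc
    else:
        raw = pd.read_csv(path)

    variable_map = dict(variable_map or {})
    out = pd.DataFrame(index=raw.index)
    binary_fields = {"sex", "lacunes_present", "microbleeds_present"}
    missing_cols = []
    for canon in CANONICAL_FIELDS:
        spec = variable_map.get(canon, canon)
        recode = None
        if isinstance(spec, Mapping):
            recode = spec.get("recode")
            spec = spec["column"]
        if spec not in raw.columns:
            if canon in required:
                missing_cols.append(f"{canon} (looked for column {spec!r})")
            continue
        col = raw[spec].replace(list(_MISSING_CODES), np.nan)
        if canon in binary_fields:
            col = _coerce_binary(col, recode)
        elif canon not in ("subject_id", "diagnosis"):
            col = pd.to_numeric(col, errors="coerce")
        out[canon] = col
    if missing_cols:
        raise KeyError(
            "variable map does not cover required fields: " + ", ".join(missing_cols)
        )
    # carry through any extra columns (subtests, volumes) untouched
    mapped = {
        (spec["column"] if isinstance(spec, Mapping) else spec)
        for spec in (variable_map.get(c, c) for c in CANONICAL_FIELDS)
    }
    for col in raw.columns:
        if col not in mapped and col not in out.columns:
            out[col] = raw[col].replace(list(_MISSING_CODES), np.nan)
    if "subject_id" in out.columns:
        out["subject_id"] = out["subject_id"].astype(str)
        if out["subject_id"].duplicated().any():
            raise ValueError("duplicate subject_id in cohort table")
    return out
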